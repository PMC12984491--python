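import numpy as np
import pytest

from cardiovcg.ecg_io import LEAD_NAMES, EcgRecord


def gaussian(t, center, sigma, amp):
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def make_synthetic_lead(
    fs=500.0,
    duration_s=10.0,
    rr_s=1.0,
    p_amp=0.15,
    r_amp=1.0,
    t_amp=0.3,
    p_center=-0.18,
    t_center=0.30,
    p_sigma=0.025,
    t_sigma=0.05,
):
    """Single-lead beat train: Gaussian P and T, narrow triangular R."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    r_times = np.arange(0.5, duration_s - 0.3, rr_s)
    for rt in r_times:
        x += gaussian(t, rt + p_center, p_sigma, p_amp)
        x += gaussian(t, rt + t_center, t_sigma, t_amp)
        x += gaussian(t, rt, 0.008, r_amp)
    return x, (r_times * fs).round().astype(int)


@pytest.fixture
def zero_record():
    n = 5000
    leads = {name: np.zeros(n) for name in LEAD_NAMES}
    return EcgRecord(
        record_id="zeros", patient_id="p0", sampling_rate=500.0, leads=leads
    )


@pytest.fixture(scope="session")
def preset_catalog():
    from cardiovcg.synth_cohort import preset_profiles

    return preset_profiles()


@pytest.fixture(scope="session")
def small_cohort(preset_catalog):
    """Tiny mixed cohort reused by several pipeline tests."""
    from dataclasses import replace

    from cardiovcg.synth_cohort import generate_cohort

    profiles = [
        replace(preset_catalog["HCM"], n_records=5),
        replace(preset_catalog["DCM-I"], n_records=5),
    ]
    return generate_cohort(profiles, seed=101)
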