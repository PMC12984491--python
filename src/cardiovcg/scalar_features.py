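"""Per-lead amplitude, interval, spectral and moment features.

Amplitudes are referenced to the isoelectric PR baseline of each beat.  R, P
and T amplitudes are signed; Q and S are reported as the absolute magnitude
of their negative deflection.  Durations come from the fixed global windows
and are not rate-corrected.  Spectral moments use a single-taper periodogram
of the linearly detrended signal with the DC bin excluded; time-domain
moments are computed on the full cleaned lead signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.signal import butter, periodogram, sosfiltfilt

from .ecg_io import LEAD_NAMES, EcgRecord
from .delineate import FiducialSet, GlobalWindows
from .vcg_features import VCG_FEATURE_NAMES

RS_FLOOR_MV = 0.01
CLEAN_LOWPASS_HZ = 40.0


class FeatureError(Exception):
    pass


def clean_signal(
    signal: np.ndarray, fs: float, band: tuple[float, float] = (0.5, CLEAN_LOWPASS_HZ)
) -> np.ndarray:
    """Zero-phase band-pass cleaning filter (detection-stage cleaning).

    Note the high-pass leg removes the mean, so inter-wave segments sit at
    minus the mean wave area rather than at zero; downstream processing
    therefore prefers :func:`clean_signal_anchored` once beat anchors are
    known.
    """
    sos = butter(3, band, btype="band", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def clean_signal_anchored(
    signal: np.ndarray, fs: float, anchors, smooth_ms: float = 4.0
) -> np.ndarray:
    """Gaussian smoothing plus knot-interpolated baseline removal.

    A Gaussian smoother (sigma = ``smooth_ms``) is used instead of a sharp
    low-pass because its monotone kernel cannot ring: Butterworth-style
    filters leave Gibbs dips around steep QRS edges that masquerade as Q/S
    waves.  One baseline node per beat is taken from the PR gap (median
    around 80 ms before each R anchor) and linearly interpolated;
    subtracting it keeps inter-wave segments at a true isoelectric zero,
    which a DC-removing high-pass cannot (it leaves them at minus the mean
    wave area).  Baseline wander slower than the beat rate is captured by
    the nodes.
    """
    from scipy.ndimage import gaussian_filter1d

    x = np.asarray(signal, dtype=float)
    y = gaussian_filter1d(x, sigma=smooth_ms * fs / 1000.0 / 2.0)
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size == 0:
        return clean_signal(x, fs)
    ms = fs / 1000.0
    nodes_t, nodes_v = [], []
    for a in anchors:
        lo, hi = int(a - 95 * ms), int(a - 60 * ms)
        if lo < 0 or hi > len(y) or hi <= lo + 3:
            continue
        w = y[lo:hi]
        # the window can clip a P-wave tail when the anchor sits late in the
        # QRS; gap samples are flat, wave samples slope, so estimate the
        # node from the flattest half
        grad = np.abs(np.gradient(w))
        flat = w[grad <= np.median(grad)]
        nodes_t.append((lo + hi) // 2)
        nodes_v.append(float(np.median(flat if flat.size else w)))
    if len(nodes_t) < 2:
        return clean_signal(x, fs)
    # a node from a misanchored beat (e.g. one truncated at the record edge)
    # can land on a wave: clamp outliers to the consensus level
    vals = np.asarray(nodes_v)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    tol = max(0.05, 5.0 * mad)
    vals = np.where(np.abs(vals - med) > tol, med, vals)
    baseline = np.interp(np.arange(len(y)), nodes_t, vals)
    return y - baseline


def pr_baseline(signal: np.ndarray, fiducials: FiducialSet, beat: int, fs: float) -> float | None:
    """Mean of the [P_off, QRS_on) segment; falls back to the 40-10 ms
    pre-QRS window, and to missing when QRS_on is unknown."""
    x = np.asarray(signal, dtype=float)
    b = fiducials.beats[beat]
    p_off, qrs_on = b.get("P_off"), b.get("QRS_on")
    if p_off is not None and qrs_on is not None and qrs_on > p_off:
        return float(np.mean(x[p_off:qrs_on]))
    if qrs_on is None:
        return None
    lo = max(0, qrs_on - int(round(0.040 * fs)))
    hi = max(lo + 1, qrs_on - int(round(0.010 * fs)))
    return float(np.mean(x[lo:hi]))


def wave_amplitudes(
    signal: np.ndarray, fiducials: FiducialSet, fs: float
) -> dict[str, float | None]:
    """Median per-beat peak amplitudes vs the PR baseline for one lead."""
    x = np.asarray(signal, dtype=float)
    per_wave: dict[str, list[float]] = {w: [] for w in ("P", "Q", "R", "S", "T")}
    for i, b in enumerate(fiducials.beats):
        base = pr_baseline(x, fiducials, i, fs)
        if base is None:
            continue
        for wave, landmark in (("P", "P_peak"), ("Q", "Q_peak"), ("R", "R_peak"),
                               ("S", "S_peak"), ("T", "T_peak")):
            idx = b.get(landmark)
            if idx is None:
                continue
            amp = x[idx] - base
            if wave in ("Q", "S"):
                amp = abs(min(amp, 0.0))
            per_wave[wave].append(float(amp))
    return {
        w: (float(np.median(v)) if v else None) for w, v in per_wave.items()
    }


def rs_ratio(r_amp: float | None, s_amp: float | None, floor: float = RS_FLOOR_MV) -> float | None:
    if r_amp is None:
        return None
    denom = max(s_amp if s_amp is not None else 0.0, floor)
    return r_amp / denom


def interval_features(
    fiducial_sets: Mapping[str, FiducialSet],
    global_windows: GlobalWindows,
    fs: float,
    r_peaks: Sequence[int],
) -> dict[str, float | None]:
    """Global interval/duration features in ms (not rate-corrected)."""
    gw = global_windows
    out: dict[str, float | None] = {}
    has_p = gw.P_on_rel is not None and gw.P_off_rel is not None
    out["p_duration_ms"] = (gw.P_off_rel - gw.P_on_rel) if has_p else None
    out["pr_interval_ms"] = (gw.QRS_on_rel - gw.P_on_rel) if has_p else None
    out["qrs_duration_ms"] = gw.QRS_off_rel - gw.QRS_on_rel
    out["qt_interval_ms"] = gw.T_off_rel - gw.QRS_on_rel
    out["t_duration_ms"] = gw.T_off_rel - gw.T_on_rel

    t_peak_rel = _pooled_landmark_rel(fiducial_sets, "T_peak", fs)
    if t_peak_rel is not None:
        up = t_peak_rel - gw.T_on_rel
        down = gw.T_off_rel - t_peak_rel
        out["t_upslope_ms"] = up
        out["t_downslope_ms"] = down
        out["t_index"] = up / down if down > 0 else None
    else:
        out["t_upslope_ms"] = out["t_downslope_ms"] = out["t_index"] = None

    # representative-beat frame starts 40 ms before the global P-onset
    if has_p:
        frame0 = gw.P_on_rel - 40.0
        out["frame_qrs_onset_ms"] = gw.QRS_on_rel - frame0
        out["frame_qrs_end_ms"] = gw.QRS_off_rel - frame0
    else:
        out["frame_qrs_onset_ms"] = out["frame_qrs_end_ms"] = None

    r = np.asarray(r_peaks, dtype=float)
    if len(r) >= 2:
        rr = np.diff(r) * 1000.0 / fs
        out["median_rr_ms"] = float(np.median(rr))
        out["heart_rate_bpm"] = 60000.0 / out["median_rr_ms"]
    else:
        out["median_rr_ms"] = out["heart_rate_bpm"] = None
    return out


def _pooled_landmark_rel(
    fiducial_sets: Mapping[str, FiducialSet], name: str, fs: float
) -> float | None:
    meds = []
    for fset in fiducial_sets.values():
        offs = fset.landmark_offsets(name)
        if len(offs):
            meds.append(float(np.median(offs)))
    if not meds:
        return None
    return float(np.median(meds)) * 1000.0 / fs


def spectral_features(signal: np.ndarray, fs: float) -> dict[str, float | None]:
    """Power-weighted spectral mean / spread / skewness (DC bin excluded)."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise FeatureError("need at least 2 s of signal for spectral features")
    freqs, psd = periodogram(x, fs=fs, detrend="linear")
    freqs, psd = freqs[1:], psd[1:]
    total = float(np.sum(psd))
    if total <= 1e-18:
        return {"spectral_mean_hz": None, "spectral_spread_hz": None, "spectral_skewness": None}
    w = psd / total
    mean = float(np.sum(freqs * w))
    var = float(np.sum((freqs - mean) ** 2 * w))
    spread = np.sqrt(var)
    skew = float(np.sum((freqs - mean) ** 3 * w)) / spread**3 if spread > 0 else None
    return {"spectral_mean_hz": mean, "spectral_spread_hz": spread, "spectral_skewness": skew}


def moment_features(signal: np.ndarray) -> dict[str, float | None]:
    """Time-domain skewness and excess kurtosis of the full lead signal."""
    x = np.asarray(signal, dtype=float)
    if len(np.unique(x)) < 2 or np.std(x) == 0:
        return {"skewness": None, "excess_kurtosis": None}
    return {
        "skewness": float(stats.skew(x)),
        "excess_kurtosis": float(stats.kurtosis(x, fisher=True)),
    }


# ---------------------------------------------------------------------------
# Registry and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    unit: str
    family: str


def build_registry(
    machine_numeric_names: Sequence[str] = (),
    machine_flag_names: Sequence[str] = (),
) -> list[FeatureSpec]:
    """The ordered feature registry (names unique, units documented)."""
    reg: list[FeatureSpec] = []
    for lead in LEAD_NAMES:
        for wave in ("P", "Q", "R", "S", "T"):
            reg.append(FeatureSpec(f"{wave}_amp_{lead}", "mV", "lead_amplitude"))
        reg.append(FeatureSpec(f"rs_ratio_{lead}", "ratio", "lead_amplitude"))
    for name, unit in (
        ("p_duration_ms", "ms"), ("pr_interval_ms", "ms"), ("qrs_duration_ms", "ms"),
        ("qt_interval_ms", "ms"), ("t_duration_ms", "ms"), ("t_upslope_ms", "ms"),
        ("t_downslope_ms", "ms"), ("t_index", "ratio"), ("frame_qrs_onset_ms", "ms"),
        ("frame_qrs_end_ms", "ms"), ("median_rr_ms", "ms"), ("heart_rate_bpm", "bpm"),
    ):
        reg.append(FeatureSpec(name, unit, "interval"))
    for lead in LEAD_NAMES:
        reg.append(FeatureSpec(f"spectral_mean_hz_{lead}", "Hz", "spectral"))
        reg.append(FeatureSpec(f"spectral_spread_hz_{lead}", "Hz", "spectral"))
        reg.append(FeatureSpec(f"spectral_skewness_{lead}", "1", "spectral"))
        reg.append(FeatureSpec(f"skewness_{lead}", "1", "moment"))
        reg.append(FeatureSpec(f"excess_kurtosis_{lead}", "1", "moment"))
    for name in VCG_FEATURE_NAMES:
        unit = "mV"
        if name.endswith("_deg"):
            unit = "deg"
        elif "ratio" in name or "sigma2_over" in name or "planarity" in name or name.startswith("vg_sin"):
            unit = "ratio"
        elif name.endswith("_ms"):
            unit = "ms"
        elif "area" in name or name == "vg_magnitude":
            unit = "mV*ms"
        elif "ln_" in name:
            unit = "ln(mV)"
        reg.append(FeatureSpec(name, unit, "vcg"))
    for name in machine_numeric_names:
        reg.append(FeatureSpec(f"machine_num_{name}", "as-provided", "interval"))
    for name in machine_flag_names:
        reg.append(FeatureSpec(f"machine_flag_{name}", "bool", "boolean_passthrough"))
    names = [r.name for r in reg]
    assert len(names) == len(set(names)), "duplicate feature names in registry"
    return reg


@dataclass
class FeatureVector:
    record_id: str
    values: dict[str, float | None]
    registry: list[FeatureSpec] = field(repr=False)


def assemble_features(
    record: EcgRecord,
    *,
    fiducial_sets: Mapping[str, FiducialSet],
    global_windows: GlobalWindows,
    r_peaks: Sequence[int],
    cleaned: Mapping[str, np.ndarray],
    vcg_values: Mapping[str, float | None],
    registry: list[FeatureSpec] | None = None,
) -> FeatureVector:
    """Concatenate per-lead, interval, spectral/moment, VCG and machine
    passthrough features into one row.  Missing stays missing."""
    machine_numeric = record.machine_numeric or {}
    machine_flags = record.machine_flags or {}
    if registry is None:
        registry = build_registry(sorted(machine_numeric), sorted(machine_flags))
    values: dict[str, float | None] = {spec.name: None for spec in registry}

    for lead in LEAD_NAMES:
        x = cleaned[lead]
        fset = fiducial_sets.get(lead)
        if fset is not None:
            amps = wave_amplitudes(x, fset, record.sampling_rate)
            for wave in ("P", "Q", "R", "S", "T"):
                # a wave with no deflection above threshold is a 0 mV
                # observation at assembly level, not unknown data
                values[f"{wave}_amp_{lead}"] = amps[wave] if amps[wave] is not None else 0.0
            values[f"rs_ratio_{lead}"] = rs_ratio(
                amps["R"] if amps["R"] is not None else 0.0, amps["S"]
            )
        spec = spectral_features(x, record.sampling_rate)
        values[f"spectral_mean_hz_{lead}"] = spec["spectral_mean_hz"]
        values[f"spectral_spread_hz_{lead}"] = spec["spectral_spread_hz"]
        values[f"spectral_skewness_{lead}"] = spec["spectral_skewness"]
        mom = moment_features(x)
        values[f"skewness_{lead}"] = mom["skewness"]
        values[f"excess_kurtosis_{lead}"] = mom["excess_kurtosis"]

    values.update(
        interval_features(fiducial_sets, global_windows, record.sampling_rate, r_peaks)
    )
    for name, val in vcg_values.items():
        values[name] = val
    for name, val in machine_numeric.items():
        key = f"machine_num_{name}"
        if key in values:
            values[key] = float(val)
    for name, val in machine_flags.items():
        key = f"machine_flag_{name}"
        if key in values:
            values[key] = float(bool(val))
    return FeatureVector(record_id=record.record_id, values=values, registry=registry)
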