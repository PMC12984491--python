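import math

import numpy as np
import pytest

from cardiovcg.delineate import GlobalWindows
from cardiovcg.median_beat import MedianBeatMatrix
from cardiovcg.vcg_features import (
    KORS_MATRIX,
    VCG_FEATURE_NAMES,
    VcgError,
    VcgTrajectory,
    compute_all_vcg_features,
    extract_loop,
    kors_transform,
    loop_magnitude_features,
    loop_svd,
    spatial_angle,
    vcg_lead_scalars,
    ventricular_gradient,
)

FS = 500.0
GW = GlobalWindows(-200.0, -90.0, -50.0, 60.0, 120.0, 330.0)
GW_NO_P = GlobalWindows(None, None, -50.0, 60.0, 120.0, 330.0)


def _matrix(beats, windows=GW, r_index=150):
    return MedianBeatMatrix(
        beats=beats, r_index=r_index, fs=FS,
        n_beats_used={lead: 5 for lead in "12345678"}, windows=windows,
    )


def _traj(points, windows=GW, r_index=150):
    return VcgTrajectory(points=points, fs=FS, r_index=r_index, windows=windows)


def _random_rotation(rng):
    m = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestKorsTransform:
    def test_zero_matrix(self):
        traj = kors_transform(_matrix(np.zeros((8, 425))))
        assert np.all(traj.points == 0.0)

    def test_right_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        L = np.linalg.pinv(KORS_MATRIX)
        for _ in range(100):
            v = rng.normal(0, 1, (425, 3))
            leads = (L @ v.T)
            traj = kors_transform(_matrix(leads))
            assert np.max(np.abs(traj.points - v)) < 1e-9

    def test_linearity(self):
        rng = np.random.default_rng(1)
        beats = rng.normal(0, 0.3, (8, 425))
        t1 = kors_transform(_matrix(beats))
        t2 = kors_transform(_matrix(2.0 * beats))
        np.testing.assert_allclose(t2.points, 2.0 * t1.points, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(VcgError):
            kors_transform(_matrix(np.zeros((8, 425))), K=np.zeros((3, 7)))


class TestExtractLoop:
    def test_constant_trajectory_all_zero(self):
        loop = extract_loop(_traj(np.ones((425, 3))), "QRS")
        np.testing.assert_allclose(loop, 0.0, atol=1e-12)

    def test_qrs_window_sample_count(self):
        loop = extract_loop(_traj(np.zeros((425, 3))), "QRS")
        # [-50, +60) ms at 500 Hz -> 55 samples
        assert loop.shape == (55, 3)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (425, 3))
        offset = np.array([0.3, -0.7, 1.1])
        a = extract_loop(_traj(pts), "T")
        b = extract_loop(_traj(pts + offset), "T")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_missing_p_window_errors(self):
        with pytest.raises(VcgError):
            extract_loop(_traj(np.zeros((425, 3)), windows=GW_NO_P), "P")


class TestLoopSvd:
    def test_unit_circle(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        loop = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        s = loop_svd(loop)
        assert s.sigma2_over_sigma1 == pytest.approx(1.0, abs=1e-6)
        assert s.planarity < 1e-9

    def test_collinear_segment(self):
        loop = np.column_stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)])
        s = loop_svd(loop)
        assert s.sigma2 == pytest.approx(0.0, abs=1e-12)
        assert s.sigma2_over_sigma1 == pytest.approx(0.0, abs=1e-12)
        assert s.ln_nondipolar_ratio is None

    def test_all_zero_loop_missing_ratios(self):
        s = loop_svd(np.zeros((10, 3)))
        assert s.sigma2_over_sigma1 is None
        assert s.ln_sigma1 is None
        assert s.planarity is None

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        loop = rng.normal(0, 1, (60, 3))
        base = loop_svd(loop)
        for _ in range(50):
            rot = _random_rotation(rng)
            s = loop_svd(loop @ rot.T)
            assert abs(s.sigma1 - base.sigma1) < 1e-9
            assert abs(s.sigma2 - base.sigma2) < 1e-9
            assert abs(s.sigma3 - base.sigma3) < 1e-9

    def test_reversal_invariance_and_scaling_covariance(self):
        rng = np.random.default_rng(4)
        loop = rng.normal(0, 1, (40, 3))
        base = loop_svd(loop)
        rev = loop_svd(loop[::-1])
        assert rev.sigma1 == pytest.approx(base.sigma1, abs=1e-12)
        scaled = loop_svd(2.5 * loop)
        assert scaled.sigma1 == pytest.approx(2.5 * base.sigma1, rel=1e-12)
        assert scaled.sigma2_over_sigma1 == pytest.approx(base.sigma2_over_sigma1, rel=1e-9)

    def test_sampling_density_invariance(self):
        theta1 = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        theta2 = np.linspace(0, 2 * np.pi, 800, endpoint=False)
        s1 = loop_svd(np.column_stack([2 * np.cos(theta1), np.sin(theta1), 0 * theta1]))
        s2 = loop_svd(np.column_stack([2 * np.cos(theta2), np.sin(theta2), 0 * theta2]))
        assert s1.sigma1 == pytest.approx(s2.sigma1, rel=1e-3)

    def test_eigvecs_orthonormal_and_oriented(self):
        rng = np.random.default_rng(5)
        loop = rng.normal(0, 1, (40, 3)) + np.array([1.0, 0.5, 0.0])
        s = loop_svd(loop)
        np.testing.assert_allclose(s.eigvecs @ s.eigvecs.T, np.eye(3), atol=1e-9)
        mean_vec = loop.mean(axis=0)
        assert s.eigvecs[0] @ mean_vec >= 0

    def test_too_few_points(self):
        with pytest.raises(VcgError):
            loop_svd(np.zeros((2, 3)))


class TestLoopMagnitudeFeatures:
    def test_constant_vector(self):
        n = 50  # 100 ms at 500 Hz
        loop = np.tile([1.0, 0.0, 0.0], (n, 1))
        f = loop_magnitude_features(loop, FS)
        assert f["peak_magnitude"] == pytest.approx(1.0)
        assert f["time_voltage_area"] == pytest.approx(100.0)
        assert f["max_to_mean_ratio"] == pytest.approx(1.0)
        np.testing.assert_allclose(f["mean_vector"], [1.0, 0.0, 0.0])

    def test_half_sine_area(self):
        amp, dur_ms = 0.8, 200.0
        n = int(dur_ms * FS / 1000.0)
        mag = amp * np.sin(np.pi * (np.arange(n) + 0.5) / n)
        loop = np.column_stack([mag, np.zeros(n), np.zeros(n)])
        f = loop_magnitude_features(loop, FS)
        expected = (2 / np.pi) * amp * dur_ms
        assert f["time_voltage_area"] == pytest.approx(expected, rel=0.01)

    def test_argmax_at_start(self):
        loop = np.column_stack([np.linspace(1, 0, 20), np.zeros(20), np.zeros(20)])
        f = loop_magnitude_features(loop, FS)
        assert f["time_to_peak_ms"] == 0.0

    def test_all_zero_loop(self):
        f = loop_magnitude_features(np.zeros((10, 3)), FS)
        assert f["peak_magnitude"] == 0.0
        assert f["max_to_mean_ratio"] is None

    def test_max_to_mean_at_least_one(self):
        rng = np.random.default_rng(6)
        loop = rng.normal(0, 1, (30, 3))
        f = loop_magnitude_features(loop, FS)
        assert f["max_to_mean_ratio"] >= 1.0


class TestSpatialAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_basic(self, a, b, expected):
        assert spatial_angle(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_zero_vector_missing(self):
        assert spatial_angle(np.zeros(3), np.ones(3)) is None

    def test_range(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ang = spatial_angle(rng.normal(size=3), rng.normal(size=3))
            assert 0.0 <= ang <= 180.0


class TestVentricularGradient:
    def test_constant_x(self):
        pts = np.zeros((425, 3))
        sl = slice(150 - 25, 150 + 25)  # exactly [QRS_on, +50 ms)
        pts[150 + int(GW.QRS_on_rel / 2) : 150 + int(GW.T_off_rel / 2)] = [1.0, 0.0, 0.0]
        traj = _traj(pts)
        vg = ventricular_gradient(traj)
        n_samples = int(GW.T_off_rel / 2) - int(GW.QRS_on_rel / 2)
        assert vg.vg[0] == pytest.approx(n_samples * 2.0)
        assert vg.elevation_3d_deg == pytest.approx(0.0)
        assert vg.azimuth_horizontal_deg == pytest.approx(0.0)
        assert vg.sin_sagittal is None  # (Y, Z) projection is zero

    def test_pure_z(self):
        pts = np.zeros((425, 3))
        pts[:, 2] = 0.5
        vg = ventricular_gradient(_traj(pts))
        assert vg.elevation_3d_deg == pytest.approx(90.0)
        assert vg.sin_sagittal == pytest.approx(1.0)
        assert vg.sin_azimuth_horizontal == pytest.approx(1.0)

    def test_antisymmetric_cancels(self):
        on = 150 + int(GW.QRS_on_rel / 2)
        off = 150 + int(GW.T_off_rel / 2)
        n = off - on
        pts = np.zeros((425, 3))
        ramp = np.linspace(-1, 1, n)
        pts[on:off, 0] = ramp
        pts[on:off, 1] = ramp
        vg = ventricular_gradient(_traj(pts))
        assert vg.magnitude < 1e-9
        assert vg.azimuth_horizontal_deg is None

    def test_additivity_over_windows(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (425, 3))
        traj = _traj(pts)
        on = 150 + int(round(GW.QRS_on_rel * FS / 1000.0))
        off = 150 + int(round(GW.T_off_rel * FS / 1000.0))
        mid = (on + off) // 2
        total = pts[on:off].sum(axis=0) * 2.0
        partial = pts[on:mid].sum(axis=0) * 2.0 + pts[mid:off].sum(axis=0) * 2.0
        np.testing.assert_allclose(total, partial, atol=1e-9)
        np.testing.assert_allclose(ventricular_gradient(traj).vg, total, atol=1e-9)


class TestVcgLeadScalars:
    def test_ramp(self):
        pts = np.zeros((425, 3))
        sl = slice(150 + int(GW.QRS_on_rel / 2), 150 + int(GW.QRS_off_rel / 2))
        pts[sl, 1] = np.linspace(0, 0.5, sl.stop - sl.start)
        scalars = vcg_lead_scalars(_traj(pts))
        assert scalars["r_amplitude_y"] == pytest.approx(0.5)

    def test_zero_trajectory(self):
        scalars = vcg_lead_scalars(_traj(np.zeros((425, 3))))
        assert scalars["r_amplitude_y"] == 0.0

    def test_sign_flip(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (425, 3))
        a = vcg_lead_scalars(_traj(pts))
        b = vcg_lead_scalars(_traj(-pts))
        for key in a:
            assert b[key] == pytest.approx(-a[key], abs=1e-12)


class TestComputeAllVcgFeatures:
    def test_registry_length_and_stability(self):
        assert len(VCG_FEATURE_NAMES) == 41
        rng = np.random.default_rng(10)
        beats = rng.normal(0, 0.3, (8, 425))
        out1 = compute_all_vcg_features(_matrix(beats))
        out2 = compute_all_vcg_features(_matrix(beats))
        assert list(out1) == list(VCG_FEATURE_NAMES)
        assert out1 == out2

    def test_missing_p_loop_propagates(self):
        rng = np.random.default_rng(11)
        beats = rng.normal(0, 0.3, (8, 425))
        out = compute_all_vcg_features(_matrix(beats, windows=GW_NO_P))
        for name in VCG_FEATURE_NAMES:
            if name.startswith("p_"):
                assert out[name] is None, name
        assert out["qrs_ln_sigma1"] is not None

    def test_angles_and_sines_in_range(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            beats = rng.normal(0, 0.3, (8, 425))
            out = compute_all_vcg_features(_matrix(beats))
            for name, value in out.items():
                if value is None:
                    continue
                if "mean_vector_angle" in name or "eigvec1_angle" in name:
                    assert 0.0 <= value <= 180.0
                if name.startswith("vg_sin"):
                    assert -1.0 <= value <= 1.0
            if out["vg_elevation_deg"] is not None:
                assert -90.0 <= out["vg_elevation_deg"] <= 90.0

    def test_injected_eccentricity_recovered(self):
        from cardiovcg.synth_cohort import WaveLoopParams, make_beat_trajectory, project_to_leads

        params = {
            "QRS": WaveLoopParams(
                onset_ms=-50.0, offset_ms=50.0, amplitude=1.0,
                direction=(0.6, 0.7, -0.4), eccentricity=0.40,
            )
        }
        beat, r_index = make_beat_trajectory(params)
        leads = project_to_leads(beat)
        out = compute_all_vcg_features(_matrix(leads, windows=GW_NO_P, r_index=r_index))
        assert out["qrs_sigma2_over_sigma1"] == pytest.approx(0.40, abs=0.02)
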