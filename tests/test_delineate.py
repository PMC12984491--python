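import numpy as np
import pytest

from cardiovcg.delineate import (
    DelineationError,
    FiducialSet,
    BeatFiducials,
    aggregate_global_windows,
    delineate_prominence,
    detect_r_peaks,
    refine_qrs_bounds_dwt,
)

from conftest import gaussian, make_synthetic_lead

FS = 500.0


class TestDetectRPeaks:
    def test_impulse_train(self):
        x = np.zeros(5000)
        truth = np.arange(250, 5000, 500)
        x[truth] = 1.0
        peaks = detect_r_peaks(x, FS)
        assert len(peaks) == len(truth)
        assert np.max(np.abs(peaks - truth)) <= 1

    def test_all_zero_signal(self):
        assert len(detect_r_peaks(np.zeros(3000), FS)) == 0

    def test_too_short(self):
        with pytest.raises(DelineationError, match="2 s"):
            detect_r_peaks(np.zeros(500), FS)

    def test_strictly_ascending_with_refractory(self):
        x, truth = make_synthetic_lead(rr_s=0.8)
        peaks = detect_r_peaks(x, FS)
        assert np.all(np.diff(peaks) >= int(0.2 * FS))
        assert np.all(np.diff(peaks) > 0)

    def test_clean_beats_within_2_samples(self):
        x, truth = make_synthetic_lead()
        peaks = detect_r_peaks(x, FS)
        assert len(peaks) == len(truth)
        assert np.max(np.abs(peaks - truth)) <= 2


class TestDelineateProminence:
    def _beat_train(self, p_amp=0.2, t_amp=0.4):
        return make_synthetic_lead(p_amp=p_amp, t_amp=t_amp, p_center=-0.18, t_center=0.30)

    def test_requires_two_peaks(self):
        x, _ = self._beat_train()
        with pytest.raises(DelineationError):
            delineate_prominence(x, FS, [500])

    def test_p_t_peaks_within_4ms(self):
        x, truth = self._beat_train()
        fset = delineate_prominence(x, FS, truth)
        for r, beat in zip(truth, fset.beats):
            p = beat.get("P_peak")
            t = beat.get("T_peak")
            assert p is not None and abs((p - (r - 0.18 * FS)) / FS) * 1000 <= 4
            assert t is not None and abs((t - (r + 0.30 * FS)) / FS) * 1000 <= 4

    def test_zero_p_amplitude_absent(self):
        x, truth = self._beat_train(p_amp=0.0)
        fset = delineate_prominence(x, FS, truth)
        for beat in fset.beats:
            assert beat.get("P_peak") is None
            assert beat.get("P_on") is None

    def test_t_off_at_truncated_gaussian_base(self):
        # Gaussian T truncated to zero beyond 3 sigma, followed by flat
        # baseline: the flanking minimum of the descending limb is the
        # truncation point.
        fs = FS
        n = int(10 * fs)
        t = np.arange(n) / fs
        x = np.zeros(n)
        sigma = 0.05
        r_times = np.arange(0.5, 9.5, 1.0)
        for rt in r_times:
            x += gaussian(t, rt, 0.008, 1.0)
            bump = gaussian(t, rt + 0.30, sigma, 0.4)
            bump[np.abs(t - (rt + 0.30)) > 3 * sigma] = 0.0
            x += bump
        fset = delineate_prominence(x, fs, (r_times * fs).astype(int))
        for rt, beat in zip(r_times, fset.beats):
            t_off = beat.get("T_off")
            assert t_off is not None
            expected = (rt + 0.30 + 3 * sigma) * fs
            assert abs(t_off - expected) / fs * 1000 <= 6

    def test_deterministic(self):
        x, truth = self._beat_train()
        a = delineate_prominence(x, FS, truth)
        b = delineate_prominence(x, FS, truth)
        for ba, bb in zip(a.beats, b.beats):
            assert ba.indices == bb.indices

    def test_ordering_invariant_validated(self):
        x, truth = self._beat_train()
        fset = delineate_prominence(x, FS, truth)
        fset.validate()  # must not raise


class TestRefineQrsBounds:
    def _biphasic_train(self, noise=0.0, seed=0):
        # biphasic QRS supported on [-40, +60] ms around each anchor
        fs = FS
        n = int(10 * fs)
        x = np.zeros(n)
        anchors = np.arange(400, n - 400, 500)
        on, off = int(-0.040 * fs), int(0.060 * fs)
        width = off - on
        tt = (np.arange(width) + 0.5) / width
        shape = np.sin(np.pi * tt) * np.cos(2 * np.pi * tt) * -1.2
        for a in anchors:
            x[a + on : a + off] += shape
        if noise:
            x = x + np.random.default_rng(seed).normal(0, noise, n)
        return x, anchors

    def test_known_support_recovered(self):
        x, anchors = self._biphasic_train()
        # anchor the delineator on the main deflection
        peaks = detect_r_peaks(x, FS)
        fset = delineate_prominence(x, FS, peaks)
        fset = refine_qrs_bounds_dwt(x, FS, fset)
        for beat, a in zip(fset.beats, anchors):
            on_ms = (beat.get("QRS_on") - a) * 1000 / FS
            off_ms = (beat.get("QRS_off") - a) * 1000 / FS
            assert abs(on_ms - (-40.0)) <= 6.0
            assert abs(off_ms - 60.0) <= 6.0

    def test_small_noise_moves_bounds_at_most_2_samples(self):
        x0, _ = self._biphasic_train()
        x1, _ = self._biphasic_train(noise=0.005, seed=3)
        peaks = detect_r_peaks(x0, FS)
        clean = refine_qrs_bounds_dwt(x0, FS, delineate_prominence(x0, FS, peaks))
        noisy = refine_qrs_bounds_dwt(x1, FS, delineate_prominence(x1, FS, peaks))
        for bc, bn in zip(clean.beats, noisy.beats):
            assert abs(bc.get("QRS_on") - bn.get("QRS_on")) <= 2
            assert abs(bc.get("QRS_off") - bn.get("QRS_off")) <= 2

    def test_pure_spike(self):
        x = np.zeros(3000)
        spikes = [500, 1000, 1500, 2000]
        for s in spikes:
            x[s] = 1.0
        peaks = detect_r_peaks(x, FS)
        fset = delineate_prominence(x, FS, peaks)
        fset = refine_qrs_bounds_dwt(x, FS, fset)
        for beat, s in zip(fset.beats, spikes):
            assert abs(beat.get("QRS_on") - s) <= 4
            assert abs(beat.get("QRS_off") - s) <= 4
            assert "narrow_qrs" in beat.flags or "degenerate_qrs" in beat.flags

    def test_degenerate_flat_beat_flagged(self):
        x = np.zeros(3000)
        fset = FiducialSet(
            beats=[BeatFiducials(indices={"R_peak": 700}, ref_index=700),
                   BeatFiducials(indices={"R_peak": 1500}, ref_index=1500)],
            fs=FS, n_samples=3000,
        )
        out = refine_qrs_bounds_dwt(x, FS, fset)
        for beat in out.beats:
            assert "degenerate_qrs" in beat.flags
            assert beat.get("QRS_on") == beat.get("R_peak") - 1
            assert beat.get("QRS_off") == beat.get("R_peak") + 1


class TestAggregateGlobalWindows:
    def _fset(self, offsets, r=1000, n=5000):
        """FiducialSet with one beat per given landmark offset mapping."""
        beat = BeatFiducials(ref_index=r)
        beat.set("R_peak", r)
        for name, off in offsets.items():
            beat.set(name, r + off)
        beat2 = BeatFiducials(ref_index=r + 2000)
        beat2.set("R_peak", r + 2000)
        for name, off in offsets.items():
            beat2.set(name, r + 2000 + off)
        return FiducialSet(beats=[beat, beat2], fs=FS, n_samples=n)

    BASE = {"P_on": -100, "P_off": -50, "QRS_on": -25, "QRS_off": 30, "T_on": 60, "T_off": 200}

    def test_identical_leads(self):
        fsets = {lead: self._fset(self.BASE) for lead in ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")}
        gw = aggregate_global_windows(fsets, FS)
        assert gw.QRS_on_rel == pytest.approx(-50.0)  # -25 samples at 500 Hz

    def test_median_over_leads(self):
        offs = [30, 30, 31, 31, 32, 33, 33, 34]
        fsets = {}
        for lead, off in zip(("I", "II", "V1", "V2", "V3", "V4", "V5", "V6"), offs):
            d = dict(self.BASE)
            d["QRS_off"] = off
            fsets[lead] = self._fset(d)
        gw = aggregate_global_windows(fsets, FS)
        assert gw.QRS_off_rel == pytest.approx(63.0)  # median 31.5 samples

    def test_missing_lead_pooled_over_rest(self):
        fsets = {}
        for lead in ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6"):
            d = dict(self.BASE)
            if lead == "V1":
                d.pop("T_on"); d.pop("T_off")
            fsets[lead] = self._fset(d)
        gw = aggregate_global_windows(fsets, FS)
        assert gw.T_off_rel == pytest.approx(400.0)

    def test_all_missing_landmark_errors(self):
        d = {k: v for k, v in self.BASE.items() if not k.startswith("T")}
        fsets = {lead: self._fset(d) for lead in ("I", "II")}
        with pytest.raises(DelineationError, match="T_on"):
            aggregate_global_windows(fsets, FS)

    def test_allow_missing_p(self):
        d = {k: v for k, v in self.BASE.items() if not k.startswith("P")}
        fsets = {lead: self._fset(d) for lead in ("I", "II")}
        gw = aggregate_global_windows(fsets, FS, allow_missing={"P_on", "P_off"})
        assert gw.P_on_rel is None and gw.P_off_rel is None

    def test_order_violation_errors(self):
        d = dict(self.BASE)
        d["T_on"] = 20  # before QRS_off
        fsets = {lead: self._fset(d) for lead in ("I", "II")}
        with pytest.raises(DelineationError, match="order"):
            aggregate_global_windows(fsets, FS)


class TestFiducialSetInvariants:
    def test_validate_rejects_disorder(self):
        beat = BeatFiducials(indices={"P_on": 100, "P_peak": 90, "R_peak": 200})
        fset = FiducialSet(beats=[beat], fs=FS, n_samples=1000)
        with pytest.raises(DelineationError):
            fset.validate()

    def test_validate_rejects_out_of_range(self):
        beat = BeatFiducials(indices={"R_peak": 5000})
        fset = FiducialSet(beats=[beat], fs=FS, n_samples=1000)
        with pytest.raises(DelineationError):
            fset.validate()
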