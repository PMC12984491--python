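"""R-peak detection and P/QRS/T wave delineation.

The delineator follows a prominence-based scheme: P- and T-peaks are the
most prominent local extrema inside physiological search windows around each
R-peak, and each wave's onset/offset is the adjacent prominence base (the
nearest flanking local minimum of the absolute baseline-referenced signal).
QRS onset/offset are refined with a non-decimated dyadic wavelet stage plus
amplitude-floor checks, because the prominence scheme alone does not place
Q-onsets and S-offsets.

All indices are 0-based samples; intervals are half-open [on, off);
millisecond conversions use ms = samples * 1000 / fs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

logger = logging.getLogger(__name__)

LANDMARKS = (
    "P_on", "P_peak", "P_off",
    "QRS_on", "Q_peak", "R_peak", "S_peak", "QRS_off",
    "T_on", "T_peak", "T_off",
)

#: Ordering constraint among landmarks (Q between QRS_on and R, S between R
#: and QRS_off; all others totally ordered).
_ORDER = (
    "P_on", "P_peak", "P_off", "QRS_on", "R_peak", "QRS_off", "T_on", "T_peak", "T_off",
)


class DelineationError(Exception):
    pass


@dataclass
class BeatFiducials:
    """Landmark sample indices for one beat in one lead (None = absent).

    ``ref_index`` is the shared (reference-lead) R anchor the beat was
    delineated against; offsets pooled across leads are measured from it so
    that leads with negative-dominant QRS complexes stay aligned.
    """

    indices: dict[str, int | None] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    ref_index: int | None = None

    def get(self, name: str) -> int | None:
        return self.indices.get(name)

    def set(self, name: str, value: int | None) -> None:
        self.indices[name] = None if value is None else int(value)


@dataclass
class FiducialSet:
    """Per-beat fiducials for a single lead."""

    beats: list[BeatFiducials]
    fs: float
    n_samples: int

    def landmark_offsets(self, name: str) -> np.ndarray:
        """Offsets (samples) of a landmark relative to the beat's R anchor."""
        vals = []
        for b in self.beats:
            r = b.ref_index if b.ref_index is not None else b.get("R_peak")
            v = b.get(name)
            if r is not None and v is not None:
                vals.append(v - r)
        return np.asarray(vals, dtype=float)

    def validate(self) -> None:
        for b in self.beats:
            present = [(n, b.get(n)) for n in _ORDER if b.get(n) is not None]
            for (n1, v1), (n2, v2) in zip(present, present[1:]):
                if v1 > v2:
                    raise DelineationError(f"landmark order violated: {n1}={v1} > {n2}={v2}")
            for n, v in present:
                if not (0 <= v < self.n_samples):
                    raise DelineationError(f"{n}={v} outside record of {self.n_samples} samples")
            q, s, r = b.get("Q_peak"), b.get("S_peak"), b.get("R_peak")
            if q is not None and r is not None and not q <= r:
                raise DelineationError("Q_peak after R_peak")
            if s is not None and r is not None and not r <= s:
                raise DelineationError("S_peak before R_peak")


@dataclass(frozen=True)
class GlobalWindows:
    """Fixed global wave windows in ms relative to the R-peak (signed).

    P windows may be None when no lead contributed P landmarks and the caller
    opted in to that (``allow_missing``).
    """

    P_on_rel: float | None
    P_off_rel: float | None
    QRS_on_rel: float
    QRS_off_rel: float
    T_on_rel: float
    T_off_rel: float

    def window(self, wave: str) -> tuple[float, float] | None:
        if wave == "P":
            if self.P_on_rel is None or self.P_off_rel is None:
                return None
            return (self.P_on_rel, self.P_off_rel)
        if wave == "QRS":
            return (self.QRS_on_rel, self.QRS_off_rel)
        if wave == "T":
            return (self.T_on_rel, self.T_off_rel)
        raise KeyError(wave)


@dataclass(frozen=True)
class DelineationConfig:
    refractory_ms: float = 200.0
    p_window_ms: tuple[float, float] = (-300.0, -60.0)
    t_window_ms: tuple[float, float] = (80.0, 500.0)
    q_window_ms: float = 60.0   # Q searched in [R - q_window, R)
    s_window_ms: float = 90.0   # S searched in (R, R + s_window]
    prominence_mv: float = 0.03
    qs_depth_mv: float = 0.025
    dwt_levels: int = 4
    dwt_scales: tuple[int, ...] = (3, 4)
    dwt_threshold_frac: float = 0.05
    amplitude_floor_mv: float = 0.02
    rel_floor_frac: float = 0.0  # optional relative floor (fraction of in-beat peak)
    slope_floor_mv_ms: float = 0.002
    rel_slope_frac: float = 0.04
    bound_pad_ms: float = 0.0  # smoothing already widens the floor crossing outward
    qrs_search_ms: tuple[float, float] = (-120.0, 140.0)


DEFAULT_CONFIG = DelineationConfig()


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 3) -> np.ndarray:
    sos = butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def detect_r_peaks(
    signal: np.ndarray, fs: float, refractory_ms: float = 200.0
) -> np.ndarray:
    """Detect R-peaks via band-passed squared-derivative energy.

    Returns strictly ascending sample indices; an empty array (with a logged
    quality warning) for flat or unusable signals.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise DelineationError("signal shorter than 2 s")
    band = _bandpass(x, fs, 5.0, 25.0)
    energy = np.gradient(band) ** 2
    win = max(1, int(round(0.15 * fs)))
    kernel = np.ones(win) / win
    integ = np.convolve(energy, kernel, mode="same")
    peak_level = np.max(integ)
    if peak_level <= 0 or np.ptp(x) < 1e-6:
        logger.warning("flat or zero-energy signal: no R-peaks detected")
        return np.array([], dtype=int)
    # the median guard suppresses noise-only detections but must never
    # exceed a fraction of the peak (at high heart rates with wide waves
    # the energy median itself is large)
    threshold = min(
        max(0.15 * peak_level, 3.0 * float(np.median(integ))), 0.6 * peak_level
    )
    distance = max(1, int(round(refractory_ms * fs / 1000.0)))
    rough, _ = find_peaks(integ, height=threshold, distance=distance)
    if len(rough) == 0:
        logger.warning("no energy peaks above adaptive threshold")
        return np.array([], dtype=int)
    # Coarse recentering: the integrated-energy peak can sit on a plateau or
    # side lobe, so snap each candidate to the nearest raw extremum first.
    level = float(np.median(x))
    coarse_half = int(round(0.075 * fs))
    recentred = []
    for p in rough:
        lo, hi = max(0, p - coarse_half), min(len(x), p + coarse_half + 1)
        recentred.append(lo + int(np.argmax(np.abs(x[lo:hi] - level))))
    rough = np.asarray(recentred)
    # Refine with template cross-correlation so every beat gets the *same*
    # intra-QRS anchor: a per-beat argmax is unstable when two deflections of
    # similar magnitude compete, which would smear the averaged beat.
    half = int(round(0.1 * fs))
    segs = [
        x[p - half : p + half + 1] - level
        for p in rough
        if p - half >= 0 and p + half + 1 <= len(x)
    ]
    if segs:
        template = np.median(np.vstack(segs), axis=0)
        tpl_peak = int(np.argmax(np.abs(template - np.median(template)))) - half
        search = int(round(0.03 * fs))
        refined = []
        for p in rough:
            best_off, best_score = 0, -np.inf
            for off in range(-search, search + 1):
                lo, hi = p + off - half, p + off + half + 1
                if lo < 0 or hi > len(x):
                    continue
                score = float(template @ (x[lo:hi] - level))
                if score > best_score:
                    best_score, best_off = score, off
            refined.append(p + best_off + tpl_peak)
    else:
        refined = [
            max(0, min(len(x) - 1, p + int(np.argmax(np.abs(
                x[max(0, p - half) : p + half + 1] - level))) - min(p, half)))
            for p in rough
        ]
    refined = np.unique(refined)
    # enforce refractory after refinement
    out: list[int] = []
    for r in refined:
        if not out or r - out[-1] >= distance:
            out.append(int(r))
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# Prominence delineation
# ---------------------------------------------------------------------------

def _walk_to_base(
    absdev: np.ndarray,
    start: int,
    step: int,
    limit: int,
    lookahead: int = 12,
    min_drop: float = 0.0012,
) -> int:
    """Walk from ``start`` in direction ``step`` to the nearest flanking local
    minimum of ``absdev``, bounded by ``limit`` (inclusive).

    A short look-ahead steps through sample-level noise dips: the walk jumps
    to the lowest sample within the next ``lookahead`` samples while that
    improves on the current value by at least ``min_drop`` mV, then stops.
    """
    j = start
    while j != limit:
        lo = j + step
        hi = j + step * lookahead
        lo, hi = (lo, min(hi, limit)) if step > 0 else (max(hi, limit), lo)
        if hi < lo:
            break
        window = absdev[lo : hi + 1]
        if window.size == 0:
            break
        k = int(np.argmin(window)) + lo
        if absdev[k] < absdev[j] - min_drop:
            j = k
        else:
            break
    return j


def _most_prominent_extremum(
    seg: np.ndarray, prominence: float
) -> tuple[int, float] | None:
    """Index (within seg) and prominence of the most prominent extremum of
    either polarity, or None if nothing passes the threshold.

    ``seg`` must already be baseline-referenced; candidates must also
    deviate from that baseline by the threshold, because a flat stretch
    between two opposite-signed waves is "prominent" without being a wave.
    """
    best: tuple[int, float] | None = None
    for sign in (1.0, -1.0):
        peaks, props = find_peaks(sign * seg, prominence=prominence)
        for idx, prom in zip(peaks, props["prominences"]):
            if sign * seg[idx] < prominence:
                continue
            if best is None or prom > best[1]:
                best = (int(idx), float(prom))
    return best


def delineate_prominence(
    signal: np.ndarray,
    fs: float,
    r_peaks: Sequence[int],
    config: DelineationConfig = DEFAULT_CONFIG,
    isoelectric_level: float | None = None,
) -> FiducialSet:
    """Delineate one lead given R-peak indices.

    P and T peaks are the most prominent extrema in the configured windows
    (capped at neighboring-beat midpoints); their onsets/offsets are the
    flanking prominence bases.  Landmarks that fail the prominence threshold
    are absent.  QRS on/off are left unset (see refine_qrs_bounds_dwt); the
    per-lead R-peak is re-anchored to the positive maximum near the provided
    reference index, with Q and S as the most negative deflections on either
    side.
    """
    x = np.asarray(signal, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        raise DelineationError("need at least 2 R-peaks to delineate")
    ms = fs / 1000.0
    modulus = dwt_detail_modulus(x, config.dwt_levels, config.dwt_scales)
    # a baseline-corrected working signal is zero-referenced by
    # construction; callers that did not correct it can leave the level to
    # the global median
    level = float(np.median(x)) if isoelectric_level is None else float(isoelectric_level)
    beats: list[BeatFiducials] = []
    for k, r_ref in enumerate(r_peaks):
        prev_r = r_peaks[k - 1] if k > 0 else None
        next_r = r_peaks[k + 1] if k + 1 < len(r_peaks) else None
        beat = BeatFiducials(ref_index=int(r_ref))
        mod_on, mod_off = _rough_qrs_extent(modulus, r_ref, fs, config)
        baseline = level
        absdev = np.abs(x - baseline)
        # smoothed copy for the base walks: P/T tails are shallow, so the
        # walk must not be derailed by single-sample noise dips
        ksm = max(1, int(round(0.010 * fs)) | 1)
        absdev_sm = np.convolve(absdev, np.ones(ksm) / ksm, mode="same")

        # dominant QRS deflection (either polarity) inside the rough extent,
        # then the per-lead R as the positive maximum around it: this stays
        # inside the QRS even for negative-dominant leads such as aVR/V1
        dom = mod_on + int(np.argmax(absdev[mod_on : mod_off + 1]))
        r_lo = max(mod_on, int(dom - 50 * ms))
        r_hi = min(mod_off + 1, int(dom + 50 * ms) + 1)
        r_idx = r_lo + int(np.argmax(x[r_lo:r_hi]))
        if x[r_idx] - baseline < config.qs_depth_mv:
            # no real positive deflection (QS-type complex): anchor the beat
            # on the dominant deflection instead of a baseline wiggle
            r_idx = dom
        beat.set("R_peak", r_idx)

        # Q: most negative between the rough QRS onset and R;
        # S: most negative between R and the rough QRS offset.  A nadir at
        # the extent boundary is the baseline settling, not a wave, and the
        # depth must clear the low-pass pre/post-ringing of the main
        # deflection, which scales with its amplitude.
        peak_here = float(np.max(absdev[mod_on : mod_off + 1]))
        qs_depth = max(config.qs_depth_mv, 0.05 * peak_here)
        q_lo = max(mod_on, int(r_idx - config.q_window_ms * ms))
        if q_lo < r_idx:
            q_idx = q_lo + int(np.argmin(x[q_lo:r_idx]))
            if baseline - x[q_idx] >= qs_depth and q_idx > mod_on + 2:
                beat.set("Q_peak", q_idx)
        s_hi = min(mod_off, int(r_idx + config.s_window_ms * ms))
        if r_idx + 1 <= s_hi:
            s_idx = r_idx + 1 + int(np.argmin(x[r_idx + 1 : s_hi + 1]))
            if baseline - x[s_idx] >= qs_depth and s_idx < mod_off - 2:
                beat.set("S_peak", s_idx)

        # P wave
        p_lo = int(r_ref + config.p_window_ms[0] * ms)
        p_hi = int(r_ref + config.p_window_ms[1] * ms)
        if prev_r is not None:
            # stay clear of the previous beat's T wave at short RR intervals
            p_lo = max(p_lo, (prev_r + r_ref) // 2, prev_r + int(340 * ms))
        p_lo = max(0, p_lo)
        if p_hi - p_lo > 3:
            hit = _most_prominent_extremum(x[p_lo:p_hi] - baseline, config.prominence_mv)
            if hit is not None:
                p_idx = p_lo + hit[0]
                beat.set("P_peak", p_idx)
                beat.set("P_on", _walk_to_base(absdev_sm, p_idx, -1, p_lo))
                beat.set("P_off", _walk_to_base(absdev_sm, p_idx, +1, min(p_hi, r_idx) - 1))

        # T wave
        t_lo = int(r_ref + config.t_window_ms[0] * ms)
        t_hi = int(r_ref + config.t_window_ms[1] * ms)
        if next_r is not None:
            t_hi = min(t_hi, (r_ref + next_r) // 2)
        t_hi = min(t_hi, len(x))
        if t_hi - t_lo > 3 and t_lo >= 0:
            hit = _most_prominent_extremum(x[t_lo:t_hi] - baseline, config.prominence_mv)
            if hit is not None:
                t_idx = t_lo + hit[0]
                beat.set("T_peak", t_idx)
                beat.set("T_on", _walk_to_base(absdev_sm, t_idx, -1, t_lo))
                beat.set("T_off", _walk_to_base(absdev_sm, t_idx, +1, t_hi - 1))

        _enforce_beat_order(beat)
        beats.append(beat)
    fset = FiducialSet(beats=beats, fs=fs, n_samples=len(x))
    fset.validate()
    return fset


def _enforce_beat_order(beat: BeatFiducials) -> None:
    """Drop landmarks that violate the ordering invariant (never reorder)."""
    r = beat.get("R_peak")
    if r is None:
        return
    for name in ("P_on", "P_peak", "P_off", "QRS_on", "Q_peak"):
        v = beat.get(name)
        if v is not None and v > r:
            beat.set(name, None)
    for name in ("QRS_off", "S_peak", "T_on", "T_peak", "T_off"):
        v = beat.get(name)
        if v is not None and v < r:
            beat.set(name, None)
    # P triple internally ordered, else dropped wholesale
    p = [beat.get(n) for n in ("P_on", "P_peak", "P_off")]
    if any(v is not None for v in p):
        pv = [v for v in p if v is not None]
        if pv != sorted(pv):
            for n in ("P_on", "P_peak", "P_off"):
                beat.set(n, None)
    t = [beat.get(n) for n in ("T_on", "T_peak", "T_off")]
    if any(v is not None for v in t):
        tv = [v for v in t if v is not None]
        if tv != sorted(tv):
            for n in ("T_on", "T_peak", "T_off"):
                beat.set(n, None)
    # P must end before QRS region
    p_off, q = beat.get("P_off"), beat.get("Q_peak")
    if p_off is not None and q is not None and p_off > q:
        for n in ("P_on", "P_peak", "P_off"):
            beat.set(n, None)
    # T must begin after S
    t_on, s = beat.get("T_on"), beat.get("S_peak")
    if t_on is not None and s is not None and t_on < s:
        beat.set("T_on", s)


# ---------------------------------------------------------------------------
# Dyadic wavelet QRS-bound refinement
# ---------------------------------------------------------------------------

def _upsample_kernel(kernel: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return kernel
    out = np.zeros((len(kernel) - 1) * factor + 1)
    out[::factor] = kernel
    return out

# Centered dyadic filter pair (odd length => integer, zero delay with
# mode='same'):  binomial smoother + central-difference detail.
_H = np.array([1.0, 2.0, 1.0]) / 4.0
_G = np.array([1.0, 0.0, -1.0])


def dwt_detail_modulus(
    signal: np.ndarray, levels: int = 4, scales: Iterable[int] = (3, 4)
) -> np.ndarray:
    """Summed modulus of the selected non-decimated detail coefficients."""
    a = np.asarray(signal, dtype=float)
    details = {}
    for j in range(1, levels + 1):
        up = 2 ** (j - 1)
        d = np.convolve(a, _upsample_kernel(_G, up), mode="same")
        a = np.convolve(a, _upsample_kernel(_H, up), mode="same")
        details[j] = d
    return sum(np.abs(details[s]) for s in scales)


def _sustained_crossing(
    dev: np.ndarray, start: int, step: int, limit: int, floor: float, sustain: int
) -> int:
    """First index from ``start`` (moving by ``step``) where ``dev`` drops to
    ``floor`` or below and stays there for ``sustain`` samples."""
    j = start
    while (step < 0 and j >= limit) or (step > 0 and j <= limit):
        if dev[j] <= floor:
            if step < 0:
                lo, hi = max(limit, j - sustain + 1), j + 1
            else:
                lo, hi = j, min(limit, j + sustain - 1) + 1
            if hi > lo and bool(np.all(dev[lo:hi] <= floor)):
                return j
        j += step
    return limit


def refine_qrs_bounds_dwt(
    signal: np.ndarray,
    fs: float,
    fiducials: FiducialSet,
    config: DelineationConfig = DEFAULT_CONFIG,
    isoelectric_level: float | None = None,
) -> FiducialSet:
    """Fill QRS_on / QRS_off for every beat of one lead.

    Bounds are placed where the wavelet detail modulus falls below
    ``dwt_threshold_frac`` of its in-beat maximum, then pushed outward while
    the baseline-referenced amplitude exceeds ``amplitude_floor_mv``, and
    finally widened (if needed) to contain the Q and S deflections.
    """
    x = np.asarray(signal, dtype=float)
    ms = fs / 1000.0
    modulus = dwt_detail_modulus(x, config.dwt_levels, config.dwt_scales)
    level = float(np.median(x)) if isoelectric_level is None else float(isoelectric_level)
    for beat in fiducials.beats:
        r = beat.get("R_peak")
        if r is None:
            raise DelineationError("R_peak missing; run delineate_prominence first")
        anchor = beat.ref_index if beat.ref_index is not None else r
        w_lo = max(0, int(anchor + config.qrs_search_ms[0] * ms))
        w_hi = min(len(x), int(anchor + config.qrs_search_ms[1] * ms))
        seg_mod = modulus[w_lo:w_hi]
        mmax = float(np.max(seg_mod)) if len(seg_mod) else 0.0
        rough_on, rough_off = _rough_qrs_extent(modulus, anchor, fs, config)
        # light smoothing so the floor crossing is not triggered by single
        # noise samples
        k = max(1, int(round(0.004 * fs)) | 1)
        smooth = np.convolve(x, np.ones(k) / k, mode="same")
        dev_l = dev_r = dev = np.abs(smooth - level)
        peak_dev = float(np.max(dev[w_lo:w_hi])) if w_hi > w_lo else 0.0
        if mmax <= 0 or peak_dev < config.amplitude_floor_mv:
            beat.set("QRS_on", max(0, r - 1))
            beat.set("QRS_off", min(len(x) - 1, r + 1))
            beat.flags.append("degenerate_qrs")
            continue
        if peak_dev < 6.0 * config.amplitude_floor_mv:
            beat.flags.append("low_amplitude_qrs")
        floor = max(config.amplitude_floor_mv, config.rel_floor_frac * peak_dev)
        # amplitude check: scan outward from R for the first *sustained*
        # below-floor stretch.  Brief intra-QRS zero crossings (between
        # lobes) are skipped by the sustain requirement, and an adjacent
        # P/T wave can never capture the bound because the scan stops at
        # the first true gap.
        sustain = max(2, int(round(0.020 * fs)))
        on = _sustained_crossing(dev, r - 1, -1, w_lo, floor, sustain)
        off = _sustained_crossing(dev, r + 1, +1, w_hi - 1, floor, sustain)
        # final slope trim: the amplitude crossing can linger on filter
        # ringing or slow baseline curvature, both of which have much
        # smaller derivatives than a true QRS edge
        deriv = np.abs(np.gradient(smooth)) * fs / 1000.0  # mV per ms
        slope_floor = max(
            config.slope_floor_mv_ms,
            config.rel_slope_frac * float(np.max(deriv[w_lo:w_hi])),
        )
        while on < r and deriv[on] <= slope_floor:
            on += 1
        while off > r and deriv[off] <= slope_floor:
            off -= 1
        if off - on < int(round(0.020 * fs)):
            beat.flags.append("narrow_qrs")
        else:
            # small outward pad: the floor crossing sits slightly inside the
            # true deflection, and the loop onset should be isoelectric
            pad = int(round(config.bound_pad_ms * ms))
            on = max(w_lo, on - pad)
            off = min(w_hi - 1, off + pad)
        q, s = beat.get("Q_peak"), beat.get("S_peak")
        if q is not None:
            on = min(on, q - 1)
        if s is not None:
            off = max(off, s + 1)
        on = min(on, r - 1)
        off = max(off, r + 1)
        beat.set("QRS_on", max(0, on))
        beat.set("QRS_off", min(len(x) - 1, off))
        p_off = beat.get("P_off")
        if p_off is not None and p_off > beat.get("QRS_on"):
            # P offset swallowed by the refined QRS onset: drop the P triple
            for n in ("P_on", "P_peak", "P_off"):
                beat.set(n, None)
        t_on, t_peak = beat.get("T_on"), beat.get("T_peak")
        qrs_off = beat.get("QRS_off")
        if t_peak is not None and t_peak <= qrs_off:
            # T wave swallowed by the refined QRS: drop it
            for n in ("T_on", "T_peak", "T_off"):
                beat.set(n, None)
        elif t_on is not None and t_on < qrs_off:
            beat.set("T_on", qrs_off)
    fiducials.validate()
    return fiducials


def _rough_qrs_extent(
    modulus: np.ndarray, anchor: int, fs: float, config: DelineationConfig
) -> tuple[int, int]:
    """Rough QRS support from the wavelet detail modulus around ``anchor``.

    The extent is where the modulus stays above ``dwt_threshold_frac`` of its
    local maximum; it overshoots the true deflection by roughly a filter
    half-width, which is fine for its two uses (bounding Q/S searches and
    anchoring the baseline window)."""
    ms = fs / 1000.0
    w_lo = max(0, int(anchor + config.qrs_search_ms[0] * ms))
    w_hi = min(len(modulus), int(anchor + config.qrs_search_ms[1] * ms))
    seg = modulus[w_lo:w_hi]
    if seg.size == 0 or float(np.max(seg)) <= 0:
        return max(0, anchor - 1), min(len(modulus) - 1, anchor + 1)
    # the center must stay near the anchor: in leads with a small QRS
    # projection the T upstroke can carry more detail energy
    c_lo = max(w_lo, anchor - int(round(0.060 * fs)))
    c_hi = min(w_hi, anchor + int(round(0.060 * fs)) + 1)
    center = c_lo + int(np.argmax(modulus[c_lo:c_hi]))
    thr = config.dwt_threshold_frac * float(np.max(modulus[c_lo:c_hi]))
    # cap the walk at a physiological half-QRS so a neighboring P/T wave's
    # modulus cannot be swallowed in leads with a small QRS projection
    w_lo = max(w_lo, center - int(round(0.090 * fs)))
    w_hi = min(w_hi, center + int(round(0.090 * fs)) + 1)
    # the detail modulus has exact zeros at antisymmetry points (e.g. under a
    # spike apex), so tolerate sub-threshold dips of a few samples
    gap = max(1, int(round(0.006 * fs)))
    on = center
    while on - 1 >= w_lo:
        look = modulus[max(w_lo, on - 1 - gap) : on]
        if look.size and float(np.max(look)) >= thr:
            on -= 1
        else:
            break
    off = center
    while off + 1 < w_hi:
        look = modulus[off + 1 : min(w_hi, off + 2 + gap)]
        if look.size and float(np.max(look)) >= thr:
            off += 1
        else:
            break
    return on, off


# ---------------------------------------------------------------------------
# Global window aggregation
# ---------------------------------------------------------------------------

_WINDOW_LANDMARKS = ("P_on", "P_off", "QRS_on", "QRS_off", "T_on", "T_off")


def aggregate_global_windows(
    fiducial_sets: Mapping[str, FiducialSet],
    fs: float,
    allow_missing: frozenset[str] | set[str] = frozenset(),
) -> GlobalWindows:
    """Median-of-medians pooling of per-lead landmark offsets into fixed
    global windows (ms relative to R).

    Each relative landmark is the median over leads of the per-lead median
    over beats of (landmark - R_peak).  A landmark absent in all leads raises
    unless listed in ``allow_missing`` (then its window field is None, which
    is only supported for the P wave).
    """
    rel: dict[str, float | None] = {}
    for name in _WINDOW_LANDMARKS:
        lead_medians = []
        for fset in fiducial_sets.values():
            offs = fset.landmark_offsets(name)
            if len(offs):
                lead_medians.append(float(np.median(offs)))
        if not lead_medians:
            if name in allow_missing:
                rel[name] = None
                continue
            raise DelineationError(f"landmark {name} absent in all leads")
        rel[name] = float(np.median(lead_medians)) * 1000.0 / fs

    gw = GlobalWindows(
        P_on_rel=rel["P_on"],
        P_off_rel=rel["P_off"],
        QRS_on_rel=rel["QRS_on"],
        QRS_off_rel=rel["QRS_off"],
        T_on_rel=rel["T_on"],
        T_off_rel=rel["T_off"],
    )
    _check_window_order(gw)
    return gw


def _check_window_order(gw: GlobalWindows) -> None:
    seq: list[tuple[str, float]] = []
    if gw.P_on_rel is not None and gw.P_off_rel is not None:
        seq += [("P_on", gw.P_on_rel), ("P_off", gw.P_off_rel)]
    elif (gw.P_on_rel is None) != (gw.P_off_rel is None):
        raise DelineationError("P_on/P_off must be jointly present or absent")
    seq += [
        ("QRS_on", gw.QRS_on_rel),
        ("QRS_off", gw.QRS_off_rel),
        ("T_on", gw.T_on_rel),
        ("T_off", gw.T_off_rel),
    ]
    for (n1, v1), (n2, v2) in zip(seq, seq[1:]):
        if v1 > v2:
            raise DelineationError(f"global window order violated: {n1}={v1:.1f} > {n2}={v2:.1f}")
    if not (gw.QRS_on_rel < 0 < gw.QRS_off_rel):
        raise DelineationError("QRS window must straddle the R-peak")
    span_start = gw.P_on_rel if gw.P_on_rel is not None else gw.QRS_on_rel
    if gw.T_off_rel - span_start > 850.0:
        raise DelineationError("global window span exceeds 850 ms")


def fiducials_to_frame(record_id: str, fiducial_sets: Mapping[str, FiducialSet]):
    """Tidy export: one row per (lead, beat, landmark)."""
    import pandas as pd

    rows = []
    for lead, fset in fiducial_sets.items():
        for b, beat in enumerate(fset.beats):
            for name, idx in beat.indices.items():
                if idx is None:
                    continue
                rows.append(
                    {
                        "record_id": record_id,
                        "lead": lead,
                        "beat": b,
                        "landmark": name,
                        "sample_index": idx,
                        "time_ms": idx * 1000.0 / fset.fs,
                    }
                )
    return pd.DataFrame(rows)
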