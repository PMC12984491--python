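"""Vectorcardiogram construction and the 41-feature VCG registry.

The 8-lead median-beat matrix is projected to orthogonal X/Y/Z axes with the
Kors regression matrix.  Axis convention: X positive leftward, Y positive
inferior, Z positive posterior.  The horizontal plane is X-Z (angle measured
from +X toward +Z), the sagittal plane is Y-Z (from +Y toward +Z), and
elevation is measured from the XY plane toward +Z.

Loops are referenced to their window-onset point (the isoelectric level) and
are not mean-centered before SVD, so the first singular value is an
amplitude-like "dipolar" measure.  Singular values are scaled by 1/sqrt(M)
for sampling-density invariance.  Natural log is used for all log-valued
features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .median_beat import MedianBeatMatrix
from .delineate import GlobalWindows

#: Kors regression coefficients, rows X/Y/Z, columns I, II, V1..V6.
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
    ]
)


class VcgError(Exception):
    pass


@dataclass
class VcgTrajectory:
    """W x 3 trajectory (X, Y, Z in mV) with its timing context."""

    points: np.ndarray
    fs: float
    r_index: int
    windows: GlobalWindows

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise VcgError(f"trajectory must be W x 3, got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise VcgError("non-finite trajectory samples")


@dataclass
class LoopSummary:
    sigma1: float
    sigma2: float
    sigma3: float
    eigvecs: np.ndarray  # 3 x 3, rows are oriented unit vectors
    sigma2_over_sigma1: float | None
    ln_nondipolar_ratio: float | None
    ln_sigma1: float | None
    planarity: float | None


@dataclass
class VentricularGradient:
    vg: np.ndarray  # mV*ms
    magnitude: float
    azimuth_horizontal_deg: float | None
    sagittal_angle_deg: float | None
    sin_azimuth_horizontal: float | None
    sin_sagittal: float | None
    elevation_3d_deg: float | None


def kors_transform(matrix: MedianBeatMatrix, K: np.ndarray = KORS_MATRIX) -> VcgTrajectory:
    """Project the 8-lead median-beat matrix into VCG space: points = (K @ leads).T."""
    K = np.asarray(K, dtype=float)
    if K.shape != (3, matrix.beats.shape[0]):
        raise VcgError(f"Kors matrix shape {K.shape} does not match {matrix.beats.shape[0]} leads")
    windows = getattr(matrix, "windows", None)
    if windows is None:
        raise VcgError("median-beat matrix carries no global windows")
    return VcgTrajectory(
        points=(K @ matrix.beats).T,
        fs=matrix.fs,
        r_index=matrix.r_index,
        windows=windows,
    )


def _window_slice(traj: VcgTrajectory, wave: str) -> slice:
    win = traj.windows.window(wave)
    if win is None:
        raise VcgError(f"{wave} window undefined")
    on = traj.r_index + int(round(win[0] * traj.fs / 1000.0))
    off = traj.r_index + int(round(win[1] * traj.fs / 1000.0))
    on = max(0, on)
    off = min(len(traj.points), off)
    if off <= on:
        raise VcgError(f"empty {wave} window")
    return slice(on, off)


def extract_loop(traj: VcgTrajectory, wave: str) -> np.ndarray:
    """Loop points for a wave window, translated to the window-onset origin.

    The origin is the mean of a short patch ending at the window onset
    (nominally isoelectric), rather than the single onset sample, so one
    noisy sample or a bound sitting a sample inside the deflection does not
    shift the whole loop.
    """
    sl = _window_slice(traj, wave)
    pts = traj.points[sl]
    patch = traj.points[max(0, sl.start - 5) : sl.start + 1]
    return pts - patch.mean(axis=0)


def loop_svd(loop: np.ndarray) -> LoopSummary:
    """Singular-value summary of an M x 3 loop (no mean-centering).

    Singular values are scaled by 1/sqrt(M).  Eigenvector signs are oriented
    to a non-negative dot product with the loop mean vector (ties resolved by
    making the first nonzero coordinate positive).
    """
    loop = np.asarray(loop, dtype=float)
    if loop.ndim != 2 or loop.shape[1] != 3 or loop.shape[0] < 3:
        raise VcgError("loop must be M x 3 with M >= 3")
    m = loop.shape[0]
    _, s, vt = np.linalg.svd(loop / math.sqrt(m), full_matrices=False)
    mean_vec = loop.mean(axis=0)
    eigvecs = np.empty((3, 3))
    for i in range(3):
        v = vt[i]
        d = float(v @ mean_vec)
        if d < 0:
            v = -v
        elif d == 0:
            nz = np.nonzero(v)[0]
            if len(nz) and v[nz[0]] < 0:
                v = -v
        eigvecs[i] = v
    s1, s2, s3 = (float(x) for x in s)
    ratio = s2 / s1 if s1 > 0 else None
    nd = (s2 + s3) / s1 if s1 > 0 else None
    ln_nd = math.log(nd) if nd is not None and nd > 0 else None
    return LoopSummary(
        sigma1=s1,
        sigma2=s2,
        sigma3=s3,
        eigvecs=eigvecs,
        sigma2_over_sigma1=ratio,
        ln_nondipolar_ratio=ln_nd,
        ln_sigma1=math.log(s1) if s1 > 0 else None,
        planarity=s3 / s1 if s1 > 0 else None,
    )


def loop_magnitude_features(
    loop: np.ndarray, fs: float
) -> dict[str, float | np.ndarray | None]:
    """Peak magnitude, time-to-peak, time-voltage area, max/mean ratio, mean vector."""
    loop = np.asarray(loop, dtype=float)
    if loop.ndim != 2 or loop.shape[1] != 3 or loop.shape[0] < 1:
        raise VcgError("loop must be M x 3 with M >= 1")
    mags = np.linalg.norm(loop, axis=1)
    dt_ms = 1000.0 / fs
    peak = float(np.max(mags))
    mean_mag = float(np.mean(mags))
    return {
        "peak_magnitude": peak,
        "time_to_peak_ms": float(np.argmax(mags)) * dt_ms,
        "time_voltage_area": float(np.sum(mags)) * dt_ms,
        "max_to_mean_ratio": peak / mean_mag if mean_mag > 0 else None,
        "mean_vector": loop.mean(axis=0),
    }


def spatial_angle(a: np.ndarray, b: np.ndarray) -> float | None:
    """Angle in degrees in [0, 180] between two nonzero 3-vectors (None if degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _plane_angle(first: float, second: float) -> float | None:
    """Signed angle (deg) of a 2D projection, measured from the first axis
    toward the second; None for a (numerically) zero projection."""
    if math.hypot(first, second) < 1e-12:
        return None
    return math.degrees(math.atan2(second, first))


def ventricular_gradient(traj: VcgTrajectory) -> VentricularGradient:
    """Spatial integral of the heart vector over [QRS_on, T_off)."""
    on = traj.r_index + int(round(traj.windows.QRS_on_rel * traj.fs / 1000.0))
    off = traj.r_index + int(round(traj.windows.T_off_rel * traj.fs / 1000.0))
    on, off = max(0, on), min(len(traj.points), off)
    if off <= on:
        raise VcgError("empty VG integration window")
    dt_ms = 1000.0 / traj.fs
    vg = traj.points[on:off].sum(axis=0) * dt_ms
    mag = float(np.linalg.norm(vg))
    if mag < 1e-6:
        return VentricularGradient(vg, mag, None, None, None, None, None)
    x, y, z = (float(v) for v in vg)
    az = _plane_angle(x, z)
    sag = _plane_angle(y, z)
    return VentricularGradient(
        vg=vg,
        magnitude=mag,
        azimuth_horizontal_deg=az,
        sagittal_angle_deg=sag,
        sin_azimuth_horizontal=math.sin(math.radians(az)) if az is not None else None,
        sin_sagittal=math.sin(math.radians(sag)) if sag is not None else None,
        elevation_3d_deg=math.degrees(math.asin(np.clip(z / mag, -1.0, 1.0))),
    )


def vcg_lead_scalars(traj: VcgTrajectory) -> dict[str, float]:
    """Signed QRS-window extremum of each derived axis, referenced to window onset."""
    sl = _window_slice(traj, "QRS")
    seg = traj.points[sl] - traj.points[sl.start]
    out = {}
    for i, axis in enumerate(("x", "y", "z")):
        col = seg[:, i]
        idx = int(np.argmax(np.abs(col)))
        out[f"r_amplitude_{axis}"] = float(col[idx])
    return out


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

_LOOP_FIELDS = (
    "ln_sigma1", "sigma2", "sigma3", "sigma2_over_sigma1", "ln_nondipolar_ratio",
    "planarity", "peak_magnitude", "time_to_peak_ms", "time_voltage_area",
    "max_to_mean_ratio",
)

VCG_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{w}_{f}" for w in ("p", "qrs", "t") for f in _LOOP_FIELDS]
    + [
        "p_qrs_mean_vector_angle_deg",
        "qrs_t_mean_vector_angle_deg",
        "qrs_t_eigvec1_angle_deg",
        "vg_magnitude",
        "vg_azimuth_horizontal_deg",
        "vg_sagittal_angle_deg",
        "vg_sin_azimuth_horizontal",
        "vg_sin_sagittal",
        "vg_elevation_deg",
        "r_amplitude_y",
        "r_amplitude_z",
    ]
)

assert len(VCG_FEATURE_NAMES) == 41


def compute_all_vcg_features(
    matrix: MedianBeatMatrix, K: np.ndarray = KORS_MATRIX
) -> dict[str, float | None]:
    """Compute the full 41-feature VCG registry for one record.

    Absent loops (e.g. no P window) yield missing values; component errors
    propagate as missing values, never as fabricated numbers.
    """
    traj = kors_transform(matrix, K)
    out: dict[str, float | None] = {name: None for name in VCG_FEATURE_NAMES}

    loops: dict[str, np.ndarray | None] = {}
    for wave in ("P", "QRS", "T"):
        try:
            loops[wave] = extract_loop(traj, wave)
        except VcgError:
            loops[wave] = None

    summaries: dict[str, LoopSummary | None] = {}
    means: dict[str, np.ndarray | None] = {}
    for wave, prefix in (("P", "p"), ("QRS", "qrs"), ("T", "t")):
        loop = loops[wave]
        if loop is None:
            summaries[wave] = None
            means[wave] = None
            continue
        summ = loop_svd(loop)
        summaries[wave] = summ
        out[f"{prefix}_ln_sigma1"] = summ.ln_sigma1
        out[f"{prefix}_sigma2"] = summ.sigma2
        out[f"{prefix}_sigma3"] = summ.sigma3
        out[f"{prefix}_sigma2_over_sigma1"] = summ.sigma2_over_sigma1
        out[f"{prefix}_ln_nondipolar_ratio"] = summ.ln_nondipolar_ratio
        out[f"{prefix}_planarity"] = summ.planarity
        mf = loop_magnitude_features(loop, traj.fs)
        means[wave] = mf["mean_vector"]
        for key in ("peak_magnitude", "time_to_peak_ms", "time_voltage_area", "max_to_mean_ratio"):
            out[f"{prefix}_{key}"] = mf[key]

    if means["P"] is not None and means["QRS"] is not None:
        out["p_qrs_mean_vector_angle_deg"] = spatial_angle(means["P"], means["QRS"])
    if means["QRS"] is not None and means["T"] is not None:
        out["qrs_t_mean_vector_angle_deg"] = spatial_angle(means["QRS"], means["T"])
    if summaries["QRS"] is not None and summaries["T"] is not None:
        out["qrs_t_eigvec1_angle_deg"] = spatial_angle(
            summaries["QRS"].eigvecs[0], summaries["T"].eigvecs[0]
        )

    try:
        vg = ventricular_gradient(traj)
    except VcgError:
        vg = None
    if vg is not None:
        out["vg_magnitude"] = vg.magnitude
        out["vg_azimuth_horizontal_deg"] = vg.azimuth_horizontal_deg
        out["vg_sagittal_angle_deg"] = vg.sagittal_angle_deg
        out["vg_sin_azimuth_horizontal"] = vg.sin_azimuth_horizontal
        out["vg_sin_sagittal"] = vg.sin_sagittal
        out["vg_elevation_deg"] = vg.elevation_3d_deg

    if loops["QRS"] is not None:
        scalars = vcg_lead_scalars(traj)
        out["r_amplitude_y"] = scalars["r_amplitude_y"]
        out["r_amplitude_z"] = scalars["r_amplitude_z"]
    return out
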