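"""Reading and writing 12-lead ECG records, manifests and exclusion rules.

Records are exchanged either as WFDB header/signal pairs (format 16 only,
the layout used by 500 Hz 12-lead resting ECG exports) or as a simple CSV
dialect: first column ``time_s`` followed by the 12 lead columns named
``I, II, III, aVR, aVL, aVF, V1..V6`` with values in mV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The 8 linearly independent leads, in the fixed order used downstream.
INDEPENDENT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

TARGET_FS = 500.0


class EcgIoError(Exception):
    """Raised for unreadable, incomplete or ambiguous record input."""


@dataclass
class EcgRecord:
    """A 12-lead ECG with optional report text, machine features and label.

    All lead series are float arrays in mV with a common length.
    """

    record_id: str
    patient_id: str
    sampling_rate: float
    leads: dict[str, np.ndarray]
    report_text: str | None = None
    machine_numeric: dict[str, float] | None = None
    machine_flags: dict[str, bool] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise EcgIoError(f"sampling_rate must be positive, got {self.sampling_rate}")
        missing = [name for name in LEAD_NAMES if name not in self.leads]
        if missing:
            raise EcgIoError(f"lead {missing[0]} absent")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise EcgIoError(f"leads have unequal lengths: {sorted(lengths)}")
        for name in LEAD_NAMES:
            arr = np.asarray(self.leads[name], dtype=float)
            if not np.all(np.isfinite(arr)):
                raise EcgIoError(f"lead {name} contains non-finite samples")
            self.leads[name] = arr

    @property
    def n_samples(self) -> int:
        return len(self.leads["I"])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead_matrix(self, names: Sequence[str] = INDEPENDENT_LEADS) -> np.ndarray:
        """Stack the named leads into an (n_leads, n_samples) array."""
        return np.vstack([self.leads[n] for n in names])


def derive_augmented_leads(
    lead_i: np.ndarray, lead_ii: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (III, aVR, aVL, aVF) from leads I and II by Einthoven/Goldberger algebra."""
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise EcgIoError(
            f"lead I and II length mismatch: {lead_i.shape} vs {lead_ii.shape}"
        )
    lead_iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return lead_iii, avr, avl, avf


def complete_leads(leads: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Fill in the four augmented limb leads when only the 8 independent leads exist."""
    out = {k: np.asarray(v, dtype=float) for k, v in leads.items()}
    if all(n in out for n in ("III", "aVR", "aVL", "aVF")):
        return out
    if "I" not in out or "II" not in out:
        raise EcgIoError("lead I absent" if "I" not in out else "lead II absent")
    iii, avr, avl, avf = derive_augmented_leads(out["I"], out["II"])
    out.setdefault("III", iii)
    out.setdefault("aVR", avr)
    out.setdefault("aVL", avl)
    out.setdefault("aVF", avf)
    return out


def _resample_to(leads: dict[str, np.ndarray], fs: float, target: float) -> dict[str, np.ndarray]:
    from fractions import Fraction

    frac = Fraction(target / fs).limit_denominator(1000)
    return {
        k: resample_poly(v, frac.numerator, frac.denominator) for k, v in leads.items()
    }


# ---------------------------------------------------------------------------
# WFDB (format 16) header/signal I/O.
#
# Only the subset of the header grammar needed for 12-lead resting ECGs is
# supported: one segment, format 16 (little-endian int16), explicit
# gain(baseline)/units per signal.  The ``wfdb`` reference package is not
# available in the runtime environment, so this minimal reader/writer is
# provided in its place.
# ---------------------------------------------------------------------------

_SIGNAL_SPEC = re.compile(
    r"^(?P<fname>\S+)\s+(?P<fmt>\d+)\s+(?P<gain>[-\d.]+)"
    r"(?:\((?P<baseline>[-\d]+)\))?(?:/(?P<units>\S+))?\s+\S+\s+\S+\s+\S+\s+\S+\s+\S+\s+(?P<desc>.+)$"
)


def write_wfdb(record: EcgRecord, directory: str | Path, gain: float = 1000.0) -> Path:
    """Write ``record`` as ``<record_id>.hea`` + ``<record_id>.dat`` (format 16).

    Returns the header path.  Samples are quantized to ``round(value * gain)``
    ADC counts, so the round-trip error is at most half a quantization step.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    n = record.n_samples
    lines = [f"{name} {len(LEAD_NAMES)} {record.sampling_rate:g} {n}"]
    data = np.empty((n, len(LEAD_NAMES)), dtype="<i2")
    for j, lead in enumerate(LEAD_NAMES):
        counts = np.round(record.leads[lead] * gain)
        if np.any(np.abs(counts) > 32767):
            raise EcgIoError(f"lead {lead} overflows int16 at gain {gain}")
        data[:, j] = counts.astype("<i2")
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    if record.report_text:
        lines.append(f"# report: {record.report_text}")
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    (directory / f"{name}.dat").write_bytes(data.tobytes())
    return hea


def _read_wfdb(path: Path) -> tuple[dict[str, np.ndarray], float, str | None]:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise EcgIoError(f"header not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    lines = [ln for ln in lines if not ln.startswith("#")]
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        m = _SIGNAL_SPEC.match(ln)
        if m is None:
            raise EcgIoError(f"unparseable signal line in {hea}: {ln!r}")
        if int(m["fmt"]) != 16:
            raise EcgIoError(f"unsupported WFDB format {m['fmt']} (only 16)")
        gain = float(m["gain"])
        if gain == 0:
            raise EcgIoError(
                f"signal {m['desc']!r} has zero gain: raw ADC counts without a "
                "physical-unit calibration are ambiguous"
            )
        units = m["units"] or "mV"
        if units not in ("mV", "uV", "mv", "uV"):
            raise EcgIoError(f"unsupported amplitude unit {units!r}")
        specs.append((m["fname"], gain, int(m["baseline"] or 0), units, m["desc"].strip()))
    fnames = {s[0] for s in specs}
    if len(fnames) != 1:
        raise EcgIoError("multi-file WFDB records are not supported")
    dat = hea.parent / specs[0][0]
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    raw = raw.reshape(n_samp, n_sig)
    leads: dict[str, np.ndarray] = {}
    for j, (_, gain, baseline, units, desc) in enumerate(specs):
        scale = 1.0 if units.lower() == "mv" else 1e-3
        leads[desc] = (raw[:, j].astype(float) - baseline) / gain * scale
    report = None
    for c in comments:
        if c.lower().startswith("report:"):
            report = c.split(":", 1)[1].strip()
    return leads, fs, report


def _read_csv(path: Path) -> tuple[dict[str, np.ndarray], float]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise EcgIoError(f"CSV {path} lacks required first column 'time_s'")
    for lead in LEAD_NAMES:
        if lead not in df.columns:
            raise EcgIoError(f"lead {lead} absent")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise EcgIoError("CSV record shorter than 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise EcgIoError("CSV time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    return {lead: df[lead].to_numpy(dtype=float) for lead in LEAD_NAMES}, fs


def read_record(
    path: str | Path,
    dialect: str = "wfdb",
    *,
    record_id: str | None = None,
    patient_id: str = "",
    resample_non_target: bool = True,
    **meta,
) -> EcgRecord:
    """Read one 12-lead record from ``path``.

    Parameters
    ----------
    path : path to ``.hea``/``.dat`` pair (``dialect='wfdb'``) or CSV file.
    dialect : ``'wfdb'`` or ``'csv'``.
    resample_non_target : if True (default), records not sampled at 500 Hz are
        polyphase-resampled to 500 Hz; if False such records are rejected.
    meta : forwarded to :class:`EcgRecord` (label, report_text, machine_*).
    """
    path = Path(path)
    if dialect == "wfdb":
        leads, fs, report = _read_wfdb(path)
        if report is not None and "report_text" not in meta:
            meta["report_text"] = report
    elif dialect == "csv":
        leads, fs = _read_csv(path)
    else:
        raise EcgIoError(f"unknown dialect {dialect!r}")
    leads = complete_leads(leads)
    if abs(fs - TARGET_FS) > 1e-6:
        if not resample_non_target:
            raise EcgIoError(f"record sampled at {fs} Hz, expected {TARGET_FS}")
        leads = _resample_to(leads, fs, TARGET_FS)
        fs = TARGET_FS
    return EcgRecord(
        record_id=record_id or path.stem,
        patient_id=patient_id,
        sampling_rate=fs,
        leads=leads,
        **meta,
    )


def write_csv(record: EcgRecord, path: str | Path) -> Path:
    """Write the CSV dialect (time_s + 12 lead columns, mV)."""
    path = Path(path)
    t = np.arange(record.n_samples) / record.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for lead in LEAD_NAMES:
        df[lead] = record.leads[lead]
    df.to_csv(path, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Report-text exclusion rules
# ---------------------------------------------------------------------------

#: Default machine-report exclusion phrases.  Phrase lists are configurable;
#: these cover paced rhythm, artifact, bundle branch block, fascicular /
#: posterior block, intraventricular conduction defect, PVCs, atrial
#: fibrillation and atrial flutter.
DEFAULT_EXCLUSION_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("paced", ("paced rhythm", "pacemaker", "ventricular pacing", "atrial pacing")),
    ("artifact", ("artifact", "artefact", "poor quality", "lead reversal")),
    ("bbb", ("bundle branch block", "bundle-branch block", "lbbb", "rbbb")),
    ("fascicular_block", ("fascicular block", "posterior block", "hemiblock")),
    ("ivcd", ("intraventricular conduction defect", "intraventricular conduction delay")),
    ("pvc", ("premature ventricular contraction", "premature ventricular complexes", "ventricular premature")),
    ("afib", ("atrial fibrillation", "a-fib", "afib")),
    ("aflutter", ("atrial flutter", "a-flutter")),
)

NEGATION_MARKERS = ("no ", "without ", "not ")
NEGATION_WINDOW = 30  # characters looked back for a negation marker


def _phrase_matches(text: str, phrase: str, window: int) -> bool:
    start = 0
    while True:
        idx = text.find(phrase, start)
        if idx < 0:
            return False
        prefix = text[max(0, idx - window) : idx]
        if not any(marker in prefix for marker in NEGATION_MARKERS):
            return True
        start = idx + 1


def exclusion_filter(
    report_text: str | None,
    rules: Iterable[tuple[str, Iterable[str]]] = DEFAULT_EXCLUSION_RULES,
    *,
    strict_empty: bool = True,
    negation_window: int = NEGATION_WINDOW,
) -> tuple[str, list[str]]:
    """Decide keep/exclude for a machine report.

    Matching is case-insensitive substring search with a negation guard:
    phrases preceded by "no "/"without "/"not " within ``negation_window``
    characters do not match.

    Returns ``(decision, matched_rule_names)`` with decision in
    ``{'keep', 'exclude'}``.  An empty/missing report excludes with reason
    ``'no report'`` in strict mode, keeps with no matches otherwise.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("rules must be non-empty")
    if report_text is None or not report_text.strip():
        if strict_empty:
            return "exclude", ["no report"]
        return "keep", []
    text = report_text.lower()
    matched = [
        name
        for name, phrases in rules
        if any(_phrase_matches(text, p.lower(), negation_window) for p in phrases)
    ]
    return ("exclude" if matched else "keep"), matched


def select_primary_ecg(
    candidates: Sequence[tuple[str, bool, bool, float]],
) -> str:
    """Pick one record per patient.

    ``candidates`` holds ``(record_id, is_clean, label_definitive, timestamp)``
    tuples.  Priority: clean first, then definitive label, then earliest
    timestamp, then record_id ascending (full determinism).
    """
    if not candidates:
        raise ValueError("no candidate records")
    return min(
        candidates,
        key=lambda c: (not c[1], not c[2], c[3], c[0]),
    )[0]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: record_id, patient_id, path, label.  Optional:
    report_text plus any number of machine_num_* / machine_flag_* columns.
    """
    df = pd.read_csv(path)
    required = ["record_id", "patient_id", "path", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EcgIoError(f"manifest missing column(s): {', '.join(missing)}")
    return df


def record_from_manifest_row(row: pd.Series, base_dir: str | Path, dialect: str = "wfdb") -> EcgRecord:
    """Load the record referenced by a manifest row, attaching metadata."""
    machine_numeric = {
        c[len("machine_num_"):]: float(row[c])
        for c in row.index
        if c.startswith("machine_num_") and pd.notna(row[c])
    }
    machine_flags = {
        c[len("machine_flag_"):]: bool(row[c])
        for c in row.index
        if c.startswith("machine_flag_") and pd.notna(row[c])
    }
    report = row.get("report_text")
    return read_record(
        Path(base_dir) / str(row["path"]),
        dialect=dialect,
        record_id=str(row["record_id"]),
        patient_id=str(row["patient_id"]),
        label=str(row["label"]) if pd.notna(row["label"]) else None,
        report_text=str(report) if isinstance(report, str) and report else None,
        machine_numeric=machine_numeric or None,
        machine_flags=machine_flags or None,
    )
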