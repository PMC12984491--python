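"""Between-group feature comparisons: Mann-Whitney U, Cliff's delta, risk
difference, and top-k discriminative feature ranking.

No multiplicity adjustment is applied by default; optional Benjamini-
Hochberg adjusted p-values can be appended, clearly labeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration limit (n1 + n2)


@dataclass
class ComparisonRow:
    feature: str
    median_1: float | None
    iqr_1: tuple[float, float] | None
    median_2: float | None
    iqr_2: tuple[float, float] | None
    effect_size: float | None
    effect_type: str  # 'cliffs_delta' | 'risk_difference'
    p_value: float | None
    n1: int
    n2: int


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n1 + n2 <= EXACT_MAX_N and there are no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.  Returns (U for x, two-sided p).
    """
    x = np.asarray([v for v in x if np.isfinite(v)], dtype=float)
    y = np.asarray([v for v in y if np.isfinite(v)], dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty after missing removal")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """(#{x_i > y_j} - #{x_i < y_j}) / (n1 * n2)."""
    x = np.asarray([v for v in x if np.isfinite(v)], dtype=float)
    y = np.asarray([v for v in y if np.isfinite(v)], dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(x) * len(y)))


def risk_difference(k1: int, n1: int, k2: int, n2: int) -> float:
    """Difference of proportions k1/n1 - k2/n2."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    return k1 / n1 - k2 / n2


def two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float | None:
    """Two-sided two-proportion z-test with continuity correction."""
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return None
    diff = abs(k1 / n1 - k2 / n2)
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = max(0.0, diff - cc) / se
    return float(2 * stats.norm.sf(z))


def _is_boolean(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return series.dtype == bool or (
        len(vals) > 0 and set(np.unique(vals)).issubset({0.0, 1.0, 0, 1, True, False})
    )


def compare_groups(
    features: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str],
    alpha: float = 0.05,
    *,
    boolean_features: Sequence[str] | None = None,
    append_adjusted: bool = False,
) -> list[ComparisonRow]:
    """One ComparisonRow per feature column, sorted by p-value.

    Numeric features get Mann-Whitney U + Cliff's delta; Boolean features get
    a two-proportion z-test + risk difference.  Constant features yield rows
    with missing p (logged).
    """
    g1, g2 = groups
    mask1 = (labels == g1).to_numpy()
    mask2 = (labels == g2).to_numpy()
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError(f"need >= 2 members per group, got {mask1.sum()} and {mask2.sum()}")
    boolean_set = set(boolean_features or [])
    rows: list[ComparisonRow] = []
    for col in features.columns:
        series = features[col]
        x = series[mask1].dropna().to_numpy(dtype=float)
        y = series[mask2].dropna().to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            rows.append(ComparisonRow(col, None, None, None, None, None, "cliffs_delta", None, len(x), len(y)))
            continue
        is_bool = col in boolean_set or (boolean_features is None and _is_boolean(series))
        if is_bool:
            k1, k2 = int(np.sum(x)), int(np.sum(y))
            effect = risk_difference(k1, len(x), k2, len(y))
            p = two_proportion_p(k1, len(x), k2, len(y))
            rows.append(
                ComparisonRow(
                    col, float(np.mean(x)), None, float(np.mean(y)), None,
                    effect, "risk_difference", p, len(x), len(y),
                )
            )
            continue
        constant = len(np.unique(np.concatenate([x, y]))) < 2
        if constant:
            logger.info("feature %s constant in both groups: p missing", col)
            p = None
            effect = 0.0
        else:
            _, p = mann_whitney_u(x, y)
            effect = cliffs_delta(x, y)
        rows.append(
            ComparisonRow(
                col,
                float(np.median(x)), (float(np.percentile(x, 25)), float(np.percentile(x, 75))),
                float(np.median(y)), (float(np.percentile(y, 25)), float(np.percentile(y, 75))),
                effect, "cliffs_delta", p, len(x), len(y),
            )
        )
    rows.sort(key=lambda r: (r.p_value is None, r.p_value if r.p_value is not None else 1.0, r.feature))
    return rows


def rank_features(rows: Sequence[ComparisonRow], k: int = 15) -> list[str]:
    """Top-k features by |effect size|; ties broken by smaller p, then name."""
    valid = [r for r in rows if r.effect_size is not None and r.p_value is not None]
    if len(valid) < k:
        logger.warning("only %d valid rows for top-%d ranking", len(valid), k)
    ranked = sorted(valid, key=lambda r: (-abs(r.effect_size), r.p_value, r.feature))
    return [r.feature for r in ranked[:k]]


def comparison_to_frame(rows: Sequence[ComparisonRow], groups: tuple[str, str]) -> pd.DataFrame:
    """Table-style export: feature, median [IQR] per group, effect size, p."""
    g1, g2 = groups

    def fmt(median, iqr):
        if median is None:
            return ""
        if iqr is None:
            return f"{median:.3f}"
        return f"{median:.3f} [{iqr[0]:.3f}, {iqr[1]:.3f}]"

    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            f"{g1} (n)": [r.n1 for r in rows],
            f"{g1} median [IQR]": [fmt(r.median_1, r.iqr_1) for r in rows],
            f"{g2} (n)": [r.n2 for r in rows],
            f"{g2} median [IQR]": [fmt(r.median_2, r.iqr_2) for r in rows],
            "effect_size": [r.effect_size for r in rows],
            "effect_type": [r.effect_type for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
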