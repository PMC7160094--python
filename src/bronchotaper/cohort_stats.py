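"""Cohort-level statistics: artery-size stratification, per-subject
robust summaries, rank-based group comparison and correlation with
visual scores.

Branches are stratified into small / medium / large airways by the
diameter of the accompanying artery, with thresholds at the 33.33rd and
66.67th percentiles (linear interpolation) of the artery diameters of a
reference cohort — three equally sized groups on that cohort.  The
per-subject median summarises each biomarker; groups are compared with
the two-sided Mann-Whitney U test (exact when both groups are small and
tie-free, normal approximation with tie and continuity corrections
otherwise) and monotone association with the visual bronchiectasis
score is measured by Spearman's rank correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SizeThresholds",
    "CohortSummary",
    "derive_size_thresholds",
    "assign_size_groups",
    "per_subject_medians",
    "compare_groups",
    "correlate_with_visual",
    "holm_adjust",
    "cohort_summary_table",
]

logger = logging.getLogger(__name__)

#: Combined sample size up to which the exact Mann-Whitney null is used
#: (when there are no ties).
EXACT_MWU_MAX_N = 12

SIZE_GROUPS = ("small", "medium", "large")


@dataclass(frozen=True)
class SizeThresholds:
    """Artery-diameter cut points (mm) splitting branches into tertiles."""

    low: float
    high: float
    source_cohort_id: str = ""

    def classify(self, artery_diameter: float) -> str:
        if np.isnan(artery_diameter):
            return "unassigned"
        if artery_diameter < self.low:
            return "small"
        if artery_diameter > self.high:
            return "large"
        return "medium"


@dataclass
class CohortSummary:
    """Comparison of one biomarker between two groups of subjects."""

    biomarker: str
    labels: tuple[str, str]
    medians_a: dict[str, float]
    medians_b: dict[str, float]
    median_a: float = field(init=False)
    median_b: float = field(init=False)
    iqr_a: tuple[float, float] = field(init=False)
    iqr_b: tuple[float, float] = field(init=False)
    u_statistic: float = np.nan
    p_value: float = np.nan
    n_a: int = field(init=False)
    n_b: int = field(init=False)
    method: str = ""

    def __post_init__(self) -> None:
        for suffix, medians in (("a", self.medians_a), ("b", self.medians_b)):
            vals = np.asarray(list(medians.values()), dtype=float)
            setattr(self, f"n_{suffix}", len(vals))
            setattr(self, f"median_{suffix}", float(np.median(vals)))
            q25, q75 = np.percentile(vals, [25, 75])
            setattr(self, f"iqr_{suffix}", (float(q25), float(q75)))


def derive_size_thresholds(reference_branches: pd.DataFrame,
                           source_cohort_id: str = "") -> SizeThresholds:
    """Tertile thresholds from the accompanying-artery diameters of a
    reference cohort's paired branches (column ``artery_mm``)."""
    d = reference_branches["artery_mm"].to_numpy(dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 3:
        raise ValueError(
            f"need >= 3 paired branches with artery diameters, got {len(d)}"
        )
    low, high = np.percentile(d, [100.0 / 3.0, 200.0 / 3.0])
    if not low < high:
        warnings.warn(
            "degenerate artery-size thresholds (all diameters equal); "
            "every branch will fall in the 'medium' group",
            stacklevel=2,
        )
    return SizeThresholds(float(low), float(high), source_cohort_id)


def assign_size_groups(branches: pd.DataFrame,
                       thresholds: SizeThresholds) -> pd.DataFrame:
    """Return a copy with ``size_group`` filled from ``artery_mm``; a
    pure function of the diameter, so thresholds transfer unchanged
    across cohorts."""
    out = branches.copy()
    out["size_group"] = [
        thresholds.classify(d) for d in out["artery_mm"].to_numpy(dtype=float)
    ]
    return out


def per_subject_medians(branches: pd.DataFrame, biomarker: str,
                        size_group: str = "all") -> dict[str, float]:
    """Median of one biomarker per subject, optionally within one artery
    size stratum; missing values are excluded first and subjects with no
    usable branch in the stratum are omitted (logged)."""
    table = branches
    if size_group != "all":
        table = table[table["size_group"] == size_group]
    medians: dict[str, float] = {}
    for sid, sub in table.groupby("subject_id", sort=True):
        vals = sub[biomarker].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            logger.info(
                "subject %s: no usable %s branches in stratum %s; omitted",
                sid, biomarker, size_group,
            )
            continue
        medians[str(sid)] = float(np.median(vals))
    return medians


def compare_groups(medians_a: dict[str, float], medians_b: dict[str, float],
                   biomarker: str = "",
                   labels: tuple[str, str] = ("a", "b")) -> CohortSummary:
    """Two-sided Mann-Whitney U comparison of per-subject medians.

    The exact null distribution is enumerated when the combined sample
    size is at most 12 and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(list(medians_a.values()), dtype=float)
    b = np.asarray(list(medians_b.values()), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one subject")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) + len(b) <= EXACT_MWU_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    summary = CohortSummary(
        biomarker=biomarker,
        labels=labels,
        medians_a=medians_a,
        medians_b=medians_b,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
    )
    return summary


def correlate_with_visual(medians: dict[str, float],
                          scores: dict[str, float]) -> tuple[float, float]:
    """Spearman rank correlation between per-subject biomarker medians
    and visual bronchiectasis scores over subjects carrying both.

    Returns ``(rho, p)``; degenerate ranks (either variable constant)
    yield ``(nan, nan)``.
    """
    common = sorted(set(medians) & set(scores))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 subjects with both biomarker and score, got {len(common)}"
        )
    x = np.asarray([medians[s] for s in common], dtype=float)
    y = np.asarray([scores[s] for s in common], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (optional; comparisons are reported
    unadjusted by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def cohort_summary_table(branches: pd.DataFrame, phenotypes: dict[str, str],
                         thresholds: SizeThresholds | None = None,
                         biomarkers: tuple[str, ...] = (
                             "aa_inner", "aa_outer",
                             "intraBT_inner", "intraBT_outer",
                             "interBT_inner", "interBT_outer",
                         ),
                         labels: tuple[str, str] = ("bronchiectasis", "control"),
                         ) -> pd.DataFrame:
    """Group comparison of every biomarker, overall and per artery-size
    stratum: median [IQR] per group, U and p per row."""
    if thresholds is not None:
        branches = assign_size_groups(branches, thresholds)
    strata = ("all",) + (SIZE_GROUPS if thresholds is not None else ())
    rows = []
    for biomarker in biomarkers:
        for stratum in strata:
            med = per_subject_medians(branches, biomarker, stratum)
            group_a = {s: v for s, v in med.items()
                       if phenotypes.get(s) == labels[0]}
            group_b = {s: v for s, v in med.items()
                       if phenotypes.get(s) == labels[1]}
            if not group_a or not group_b:
                continue
            cs = compare_groups(group_a, group_b, biomarker, labels)
            rows.append(
                {
                    "biomarker": biomarker,
                    "size_group": stratum,
                    f"median_{labels[0]}": cs.median_a,
                    f"iqr25_{labels[0]}": cs.iqr_a[0],
                    f"iqr75_{labels[0]}": cs.iqr_a[1],
                    f"median_{labels[1]}": cs.median_b,
                    f"iqr25_{labels[1]}": cs.iqr_b[0],
                    f"iqr75_{labels[1]}": cs.iqr_b[1],
                    "U": cs.u_statistic,
                    "p": cs.p_value,
                    f"n_{labels[0]}": cs.n_a,
                    f"n_{labels[1]}": cs.n_b,
                    "method": cs.method,
                }
            )
    return pd.DataFrame(rows)
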