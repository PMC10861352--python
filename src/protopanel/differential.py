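"""Per-marker two-group statistics and the volcano significance rule.

Each marker is compared between cases and controls with three tests — a
two-sample t-test (Welch by default), the two-sample Kolmogorov–Smirnov
test, and the Mann–Whitney test. The volcano rule flags a marker as
differentially expressed when |log2 fold change| >= 0.2 (inclusive) and the
t-test p-value < 0.05 (strict). Fold change is the case-minus-control mean
difference of the pre-standardization log2 values; all three p-values are
invariant to the per-marker affine standardization, so the tests may be run
on either scale.

Test dialects (small-sample behavior is sensitive to these):

* t: Welch (unequal variances) unless ``t_variant="pooled"``; zero variance
  in both groups with equal means gives p = 1 by convention (p = 0 when the
  means differ).
* KS: exact p-value when ``n_case * n_control <= 10_000``, else asymptotic.
* Mann–Whitney: exact enumeration when both groups have <= 8 observations
  and there are no ties; otherwise the normal approximation with tie and
  continuity corrections.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GroupLabels

UP, DOWN, NS = "up", "down", "ns"

MarkerTestResult = namedtuple(
    "MarkerTestResult", ["p_t", "p_ks", "p_mw", "t_stat", "ks_stat", "mw_stat"]
)
VolcanoCounts = namedtuple("VolcanoCounts", ["up", "down", "ns"])

_KS_EXACT_MAX = 10_000
_MW_EXACT_MAX = 8


@dataclass
class VolcanoThresholds:
    """Significance gates: |log2FC| >= fc_min and p < p_max."""

    fc_min: float = 0.2
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not self.fc_min > 0:
            raise ValueError("fc_min must be > 0")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")


@dataclass
class MarkerStat:
    """Differential summary for one marker."""

    marker_id: str
    log2fc: float
    p_t: float
    p_ks: float
    p_mw: float
    t_stat: float = 0.0
    ks_stat: float = 0.0
    mw_stat: float = 0.0
    volcano_class: str = NS


def marker_log2fc(case_values, control_values) -> float:
    """Case mean minus control mean, inputs already on the log2 scale."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups need at least one value")
    return float(case_values.mean() - control_values.mean())


def _t_pvalues(case: np.ndarray, control: np.ndarray, variant: str):
    res = stats.ttest_ind(case, control, axis=0, equal_var=(variant == "pooled"))
    stat = np.atleast_1d(np.asarray(res.statistic, dtype=float))
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    # zero variance in both groups: scipy yields nan
    bad = ~np.isfinite(stat)
    if bad.any():
        eq = np.isclose(case.mean(axis=0), control.mean(axis=0))
        eq = np.atleast_1d(eq)
        stat[bad] = 0.0
        p[bad & eq] = 1.0
        p[bad & ~eq] = 0.0
    return stat, p


def _ks_one(case: np.ndarray, control: np.ndarray):
    method = "exact" if len(case) * len(control) <= _KS_EXACT_MAX else "asymp"
    res = stats.ks_2samp(case, control, method=method)
    return float(res.statistic), float(res.pvalue)


def _mw_method(case: np.ndarray, control: np.ndarray) -> str:
    if len(case) <= _MW_EXACT_MAX and len(control) <= _MW_EXACT_MAX:
        pooled = np.r_[case, control]
        if len(np.unique(pooled)) == len(pooled):
            return "exact"
    return "asymptotic"


def _mw_one(case: np.ndarray, control: np.ndarray):
    res = stats.mannwhitneyu(
        case, control, alternative="two-sided",
        method=_mw_method(case, control), use_continuity=True,
    )
    u = float(res.statistic)
    return abs(u - len(case) * len(control) / 2.0), float(res.pvalue)


def marker_tests(case_values, control_values, t_variant: str = "welch"):
    """Two-sided p-values (p_t, p_ks, p_mw) for one marker.

    Requires >= 2 values per group for the t-test. Returns a
    :class:`MarkerTestResult` whose first three fields are the p-values, so
    it unpacks as a triple of (p_t, p_ks, p_mw, ...).
    """
    if t_variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {t_variant!r}")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("the t-test needs at least 2 values per group")
    t_stat, p_t = _t_pvalues(case, control, t_variant)
    ks_stat, p_ks = _ks_one(case, control)
    mw_stat, p_mw = _mw_one(case, control)
    return MarkerTestResult(float(p_t[0]), p_ks, p_mw,
                            float(t_stat[0]), ks_stat, mw_stat)


def compute_marker_stats(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    t_variant: str = "welch",
) -> list[MarkerStat]:
    """All per-marker statistics for a cohort, vectorized where possible.

    Fold changes use the pre-standardization log2 values; tests run on the
    same values (their p-values are standardization-invariant).
    """
    if matrix.subject_ids != labels.subject_ids:
        raise ValueError("matrix and labels subject orderings differ")
    if labels.n_case < 2 or labels.n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    log2v = matrix.log2_frame().to_numpy()
    is_case = labels.status == 1
    case, control = log2v[is_case], log2v[~is_case]

    log2fc = case.mean(axis=0) - control.mean(axis=0)
    t_stat, p_t = _t_pvalues(case, control, t_variant)

    ks = [_ks_one(case[:, j], control[:, j]) for j in range(matrix.p)]

    n1, n0 = case.shape[0], control.shape[0]
    if n1 <= _MW_EXACT_MAX and n0 <= _MW_EXACT_MAX:
        mw = [_mw_one(case[:, j], control[:, j]) for j in range(matrix.p)]
        mw_stat = np.array([m[0] for m in mw])
        p_mw = np.array([m[1] for m in mw])
    else:
        res = stats.mannwhitneyu(case, control, axis=0, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        mw_stat = np.abs(np.asarray(res.statistic, dtype=float) - n1 * n0 / 2.0)
        p_mw = np.asarray(res.pvalue, dtype=float)

    return [
        MarkerStat(
            marker_id=m, log2fc=float(log2fc[j]),
            p_t=float(p_t[j]), p_ks=float(ks[j][1]), p_mw=float(p_mw[j]),
            t_stat=float(t_stat[j]), ks_stat=float(ks[j][0]),
            mw_stat=float(mw_stat[j]),
        )
        for j, m in enumerate(matrix.marker_ids)
    ]


def volcano_classify(
    stats_list: list[MarkerStat],
    thresholds: VolcanoThresholds | None = None,
) -> tuple[VolcanoCounts, list[MarkerStat]]:
    """Partition markers into up / down / not-significant.

    A marker is up when log2fc >= +fc_min and p_t < p_max, down when
    log2fc <= -fc_min and p_t < p_max, else ns; up + down + ns = p.
    """
    thr = thresholds or VolcanoThresholds()
    counts = {UP: 0, DOWN: 0, NS: 0}
    for s in stats_list:
        if s.p_t < thr.p_max and s.log2fc >= thr.fc_min:
            s.volcano_class = UP
        elif s.p_t < thr.p_max and s.log2fc <= -thr.fc_min:
            s.volcano_class = DOWN
        else:
            s.volcano_class = NS
        counts[s.volcano_class] += 1
    return VolcanoCounts(counts[UP], counts[DOWN], counts[NS]), stats_list


def stats_to_frame(stats_list: list[MarkerStat]) -> pd.DataFrame:
    """Volcano table: marker_id, log2fc, three p-values, class."""
    return pd.DataFrame(
        {
            "marker_id": [s.marker_id for s in stats_list],
            "log2fc": [s.log2fc for s in stats_list],
            "p_t": [s.p_t for s in stats_list],
            "p_ks": [s.p_ks for s in stats_list],
            "p_mw": [s.p_mw for s in stats_list],
            "volcano_class": [s.volcano_class for s in stats_list],
        }
    )
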