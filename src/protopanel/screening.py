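"""Sure independence screening with multi-test consensus.

In ultra-high-dimensional settings (p >> n), analyzing every marker jointly
invites noise accumulation and spurious correlation, so a marginal screen
first ranks markers by per-marker significance and keeps only the top d_n
per test. The recommended retention size is n/ln(n) (rounded); a more
conservative fixed d_n (default 50) can be used instead. Running the screen
under three different tests (t, Kolmogorov–Smirnov, Mann–Whitney) and
intersecting the three top-d_n lists keeps only markers that discriminate
consistently regardless of the test's notion of difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .differential import MarkerStat, compute_marker_stats
from .io import ExpressionMatrix, GroupLabels

TESTS = ("t", "ks", "mw")
_P_ATTR = {"t": "p_t", "ks": "p_ks", "mw": "p_mw"}
_STAT_ATTR = {"t": "t_stat", "ks": "ks_stat", "mw": "mw_stat"}


def recommended_dn(n: int) -> int:
    """The n/ln(n) retention size, rounded half away from zero (n=40 -> 11)."""
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    return int(math.floor(n / math.log(n) + 0.5))


@dataclass
class ScreeningConfig:
    d_n: int = 50
    tests: tuple[str, ...] = TESTS

    def __post_init__(self) -> None:
        if self.d_n < 1:
            raise ValueError("d_n must be a positive integer")
        if not self.tests:
            raise ValueError("at least one test required")
        unknown = [t for t in self.tests if t not in TESTS]
        if unknown:
            raise ValueError(f"unknown test(s): {unknown}")


@dataclass
class ScreeningResult:
    """Per-test top-d_n lists and their intersection (the consensus set)."""

    ranked_lists: dict[str, list[str]]
    consensus: list[str]
    d_n: int

    def to_frame(self, stats_list: list[MarkerStat]) -> pd.DataFrame:
        """Screening table with per-test ranks/p-values and consensus flag."""
        rows = {}
        for s in stats_list:
            rows[s.marker_id] = {"marker_id": s.marker_id}
        for test in self.ranked_lists:
            full = _full_ranking(stats_list, test)
            for rank, mid in enumerate(full, start=1):
                rows[mid][f"rank_{test}"] = rank
            for s in stats_list:
                rows[s.marker_id][f"p_{test}"] = getattr(s, _P_ATTR[test])
        in_cons = set(self.consensus)
        for mid in rows:
            rows[mid]["in_consensus"] = int(mid in in_cons)
        return pd.DataFrame(list(rows.values()))


def _full_ranking(stats_list: list[MarkerStat], test: str) -> list[str]:
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}")
    p_attr, s_attr = _P_ATTR[test], _STAT_ATTR[test]
    # ascending p, then descending |statistic|, then marker id: deterministic
    order = sorted(
        stats_list,
        key=lambda s: (getattr(s, p_attr), -abs(getattr(s, s_attr)), s.marker_id),
    )
    return [s.marker_id for s in order]


def rank_by_test(stats_list: list[MarkerStat], test: str, d_n: int) -> list[str]:
    """The d_n most significant markers under one test, most significant first."""
    if d_n > len(stats_list):
        raise ValueError(f"d_n={d_n} exceeds the number of markers {len(stats_list)}")
    return _full_ranking(stats_list, test)[:d_n]


def consensus_screen(
    stats_list: list[MarkerStat], config: ScreeningConfig | None = None
) -> ScreeningResult:
    """Intersect the per-test top-d_n lists.

    The consensus is ordered by ascending mean rank across the tests (marker
    id breaks ties); an empty intersection is a valid result but warns, since
    every downstream stage then has nothing to model.
    """
    cfg = config or ScreeningConfig()
    ranked = {t: rank_by_test(stats_list, t, cfg.d_n) for t in cfg.tests}
    common = set.intersection(*(set(lst) for lst in ranked.values()))
    full = {t: _full_ranking(stats_list, t) for t in cfg.tests}
    mean_rank = {
        m: np.mean([full[t].index(m) + 1 for t in cfg.tests]) for m in common
    }
    consensus = sorted(common, key=lambda m: (mean_rank[m], m))
    if not consensus:
        warnings.warn("consensus screen is empty: no marker is in every "
                      "top-d_n list", stacklevel=2)
    return ScreeningResult(ranked_lists=ranked, consensus=consensus, d_n=cfg.d_n)


class SureIndependenceScreen(TransformerMixin, BaseEstimator):
    """Consensus sure-independence screen as a scikit-learn feature selector.

    ``fit`` computes per-marker statistics on the training data (assumed to
    be log2 or standardized-log2 values), ranks markers under each requested
    test and intersects the per-test top-``d_n`` lists; ``transform``
    restricts a matrix to the consensus markers.

    Parameters
    ----------
    d_n : int, default=50
        Markers retained per test.
    tests : tuple of {"t", "ks", "mw"}
        Tests to run; the consensus intersects their top lists.
    t_variant : {"welch", "pooled"}
        Two-sample t-test flavor.

    Attributes
    ----------
    stats_ : list of MarkerStat
    result_ : ScreeningResult
    consensus_ : list of str
    support_ : bool array of shape (p,)
    """

    def __init__(self, d_n: int = 50, tests: tuple[str, ...] = TESTS,
                 t_variant: str = "welch"):
        self.d_n = d_n
        self.tests = tests
        self.t_variant = t_variant

    def _to_stats(self, X, y) -> tuple[list[MarkerStat], list[str]]:
        if isinstance(X, pd.DataFrame):
            marker_ids = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
            subject_ids = [str(i) for i in X.index]
        else:
            values = np.asarray(X, dtype=float)
            marker_ids = [f"x{j}" for j in range(values.shape[1])]
            subject_ids = [f"s{i}" for i in range(values.shape[0])]
        em = ExpressionMatrix(subject_ids, marker_ids, values, scale="log2")
        labels = GroupLabels(subject_ids, np.asarray(y))
        return compute_marker_stats(em, labels, t_variant=self.t_variant), marker_ids

    def fit(self, X, y):
        stats_list, marker_ids = self._to_stats(X, y)
        cfg = ScreeningConfig(d_n=self.d_n, tests=tuple(self.tests))
        if cfg.d_n > len(marker_ids):
            raise ValueError("d_n exceeds the number of markers")
        self.stats_ = stats_list
        self.result_ = consensus_screen(stats_list, cfg)
        self.consensus_ = self.result_.consensus
        in_cons = set(self.consensus_)
        self.support_ = np.array([m in in_cons for m in marker_ids])
        self.feature_names_in_ = np.asarray(marker_ids, dtype=object)
        self.n_features_in_ = len(marker_ids)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            missing = [m for m in self.consensus_ if m not in X.columns]
            if missing:
                raise KeyError(f"markers absent from input: {missing}")
            return X[self.consensus_]
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        order = [list(self.feature_names_in_).index(m) for m in self.consensus_]
        return X[:, order]
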