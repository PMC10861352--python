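"""Synthetic case-control proteomic cohorts.

The generator emulates the statistical shape the analysis pipeline assumes:
a small balanced cohort (default 20 cases vs. 20 controls) measured on many
markers (default p = 1433), with raw positive intensities whose log2 values
are Gaussian. A small planted subset of markers carries an additive shift on
the log2 scale, expressed in units of the marker's log2-scale SD (a
standardized effect size), in cases only. Optional block-equicorrelation
stresses the spurious-correlation behavior that motivates marginal
screening in p >> n problems.

Raw intensities are 2**(log2 value), so the pipeline's log2 transform
round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GroupLabels
from .panel import LogisticPanelModel


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a simulated case-control cohort.

    Defaults mirror the target study conditions: 20/20 subjects, 1433
    markers, five truly differential markers shifted by 2 SD on the log2
    scale, independent markers.

    Parameters
    ----------
    n_case, n_control
        Group sizes (each >= 2).
    p
        Number of markers.
    true_markers
        Column indices of the truly differential markers.
    delta
        Standardized log2-scale mean shift in cases, scalar or one value
        per true marker.
    sigma_log2
        Log2-scale SD, scalar or one value per marker (> 0).
    rho
        Within-block equicorrelation in [0, 1); 0 with ``block_size=1``
        gives mutually independent markers.
    block_size
        Markers per correlation block (consecutive columns).
    baseline_log2
        Control-group mean on the log2 scale (typical RFU magnitude ~2^10).
    seed
        Governs all randomness; identical seeds give bit-identical cohorts.
    """

    n_case: int = 20
    n_control: int = 20
    p: int = 1433
    true_markers: tuple[int, ...] = (0, 1, 2, 3, 4)
    delta: float | tuple[float, ...] = 2.0
    sigma_log2: float | tuple[float, ...] = 1.0
    rho: float = 0.0
    block_size: int = 1
    baseline_log2: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        tm = tuple(int(j) for j in self.true_markers)
        if len(set(tm)) != len(tm):
            raise ValueError("true_markers must be distinct")
        if tm and (min(tm) < 0 or max(tm) >= self.p):
            raise ValueError("true_markers out of range")
        if len(tm) > self.p:
            raise ValueError("more true markers than markers")
        object.__setattr__(self, "true_markers", tm)
        deltas = self._per_true_delta()
        sig = self._per_marker_sigma()
        if (sig <= 0).any():
            raise ValueError("sigma_log2 must be > 0")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        del deltas

    def _per_true_delta(self) -> np.ndarray:
        d = np.asarray(self.delta, dtype=float)
        if d.ndim == 0:
            return np.full(len(self.true_markers), float(d))
        if d.shape != (len(self.true_markers),):
            raise ValueError("delta must be scalar or one value per true marker")
        return d

    def _per_marker_sigma(self) -> np.ndarray:
        s = np.asarray(self.sigma_log2, dtype=float)
        if s.ndim == 0:
            return np.full(self.p, float(s))
        if s.shape != (self.p,):
            raise ValueError("sigma_log2 must be scalar or one value per marker")
        return s


def simulate_cohort(design: CohortDesign) -> tuple[ExpressionMatrix, GroupLabels]:
    """Draw one cohort: raw-scale intensities plus case/control labels.

    Cases come first in the subject ordering (fixed given the seed); marker
    ``j``'s log2 values are Gaussian with SD ``sigma_log2[j]``, mean
    ``baseline_log2`` in controls and ``baseline_log2 + delta_j*sigma_log2[j]``
    in cases iff ``j`` is a true marker.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_case + design.n_control
    p = design.p
    eps = rng.standard_normal((n, p))
    if design.rho > 0 and design.block_size > 1:
        n_blocks = -(-p // design.block_size)
        shared = rng.standard_normal((n, n_blocks))
        block_of = np.arange(p) // design.block_size
        z = np.sqrt(design.rho) * shared[:, block_of] + np.sqrt(1 - design.rho) * eps
    else:
        z = eps
    sigma = design._per_marker_sigma()
    log2_vals = design.baseline_log2 + sigma * z
    deltas = design._per_true_delta()
    for j, d in zip(design.true_markers, deltas):
        log2_vals[: design.n_case, j] += d * sigma[j]

    width = len(str(p))
    marker_ids = [f"M{j + 1:0{width}d}" for j in range(p)]
    subject_ids = [f"case{i + 1:02d}" for i in range(design.n_case)] + [
        f"ctrl{i + 1:02d}" for i in range(design.n_control)
    ]
    status = np.r_[np.ones(design.n_case, dtype=int),
                   np.zeros(design.n_control, dtype=int)]
    matrix = ExpressionMatrix(subject_ids, marker_ids, 2.0 ** log2_vals, scale="raw")
    return matrix, GroupLabels(subject_ids, status)


#: Published 12-marker preoperative plasma panel for postoperative delirium:
#: lasso logistic coefficients (per 1 SD of the standardized log2 marker) and
#: per-marker empirical AUCs. The intercept was not reported and is set to 0;
#: nothing downstream depends on it.
_REFERENCE_COEF = {
    "TARDBP": -0.595,
    "YARS2": 0.351,
    "PRL": 0.679,
    "IRF5": -0.105,
    "TNFSF14": -0.002,
    "ADAM10": 0.534,
    "CTSB": 0.121,
    "LILRB4": -0.025,
    "F2": 0.562,
    "UBE2D2": -0.079,
    "CTSS": -0.608,
    "NTS": -0.326,
}
_REFERENCE_AUC = {
    "TARDBP": 0.80,
    "YARS2": 0.79,
    "PRL": 0.78,
    "IRF5": 0.78,
    "TNFSF14": 0.77,
    "ADAM10": 0.75,
    "CTSB": 0.74,
    "LILRB4": 0.74,
    "F2": 0.74,
    "UBE2D2": 0.73,
    "CTSS": 0.73,
    "NTS": 0.73,
}


def reference_panel() -> LogisticPanelModel:
    """The published 12-marker delirium panel as a fitted-model fixture.

    Useful for exercising odds-ratio arithmetic, support extraction and
    prediction without any data; coefficients are on the 1-SD standardized
    scale.
    """
    return LogisticPanelModel(
        intercept=0.0,
        coefficients=dict(_REFERENCE_COEF),
        lam=None,
        fit_meta={"source": "published 12-marker preoperative delirium panel"},
        marker_auc=dict(_REFERENCE_AUC),
    )
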