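"""Independent reference computations used to cross-check the package.

These deliberately avoid the package's own code paths: brute-force pair
counting for the AUC and a from-scratch iteratively-reweighted least
squares (IRLS) solver for unpenalized logistic regression.
"""

from __future__ import annotations

import numpy as np


def brute_force_auc(scores, labels) -> float:
    """O(n^2) pair counting: case-beats-control pairs, ties worth half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    case = scores[labels == 1]
    control = scores[labels == 0]
    wins = 0.0
    for c in case:
        for k in control:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case) * len(control))


def irls_logistic(X, y, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Unpenalized logistic MLE by plain IRLS; returns [intercept, slopes]."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        wx = Xd * w[:, None]
        new = np.linalg.solve(Xd.T @ wx, wx.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta
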