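"""Brute-force reference implementations used only by the tests.

Deliberately naive: normal equations for OLS and a literal loop over
clusters for the sandwich variance, so any agreement with the package is
between two independent code paths.
"""

from __future__ import annotations

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = (X'X)^-1 X'y, solved exactly as written."""
    XtX = X.T @ X
    return np.linalg.solve(XtX, X.T @ y)


def cluster_sandwich_loop(X: np.ndarray, resid: np.ndarray,
                          groups: np.ndarray,
                          small_sample: str = "stata") -> np.ndarray:
    """Sandwich vcov with an explicit per-cluster outer-product loop."""
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    labels = np.unique(groups)
    for g in labels:
        rows = groups == g
        Xg = X[rows]
        eg = resid[rows]
        s = Xg.T @ eg
        meat += np.outer(s, s)
    G = len(labels)
    if small_sample == "stata":
        c = (G / (G - 1)) * ((n - 1) / (n - k))
    elif small_sample == "cluster":
        c = G / (G - 1)
    else:
        c = 1.0
    return c * bread @ meat @ bread
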