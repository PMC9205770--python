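"""Segmented-regression OLS fit with cluster-robust small-sample inference.

The impact model is fit by ordinary least squares on unit-month totals.
Because observations within a sub-national unit are serially correlated,
standard errors come from the clustered sandwich estimator

    V = c * (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1,
    c = [G/(G-1)] * [(n-1)/(n-k)],

with G the number of units, and confidence intervals / p values use a
t-distribution with G-2 degrees of freedom — deliberately conservative when
few units are available.  The finite-sample factor c is the de-facto
standard of major econometrics packages; ``small_sample="cluster"`` keeps
only G/(G-1) and ``"none"`` drops the correction, for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DesignMatrix


@dataclass
class ItsFit:
    """OLS solution plus everything clustered inference needs."""

    beta: pd.Series          # aligned to design columns
    residuals: np.ndarray
    X: pd.DataFrame
    clusters: pd.Series
    n_obs: int
    n_params: int

    @property
    def G(self) -> int:
        return int(self.clusters.nunique())

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        Xm = self.X if X is None else X[self.beta.index]
        return Xm.to_numpy() @ self.beta.to_numpy()

    def to_json(self, path: str | Path, vcov: np.ndarray | None = None) -> None:
        payload = {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "n_obs": self.n_obs, "n_params": self.n_params, "G": self.G,
            "df": self.G - 2,
        }
        if vcov is not None:
            payload["vcov"] = np.asarray(vcov).tolist()
            payload["vcov_columns"] = list(self.beta.index)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def fit_ols(design: DesignMatrix) -> ItsFit:
    """Least-squares fit via a stable orthogonal decomposition.

    Refuses rank-deficient designs (listing the collinear columns) rather
    than silently pinning coefficients.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y.to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n_obs={n} must exceed n_params={k}")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0)
    if (diag <= tol).any():
        bad = [design.X.columns[j] for j in np.flatnonzero(diag <= tol)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    return ItsFit(beta=pd.Series(beta, index=design.X.columns),
                  residuals=resid, X=design.X, clusters=design.clusters,
                  n_obs=n, n_params=k)


def cluster_robust_vcov(fit: ItsFit,
                        small_sample: str = "stata") -> np.ndarray:
    """Clustered sandwich covariance of the OLS coefficients.

    ``small_sample``: ``"stata"`` applies [G/(G-1)]*[(n-1)/(n-k)] (default),
    ``"cluster"`` applies G/(G-1) only, ``"none"`` applies no correction.
    With every observation in its own cluster the default reduces to the
    HC1 heteroskedasticity-robust estimator.
    """
    X = fit.X.to_numpy(dtype=float)
    e = fit.residuals
    groups = fit.clusters.to_numpy()
    labels, inverse = np.unique(groups, return_inverse=True)
    G = len(labels)
    if G < 2:
        raise ValueError("clustered vcov needs at least 2 clusters")
    n, k = X.shape

    # sum_g (X_g' e_g)(X_g' e_g)' computed via per-cluster score totals
    Xe = X * e[:, None]
    scores = np.zeros((G, k))
    np.add.at(scores, inverse, Xe)
    meat = scores.T @ scores

    bread = np.linalg.inv(X.T @ X)
    if small_sample == "stata":
        c = (G / (G - 1)) * ((n - 1) / (n - k))
    elif small_sample == "cluster":
        c = G / (G - 1)
    elif small_sample == "none":
        c = 1.0
    else:
        raise ValueError(f"unknown small_sample option {small_sample!r}")
    V = c * bread @ meat @ bread
    return (V + V.T) / 2.0


def inference(fit: ItsFit, vcov: np.ndarray,
              alpha: float = 0.05) -> pd.DataFrame:
    """Coefficient table with t(G-2) confidence intervals and p values.

    Returns a DataFrame indexed by design column with columns
    ``estimate, se, t, p, ci_low, ci_high, df``.
    """
    if fit.G < 3:
        raise ValueError("inference requires G >= 3 (df = G - 2 > 0)")
    vcov = np.asarray(vcov)
    if vcov.shape != (fit.n_params, fit.n_params):
        raise ValueError("vcov not conformable with the coefficient vector")
    diag = np.diag(vcov).copy()
    tol = 1e-10 * max(np.abs(diag).max(), 1.0)
    if (diag < -tol).any():
        raise ValueError("vcov has negative diagonal entries")
    diag[diag < 0] = 0.0  # rounding noise on a PSD sandwich
    se = np.sqrt(diag)
    df = fit.G - 2
    est = fit.beta.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p = 2 * stats.t.sf(np.abs(tstat), df)
    crit = stats.t.ppf(1 - alpha / 2, df)
    table = pd.DataFrame({
        "estimate": est,
        "se": se,
        "t": tstat,
        "p": p,
        "ci_low": est - crit * se,
        "ci_high": est + crit * se,
        "df": df,
    }, index=fit.beta.index)
    table.index.name = "term"
    return table


def fit_and_infer(design: DesignMatrix, alpha: float = 0.05,
                  small_sample: str = "stata",
                  ) -> tuple[ItsFit, np.ndarray, pd.DataFrame]:
    """Convenience wrapper: fit, clustered vcov, coefficient table."""
    fit = fit_ols(design)
    V = cluster_robust_vcov(fit, small_sample=small_sample)
    return fit, V, inference(fit, V, alpha=alpha)
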