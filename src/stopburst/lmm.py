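"""Point-wise linear mixed models and mass regression on marginal data.

The mass-univariate scheme fits, at every channel x bin point, the model

    y ~ 1 + condition + (1 | participant)

with the condition effects-coded Go = -1 / Stop = +1 (or no-burst = -1 /
burst = +1), so a positive slope means "greater on Stop/burst trials" and
the slope is half the condition difference. The estimated random intercepts
are then subtracted from the response ("marginal data") and ordinary least
squares — a single factorized solve shared by all points — reproduces the
mixed-model fixed-effect t statistics at a tiny fraction of the cost, which
is what makes whole-map permutation testing feasible.

The point model is estimated by profiled REML: with a single random
intercept per participant, V = I + lambda * Z Z' has a closed-form inverse
per participant block, leaving a 1-D optimization over the variance ratio
lambda = sigma_u^2 / sigma_e^2. A boundary estimate (lambda -> 0) degrades
gracefully to OLS with zero intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
_BOUNDARY_LAMBDA = 1e-8


@dataclass
class PointFit:
    """REML fit of y ~ X + (1 | group) at one map point."""

    beta: np.ndarray            # fixed coefficients (intercept, slope)
    t: float                    # fixed-effect (slope) t statistic
    sigma2: float               # residual variance (REML)
    lam: float                  # variance ratio sigma_u^2 / sigma_e^2
    intercepts: np.ndarray      # BLUP random intercept per group
    ols_fallback: bool          # True when the fit hit the lambda=0 boundary


class GroupDesign:
    """Precomputed sufficient statistics for repeated fits with a fixed
    design matrix and grouping (only the response changes across points)."""

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, float)
        groups = np.asarray(groups)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.X, self.groups = X, groups
        self.labels, self.inv = np.unique(groups, return_inverse=True)
        self.G = len(self.labels)
        self.n, self.p = X.shape
        self.n_i = np.bincount(self.inv, minlength=self.G).astype(float)
        # per-group sums of X columns: (G, p)
        self.gx = np.stack([np.bincount(self.inv, weights=X[:, k],
                                        minlength=self.G)
                            for k in range(self.p)], axis=1)
        self.XtX = X.T @ X

    def group_sums(self, y: np.ndarray) -> np.ndarray:
        return np.bincount(self.inv, weights=y, minlength=self.G)


def _profile(design: GroupDesign, lam: float, Xty, yty, gy):
    """GLS pieces at a given variance ratio lambda."""
    c = lam / (1.0 + lam * design.n_i)                     # (G,)
    A = design.XtX - (design.gx * c[:, None]).T @ design.gx
    b = Xty - design.gx.T @ (c * gy)
    q = yty - float(c @ (gy ** 2))
    beta = np.linalg.solve(A, b)
    rVr = max(q - float(b @ beta), 0.0)
    return A, beta, rVr


def _reml_criterion(design: GroupDesign, lam: float, Xty, yty, gy) -> float:
    A, _, rVr = _profile(design, lam, Xty, yty, gy)
    dof = design.n - design.p
    sigma2 = max(rVr / dof, 1e-300)
    logdetV = float(np.sum(np.log1p(lam * design.n_i)))
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return dof * np.log(sigma2) + logdetV + logdetA


def fit_point_lmm(y: np.ndarray, X: np.ndarray | GroupDesign,
                  groups: np.ndarray | None = None) -> PointFit:
    """REML fit of the random-intercept model at one point.

    Accepts either (y, X, groups) or (y, GroupDesign) with the design
    prebuilt. The slope t uses the REML residual variance and the GLS
    covariance of the fixed effects.
    """
    design = X if isinstance(X, GroupDesign) else GroupDesign(X, groups)
    y = np.asarray(y, float)
    Xty = design.X.T @ y
    yty = float(y @ y)
    gy = design.group_sums(y)

    def obj(theta):
        return _reml_criterion(design, np.exp(theta), Xty, yty, gy)

    res = minimize_scalar(obj, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    if _reml_criterion(design, 0.0, Xty, yty, gy) <= res.fun:
        lam = 0.0
    fallback = lam < _BOUNDARY_LAMBDA
    if fallback:
        lam = 0.0
        logger.debug("singular random-intercept fit; falling back to OLS")

    A, beta, rVr = _profile(design, lam, Xty, yty, gy)
    dof = design.n - design.p
    sigma2 = rVr / dof
    cov = sigma2 * np.linalg.inv(A)
    t = float(beta[1] / np.sqrt(cov[1, 1])) if cov[1, 1] > 0 else 0.0
    resid_sums = gy - design.gx @ beta
    c = lam / (1.0 + lam * design.n_i)
    intercepts = c * resid_sums
    return PointFit(beta=beta, t=t, sigma2=float(sigma2), lam=lam,
                    intercepts=intercepts, ols_fallback=fallback)


def marginalize(y: np.ndarray, fit: PointFit,
                design: GroupDesign) -> np.ndarray:
    """Remove the predicted random intercept of each trial's participant,
    keeping the fixed-effects structure and residuals."""
    return np.asarray(y, float) - fit.intercepts[design.inv]


def fit_and_marginalize(Y: np.ndarray, X: np.ndarray, groups: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, GroupDesign]:
    """Point-wise REML over a (points x trials) response matrix.

    Returns (Y_marginal, t_mixed, design): the marginal responses, the
    mixed-model fixed-effect t per point, and the reusable design.
    """
    design = GroupDesign(X, groups)
    Y = np.asarray(Y, float)
    Ym = np.empty_like(Y)
    t = np.empty(Y.shape[0])
    for i in range(Y.shape[0]):
        fit = fit_point_lmm(Y[i], design)
        Ym[i] = marginalize(Y[i], fit, design)
        t[i] = fit.t
    return Ym, t, design


def mass_ols(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Slope t statistics of OLS regressions of every row of Y on X.

    One shared factorization serves all points: with P = (X'X)^-1,
    B = P X' Y', t = B_slope / sqrt(sigma2 * P_11).
    """
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    n, p = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < p:
        raise ValueError("design matrix is rank deficient")
    P = np.linalg.inv(XtX)
    B = P @ (X.T @ Y.T)                      # (p, points)
    resid = Y.T - X @ B                      # (n, points)
    sigma2 = (resid ** 2).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * P[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1] / se, 0.0)
    return t


def permute_design(X: np.ndarray, groups: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Shuffle the predictor column within each participant's trials.

    One permutation is shared across all points of a map, preserving the
    spatiotemporal correlation structure of the responses.
    """
    X = np.asarray(X, float)
    out = X.copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        out[idx, 1] = X[rng.permutation(idx), 1]
    return out


def build_design(trials: pd.DataFrame, contrast: str,
                 positive: str, negative: str, column: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (intercept + effects-coded predictor) from a trial
    table subset: rows with ``column`` == positive code +1, == negative -1."""
    vals = trials[column].astype(str)
    keep = vals.isin([positive, negative])
    sub = trials[keep]
    x = np.where(sub[column].astype(str) == positive, 1.0, -1.0)
    X = np.column_stack([np.ones(len(sub)), x])
    return X, sub.index.to_numpy()
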