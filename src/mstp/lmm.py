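"""Maximum-likelihood linear mixed models with a subject random intercept.

Implements the marginal Gaussian model y_i ~ N(X_i beta, sigma_b^2 J +
sigma_e^2 I) per subject, with optional per-subject analysis weights that
scale each subject's log-likelihood contribution (used to carry variable-
ratio matching weights). Estimation alternates an exact generalized-least-
squares update of beta with an expectation-maximization update of the
variance components; both steps increase the weighted marginal likelihood,
so the iteration is monotone.

The same per-subject sufficient statistics (X'X, X'y, column sums, y sums)
drive the latent-class EM in :mod:`mstp.trajectories`, which calls into the
primitives defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupStats:
    """Per-subject sufficient statistics for the random-intercept model."""

    ids: np.ndarray        # (g,) subject identifiers
    n: np.ndarray          # (g,) visits per subject
    sxx: np.ndarray        # (g, p, p) X_i' X_i
    sxy: np.ndarray        # (g, p)    X_i' y_i
    sx: np.ndarray         # (g, p)    column sums of X_i
    sy: np.ndarray         # (g,)      sum of y_i
    syy: np.ndarray        # (g,)      y_i' y_i

    @property
    def n_groups(self) -> int:
        return len(self.n)

    @property
    def n_obs(self) -> int:
        return int(self.n.sum())

    @property
    def p(self) -> int:
        return self.sx.shape[1]


def group_stats(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> GroupStats:
    """Aggregate rows into per-subject sufficient statistics."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    ids, starts = np.unique(groups, return_index=True)
    starts = np.sort(starts)
    n = np.diff(np.append(starts, len(y)))
    outer = X[:, :, None] * X[:, None, :]
    sxx = np.add.reduceat(outer, starts, axis=0)
    sxy = np.add.reduceat(X * y[:, None], starts, axis=0)
    sx = np.add.reduceat(X, starts, axis=0)
    sy = np.add.reduceat(y, starts)
    syy = np.add.reduceat(y * y, starts)
    return GroupStats(ids=groups[starts], n=n, sxx=sxx, sxy=sxy, sx=sx, sy=sy, syy=syy)


def residual_stats(gs: GroupStats, beta: np.ndarray):
    """Per-subject (sum of residuals, sum of squared residuals) for fixed beta."""
    r1 = gs.sy - gs.sx @ beta
    rss = gs.syy - 2.0 * (gs.sxy @ beta) + np.einsum("gij,i,j->g", gs.sxx, beta, beta)
    return r1, np.maximum(rss, 0.0)


def group_loglik(gs: GroupStats, beta: np.ndarray, sigma_b2: float, sigma_e2: float) -> np.ndarray:
    """Marginal log-likelihood of each subject under (beta, variances)."""
    n = gs.n
    denom = sigma_e2 + n * sigma_b2
    c = sigma_b2 / denom
    r1, rss = residual_stats(gs, beta)
    quad = (rss - c * r1**2) / sigma_e2
    logdet = (n - 1) * np.log(sigma_e2) + np.log(denom)
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def gls_update(gs: GroupStats, weights: np.ndarray, sigma_b2: float, sigma_e2: float):
    """Weighted GLS solve for beta; returns (beta, unscaled information A).

    Cov(beta) = sigma_e2 * A^{-1} under unit analysis weights.
    """
    c = sigma_b2 / (sigma_e2 + gs.n * sigma_b2)
    w = weights
    A = np.einsum("g,gij->ij", w, gs.sxx) - np.einsum(
        "g,gi,gj->ij", w * c, gs.sx, gs.sx)
    rhs = np.einsum("g,gi->i", w, gs.sxy) - (w * c * gs.sy) @ gs.sx
    beta = np.linalg.solve(A, rhs)
    return beta, A


def variance_update(gs: GroupStats, beta: np.ndarray, weights: np.ndarray,
                    sigma_b2: float, sigma_e2: float):
    """EM update of the variance components given beta.

    Treats the subject intercepts as missing data; the posterior of b_i is
    N(c_i * r1_i, v_i) with v_i = sigma_b2*sigma_e2/(sigma_e2 + n_i*sigma_b2).
    """
    n = gs.n
    denom = sigma_e2 + n * sigma_b2
    c = sigma_b2 / denom
    v = sigma_b2 * sigma_e2 / denom
    r1, rss = residual_stats(gs, beta)
    m = c * r1
    w = weights
    new_b2 = float(np.sum(w * (m**2 + v)) / np.sum(w))
    new_e2 = float(np.sum(w * (rss - 2.0 * m * r1 + n * (m**2 + v))) / np.sum(w * n))
    return max(new_b2, 1e-10), max(new_e2, 1e-10)


@dataclass
class LMMFit:
    names: list
    beta: np.ndarray
    bse: np.ndarray
    sigma_b: float
    sigma_e: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    n_iter: int
    loglik_history: list = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        return self.beta / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "beta": self.beta, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues,
        })


def fit_lmm(
    y,
    X,
    groups,
    weights: Optional[Sequence[float]] = None,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> LMMFit:
    """Fit the weighted random-intercept LMM by ML.

    ``weights`` are per-subject (keyed by order of first appearance after
    sorting by group id); ``None`` means equal weights. Raises
    ``np.linalg.LinAlgError`` with a message on singular designs.
    """
    gs = group_stats(y, X, groups)
    p = gs.p
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if weights is None:
        w = np.ones(gs.n_groups)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) == gs.n_groups:
            pass
        elif len(w) == len(np.asarray(y)):
            raise ValueError("weights must be per-subject, aligned with sorted unique group ids")
        else:
            raise ValueError("weights length must equal the number of subjects")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")

    # OLS start
    try:
        beta, A = gls_update(gs, w, 0.0, 1.0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular fixed-effects design; check for collinear or constant columns") from err
    r1, rss = residual_stats(gs, beta)
    sigma_e2 = float(np.sum(w * rss) / np.sum(w * gs.n))
    sigma_e2 = max(sigma_e2, 1e-8)
    means = r1 / gs.n
    sigma_b2 = max(float(np.average(means**2, weights=w)) - sigma_e2 / float(np.mean(gs.n)), 1e-4)

    ll_old = -np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta, A = gls_update(gs, w, sigma_b2, sigma_e2)
        sigma_b2, sigma_e2 = variance_update(gs, beta, w, sigma_b2, sigma_e2)
        ll = float(np.sum(w * group_loglik(gs, beta, sigma_b2, sigma_e2)))
        history.append(ll)
        if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    cov = sigma_e2 * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov))
    return LMMFit(names=list(names), beta=beta, bse=bse,
                  sigma_b=float(np.sqrt(sigma_b2)), sigma_e=float(np.sqrt(sigma_e2)),
                  loglik=ll_old, n_obs=gs.n_obs, n_groups=gs.n_groups,
                  converged=converged, n_iter=it, loglik_history=history)
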