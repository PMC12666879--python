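"""Latent-class mixed models of EDSS versus time.

Each class k has a quadratic mean trajectory b0 + b1*t + b2*t^2; patients
carry a shared-variance random intercept, residuals are Gaussian, and class
membership is a multinomial with weights pi. Estimation is EM on the
per-patient marginal likelihood; model order is chosen by information
criteria (AIC/BIC/SABIC/ICL) with 10-fold cross-validation available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from . import lmm

logger = logging.getLogger(__name__)

DEGREE = 2  # quadratic trajectories: intercept, time, time^2


class FitError(RuntimeError):
    pass


@dataclass
class TrajectoryModel:
    K: int
    pi: np.ndarray                 # (K,)
    B: np.ndarray                  # (K, 3) per-class (intercept, time, time^2)
    sigma_b: float
    sigma_e: float
    loglik: float
    n_params: int
    converged: bool
    posterior: pd.DataFrame        # n_subjects x K, indexed by patient id
    cov_B: np.ndarray              # (K, 3, 3) approximate covariance of B rows
    loglik_history: list = field(default_factory=list)
    time_range: Tuple[float, float] = (0.0, 20.0)
    class_names: Optional[list] = None

    @property
    def n_subjects(self) -> int:
        return len(self.posterior)

    @property
    def predictive_sd(self) -> float:
        """Patient-level spread around a class mean: sqrt(sigma_b^2 + sigma_e^2)."""
        return float(np.sqrt(self.sigma_b**2 + self.sigma_e**2))

    def class_mean(self, k: int, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.B[k, 0] + self.B[k, 1] * t + self.B[k, 2] * t**2

    def modal_assignments(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)

    def to_dict(self) -> dict:
        return {
            "K": self.K, "pi": self.pi.tolist(), "B": self.B.tolist(),
            "sigma_b": self.sigma_b, "sigma_e": self.sigma_e,
            "loglik": self.loglik, "n_params": self.n_params,
            "converged": self.converged, "class_names": self.class_names,
            "time_range": list(self.time_range),
            "cov_B": self.cov_B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict, posterior: Optional[pd.DataFrame] = None) -> "TrajectoryModel":
        if posterior is None:
            posterior = pd.DataFrame(np.zeros((0, d["K"])))
        return cls(K=d["K"], pi=np.array(d["pi"]), B=np.array(d["B"]),
                   sigma_b=d["sigma_b"], sigma_e=d["sigma_e"], loglik=d["loglik"],
                   n_params=d["n_params"], converged=d["converged"],
                   posterior=posterior, cov_B=np.array(d["cov_B"]),
                   time_range=tuple(d.get("time_range", (0.0, 20.0))),
                   class_names=d.get("class_names"))


@dataclass
class ModelFitSummary:
    K: int
    loglik: float
    n_params: int
    AIC: float
    BIC: float
    SABIC: float
    ICL: float        # log scale, higher is better
    ICL_bic: float    # BIC scale, lower is better
    entropy: float
    converged: bool
    cv_loglik: Optional[float] = None


def _design(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return np.column_stack([np.ones_like(t), t, t**2])


def stats_from_frame(visits: pd.DataFrame) -> lmm.GroupStats:
    """Per-patient sufficient statistics from a long (patient_id, time_years, edss) table."""
    t = visits["time_years"].to_numpy(dtype=float)
    y = visits["edss"].to_numpy(dtype=float)
    return lmm.group_stats(y, _design(t), visits["patient_id"].to_numpy())


def _per_patient_ols(gs: lmm.GroupStats) -> np.ndarray:
    """Per-patient (intercept, slope, curvature) estimates for initialization.

    Quadratic OLS where the patient has >=4 visits and a well-conditioned
    design, else a line (curvature 0), else a flat intercept.
    """
    out = np.zeros((gs.n_groups, 3))
    for i in range(gs.n_groups):
        n = gs.n[i]
        if n >= 4:
            A = gs.sxx[i]
            if np.linalg.cond(A) < 1e8:
                out[i] = np.linalg.solve(A, gs.sxy[i])
                continue
        st, stt = gs.sx[i, 1], gs.sxx[i, 1, 1]
        sy, sty = gs.sy[i], gs.sxy[i, 1]
        det = n * stt - st**2
        if det > 1e-12:
            slope = (n * sty - st * sy) / det
            out[i] = [(sy - slope * st) / n, slope, 0.0]
        else:
            out[i] = [sy / n, 0.0, 0.0]
    return out


def _class_loglik_matrix(gs: lmm.GroupStats, B: np.ndarray,
                         sigma_b2: float, sigma_e2: float) -> np.ndarray:
    """(n_subjects, K) marginal log density of each patient under each class."""
    return np.column_stack([
        lmm.group_loglik(gs, B[k], sigma_b2, sigma_e2) for k in range(B.shape[0])
    ])


def _m_step(gs: lmm.GroupStats, W: np.ndarray, sigma_b2: float, sigma_e2: float,
            update_variances: bool = True):
    """Posterior-weighted GLS update of B, EM update of shared variances, pi.

    ``update_variances=False`` is used for the initialization step, where W
    is a heuristic hard assignment rather than a posterior: updating the
    variance components there lets the residuals of mis-seeded patients
    inflate sigma_b and trap the EM in a single-blob optimum.
    """
    K = W.shape[1]
    p = gs.p
    B = np.zeros((K, p))
    A_list = []
    for k in range(K):
        wk = np.maximum(W[:, k], 1e-12)
        Bk, Ak = lmm.gls_update(gs, wk, sigma_b2, sigma_e2)
        B[k] = Bk
        A_list.append(Ak)
    if not update_variances:
        pi = W.mean(axis=0)
        return B, sigma_b2, sigma_e2, pi, A_list
    n = gs.n
    denom = sigma_e2 + n * sigma_b2
    c = sigma_b2 / denom
    v = sigma_b2 * sigma_e2 / denom
    num_b, num_e = 0.0, 0.0
    for k in range(K):
        r1, rss = lmm.residual_stats(gs, B[k])
        m = c * r1
        wk = W[:, k]
        num_b += np.sum(wk * (m**2 + v))
        num_e += np.sum(wk * (rss - 2.0 * m * r1 + n * (m**2 + v)))
    new_b2 = max(float(num_b / W.sum()), 1e-10)
    new_e2 = max(float(num_e / np.sum(gs.n)), 1e-10)
    pi = W.mean(axis=0)
    return B, new_b2, new_e2, pi, A_list


def _em(gs: lmm.GroupStats, K: int, W0: np.ndarray, tol: float, max_iter: int):
    """Run EM from an initial responsibility matrix; returns fit pieces."""
    # initial M-step from the heuristic hard assignment: coefficients and
    # mixing weights only, variances from the pooled within-patient spread
    resid_var = max(float(np.mean(gs.syy / gs.n - (gs.sy / gs.n) ** 2)), 0.05)
    sigma_b2, sigma_e2 = 0.25, max(resid_var * 0.5, 0.05)
    B, sigma_b2, sigma_e2, pi, A_list = _m_step(gs, W0, sigma_b2, sigma_e2,
                                                update_variances=False)
    pi = np.maximum(pi, 1e-8)
    pi /= pi.sum()
    ll_old = -np.inf
    history = []
    converged = False
    W = W0
    for it in range(1, max_iter + 1):
        logdens = _class_loglik_matrix(gs, B, sigma_b2, sigma_e2) + np.log(pi)
        norm = logsumexp(logdens, axis=1)
        ll = float(norm.sum())
        W = np.exp(logdens - norm[:, None])
        history.append(ll)
        if ll < ll_old - 1e-6 * (1.0 + abs(ll_old)):
            logger.warning("EM log-likelihood decreased at iteration %d (%.6g -> %.6g)",
                           it, ll_old, ll)
        if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
        if np.any(W.sum(axis=0) < 1.0):
            return None  # empty class; caller restarts
        B, sigma_b2, sigma_e2, pi, A_list = _m_step(gs, W, sigma_b2, sigma_e2)
        pi = np.maximum(pi, 1e-10)
        pi /= pi.sum()
    return B, sigma_b2, sigma_e2, pi, W, ll_old, history, converged, A_list


def _soft_from_hard(labels: np.ndarray, K: int) -> np.ndarray:
    W0 = np.full((len(labels), K), 0.02 / max(K - 1, 1))
    W0[np.arange(len(labels)), labels] = 0.98
    return W0


def _initial_responsibilities(gs: lmm.GroupStats, K: int, rng: np.random.Generator,
                              jitter: bool) -> np.ndarray:
    feats = _per_patient_ols(gs)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    Z = feats / scale
    if K == 1:
        return np.ones((gs.n_groups, 1))
    km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(Z)
    if jitter:
        flip = rng.uniform(size=len(labels)) < 0.15
        labels = np.where(flip, rng.integers(0, K, size=len(labels)), labels)
    return _soft_from_hard(labels, K)


def _split_starts(gs: lmm.GroupStats, prev: "TrajectoryModel",
                  rng: np.random.Generator) -> list:
    """Warm starts for K classes from a fitted (K-1)-class model.

    Two families of starts: (a) each previous class split in two by k-means
    on per-patient coefficient estimates; (b) a new class seeded from the 5%
    of patients with the worst per-patient log-likelihood under the previous
    model. Both help the EM find small classes that cold k-means starts miss
    and make likelihoods nested in K in practice.
    """
    feats = _per_patient_ols(gs)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    Z = feats / scale
    prev_labels = prev.posterior.to_numpy().argmax(axis=1)
    starts = []
    for cls in range(prev.K):
        members = np.nonzero(prev_labels == cls)[0]
        if len(members) < 10:
            continue
        km = KMeans(n_clusters=2, n_init=2, random_state=int(rng.integers(2**31 - 1)))
        sub = km.fit_predict(Z[members])
        labels = prev_labels.copy()
        labels[members[sub == 1]] = prev.K  # new class index
        starts.append(_soft_from_hard(labels, prev.K + 1))
        # curvature-targeted split: seed a new class from the members whose
        # individual quadratic coefficient is in the top decile of the class
        curv = feats[members, 2]
        cut = np.quantile(curv, 0.9)
        high = members[curv >= cut]
        if 2 <= len(high) < len(members):
            labels = prev_labels.copy()
            labels[high] = prev.K
            starts.append(_soft_from_hard(labels, prev.K + 1))
    logdens = _class_loglik_matrix(gs, prev.B, prev.sigma_b**2, prev.sigma_e**2)
    per_patient = logsumexp(logdens + np.log(prev.pi), axis=1) / np.maximum(gs.n, 1)
    n_seed = max(int(0.05 * gs.n_groups), prev.K + 1)
    worst = np.argsort(per_patient)[:n_seed]
    labels = prev_labels.copy()
    labels[worst] = prev.K
    starts.append(_soft_from_hard(labels, prev.K + 1))
    return starts


def fit_latent_classes(
    visits: pd.DataFrame,
    K: int,
    n_starts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
    prev_model: Optional["TrajectoryModel"] = None,
) -> TrajectoryModel:
    """Fit a K-class latent-class mixed model to long-format visits.

    The best of ``n_starts`` initializations (k-means on per-patient OLS
    coefficients, jittered after the first) is kept; when a fitted
    (K-1)-class ``prev_model`` is supplied, class-split warm starts are
    tried as well. Classes are returned in canonical order of increasing
    mean EDSS at year 15.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    gs = stats_from_frame(visits)
    if gs.n_groups < K:
        raise FitError(f"cannot fit {K} classes to {gs.n_groups} subjects")
    rng = np.random.default_rng(seed)
    queued = []
    if prev_model is not None and prev_model.K == K - 1 and len(prev_model.posterior) == gs.n_groups:
        queued = _split_starts(gs, prev_model, rng)
    best = None
    attempts = 0
    starts_done = 0
    total_starts = n_starts + len(queued)
    while starts_done < total_starts and attempts < 4 * total_starts:
        attempts += 1
        if queued:
            W0 = queued.pop(0)
        else:
            W0 = _initial_responsibilities(gs, K, rng, jitter=starts_done > 0)
        result = _em(gs, K, W0, tol, max_iter)
        if result is None:
            continue  # empty class: re-initialize without consuming a start
        starts_done += 1
        if best is None or result[5] > best[5]:
            best = result
    if best is None:
        raise FitError(f"all EM starts degenerated for K={K}")
    B, sigma_b2, sigma_e2, pi, W, ll, history, converged, A_list = best
    if not converged:
        logger.warning("EM for K=%d did not converge within %d iterations", K, max_iter)
    # canonical ordering by fitted mean at year 15
    mean15 = B[:, 0] + 15.0 * B[:, 1] + 225.0 * B[:, 2]
    order = np.argsort(mean15)
    B, pi, W = B[order], pi[order], W[:, order]
    cov_B = np.stack([sigma_e2 * np.linalg.inv(A_list[k]) for k in order])
    n_params = (K - 1) + B.size + 2
    posterior = pd.DataFrame(W, index=pd.Index(gs.ids, name="patient_id"),
                             columns=list(range(K)))
    tmin = float(visits["time_years"].min())
    tmax = float(visits["time_years"].max())
    return TrajectoryModel(K=K, pi=pi, B=B, sigma_b=float(np.sqrt(sigma_b2)),
                           sigma_e=float(np.sqrt(sigma_e2)), loglik=ll,
                           n_params=n_params, converged=converged,
                           posterior=posterior, cov_B=cov_B,
                           loglik_history=history, time_range=(tmin, tmax))


def information_criteria(model: TrajectoryModel, n_subjects: Optional[int] = None,
                         cv_loglik: Optional[float] = None) -> ModelFitSummary:
    """AIC/BIC/SABIC and both conventions of the ICL for a fitted model."""
    n = model.n_subjects if n_subjects is None else n_subjects
    if n < 2:
        raise ValueError("n_subjects must be >= 2")
    ll, p = model.loglik, model.n_params
    W = model.posterior.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.sum(np.where(W > 0, W * np.log(W), 0.0)))
    return ModelFitSummary(
        K=model.K, loglik=ll, n_params=p,
        AIC=-2.0 * ll + 2.0 * p,
        BIC=-2.0 * ll + p * np.log(n),
        SABIC=-2.0 * ll + p * np.log((n + 2.0) / 24.0),
        ICL=ll - ent,
        ICL_bic=-2.0 * ll + p * np.log(n) + 2.0 * ent,
        entropy=ent, converged=model.converged, cv_loglik=cv_loglik)


def criteria_table(summaries: Sequence[ModelFitSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "K": s.K, "loglik": s.loglik, "AIC": s.AIC, "BIC": s.BIC,
        "SABIC": s.SABIC, "ICL": s.ICL, "ICL_bic": s.ICL_bic,
        "entropy": s.entropy, "converged": s.converged, "cv_loglik": s.cv_loglik,
    } for s in summaries])


def select_class_number(
    visits: pd.DataFrame,
    k_range: Iterable[int] = range(1, 11),
    criterion: str = "BIC",
    n_starts: int = 5,
    seed: Optional[int] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> Tuple[int, list, Dict[int, TrajectoryModel]]:
    """Fit each K in ``k_range``; pick the best by the stated criterion.

    Lower is better for AIC/BIC/SABIC, higher for ICL; ties break toward
    smaller K. Returns (K_best, summaries, fitted models).
    """
    criterion = criterion.upper()
    if criterion not in {"AIC", "BIC", "SABIC", "ICL"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    models, summaries, failures = {}, [], {}
    rng = np.random.default_rng(seed)
    prev = None
    for K in sorted(k_range):
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            model = fit_latent_classes(visits, K, n_starts=n_starts, tol=tol,
                                       max_iter=max_iter, seed=sub_seed,
                                       prev_model=prev)
        except FitError as err:
            failures[K] = str(err)
            continue
        models[K] = model
        prev = model
        summaries.append(information_criteria(model))
    if not models:
        raise FitError(f"no class count could be fitted: {failures}")
    sign = -1.0 if criterion == "ICL" else 1.0
    best = min(summaries, key=lambda s: (sign * getattr(s, criterion), s.K))
    return best.K, summaries, models


def cross_validate(visits: pd.DataFrame, K: int, folds: int = 10,
                   seed: Optional[int] = None, n_starts: int = 3,
                   tol: float = 1e-6, max_iter: int = 500) -> float:
    """Patient-level K-fold CV; returns mean held-out per-patient log-likelihood."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids = visits["patient_id"].unique()
    if len(ids) < folds:
        raise ValueError("need at least as many subjects as folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignments = np.empty(len(ids), dtype=int)
    assignments[perm] = np.arange(len(ids)) % folds
    fold_of = dict(zip(ids, assignments))
    held_out = []
    for f in range(folds):
        test_ids = {pid for pid in ids if fold_of[pid] == f}
        train = visits[~visits["patient_id"].isin(test_ids)]
        test = visits[visits["patient_id"].isin(test_ids)]
        model = fit_latent_classes(train, K, n_starts=n_starts, tol=tol,
                                   max_iter=max_iter, seed=int(rng.integers(2**31 - 1)))
        gs = stats_from_frame(test)
        logdens = _class_loglik_matrix(gs, model.B, model.sigma_b**2, model.sigma_e**2)
        held_out.extend(logsumexp(logdens + np.log(model.pi), axis=1).tolist())
    return float(np.mean(held_out))


@dataclass
class PhenotypeAssignment:
    patient_id: str
    label: object            # class index or name
    probabilities: np.ndarray


def posterior_classify(model: TrajectoryModel, times, edss,
                       patient_id: str = "") -> PhenotypeAssignment:
    """Posterior class probabilities for one (possibly unseen) patient."""
    times = np.asarray(times, dtype=float)
    edss = np.asarray(edss, dtype=float)
    if times.size == 0:
        raise ValueError("patient has no retained visits")
    gs = lmm.group_stats(edss, _design(times), np.zeros(len(times), dtype=int))
    logdens = _class_loglik_matrix(gs, model.B, model.sigma_b**2, model.sigma_e**2)[0]
    logpost = logdens + np.log(model.pi)
    probs = np.exp(logpost - logsumexp(logpost))
    k = int(np.argmax(probs))
    label = model.class_names[k] if model.class_names else k
    return PhenotypeAssignment(patient_id=patient_id, label=label, probabilities=probs)


def mean_trajectory(model: TrajectoryModel, k: int, times) -> pd.DataFrame:
    """Fitted class mean with a 95% delta-method band and the predictive sd.

    Times beyond the fitted range + 5 years are flagged as extrapolation.
    """
    if not 0 <= k < model.K:
        raise ValueError(f"class index {k} out of range for K={model.K}")
    t = np.asarray(times, dtype=float)
    X = _design(t)
    mean = X @ model.B[k]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, model.cov_B[k], X), 0.0))
    hi_lim = model.time_range[1] + 5.0
    extrapolated = (t < model.time_range[0]) | (t > hi_lim)
    if np.any(extrapolated):
        warnings.warn("some requested times lie outside the fitted range; "
                      "trajectory values there are extrapolations", stacklevel=2)
    return pd.DataFrame({
        "time": t, "mean_edss": mean,
        "lower": mean - 1.96 * se, "upper": mean + 1.96 * se,
        "predictive_sd": model.predictive_sd,
        "extrapolated": extrapolated,
    })


def name_classes_by_onset(model: TrajectoryModel, horizon: float = 25.0,
                          cuts: Tuple[float, float, float] = (4.5, 7.0, 12.0)) -> list:
    """Heuristic phenotype names from the time the mean curve first exceeds
    its own baseline by 1.0 EDSS point: before the first cut rapid, the
    second early, the third late, never minimal. Duplicate names get a
    numeric suffix."""
    grid = np.linspace(0.0, horizon, 501)
    names = []
    for k in range(model.K):
        curve = model.class_mean(k, grid)
        above = np.nonzero(curve >= curve[0] + 1.0)[0]
        t_cross = grid[above[0]] if len(above) else np.inf
        if t_cross <= cuts[0]:
            names.append("rapid")
        elif t_cross <= cuts[1]:
            names.append("early")
        elif t_cross <= cuts[2]:
            names.append("late")
        else:
            names.append("minimal")
    seen = {}
    out = []
    for name in names:
        seen[name] = seen.get(name, 0) + 1
        out.append(name if seen[name] == 1 else f"{name}_{seen[name]}")
    return out


def match_classes_to_reference(model: TrajectoryModel, reference: dict,
                               horizon: float = 15.0, n_grid: int = 61) -> dict:
    """Uniquely match fitted classes to reference curves by L2 distance.

    ``reference`` maps name -> callable mean curve; returns {class index -> name}
    via optimal assignment on a year grid.
    """
    grid = np.linspace(0.0, horizon, n_grid)
    names = list(reference)
    cost = np.zeros((model.K, len(names)))
    for k in range(model.K):
        fitted = model.class_mean(k, grid)
        for j, name in enumerate(names):
            ref = np.asarray([reference[name](t) for t in grid], dtype=float)
            cost[k, j] = float(np.sum((fitted - ref) ** 2))
    rows, cols = linear_sum_assignment(cost)
    return {int(r): names[c] for r, c in zip(rows, cols)}
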