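"""Observed-vs-expected treatment-response quantification.

Treated patients' observed EDSS series are contrasted against the expected
trajectory of their assigned phenotype with linear mixed models (source x
time and source x time^2 interactions, optional treatment-timing terms),
and summarized per patient as a disability z-score: the standardized
deviation of observed EDSS from the expected mean at each visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import lmm
from .trajectories import TrajectoryModel, mean_trajectory


@dataclass
class ExpectedTrajectory:
    phenotype: str
    times: np.ndarray
    mean_edss: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    predictive_sd: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_edss = np.asarray(self.mean_edss, dtype=float)
        self.ci_lower = np.asarray(self.ci_lower, dtype=float)
        self.ci_upper = np.asarray(self.ci_upper, dtype=float)
        if self.predictive_sd <= 0:
            raise ValueError("predictive_sd must be > 0")
        if np.any(self.ci_lower > self.mean_edss) or np.any(self.mean_edss > self.ci_upper):
            raise ValueError("confidence band must bracket the mean")

    def mean_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.mean_edss)


@dataclass
class ZScorePoint:
    patient_id: str
    time: float
    observed_edss: float
    expected_mean: float
    z: float


@dataclass
class ContrastResult:
    strategy: str
    terms: dict                    # term -> (beta, se, p)
    family_size: int
    significant: dict = field(default_factory=dict)
    n_patients: int = 0

    def term_frame(self) -> pd.DataFrame:
        rows = [(t, b, s, p, self.significant.get(t, False))
                for t, (b, s, p) in self.terms.items()]
        return pd.DataFrame(rows, columns=["term", "beta", "se", "p", "significant"])


def predict_trajectory(model: TrajectoryModel, label, times) -> ExpectedTrajectory:
    """Expected trajectory of the assigned class (delegates to the fitted model)."""
    if isinstance(label, str):
        if not model.class_names or label not in model.class_names:
            raise ValueError(f"unknown class label {label!r}")
        k = model.class_names.index(label)
    else:
        k = int(label)
        if not 0 <= k < model.K:
            raise ValueError(f"class index {k} out of range")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return ExpectedTrajectory(str(label), times, times, times, times,
                                  model.predictive_sd)
    frame = mean_trajectory(model, k, times)
    return ExpectedTrajectory(
        phenotype=str(label), times=times,
        mean_edss=frame["mean_edss"].to_numpy(),
        ci_lower=frame["lower"].to_numpy(), ci_upper=frame["upper"].to_numpy(),
        predictive_sd=model.predictive_sd)


def disability_zscore(observed: Sequence, expected: ExpectedTrajectory,
                      patient_id: str = "") -> list:
    """Per-visit disability z-scores, in time order.

    z = (observed - expected mean) / predictive sd; the expected mean is
    linearly interpolated at the observed times.
    """
    if expected.predictive_sd <= 0:
        raise ValueError("predictive_sd must be > 0")
    pts = sorted(observed, key=lambda v: v[0])
    out = []
    for t, e in pts:
        mu = float(expected.mean_at(t))
        out.append(ZScorePoint(patient_id=patient_id, time=float(t),
                               observed_edss=float(e), expected_mean=mu,
                               z=(float(e) - mu) / expected.predictive_sd))
    return out


def bonferroni_adjust(pvalues: Sequence[float], family_size: int) -> list:
    """Significance flags at the Bonferroni-corrected threshold 0.05/family."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    pvals = np.asarray(pvalues, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(pvals < 0.05 / family_size)


def build_obs_pred_frame(observed: dict, expected: dict) -> pd.DataFrame:
    """Stack observed and predicted series for the contrast model.

    ``observed`` maps patient_id -> [(time, edss)]; ``expected`` maps
    patient_id -> ExpectedTrajectory. Each patient contributes both series.
    """
    rows = []
    for pid, visits in observed.items():
        exp = expected[pid]
        for t, e in visits:
            rows.append((pid, float(t), float(e), 1))
            rows.append((pid, float(t), float(exp.mean_at(t)), 0))
    return pd.DataFrame(rows, columns=["patient_id", "time", "edss", "source"])


def fit_obs_vs_pred(
    data: pd.DataFrame,
    strategy: str = "",
    weights: Optional[dict] = None,
    timing: Optional[dict] = None,
    min_patients: int = 10,
) -> ContrastResult:
    """Mixed-model contrast of observed vs predicted EDSS trajectories.

    ``data`` is long format with columns (patient_id, time, edss, source)
    where source is 1 for observed and 0 for predicted rows. Fixed effects:
    source, time, centered time^2 and their source interactions, plus
    optional source x time x timing terms where ``timing`` maps patient to
    a time-to-treatment (or time-to-switch) covariate, mean-centered before
    entry. A patient random intercept is always included; ``weights`` are
    per-patient matching weights. Negative source x time coefficients mean
    slower-than-expected worsening.
    """
    ids = data["patient_id"].unique()
    if len(ids) < min_patients:
        raise ValueError(
            f"refusing to fit with {len(ids)} patients (<{min_patients}); "
            "the contrast would be unstable")
    t = data["time"].to_numpy(dtype=float)
    t2 = t**2 - np.mean(t**2)  # centered to reduce collinearity
    src = data["source"].to_numpy(dtype=float)
    cols = [np.ones(len(data)), src, t, t2, src * t, src * t2]
    names = ["intercept", "source", "time", "time2", "source:time", "source:time2"]
    if timing is not None:
        tim = data["patient_id"].map(timing).to_numpy(dtype=float)
        if np.any(np.isnan(tim)):
            raise ValueError("timing covariate missing for some patients")
        tim = tim - tim.mean()
        cols += [src * t * tim, src * t2 * tim]
        names += ["source:time:timing", "source:time2:timing"]
    X = np.column_stack(cols)
    w = None
    if weights is not None:
        sorted_ids = np.sort(ids)  # must mirror the group ordering inside fit_lmm
        w = np.array([weights.get(pid, 1.0) for pid in sorted_ids], dtype=float)
    fit = lmm.fit_lmm(data["edss"].to_numpy(dtype=float), X,
                      data["patient_id"].to_numpy(), weights=w, names=names)
    interaction_terms = [n for n in names if n.startswith("source:")]
    family = len(interaction_terms)
    terms = {n: (float(b), float(s), float(p))
             for n, b, s, p in zip(names, fit.beta, fit.bse, fit.pvalues)}
    flags = bonferroni_adjust([terms[n][2] for n in interaction_terms], family)
    return ContrastResult(strategy=strategy, terms=terms, family_size=family,
                          significant=dict(zip(interaction_terms, flags)),
                          n_patients=len(ids))
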