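"""Propensity-score matching of treated to untreated patients.

Nearest-neighbour matching without replacement on the logit of the
propensity score, with a caliper of 0.2 standard deviations of the logit,
a variable matching ratio (an untreated patient may anchor several treated
patients), and analysis weights capped so each matched untreated patient
carries total weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

NUMERIC_COVARIATES = [
    "age_at_onset", "sex_f", "optic_nerve", "brainstem", "spinal_cord",
    "hemispheric", "ocb", "baseline_edss", "brain_t2_ord", "brain_gd",
    "sc_t2_ord", "sc_gd",
]

_BRAIN_T2_ORD = {"1-2": 0, "3-8": 1, ">=9": 2}
_SC_T2_ORD = {"0": 0, "1-2": 1, ">=3": 2}


class SeparationError(ValueError):
    pass


@dataclass
class MatchResult:
    pairs: pd.DataFrame            # treated_id, untreated_id, distance, weight
    weights: dict                  # patient_id -> analysis weight in (0, 1]
    caliper: float                 # caliper multiplier requested (e.g. 0.2)
    caliper_width: float           # caliper * sd(logit), on the logit scale
    unmatched_treated: list = field(default_factory=list)


def encode_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix from the baseline table (ordinal lesion codes)."""
    out = pd.DataFrame(index=baseline.index)
    out["patient_id"] = baseline["patient_id"]
    out["age_at_onset"] = baseline["age_at_onset"].astype(float)
    out["sex_f"] = (baseline["sex"].astype(str) == "F").astype(float)
    for col in ("optic_nerve", "brainstem", "spinal_cord", "hemispheric", "ocb",
                "brain_gd", "sc_gd"):
        out[col] = baseline[col].astype(bool).astype(float)
    out["baseline_edss"] = baseline["baseline_edss"].astype(float)
    out["brain_t2_ord"] = baseline["brain_t2"].astype(str).map(_BRAIN_T2_ORD).astype(float)
    out["sc_t2_ord"] = baseline["sc_t2"].astype(str).map(_SC_T2_ORD).astype(float)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing or unmappable covariate values in {bad}; "
                         "analyses require complete records")
    return out


def estimate_propensity(baseline: pd.DataFrame,
                        covariates: Optional[list] = None) -> pd.DataFrame:
    """Logistic model of treated-vs-untreated on baseline covariates.

    Returns a (patient_id, cohort, score, logit) table.
    """
    enc = encode_baseline(baseline)
    covariates = covariates or NUMERIC_COVARIATES
    # constant columns carry no information and make the design singular
    informative = [c for c in covariates if enc[c].nunique() > 1]
    X = sm.add_constant(enc[informative].to_numpy(), has_constant="add")
    y = (baseline["cohort"].astype(str) == "treated").astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both treated and untreated patients are required")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(
            "propensity model failed (perfect separation or singular design); "
            "review the covariate list") from err
    score = np.clip(fit.predict(X), 1e-12, 1.0 - 1e-12)
    return pd.DataFrame({
        "patient_id": baseline["patient_id"].to_numpy(),
        "cohort": baseline["cohort"].to_numpy(),
        "score": score,
        "logit": np.log(score / (1.0 - score)),
    })


def match_cohorts(scores: pd.DataFrame, caliper: float = 0.2,
                  max_ratio: int = 4) -> MatchResult:
    """Greedy nearest-neighbour caliper matching on the logit scale.

    Treated patients are processed in descending logit order (hardest to
    match first; ties by id). Each treated patient matches at most once; an
    untreated patient may anchor up to ``max_ratio`` treated patients. Each
    of the m treated sharing an anchor contributes pair weight 1/m, so every
    matched patient's cumulative weight is exactly 1.
    """
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    treated = scores[scores["cohort"] == "treated"]
    untreated = scores[scores["cohort"] == "untreated"]
    if treated.empty or untreated.empty:
        raise ValueError("both cohorts must be non-empty")
    sd = float(scores["logit"].std(ddof=1))
    width = caliper * sd if sd > 0 else np.inf
    treated = treated.sort_values(["logit", "patient_id"],
                                  ascending=[False, True])
    u_ids = untreated["patient_id"].to_numpy()
    u_logit = untreated["logit"].to_numpy(dtype=float)
    u_order = np.argsort(u_ids.astype(str))
    u_ids, u_logit = u_ids[u_order], u_logit[u_order]
    capacity = np.full(len(u_ids), int(max_ratio))
    pairs, unmatched = [], []
    for row in treated.itertuples():
        open_mask = capacity > 0
        if not open_mask.any():
            unmatched.append(row.patient_id)
            continue
        dist = np.abs(u_logit - row.logit)
        dist[~open_mask] = np.inf
        j = int(np.argmin(dist))  # ties resolved toward lowest id (sorted)
        if dist[j] <= width:
            capacity[j] -= 1
            pairs.append((row.patient_id, u_ids[j], float(dist[j])))
        else:
            unmatched.append(row.patient_id)
    pair_frame = pd.DataFrame(pairs, columns=["treated_id", "untreated_id", "distance"])
    weights = {}
    if not pair_frame.empty:
        m = pair_frame.groupby("untreated_id").size()
        pair_frame["weight"] = pair_frame["untreated_id"].map(1.0 / m)
        for tid in pair_frame["treated_id"]:
            weights[tid] = 1.0
        for uid in m.index:
            weights[uid] = 1.0
    else:
        pair_frame["weight"] = pd.Series(dtype=float)
    return MatchResult(pairs=pair_frame, weights=weights, caliper=caliper,
                       caliper_width=float(width), unmatched_treated=unmatched)


def _weighted_smd(x_t, w_t, x_u, w_u) -> float:
    mt = np.average(x_t, weights=w_t)
    mu = np.average(x_u, weights=w_u)
    vt = np.average((x_t - mt) ** 2, weights=w_t)
    vu = np.average((x_u - mu) ** 2, weights=w_u)
    pooled = np.sqrt((vt + vu) / 2.0)
    if pooled == 0:
        return 0.0
    return float((mt - mu) / pooled)


def covariate_balance(baseline: pd.DataFrame, result: MatchResult,
                      covariates: Optional[list] = None) -> pd.DataFrame:
    """Standardized mean differences per covariate before and after matching.

    After matching, treated patients carry weight 1 and untreated anchors
    their pair-weight totals (1 by construction).
    """
    enc = encode_baseline(baseline).set_index("patient_id")
    covariates = covariates or NUMERIC_COVARIATES
    cohort = baseline.set_index("patient_id")["cohort"]
    t_all = enc[cohort == "treated"]
    u_all = enc[cohort == "untreated"]
    matched_t = result.pairs["treated_id"].unique()
    u_weight = result.pairs.groupby("untreated_id")["weight"].sum()
    rows = []
    for cov in covariates:
        before = _weighted_smd(t_all[cov].to_numpy(), np.ones(len(t_all)),
                               u_all[cov].to_numpy(), np.ones(len(u_all)))
        if len(matched_t) and len(u_weight):
            after = _weighted_smd(
                enc.loc[matched_t, cov].to_numpy(), np.ones(len(matched_t)),
                enc.loc[u_weight.index, cov].to_numpy(), u_weight.to_numpy())
        else:
            after = np.nan
        rows.append((cov, before, after))
    return pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after"])
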