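"""Synthetic registry generation with known ground truth.

Generates cohorts of relapse-onset MS patients belonging to four latent
disability-worsening phenotypes (minimal, late, early, rapid), with visit
schedules every 3-6 months, EDSS scores on the legal half-point grid,
Poisson relapse processes, transient relapse-linked EDSS elevation,
phenotype-dependent baseline features, and optional disease-modifying
treatment with a known multiplicative effect on the latent slope.

Every patient is generated from an independent seeded substream derived
from ``(cohort_seed, patient_index)``, so patient ``i`` is reproducible
regardless of cohort size and treated counterfactuals can be regenerated
with identical noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .grid import round_to_grid

DAYS_PER_YEAR = 365.25

PHENOTYPE_NAMES = ("minimal", "late", "early", "rapid")

MODERATE_PRODUCTS = ("interferon-beta", "glatiramer acetate", "dimethyl fumarate", "teriflunomide")
HIGH_PRODUCTS = ("natalizumab", "fingolimod", "ocrelizumab", "cladribine", "rituximab")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PhenotypeSpec:
    """One latent trajectory phenotype.

    The mean disability curve is the quadratic
    ``beta0 + beta1*t + beta2*t**2`` (t in years since onset), capped above
    at ``plateau_cap`` and clamped to [0, 10].
    """

    name: str
    mixing_weight: float
    beta0: float
    beta1: float
    beta2: float
    arr: float
    plateau_cap: float = 10.0
    #: upper bound on follow-up (years); mirrors attrition of severely
    #: worsening patients and keeps every in-window mean exactly quadratic
    max_followup_years: Optional[float] = None

    def __post_init__(self):
        if self.arr < 0:
            raise ConfigurationError(f"arr must be >= 0, got {self.arr}")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ConfigurationError("mixing_weight must lie in [0, 1]")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ConfigurationError("mean curve must be non-decreasing (beta1, beta2 >= 0)")

    def mean(self, t):
        """Mean latent EDSS at time(s) ``t`` (years since onset)."""
        t = np.asarray(t, dtype=float)
        value = self.beta0 + self.beta1 * t + self.beta2 * t**2
        out = np.clip(value, 0.0, min(self.plateau_cap, 10.0))
        return float(out) if out.ndim == 0 else out


#: Generator defaults encoding the four printed phenotypes: minimal-worsening
#: stays near EDSS 2 through year 10; late-worsening is near-flat for a
#: decade before accelerating; early-worsening accelerates from ~5 years;
#: rapid-worsening climbs from onset. Weights 15/70/3/12 and ARRs
#: 0.23/0.24/0.28/0.36. Follow-up of the two severe phenotypes is truncated
#: before their curves saturate (disability-driven attrition).
DEFAULT_PHENOTYPES = (
    PhenotypeSpec("minimal", 0.15, 2.2, 0.0, 0.0, 0.23),
    PhenotypeSpec("late", 0.70, 1.9, 0.0, 0.015, 0.24),
    PhenotypeSpec("early", 0.03, 2.35, 0.0, 0.030, 0.28, plateau_cap=9.0,
                  max_followup_years=14.5),
    PhenotypeSpec("rapid", 0.12, 2.5, 0.33, 0.0, 0.36, max_followup_years=19.0),
)
# Noise defaults (measurement_sd=0.15, intercept_sd=0.22) are calibrated so
# that the half-point grid, the 0-1 EDSS gap, and the scale bounds leave the
# Gaussian latent-class model effectively well specified: larger spreads
# push patient tails into the floor/ceiling bins, which a mixture fit
# absorbs as spurious extra classes.


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator configuration."""

    n_patients: int = 2563
    treated_fraction: float = 0.0
    visit_interval_months: tuple = (3.0, 6.0)
    followup_median: float = 10.1
    followup_iqr: tuple = (7.3, 13.7)
    followup_range: tuple = (3.0, 20.0)
    measurement_sd: float = 0.15
    intercept_sd: float = 0.22
    relapse_bump: float = 1.0
    relapse_bump_days: float = 60.0
    seed: int = 12345
    # treatment defaults (used when treated_fraction > 0)
    effect_moderate: float = 0.6
    effect_high: float = 0.35
    strategy_probs: tuple = (0.45, 0.35, 0.20)  # moderate, high, escalation

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.treated_fraction <= 1.0:
            raise ConfigurationError("treated_fraction must lie in [0, 1]")
        if self.measurement_sd < 0 or self.intercept_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        lo, hi = self.visit_interval_months
        if not (0 < lo <= hi):
            raise ConfigurationError("visit_interval_months must satisfy 0 < min <= max")


@dataclass(frozen=True)
class BaselineFeatures:
    age_at_onset: float
    sex: str  # {"F", "M"}
    optic_nerve: bool
    brainstem: bool
    spinal_cord: bool
    hemispheric: bool
    ocb: bool
    baseline_edss: float
    brain_t2: str  # {"1-2", "3-8", ">=9"}
    brain_gd: bool
    sc_t2: str  # {"0", "1-2", ">=3"}
    sc_gd: bool

    def __post_init__(self):
        if self.age_at_onset <= 18:
            raise ConfigurationError("age_at_onset must exceed 18")
        if not (self.optic_nerve or self.brainstem or self.spinal_cord or self.hemispheric):
            raise ConfigurationError("at least one onset-site flag must be true")
        if self.brain_t2 not in {"1-2", "3-8", ">=9"}:
            raise ConfigurationError(f"illegal brain_t2 category {self.brain_t2!r}")
        if self.sc_t2 not in {"0", "1-2", ">=3"}:
            raise ConfigurationError(f"illegal sc_t2 category {self.sc_t2!r}")


@dataclass(frozen=True)
class TreatmentEpisode:
    product: str
    efficacy: str  # {"moderate", "high"}
    start_years: float
    stop_years: float


@dataclass
class PatientRecord:
    id: str
    cohort: str  # {"untreated", "treated"}
    true_phenotype: str
    baseline: BaselineFeatures
    visits: list  # [(time_years, edss)]
    relapses: list  # [(onset_years, recovery)]
    treatments: list  # [TreatmentEpisode]
    sim_key: Optional[tuple] = None  # (cohort_seed, index); generator bookkeeping

    @property
    def followup_years(self) -> float:
        return self.visits[-1][0] if self.visits else 0.0


# --- per-phenotype baseline feature distributions -------------------------
# Probabilities chosen to reflect the printed group contrasts: the early
# phenotype has high spinal-cord lesion (84% with >=1) and Gd+ burden, the
# rapid phenotype has high brain lesion load (35% with >=9) plus frequent
# hemispheric onset, and the late phenotype has elevated optic-neuritis onset.
_BASELINE_PARAMS = {
    "minimal": dict(
        age=(32.0, 9.5), female=0.67, onset=(0.22, 0.15, 0.35, 0.28), ocb=0.88,
        edss_mu=2.0, brain_t2=(0.20, 0.53, 0.27), brain_gd=0.48,
        sc_t2=(0.40, 0.54, 0.06), sc_gd=0.39,
    ),
    "late": dict(
        age=(32.0, 9.5), female=0.68, onset=(0.28, 0.13, 0.28, 0.31), ocb=0.88,
        edss_mu=1.6, brain_t2=(0.19, 0.54, 0.27), brain_gd=0.46,
        sc_t2=(0.41, 0.53, 0.06), sc_gd=0.34,
    ),
    "early": dict(
        age=(35.0, 10.0), female=0.65, onset=(0.15, 0.08, 0.59, 0.18), ocb=0.88,
        edss_mu=2.5, brain_t2=(0.12, 0.58, 0.30), brain_gd=0.62,
        sc_t2=(0.16, 0.70, 0.14), sc_gd=0.65,
    ),
    "rapid": dict(
        age=(36.0, 11.0), female=0.63, onset=(0.21, 0.12, 0.28, 0.39), ocb=0.88,
        edss_mu=2.5, brain_t2=(0.10, 0.55, 0.35), brain_gd=0.57,
        sc_t2=(0.23, 0.65, 0.12), sc_gd=0.43,
    ),
}

_ONSET_SITES = ("optic_nerve", "brainstem", "spinal_cord", "hemispheric")
_BRAIN_T2_CATS = ("1-2", "3-8", ">=9")
_SC_T2_CATS = ("0", "1-2", ">=3")


def patient_rng(cohort_seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Independent, reproducible RNG substream for one patient."""
    return np.random.default_rng(np.random.SeedSequence([int(cohort_seed), int(index), int(stream)]))


def simulate_relapses(arr: float, followup: float, rng: np.random.Generator) -> list:
    """Relapse onset times from a homogeneous Poisson process of rate ``arr``."""
    if arr < 0:
        raise ConfigurationError(f"relapse rate must be >= 0, got {arr}")
    if followup < 0:
        raise ConfigurationError(f"followup must be >= 0, got {followup}")
    count = rng.poisson(arr * followup)
    return sorted(rng.uniform(0.0, followup, size=count).tolist())


def _followup_sigma(config: CohortConfig) -> float:
    lo, hi = config.followup_iqr
    return math.log(hi / lo) / (2.0 * 0.674489750196082)


def draw_followup(config: CohortConfig, rng: np.random.Generator) -> float:
    """Follow-up duration: log-normal matched to the target median/IQR, truncated."""
    mu = math.log(config.followup_median)
    sigma = _followup_sigma(config)
    lo, hi = config.followup_range
    for _ in range(1000):
        t = float(rng.lognormal(mu, sigma))
        if lo <= t <= hi:
            return t
    return float(np.clip(t, lo, hi))


def draw_visit_times(followup: float, config: CohortConfig, rng: np.random.Generator) -> list:
    """Visit schedule: baseline visit at t=0 then gaps of 3-6 months."""
    lo, hi = config.visit_interval_months
    times = [0.0]
    t = 0.0
    while True:
        t += float(rng.uniform(lo, hi)) / 12.0
        if t > followup:
            break
        times.append(t)
    return times


def _relapse_bump(t: float, relapse_times: Sequence[float], config: CohortConfig) -> float:
    window = config.relapse_bump_days / DAYS_PER_YEAR
    if window <= 0 or config.relapse_bump == 0:
        return 0.0
    bump = 0.0
    for r in relapse_times:
        dt = t - r
        if 0.0 <= dt < window:
            bump += config.relapse_bump * (1.0 - dt / window)
    return bump


def simulate_patient_trajectory(
    spec: PhenotypeSpec,
    followup: float,
    visit_times: Sequence[float],
    relapse_times: Sequence[float],
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    intercept: Optional[float] = None,
    noise: Optional[np.ndarray] = None,
    mean_fn: Optional[Callable] = None,
) -> list:
    """Observed (time, EDSS) series for one patient.

    Latent value = class mean + patient random intercept + measurement noise
    + transient relapse bump; the result is clamped to [0, 10] and rounded
    to the legal EDSS grid.

    ``intercept``/``noise`` may be passed explicitly to rebuild a patient's
    trajectory under a modified mean curve with identical randomness.
    """
    vt = np.asarray(visit_times, dtype=float)
    if np.any(np.diff(vt) <= 0):
        raise ValueError("visit_times must be strictly increasing")
    if len(vt) and (vt[0] < 0 or vt[-1] > followup + 1e-9):
        raise ValueError("visit_times must lie within [0, followup]")
    if rng is None and (intercept is None or noise is None):
        raise ValueError("either rng or explicit (intercept, noise) draws are required")
    if intercept is None:
        intercept = float(rng.normal(0.0, config.intercept_sd))
    if noise is None:
        noise = rng.normal(0.0, 1.0, size=len(vt))
    mean = mean_fn if mean_fn is not None else spec.mean
    out = []
    for t, eps in zip(vt, noise):
        latent = float(mean(t)) + intercept + config.measurement_sd * float(eps)
        latent += _relapse_bump(t, relapse_times, config)
        out.append((float(t), round_to_grid(latent)))
    return out


def simulate_baseline_features(phenotype: str, rng: np.random.Generator, params: Optional[dict] = None) -> BaselineFeatures:
    """Draw baseline clinical/MRI features for one patient of ``phenotype``."""
    if params is None:
        if phenotype not in _BASELINE_PARAMS:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        params = _BASELINE_PARAMS[phenotype]
    age_mu, age_sd = params["age"]
    age = float(rng.normal(age_mu, age_sd))
    while age <= 18.0:
        age = float(rng.normal(age_mu, age_sd))
    site = _ONSET_SITES[int(rng.choice(4, p=params["onset"]))]
    flags = {s: s == site for s in _ONSET_SITES}
    edss = round_to_grid(float(np.clip(
        rng.normal(params["edss_mu"], params.get("edss_sd", 0.8)), 0.0, 6.0)))
    return BaselineFeatures(
        age_at_onset=age,
        sex="F" if rng.uniform() < params["female"] else "M",
        ocb=bool(rng.uniform() < params["ocb"]),
        baseline_edss=edss,
        brain_t2=_BRAIN_T2_CATS[int(rng.choice(3, p=params["brain_t2"]))],
        brain_gd=bool(rng.uniform() < params["brain_gd"]),
        sc_t2=_SC_T2_CATS[int(rng.choice(3, p=params["sc_t2"]))],
        sc_gd=bool(rng.uniform() < params["sc_gd"]),
        **flags,
    )


def _draw_recovery(rng: np.random.Generator) -> str:
    return ("complete", "incomplete", "none")[int(rng.choice(3, p=(0.6, 0.3, 0.1)))]


def _simulate_one(
    index: int,
    spec: PhenotypeSpec,
    config: CohortConfig,
    cohort: str = "untreated",
    mean_fn: Optional[Callable] = None,
) -> PatientRecord:
    """Assemble one patient from its dedicated substream.

    Draw order is fixed (follow-up, visits, relapses, recoveries, intercept,
    noise block, baseline) so the same key reproduces identical randomness
    under a different mean curve.
    """
    rng = patient_rng(config.seed, index)
    followup = draw_followup(config, rng)
    if spec.max_followup_years is not None:
        followup = min(followup, spec.max_followup_years)
    visit_times = draw_visit_times(followup, config, rng)
    relapse_times = simulate_relapses(spec.arr, followup, rng)
    recoveries = [_draw_recovery(rng) for _ in relapse_times]
    intercept = float(rng.normal(0.0, config.intercept_sd))
    noise = rng.normal(0.0, 1.0, size=len(visit_times))
    visits = simulate_patient_trajectory(
        spec, followup, visit_times, relapse_times, config,
        intercept=intercept, noise=noise, mean_fn=mean_fn,
    )
    baseline = simulate_baseline_features(spec.name, rng)
    return PatientRecord(
        id=f"P{index:05d}",
        cohort=cohort,
        true_phenotype=spec.name,
        baseline=baseline,
        visits=visits,
        relapses=list(zip(relapse_times, recoveries)),
        treatments=[],
        sim_key=(config.seed, index),
    )


def _treated_mean_fn(spec: PhenotypeSpec, episodes: Sequence[TreatmentEpisode], effects: dict) -> Callable:
    """Latent mean under treatment: post-initiation slope scaled by the
    episode's efficacy multiplier, integrated piecewise over episodes."""
    breaks = []
    for ep in sorted(episodes, key=lambda e: e.start_years):
        breaks.append((ep.start_years, effects[ep.efficacy]))

    def mean(t: float) -> float:
        t = float(t)
        value = 0.0
        prev_t, prev_mult = 0.0, 1.0
        segs = breaks + [(math.inf, None)]
        for start, mult in segs:
            seg_end = min(t, start)
            if seg_end > prev_t:
                value += prev_mult * (spec.mean(seg_end) - spec.mean(prev_t))
            if t <= start:
                break
            prev_t, prev_mult = start, mult
        return float(np.clip(spec.mean(0.0) + value, 0.0, min(spec.plateau_cap, 10.0)))

    return mean


def simulate_treatment(
    record: PatientRecord,
    strategy: str,
    config: CohortConfig,
    spec: PhenotypeSpec,
    rng: Optional[np.random.Generator] = None,
    effects: Optional[dict] = None,
) -> PatientRecord:
    """Apply a treatment strategy to an untreated ground-truth record.

    Treatment episodes are assigned and the visit series is regenerated from
    the slope-scaled latent curve using the patient's original noise draws,
    so a multiplier of 1.0 reproduces the untreated trajectory exactly.
    """
    if strategy not in {"moderate", "high", "escalation"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    if record.sim_key is None:
        raise ValueError("record lacks a sim_key; only generator output can be re-simulated")
    if effects is None:
        effects = {"moderate": config.effect_moderate, "high": config.effect_high}
    seed, index = record.sim_key
    if rng is None:
        rng = patient_rng(seed, index, stream=1)
    followup = record.followup_years
    start = float(rng.uniform(0.25, min(3.0, max(0.5, followup / 2))))
    episodes = []
    if strategy == "moderate":
        product = MODERATE_PRODUCTS[int(rng.choice(len(MODERATE_PRODUCTS)))]
        episodes.append(TreatmentEpisode(product, "moderate", start, followup))
    elif strategy == "high":
        product = HIGH_PRODUCTS[int(rng.choice(len(HIGH_PRODUCTS)))]
        episodes.append(TreatmentEpisode(product, "high", start, followup))
    else:
        switch = float(min(start + rng.uniform(1.0, 5.0), followup))
        p1 = MODERATE_PRODUCTS[int(rng.choice(len(MODERATE_PRODUCTS)))]
        p2 = HIGH_PRODUCTS[int(rng.choice(len(HIGH_PRODUCTS)))]
        episodes.append(TreatmentEpisode(p1, "moderate", start, switch))
        episodes.append(TreatmentEpisode(p2, "high", switch, followup))
    treated = _simulate_one(index, spec, config, cohort="treated",
                            mean_fn=_treated_mean_fn(spec, episodes, effects))
    treated.treatments = episodes
    return treated


def validate_phenotypes(phenotypes: Sequence[PhenotypeSpec]) -> None:
    total = sum(p.mixing_weight for p in phenotypes)
    if abs(total - 1.0) > 1e-12:
        raise ConfigurationError(f"mixing weights must sum to 1, got {total}")


def simulate_cohort(
    config: CohortConfig,
    phenotypes: Sequence[PhenotypeSpec] = DEFAULT_PHENOTYPES,
) -> list:
    """Generate a full cohort of :class:`PatientRecord`.

    Phenotype labels are drawn from the mixing weights; a ``treated_fraction``
    of patients receive a randomly drawn DMT strategy with the configured
    slope multipliers. Identical ``(config, seed)`` yields identical output.
    """
    validate_phenotypes(phenotypes)
    weights = np.array([p.mixing_weight for p in phenotypes])
    records = []
    for i in range(config.n_patients):
        assign_rng = patient_rng(config.seed, i, stream=2)
        spec = phenotypes[int(assign_rng.choice(len(phenotypes), p=weights))]
        treated = bool(assign_rng.uniform() < config.treated_fraction)
        rec = _simulate_one(i, spec, config)
        if treated:
            strategy = ("moderate", "high", "escalation")[
                int(assign_rng.choice(3, p=np.asarray(config.strategy_probs)))
            ]
            rec = simulate_treatment(rec, strategy, config, spec)
        records.append(rec)
    return records


def spec_by_name(phenotypes: Sequence[PhenotypeSpec], name: str) -> PhenotypeSpec:
    for p in phenotypes:
        if p.name == name:
            return p
    raise KeyError(name)
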