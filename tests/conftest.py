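import numpy as np
import pandas as pd
import pytest

from mstp import events as ev
from mstp import synthetic as syn
from mstp import trajectories as tj


BALANCED_PHENOTYPES = tuple(
    syn.PhenotypeSpec(**{**vars(p), "mixing_weight": w})
    for p, w in zip(syn.DEFAULT_PHENOTYPES, (0.25, 0.35, 0.2, 0.2))
)


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient untreated cohort with balanced phenotype weights, so all
    four classes are recoverable at unit-test scale (session-cached)."""
    config = syn.CohortConfig(n_patients=400, seed=20240)
    return config, syn.simulate_cohort(config, BALANCED_PHENOTYPES)


@pytest.fixture(scope="session")
def small_visits(small_cohort):
    """Relapse-filtered long-format visits for the small cohort."""
    _, records = small_cohort
    records = ev.apply_inclusion_criteria(records)
    rows = []
    for rec in records:
        kept = ev.exclude_relapse_window_scores(rec.visits, [r for r, _ in rec.relapses])
        rows.extend((rec.id, t, e) for t, e in kept)
    visits = pd.DataFrame(rows, columns=["patient_id", "time_years", "edss"])
    truth = pd.Series({rec.id: rec.true_phenotype for rec in records})
    return visits, truth


@pytest.fixture(scope="session")
def small_model(small_visits):
    visits, _ = small_visits
    return tj.fit_latent_classes(visits, 4, n_starts=4, seed=99)


def two_class_visits(n_subjects=200, seed=0, means=(1.0, 6.0), weights=(0.5, 0.5),
                     sigma_b=0.3, sigma_e=0.4):
    """Well-separated two-class longitudinal data (flat trajectories)."""
    rng = np.random.default_rng(seed)
    rows = []
    labels = rng.choice(len(means), size=n_subjects, p=weights)
    for i in range(n_subjects):
        times = np.arange(0.0, 10.0, 1.0)
        b = rng.normal(0.0, sigma_b)
        y = means[labels[i]] + b + rng.normal(0.0, sigma_e, size=len(times))
        rows.extend((f"S{i:04d}", t, v) for t, v in zip(times, y))
    return pd.DataFrame(rows, columns=["patient_id", "time_years", "edss"]), labels
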