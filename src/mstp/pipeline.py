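"""End-to-end orchestration: simulate -> filter -> events -> fit -> match ->
classify -> treatment effect, with a schema-validated config, per-stage
outputs, and a hashed manifest.

All stage outputs are plain delimited text or JSON so any stage can be run
standalone on user-supplied registry extracts with the same schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from . import classifier as clf_mod
from . import events as ev
from . import io as io_mod
from . import matching, response, synthetic
from . import trajectories as tj

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 12345
    n_patients: int = 2563
    treated_fraction: float = 0.5
    kmin: int = Field(default=1, ge=1)
    kmax: int = Field(default=6, ge=1)
    criterion: str = "BIC"
    n_starts: int = 5
    cv_folds: int = 0  # 0 disables cross-validation
    caliper: float = 0.2
    max_ratio: int = 4
    train_split: float = 0.7
    importance_repeats: int = 20
    min_patients_per_stratum: int = 10
    out_dir: str = "runs/latest"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def _treatment_timing(rec) -> Optional[float]:
    """Time to treatment start (years); for escalation, time to the switch."""
    if not rec.treatments:
        return None
    efficacies = {ep.efficacy for ep in rec.treatments}
    if efficacies == {"moderate", "high"}:
        return min(ep.start_years for ep in rec.treatments if ep.efficacy == "high")
    return min(ep.start_years for ep in rec.treatments)


def _strategy(rec) -> Optional[str]:
    if not rec.treatments:
        return None
    efficacies = {ep.efficacy for ep in rec.treatments}
    if efficacies == {"moderate", "high"}:
        return "escalation"
    return next(iter(efficacies))


def characterize_phenotypes(baseline: pd.DataFrame, assignments: pd.DataFrame,
                            bonferroni_family: int = 6) -> pd.DataFrame:
    """Pairwise baseline-feature comparisons across phenotype groups.

    Categorical features use the chi-square test (Fisher exact for 2x2
    tables with any expected count < 5); continuous features use the t test
    when a Kolmogorov-Smirnov screen does not reject normality in either
    group, and the Mann-Whitney test otherwise. Significance flags are
    Bonferroni-corrected over the pairwise family.
    """
    merged = baseline.merge(assignments[["patient_id", "label"]], on="patient_id")
    groups = sorted(merged["label"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two phenotype groups to compare")
    continuous = ["age_at_onset", "baseline_edss"]
    categorical = ["sex", "optic_nerve", "brainstem", "spinal_cord", "hemispheric",
                   "ocb", "brain_t2", "brain_gd", "sc_t2", "sc_gd"]
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            a = merged[merged["label"] == g1]
            b = merged[merged["label"] == g2]
            for feat in continuous:
                x, y = a[feat].to_numpy(float), b[feat].to_numpy(float)
                if x.std() == 0 and y.std() == 0:
                    logger.info("feature %s constant in %s vs %s; test skipped", feat, g1, g2)
                    rows.append((feat, g1, g2, "skipped (constant)", np.nan, np.nan))
                    continue
                normal = True
                for v in (x, y):
                    if v.std() > 0:
                        ks = stats.kstest((v - v.mean()) / v.std(), "norm")
                        normal &= ks.pvalue > 0.05
                if normal:
                    stat, p = stats.ttest_ind(x, y, equal_var=False)
                    test = "t"
                else:
                    stat, p = stats.mannwhitneyu(x, y)
                    test = "mannwhitney"
                rows.append((feat, g1, g2, test, float(stat), float(p)))
            for feat in categorical:
                table = pd.crosstab(
                    merged[merged["label"].isin([g1, g2])]["label"], merged[feat])
                if table.shape[1] < 2:
                    logger.info("feature %s constant in %s vs %s; test skipped", feat, g1, g2)
                    rows.append((feat, g1, g2, "skipped (constant)", np.nan, np.nan))
                    continue
                expected = stats.contingency.expected_freq(table.to_numpy())
                if table.shape == (2, 2) and (expected < 5).any():
                    _, p = stats.fisher_exact(table.to_numpy())
                    stat, test = np.nan, "fisher"
                else:
                    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
                    test = "chi2"
                rows.append((feat, g1, g2, test, float(stat) if stat == stat else np.nan, float(p)))
    out = pd.DataFrame(rows, columns=["feature", "group1", "group2", "test", "statistic", "p"])
    with np.errstate(invalid="ignore"):
        out["significant"] = out["p"] < 0.05 / bonferroni_family
    return out


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> Path:
    """Execute every stage in order; returns the run directory.

    Any stage failure raises with the stage name; a manifest with output
    hashes, the master seed, and package version is written at the end.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort_cfg = synthetic.CohortConfig(
            n_patients=config.n_patients,
            treated_fraction=config.treated_fraction,
            seed=config.seed,
        )
        records = synthetic.simulate_cohort(cohort_cfg)
        io_mod.write_cohort(records, out)

        stage = "inclusion"
        records = ev.apply_inclusion_criteria(records)
        untreated = [r for r in records if r.cohort == "untreated"]
        treated = [r for r in records if r.cohort == "treated"]
        if not untreated:
            raise ValueError("no untreated patients survive the inclusion criteria")

        stage = "events"
        event_table = ev.detect_cohort_events(records)
        event_table.to_csv(out / "events.csv", index=False)

        stage = "fit_trajectories"
        filtered_rows = []
        for rec in untreated:
            kept = ev.exclude_relapse_window_scores(rec.visits, [r for r, _ in rec.relapses])
            filtered_rows.extend((rec.id, t, e) for t, e in kept)
        visits = pd.DataFrame(filtered_rows, columns=["patient_id", "time_years", "edss"])
        k_best, summaries, models = tj.select_class_number(
            visits, range(config.kmin, config.kmax + 1), criterion=config.criterion,
            n_starts=config.n_starts, seed=config.seed)
        model = models[k_best]
        if config.cv_folds >= 2:
            cv = tj.cross_validate(visits, k_best, folds=config.cv_folds, seed=config.seed)
        else:
            cv = None
        model.class_names = tj.name_classes_by_onset(model)
        table = tj.criteria_table(summaries)
        table.to_csv(out / "criteria.csv", index=False)
        _write_json(out / "model.json", {**model.to_dict(), "K_best": k_best, "cv_loglik": cv})

        stage = "classify_untreated"
        untreated_assign = []
        for rec in untreated:
            kept = ev.exclude_relapse_window_scores(rec.visits, [r for r, _ in rec.relapses])
            times = [t for t, _ in kept]
            edss = [e for _, e in kept]
            a = tj.posterior_classify(model, times, edss, patient_id=rec.id)
            untreated_assign.append((rec.id, a.label, *a.probabilities))
        prob_cols = [f"p_{n}" for n in model.class_names]
        untreated_assign = pd.DataFrame(
            untreated_assign, columns=["patient_id", "label", *prob_cols])
        untreated_assign.to_csv(out / "untreated_assignments.csv", index=False)

        manifest_extra = {}
        match_result = None
        if treated:
            stage = "match"
            frames = io_mod.cohort_frames(records)
            baseline = frames["baseline"]
            scores = matching.estimate_propensity(baseline)
            scores = scores.merge(baseline[["patient_id"]], on="patient_id")
            match_result = matching.match_cohorts(scores, caliper=config.caliper,
                                                  max_ratio=config.max_ratio)
            match_result.pairs.to_csv(out / "matches.csv", index=False)
            matching.covariate_balance(baseline, match_result).to_csv(
                out / "balance.csv", index=False)

            stage = "train_classifier"
            untreated_baseline = baseline[baseline["cohort"] == "untreated"]
            labels = untreated_assign.set_index("patient_id")["label"]
            forest, report = clf_mod.train_classifier(
                untreated_baseline, labels, split=config.train_split, seed=config.seed,
                importance_repeats=config.importance_repeats)
            _write_json(out / "classifier_report.json", report.to_dict())

            stage = "assign_treated"
            treated_baseline = baseline[baseline["cohort"] == "treated"]
            assignments = clf_mod.assign_phenotypes(forest, treated_baseline)
            assignments.to_csv(out / "assignments.csv", index=False)

            stage = "treatment_effect"
            contrasts, zrows = [], []
            label_of = dict(zip(assignments["patient_id"], assignments["label"]))
            by_strategy = {}
            for rec in treated:
                strat = _strategy(rec)
                if strat is None:
                    continue
                by_strategy.setdefault(strat, []).append(rec)
            for strat, recs in sorted(by_strategy.items()):
                observed, expected, timing = {}, {}, {}
                for rec in recs:
                    kept = ev.exclude_relapse_window_scores(
                        rec.visits, [r for r, _ in rec.relapses])
                    if not kept:
                        continue
                    label = label_of[rec.id]
                    times = [t for t, _ in kept]
                    observed[rec.id] = kept
                    expected[rec.id] = response.predict_trajectory(model, label, times)
                    timing[rec.id] = _treatment_timing(rec)
                    for zp in response.disability_zscore(kept, expected[rec.id], rec.id):
                        zrows.append((rec.id, strat, label, zp.time, zp.observed_edss,
                                      zp.expected_mean, zp.z))
                if len(observed) < config.min_patients_per_stratum:
                    logger.warning("skipping strategy %s: only %d patients", strat, len(observed))
                    continue
                data = response.build_obs_pred_frame(observed, expected)
                result = response.fit_obs_vs_pred(
                    data, strategy=strat,
                    weights={pid: match_result.weights.get(pid, 1.0) for pid in observed},
                    timing=timing, min_patients=config.min_patients_per_stratum)
                for term, (beta, se, p) in result.terms.items():
                    contrasts.append((strat, term, beta, se, p,
                                      result.significant.get(term)))
            pd.DataFrame(contrasts, columns=["strategy", "term", "beta", "se", "p",
                                             "significant"]).to_csv(
                out / "contrasts.csv", index=False)
            pd.DataFrame(zrows, columns=["patient_id", "strategy", "label", "time_years",
                                         "observed", "expected", "z"]).to_csv(
                out / "zscores.csv", index=False)

            stage = "characterize"
            characterize_phenotypes(treated_baseline, assignments).to_csv(
                out / "characterization.csv", index=False)
            manifest_extra["n_treated"] = len(treated)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    stage = "manifest"
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": config.model_dump(),
        "version": __import__("mstp").__version__,
        "n_patients": config.n_patients,
        "n_untreated": len(untreated),
        "outputs": {p.name: _sha256(p) for p in outputs},
        **manifest_extra,
    }
    _write_json(out / "manifest.json", manifest)
    return out
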