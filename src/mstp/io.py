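"""Plain-text table I/O for cohorts and downstream stage outputs.

All stage interchange uses delimited text (CSV) so any stage can be run
standalone on registry extracts with the same schema.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .synthetic import BaselineFeatures, PatientRecord, TreatmentEpisode

BASELINE_COLUMNS = [
    "patient_id", "cohort", "age_at_onset", "sex", "optic_nerve", "brainstem",
    "spinal_cord", "hemispheric", "ocb", "baseline_edss", "brain_t2",
    "brain_gd", "sc_t2", "sc_gd",
]


def cohort_frames(records: Iterable[PatientRecord]) -> dict:
    """Long-format tables (visits, relapses, treatments, baseline, truth)."""
    visits, relapses, treatments, baseline, truth = [], [], [], [], []
    for rec in records:
        for t, e in rec.visits:
            visits.append((rec.id, t, e))
        for r, recov in rec.relapses:
            relapses.append((rec.id, r, recov))
        for ep in rec.treatments:
            treatments.append((rec.id, ep.product, ep.efficacy, ep.start_years, ep.stop_years))
        b = rec.baseline
        baseline.append((rec.id, rec.cohort, b.age_at_onset, b.sex, b.optic_nerve,
                         b.brainstem, b.spinal_cord, b.hemispheric, b.ocb,
                         b.baseline_edss, b.brain_t2, b.brain_gd, b.sc_t2, b.sc_gd))
        truth.append((rec.id, rec.true_phenotype))
    return {
        "visits": pd.DataFrame(visits, columns=["patient_id", "time_years", "edss"]),
        "relapses": pd.DataFrame(relapses, columns=["patient_id", "onset_years", "recovery"]),
        "treatments": pd.DataFrame(
            treatments, columns=["patient_id", "product", "efficacy", "start_years", "stop_years"]),
        "baseline": pd.DataFrame(baseline, columns=BASELINE_COLUMNS),
        "truth": pd.DataFrame(truth, columns=["patient_id", "true_phenotype"]),
    }


def write_cohort(records: Iterable[PatientRecord], outdir) -> dict:
    """Write the cohort tables to ``outdir``; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in cohort_frames(records).items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_cohort(indir) -> dict:
    indir = Path(indir)
    out = {}
    for name in ("visits", "relapses", "treatments", "baseline", "truth"):
        path = indir / f"{name}.csv"
        if path.exists():
            out[name] = pd.read_csv(path)
    return out


def records_from_frames(frames: dict) -> list:
    """Rebuild :class:`PatientRecord` objects from the long-format tables."""
    visits = frames["visits"].groupby("patient_id")
    relapses = frames.get("relapses")
    treatments = frames.get("treatments")
    truth = frames.get("truth")
    truth_map = {} if truth is None else dict(zip(truth.patient_id, truth.true_phenotype))
    rel_map = {} if relapses is None else {
        pid: list(zip(g.onset_years, g.recovery)) for pid, g in relapses.groupby("patient_id")}
    trt_map = {}
    if treatments is not None:
        for pid, g in treatments.groupby("patient_id"):
            trt_map[pid] = [TreatmentEpisode(r.product, r.efficacy, r.start_years, r.stop_years)
                            for r in g.itertuples()]
    records = []
    for row in frames["baseline"].itertuples():
        pid = row.patient_id
        grp = visits.get_group(pid).sort_values("time_years")
        features = BaselineFeatures(
            age_at_onset=row.age_at_onset, sex=row.sex,
            optic_nerve=bool(row.optic_nerve), brainstem=bool(row.brainstem),
            spinal_cord=bool(row.spinal_cord), hemispheric=bool(row.hemispheric),
            ocb=bool(row.ocb), baseline_edss=row.baseline_edss,
            brain_t2=str(row.brain_t2), brain_gd=bool(row.brain_gd),
            sc_t2=str(row.sc_t2), sc_gd=bool(row.sc_gd))
        records.append(PatientRecord(
            id=pid, cohort=row.cohort, true_phenotype=truth_map.get(pid, ""),
            baseline=features,
            visits=list(zip(grp.time_years, grp.edss)),
            relapses=sorted(rel_map.get(pid, [])),
            treatments=trt_map.get(pid, [])))
    return records
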