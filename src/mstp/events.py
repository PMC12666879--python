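"""EDSS preprocessing, confirmed disability worsening (CDW) detection, and
RAW/PIRA classification.

A CDW is an EDSS increase over a reference value — >=1.5 points from a
reference of 0, >=1.0 from 1.0-5.0, >=0.5 from >=5.5 — sustained to a
confirmation visit at least six months later. Events are labelled RAW when
onset falls within 30 days before to 90 days after a relapse onset, PIRA
otherwise. EDSS scores within 30 days of a relapse are excluded before
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .grid import is_on_grid
from .synthetic import DAYS_PER_YEAR, PatientRecord


@dataclass(frozen=True)
class EventConfig:
    exclusion_pre_days: float = 30.0
    exclusion_post_days: float = 30.0
    raw_pre_days: float = 30.0
    raw_post_days: float = 90.0
    confirmation_days: float = 180.0
    baseline_mode: str = "roving"  # or "fixed"

    def __post_init__(self):
        for name in ("exclusion_pre_days", "exclusion_post_days", "raw_pre_days",
                     "raw_post_days", "confirmation_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_mode not in {"roving", "fixed"}:
            raise ValueError(f"baseline_mode must be 'roving' or 'fixed'")


@dataclass(frozen=True)
class CDWEvent:
    patient_id: str
    onset_time: float
    reference_edss: float
    event_edss: float
    confirmation_time: float
    label: str = "unclassified"  # {"RAW", "PIRA", "unclassified"}


def required_increase(reference_edss: float) -> float:
    """Minimum EDSS increase for worsening, given the reference score."""
    if not is_on_grid(reference_edss):
        raise ValueError(f"reference EDSS {reference_edss} is not on the legal grid")
    if reference_edss == 0.0:
        return 1.5
    if reference_edss <= 5.0:
        return 1.0
    return 0.5


def exclude_relapse_window_scores(
    visits: Sequence[Tuple[float, float]],
    relapses: Sequence[float],
    config: EventConfig = EventConfig(),
) -> List[Tuple[float, float]]:
    """Drop visits within the relapse exclusion window (default +/-30 days)."""
    pre = config.exclusion_pre_days / DAYS_PER_YEAR
    post = config.exclusion_post_days / DAYS_PER_YEAR
    out = []
    for t, e in visits:
        if any(r - pre <= t <= r + post for r in relapses):
            continue
        out.append((t, e))
    return out


def apply_inclusion_criteria(
    records: Iterable[PatientRecord],
    config: EventConfig = EventConfig(),
    min_visits: int = 3,
    min_followup_years: float = 3.0,
    max_first_visit_years: float = 1.0,
) -> List[PatientRecord]:
    """Keep records with >=3 retained EDSS scores, >=3 years of follow-up,
    and a first assessment within 1 year of onset."""
    kept = []
    for rec in records:
        retained = exclude_relapse_window_scores(rec.visits, [r for r, _ in rec.relapses], config)
        if len(retained) < min_visits:
            continue
        if retained[-1][0] < min_followup_years:
            continue
        if retained[0][0] > max_first_visit_years:
            continue
        kept.append(rec)
    return kept


def classify_event(event: CDWEvent, relapses: Sequence[float],
                   config: EventConfig = EventConfig()) -> CDWEvent:
    """Label a confirmed event RAW if onset lies within [r - raw_pre, r + raw_post]
    of any relapse onset r, else PIRA."""
    pre = config.raw_pre_days / DAYS_PER_YEAR
    post = config.raw_post_days / DAYS_PER_YEAR
    is_raw = any(r - pre <= event.onset_time <= r + post for r in relapses)
    return replace(event, label="RAW" if is_raw else "PIRA")


def detect_cdw(
    visits: Sequence[Tuple[float, float]],
    relapses: Sequence[float] = (),
    config: EventConfig = EventConfig(),
    patient_id: str = "",
) -> List[CDWEvent]:
    """Scan relapse-filtered visits for confirmed disability worsening.

    A candidate at time t (EDSS increase >= required_increase(reference)) is
    confirmed iff some later visit at t' >= t + confirmation interval also
    meets the threshold versus the same reference and every retained visit in
    (t, t'] stays at or above it. In roving mode the reference resets to the
    event EDSS after each confirmed event and scanning resumes at the
    confirmation visit; in fixed mode the reference is the first retained
    EDSS throughout and at most one (the first) event is returned.
    """
    visits = list(visits)
    if len(visits) < 2:
        return []
    times = np.array([t for t, _ in visits])
    if np.any(np.diff(times) <= 0):
        raise ValueError("visits must be strictly increasing in time")
    conf = config.confirmation_days / DAYS_PER_YEAR
    events: List[CDWEvent] = []
    ref = visits[0][1]
    i = 1
    while i < len(visits):
        t_i, e_i = visits[i]
        thr = ref + required_increase(ref)
        if e_i >= thr:
            j_conf = None
            sustained = True
            for j in range(i + 1, len(visits)):
                t_j, e_j = visits[j]
                if e_j < thr:
                    sustained = False
                    break
                if t_j - t_i >= conf:
                    j_conf = j
                    break
            if sustained and j_conf is not None:
                event = CDWEvent(patient_id=patient_id, onset_time=t_i,
                                 reference_edss=ref, event_edss=e_i,
                                 confirmation_time=visits[j_conf][0])
                events.append(classify_event(event, relapses, config))
                if config.baseline_mode == "fixed":
                    break
                ref = e_i
                i = j_conf
                continue
        i += 1
    return events


def detect_cohort_events(records: Iterable[PatientRecord],
                         config: EventConfig = EventConfig()) -> pd.DataFrame:
    """Relapse-window filtering + CDW detection over a cohort; tidy table out."""
    rows = []
    for rec in records:
        rel = [r for r, _ in rec.relapses]
        retained = exclude_relapse_window_scores(rec.visits, rel, config)
        for ev in detect_cdw(retained, rel, config, patient_id=rec.id):
            rows.append((ev.patient_id, ev.onset_time, ev.reference_edss,
                         ev.event_edss, ev.confirmation_time, ev.label))
    return pd.DataFrame(rows, columns=["patient_id", "onset_years", "reference_edss",
                                       "event_edss", "confirmation_years", "label"])


def annualized_relapse_rate(relapses: Sequence[float], followup: float) -> float:
    if followup <= 0:
        raise ValueError(f"followup must be > 0, got {followup}")
    return len(relapses) / followup


def compare_raw_pira(events_by_group: dict) -> dict:
    """Chi-square comparison of RAW/PIRA composition across phenotype groups.

    ``events_by_group`` maps group name -> iterable of CDWEvent (or labels).
    Returns per-group counts/proportions and the chi-square test on the
    group x label contingency table (no continuity correction).
    """
    counts = {}
    for name, events in events_by_group.items():
        labels = [ev.label if isinstance(ev, CDWEvent) else str(ev) for ev in events]
        counts[name] = (labels.count("RAW"), labels.count("PIRA"))
    table = np.array([counts[g] for g in counts], dtype=float)
    if table.sum() == 0 or table.shape[0] < 2:
        raise ValueError("need at least two groups with events")
    keep = table.sum(axis=1) > 0
    reduced = table[keep]
    if reduced.shape[0] < 2:
        raise ValueError("need at least two non-empty groups")
    if reduced.std(axis=0).sum() == 0 or (reduced.sum(axis=0) == 0).any():
        # degenerate table: identical composition or a label never observed
        stat, p, df = 0.0, 1.0, (reduced.shape[0] - 1)
    else:
        stat, p, df, _ = stats.chi2_contingency(reduced, correction=False)
    summary = {
        name: {"raw": raw, "pira": pira,
               "raw_prop": raw / (raw + pira) if raw + pira else float("nan")}
        for name, (raw, pira) in counts.items()
    }
    return {"groups": summary, "chi2": float(stat), "df": int(df), "p": float(p)}


def interval_table(records: Iterable[PatientRecord],
                   config: EventConfig = EventConfig()) -> pd.DataFrame:
    """Per-interval EDSS change rates with interval ARR and midpoint time.

    For each consecutive pair of retained visits the response is
    (delta EDSS)/(delta t); the interval ARR is the relapse count inside the
    interval divided by its length.
    """
    rows = []
    for rec in records:
        rel = [r for r, _ in rec.relapses]
        retained = exclude_relapse_window_scores(rec.visits, rel, config)
        for (t0, e0), (t1, e1) in zip(retained, retained[1:]):
            dt = t1 - t0
            if dt <= 0:
                continue
            n_rel = sum(1 for r in rel if t0 <= r < t1)
            rows.append((rec.id, (e1 - e0) / dt, n_rel / dt, 0.5 * (t0 + t1)))
    return pd.DataFrame(rows, columns=["patient_id", "rate", "arr", "time"])


def fit_arr_time_model(intervals: pd.DataFrame) -> pd.DataFrame:
    """Mixed model of the EDSS change rate on ARR, time, and ARR x time with
    a patient random intercept; returns a (term, beta, se, p) table."""
    from . import lmm

    if intervals.empty or intervals.patient_id.nunique() < 2:
        raise ValueError("need intervals from at least two patients")
    X = np.column_stack([
        np.ones(len(intervals)), intervals.arr, intervals.time,
        intervals.arr * intervals.time])
    try:
        fit = lmm.fit_lmm(intervals.rate.to_numpy(), X,
                          intervals.patient_id.to_numpy(),
                          names=["intercept", "arr", "time", "arr:time"])
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular fit: {err}") from err
    return fit.summary_frame()


def arr_time_association(records: Iterable[PatientRecord],
                         config: EventConfig = EventConfig()) -> pd.DataFrame:
    """Temporal association between disability accrual and relapse rate."""
    return fit_arr_time_model(interval_table(records, config))
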