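import numpy as np
import pandas as pd
import pytest

from mstp import events as ev
from mstp import synthetic as syn
from mstp.events import CDWEvent, EventConfig
from mstp.synthetic import DAYS_PER_YEAR

D = 1.0 / DAYS_PER_YEAR  # one day in years


class TestRequiredIncrease:
    @pytest.mark.parametrize("ref,expected", [
        (0.0, 1.5), (1.0, 1.0), (4.0, 1.0), (5.0, 1.0), (5.5, 0.5), (6.0, 0.5),
        (10.0, 0.5),
    ])
    def test_thresholds(self, ref, expected):
        assert ev.required_increase(ref) == expected

    @pytest.mark.parametrize("bad", [0.5, 3.2, -1.0])
    def test_off_grid_rejected(self, bad):
        with pytest.raises(ValueError):
            ev.required_increase(bad)


class TestExclusionWindow:
    def test_no_relapses_identity(self):
        visits = [(0.0, 1.0), (1.0, 2.0)]
        assert ev.exclude_relapse_window_scores(visits, []) == visits

    def test_thirty_day_boundary(self):
        relapse = 2.0
        visits = [(relapse + 29 * D, 3.0), (relapse + 31 * D, 3.5),
                  (relapse - 29 * D, 1.0), (relapse - 31 * D, 1.5)]
        kept = ev.exclude_relapse_window_scores(sorted(visits), [relapse])
        assert kept == sorted([(relapse + 31 * D, 3.5), (relapse - 31 * D, 1.5)])

    def test_matches_bruteforce_on_random_timelines(self):
        rng = np.random.default_rng(0)
        cfg = EventConfig()
        pre = cfg.exclusion_pre_days * D
        post = cfg.exclusion_post_days * D
        for _ in range(200):
            times = np.sort(rng.uniform(0, 15, size=rng.integers(1, 15)))
            visits = [(float(t), 2.0) for t in times]
            relapses = sorted(rng.uniform(0, 15, size=rng.integers(0, 6)).tolist())
            expected = [v for v in visits
                        if not any(r - pre <= v[0] <= r + post for r in relapses)]
            assert ev.exclude_relapse_window_scores(visits, relapses) == expected


class TestInclusionCriteria:
    def _record(self, visits, relapses=()):
        baseline = syn.simulate_baseline_features("late", np.random.default_rng(0))
        return syn.PatientRecord(id="X", cohort="untreated", true_phenotype="late",
                                 baseline=baseline, visits=list(visits),
                                 relapses=[(r, "complete") for r in relapses],
                                 treatments=[])

    def test_too_few_visits_dropped(self):
        rec = self._record([(0.0, 1.0), (4.0, 2.0)])
        assert ev.apply_inclusion_criteria([rec]) == []

    def test_late_first_visit_dropped(self):
        rec = self._record([(1.5, 1.0), (2.0, 1.0), (5.0, 2.0)])
        assert ev.apply_inclusion_criteria([rec]) == []

    def test_short_followup_dropped(self):
        rec = self._record([(0.0, 1.0), (1.0, 1.0), (2.5, 2.0)])
        assert ev.apply_inclusion_criteria([rec]) == []

    def test_compliant_cohort_identity(self):
        recs = [self._record([(0.0, 1.0), (2.0, 1.5), (4.0, 2.0)]) for _ in range(3)]
        assert ev.apply_inclusion_criteria(recs) == recs

    def test_counts_post_exclusion_scores(self):
        # 3 visits but one falls in a relapse window -> only 2 retained
        rec = self._record([(0.0, 1.0), (2.0, 3.0), (4.0, 2.0)], relapses=[2.01])
        assert ev.apply_inclusion_criteria([rec]) == []


def oracle_detect(visits, relapses, config=EventConfig()):
    """Exhaustive-search reference for detect_cdw (quadratic scans)."""
    conf = config.confirmation_days * D
    events = []
    ref = visits[0][1]
    start = 1
    while start < len(visits):
        found = None
        for i in range(start, len(visits)):
            thr = ref + ev.required_increase(ref)
            if visits[i][1] < thr:
                continue
            confirmations = [
                j for j in range(i + 1, len(visits))
                if visits[j][0] - visits[i][0] >= conf
                and all(visits[m][1] >= thr for m in range(i + 1, j + 1))
            ]
            if confirmations:
                found = (i, min(confirmations))
                break
        if found is None:
            break
        i, j = found
        events.append(ev.classify_event(
            CDWEvent("", visits[i][0], ref, visits[i][1], visits[j][0]),
            relapses, config))
        if config.baseline_mode == "fixed":
            break
        ref = visits[i][1]
        start = j
    return events


class TestDetectCDW:
    def test_single_confirmed_event(self):
        events = ev.detect_cdw([(0.0, 0.0), (1.0, 1.5), (1.6, 1.5)])
        assert len(events) == 1
        e = events[0]
        assert (e.onset_time, e.reference_edss, e.event_edss, e.confirmation_time) \
            == (1.0, 0.0, 1.5, 1.6)
        assert e.label == "PIRA"

    def test_unsustained_increase_no_event(self):
        assert ev.detect_cdw([(0.0, 0.0), (1.0, 1.5), (1.2, 0.0)]) == []

    def test_under_two_visits_empty(self):
        assert ev.detect_cdw([(0.0, 2.0)]) == []
        assert ev.detect_cdw([]) == []

    def test_unconfirmable_last_visit_discarded(self):
        # increase at the final visit has no later confirmation
        assert ev.detect_cdw([(0.0, 2.0), (5.0, 3.5)]) == []

    def test_roving_baseline_multiple_events(self):
        visits = [(0.0, 2.0), (1.0, 3.0), (1.8, 3.0), (3.0, 4.0), (4.0, 4.0)]
        events = ev.detect_cdw(visits)
        assert [(e.reference_edss, e.event_edss) for e in events] == [(2.0, 3.0), (3.0, 4.0)]

    def test_fixed_baseline_single_event(self):
        cfg = EventConfig(baseline_mode="fixed")
        visits = [(0.0, 2.0), (1.0, 3.0), (1.8, 3.0), (3.0, 4.0), (4.0, 4.0)]
        events = ev.detect_cdw(visits, config=cfg)
        assert len(events) == 1 and events[0].reference_edss == 2.0

    def test_densification_at_constant_edss_is_invariant(self):
        visits = [(float(t), 3.0) for t in range(8)]
        dense = sorted(visits + [(t + 0.5, 3.0) for t, _ in visits[:-1]])
        assert ev.detect_cdw(visits) == []
        assert ev.detect_cdw(dense) == []

    @pytest.mark.parametrize("mode", ["roving", "fixed"])
    def test_oracle_equivalence_random_series(self, mode):
        rng = np.random.default_rng(11)
        cfg = EventConfig(baseline_mode=mode)
        grid_vals = np.concatenate([[0.0], np.arange(1.0, 10.01, 0.5)])
        for _ in range(500):
            n = rng.integers(2, 13)
            times = np.sort(rng.uniform(0, 12, size=n))
            while np.any(np.diff(times) <= 0):
                times = np.sort(rng.uniform(0, 12, size=n))
            edss = rng.choice(grid_vals, size=n)
            visits = list(zip(times.tolist(), edss.tolist()))
            relapses = sorted(rng.uniform(0, 12, size=rng.integers(0, 4)).tolist())
            got = ev.detect_cdw(visits, relapses, cfg)
            assert got == oracle_detect(visits, relapses, cfg)

    def test_event_invariants_on_cohort(self, small_cohort):
        _, records = small_cohort
        table = ev.detect_cohort_events(records)
        assert set(table.label) <= {"RAW", "PIRA"}
        thresholds = table.reference_edss.map(ev.required_increase)
        assert ((table.event_edss - table.reference_edss) >= thresholds - 1e-12).all()
        assert ((table.confirmation_years - table.onset_years)
                >= 180 * D - 1e-12).all()

    def test_raw_count_monotone_in_window(self, small_cohort):
        _, records = small_cohort
        counts = []
        for post in (30.0, 90.0, 180.0):
            cfg = EventConfig(raw_post_days=post)
            table = ev.detect_cohort_events(records, cfg)
            counts.append((table.label == "RAW").sum())
        assert counts == sorted(counts)


class TestClassifyEvent:
    def _event(self, onset):
        return CDWEvent("p", onset, 2.0, 3.0, onset + 0.6)

    def test_inside_raw_window(self):
        e = ev.classify_event(self._event(1.0 + 37 * D), [1.0])
        assert e.label == "RAW"

    def test_no_relapses_pira(self):
        assert ev.classify_event(self._event(1.0), []).label == "PIRA"

    def test_ninety_one_days_after_is_pira(self):
        e = ev.classify_event(self._event(1.0 + 91 * D), [1.0])
        assert e.label == "PIRA"

    def test_thirty_days_before_is_raw(self):
        e = ev.classify_event(self._event(1.0 - 30 * D), [1.0])
        assert e.label == "RAW"


class TestARR:
    def test_simple_rate(self):
        assert ev.annualized_relapse_rate([1.0, 2.0, 3.0], 10.0) == pytest.approx(0.3)

    def test_zero_relapses(self):
        assert ev.annualized_relapse_rate([], 5.0) == 0.0

    def test_nonpositive_followup_rejected(self):
        with pytest.raises(ValueError):
            ev.annualized_relapse_rate([], 0.0)

    def test_rapid_generator_rate_monte_carlo(self):
        # mean ARR over simulated rapid patients matches the generator rate
        config = syn.CohortConfig(n_patients=1, seed=77)
        spec = syn.spec_by_name(syn.DEFAULT_PHENOTYPES, "rapid")
        rng = np.random.default_rng(77)
        rates = []
        for _ in range(10_000):
            fu = syn.draw_followup(config, rng)
            fu = min(fu, spec.max_followup_years)
            rates.append(ev.annualized_relapse_rate(
                syn.simulate_relapses(spec.arr, fu, rng), fu))
        assert abs(np.mean(rates) - 0.36) < 0.01


class TestCompareRawPira:
    def test_identical_counts_zero_statistic(self):
        groups = {"a": ["RAW"] * 10 + ["PIRA"] * 10, "b": ["RAW"] * 10 + ["PIRA"] * 10}
        out = ev.compare_raw_pira(groups)
        assert out["chi2"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # 2x2 table (30,10 / 10,30) -> chi2 = 20 without continuity correction
        groups = {"a": ["RAW"] * 30 + ["PIRA"] * 10, "b": ["RAW"] * 10 + ["PIRA"] * 30}
        out = ev.compare_raw_pira(groups)
        assert out["chi2"] == pytest.approx(20.0)
        assert out["df"] == 1

    def test_proportions_reported(self):
        out = ev.compare_raw_pira({"a": ["RAW", "PIRA"], "b": ["PIRA", "PIRA"]})
        assert out["groups"]["a"]["raw_prop"] == pytest.approx(0.5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_raw_pira({"a": [], "b": []})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_raw_pira({"a": ["RAW"]})


def _simulate_intervals(beta_arr_time, rng, n_patients=60, n_intervals=10,
                        sigma_u=0.1, sigma_e=0.3):
    rows = []
    for i in range(n_patients):
        u = rng.normal(0, sigma_u)
        times = np.arange(n_intervals) + 0.5
        arr = rng.exponential(0.3, size=n_intervals)
        rate = (0.2 + 0.1 * arr + 0.01 * times + beta_arr_time * arr * times
                + u + rng.normal(0, sigma_e, size=n_intervals))
        rows.extend((f"P{i}", r, a, t) for r, a, t in zip(rate, arr, times))
    return pd.DataFrame(rows, columns=["patient_id", "rate", "arr", "time"])


class TestArrTimeAssociation:
    def test_single_patient_rejected(self):
        frame = _simulate_intervals(0.0, np.random.default_rng(0), n_patients=1)
        with pytest.raises(ValueError):
            ev.fit_arr_time_model(frame)

    def test_null_coefficient_coverage(self):
        rng = np.random.default_rng(5)
        covered = 0
        for _ in range(100):
            frame = _simulate_intervals(0.0, rng)
            fit = ev.fit_arr_time_model(frame).set_index("term")
            est, se = fit.loc["arr:time", ["beta", "se"]]
            covered += abs(est) <= 2 * se
        assert covered >= 93

    def test_recovers_negative_interaction(self):
        # generator truth -0.25 recovered in the mean over 200 replicates
        rng = np.random.default_rng(6)
        estimates = []
        for _ in range(200):
            frame = _simulate_intervals(-0.25, rng)
            fit = ev.fit_arr_time_model(frame).set_index("term")
            estimates.append(fit.loc["arr:time", "beta"])
        assert abs(np.mean(estimates) - (-0.25)) < 0.03

    def test_runs_on_generator_records(self, small_cohort):
        _, records = small_cohort
        table = ev.arr_time_association(records)
        assert set(table.term) == {"intercept", "arr", "time", "arr:time"}
        assert table.se.gt(0).all()
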