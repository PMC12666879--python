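import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from mstp import lmm
from mstp import synthetic as syn
from mstp import trajectories as tj
from tests.conftest import two_class_visits


def _dummy_model(K=2, pi=(0.5, 0.5), B=None, posterior=None, sigma_b=0.3, sigma_e=0.4):
    if B is None:
        B = np.array([[1.0, 0.0, 0.0], [5.0, 0.1, 0.0]])[:K]
    if posterior is None:
        posterior = pd.DataFrame(np.full((10, K), 1.0 / K))
    return tj.TrajectoryModel(
        K=K, pi=np.asarray(pi, float)[:K], B=np.asarray(B, float),
        sigma_b=sigma_b, sigma_e=sigma_e, loglik=-100.0,
        n_params=(K - 1) + 3 * K + 2, converged=True,
        posterior=posterior, cov_B=np.tile(np.eye(3) * 1e-4, (K, 1, 1)))


class TestFitBasics:
    def test_k1_reduces_to_single_mixed_model(self):
        visits, _ = two_class_visits(n_subjects=50, seed=1)
        model = tj.fit_latent_classes(visits, 1, n_starts=1, seed=0)
        assert np.allclose(model.posterior.to_numpy(), 1.0)
        t = visits["time_years"].to_numpy()
        X = np.column_stack([np.ones(len(t)), t, t**2])
        direct = lmm.fit_lmm(visits["edss"].to_numpy(), X,
                             visits["patient_id"].to_numpy())
        assert model.loglik == pytest.approx(direct.loglik, abs=1e-3)
        assert model.B[0] == pytest.approx(direct.beta, abs=1e-3)

    def test_invalid_k_rejected(self):
        visits, _ = two_class_visits(n_subjects=10, seed=2)
        with pytest.raises(ValueError):
            tj.fit_latent_classes(visits, 0)
        with pytest.raises(tj.FitError):
            tj.fit_latent_classes(visits, 11)

    def test_em_loglik_monotone(self):
        visits, _ = two_class_visits(n_subjects=80, seed=3)
        model = tj.fit_latent_classes(visits, 2, n_starts=2, seed=3)
        history = np.array(model.loglik_history)
        assert np.all(np.diff(history) >= -1e-8 * (1 + np.abs(history[:-1])))

    def test_two_class_recovery_against_complete_data_oracle(self):
        # oracle: maximum likelihood with the true labels known
        visits, labels = two_class_visits(n_subjects=200, seed=4)
        model = tj.fit_latent_classes(visits, 2, n_starts=3, seed=4)
        true_weights = np.bincount(labels) / len(labels)
        assert model.pi == pytest.approx(np.sort(true_weights), abs=0.05)
        ids = sorted(visits["patient_id"].unique())
        oracle_means = []
        for cls in (0, 1):
            members = [ids[i] for i in range(len(ids)) if labels[i] == cls]
            sub = visits[visits["patient_id"].isin(members)]
            oracle_means.append(sub["edss"].mean())
        fitted_intercepts = np.sort(model.B[:, 0])
        assert fitted_intercepts == pytest.approx(np.sort(oracle_means), abs=0.15)

    def test_posterior_rows_sum_to_one(self, small_model):
        sums = small_model.posterior.sum(axis=1).to_numpy()
        assert sums == pytest.approx(np.ones_like(sums), abs=1e-8)

    def test_canonical_ordering_by_mean_at_15(self, small_model):
        mean15 = small_model.class_mean(np.arange(small_model.K), 15.0) \
            if False else [small_model.class_mean(k, 15.0) for k in range(small_model.K)]
        assert list(mean15) == sorted(mean15)

    def test_label_permutation_leaves_loglik_unchanged(self, small_model, small_visits):
        visits, _ = small_visits
        gs = tj.stats_from_frame(visits)
        perm = np.array([2, 0, 3, 1])
        ll = logsumexp(tj._class_loglik_matrix(
            gs, small_model.B, small_model.sigma_b**2, small_model.sigma_e**2)
            + np.log(small_model.pi), axis=1).sum()
        ll_perm = logsumexp(tj._class_loglik_matrix(
            gs, small_model.B[perm], small_model.sigma_b**2, small_model.sigma_e**2)
            + np.log(small_model.pi[perm]), axis=1).sum()
        assert ll == pytest.approx(ll_perm, abs=1e-8)


class TestInformationCriteria:
    def test_aic_formula(self):
        model = _dummy_model(K=1, pi=(1.0,))
        model.n_params = 5
        model.loglik = -100.0
        out = tj.information_criteria(model, n_subjects=50)
        assert out.AIC == pytest.approx(210.0)

    def test_bic_formula(self):
        model = _dummy_model(K=1, pi=(1.0,))
        model.n_params = 5
        model.loglik = -100.0
        out = tj.information_criteria(model, n_subjects=100)
        assert out.BIC == pytest.approx(200 + 5 * np.log(100))
        assert out.SABIC == pytest.approx(200 + 5 * np.log(102 / 24))

    def test_icl_equals_loglik_for_hard_posteriors(self):
        posterior = pd.DataFrame(np.eye(2)[np.array([0, 1, 0, 1, 1])])
        model = _dummy_model(posterior=posterior)
        out = tj.information_criteria(model, n_subjects=5)
        assert out.ICL == pytest.approx(model.loglik)
        assert out.ICL_bic == pytest.approx(out.BIC)

    def test_aic_below_bic_for_moderate_n(self, small_model):
        out = tj.information_criteria(small_model)
        assert out.AIC < out.BIC

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tj.information_criteria(_dummy_model(), n_subjects=1)

    def test_criteria_monotone_in_params_for_fixed_loglik(self):
        rows = []
        for p in (3, 6, 9):
            model = _dummy_model(K=1, pi=(1.0,))
            model.n_params = p
            model.loglik = -500.0
            rows.append(tj.information_criteria(model, n_subjects=200))
        assert [r.AIC for r in rows] == sorted(r.AIC for r in rows)
        assert [r.BIC for r in rows] == sorted(r.BIC for r in rows)


class TestSelection:
    def test_single_class_generator_selects_one(self):
        visits, _ = two_class_visits(n_subjects=60, seed=5, weights=(1.0, 0.0))
        k_best, summaries, _ = tj.select_class_number(
            visits, range(1, 4), "BIC", n_starts=2, seed=5)
        assert k_best == 1

    def test_unknown_criterion_rejected(self):
        visits, _ = two_class_visits(n_subjects=20, seed=6)
        with pytest.raises(ValueError):
            tj.select_class_number(visits, [1], criterion="WAIC")

    def test_well_separated_two_classes_selected(self):
        visits, _ = two_class_visits(n_subjects=150, seed=7)
        k_best, _, models = tj.select_class_number(
            visits, range(1, 4), "BIC", n_starts=3, seed=7)
        assert k_best == 2


class TestCrossValidation:
    def test_leave_one_out_runs(self):
        visits, _ = two_class_visits(n_subjects=12, seed=8)
        out = tj.cross_validate(visits, K=1, folds=12, seed=0, n_starts=1)
        assert np.isfinite(out)

    def test_fold_assignment_deterministic(self):
        visits, _ = two_class_visits(n_subjects=40, seed=9)
        a = tj.cross_validate(visits, K=2, folds=4, seed=123, n_starts=1)
        b = tj.cross_validate(visits, K=2, folds=4, seed=123, n_starts=1)
        assert a == b

    def test_too_few_folds_rejected(self):
        visits, _ = two_class_visits(n_subjects=10, seed=10)
        with pytest.raises(ValueError):
            tj.cross_validate(visits, K=1, folds=1)

    def test_generating_k_beats_smaller_k(self):
        # held-out likelihood favours the generating class count
        wins = 0
        for rep in range(50):
            visits, _ = two_class_visits(n_subjects=80, seed=100 + rep)
            cv2 = tj.cross_validate(visits, K=2, folds=4, seed=rep, n_starts=1)
            cv1 = tj.cross_validate(visits, K=1, folds=4, seed=rep, n_starts=1)
            wins += cv2 > cv1
        assert wins >= 48


class TestPosteriorClassify:
    def test_class_mean_patient_confident(self):
        model = _dummy_model()
        times = np.arange(0, 8.0)
        edss = model.class_mean(1, times)
        out = tj.posterior_classify(model, times, edss)
        assert out.label == 1
        assert out.probabilities[1] > 0.99

    def test_k1_probability_one(self):
        model = _dummy_model(K=1, pi=(1.0,))
        out = tj.posterior_classify(model, [0.0, 1.0], [1.0, 1.0])
        assert out.probabilities == pytest.approx([1.0])

    def test_probabilities_normalized_on_random_input(self):
        model = _dummy_model()
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = np.sort(rng.uniform(0, 10, 5))
            edss = rng.uniform(0, 8, 5)
            out = tj.posterior_classify(model, times, edss)
            assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-8)

    def test_empty_visits_rejected(self):
        with pytest.raises(ValueError):
            tj.posterior_classify(_dummy_model(), [], [])

    def test_named_labels_used_when_available(self):
        model = _dummy_model()
        model.class_names = ["flat", "steep"]
        out = tj.posterior_classify(model, [0.0, 1.0], [5.0, 5.1])
        assert out.label == "steep"


class TestMeanTrajectory:
    def test_constant_class(self):
        model = _dummy_model(B=[[2.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        out = tj.mean_trajectory(model, 0, [0.0, 5.0, 10.0])
        assert out.mean_edss.tolist() == [2.0, 2.0, 2.0]

    def test_band_brackets_mean(self, small_model):
        out = tj.mean_trajectory(small_model, 2, np.linspace(0, 15, 31))
        assert (out.lower <= out.mean_edss + 1e-12).all()
        assert (out.mean_edss <= out.upper + 1e-12).all()
        assert (out.predictive_sd > 0).all()

    def test_extrapolation_flagged(self, small_model):
        with pytest.warns(UserWarning):
            out = tj.mean_trajectory(small_model, 0, [50.0])
        assert out.extrapolated.all()

    def test_bad_class_index_rejected(self, small_model):
        with pytest.raises(ValueError):
            tj.mean_trajectory(small_model, small_model.K, [1.0])

    def test_predictive_sd_combines_variances(self, small_model):
        expected = np.sqrt(small_model.sigma_b**2 + small_model.sigma_e**2)
        assert small_model.predictive_sd == pytest.approx(expected)


class TestNamingAndMatching:
    def test_onset_naming_default_fit(self, small_model):
        names = tj.name_classes_by_onset(small_model)
        assert sorted(names) == sorted(["minimal", "late", "early", "rapid"])

    def test_reference_matching_is_bijective(self, small_model):
        ref = {p.name: p.mean for p in syn.DEFAULT_PHENOTYPES}
        mapping = tj.match_classes_to_reference(small_model, ref)
        assert sorted(mapping.keys()) == list(range(4))
        assert sorted(mapping.values()) == sorted(ref)

    def test_serialization_roundtrip(self, small_model):
        restored = tj.TrajectoryModel.from_dict(small_model.to_dict())
        assert restored.K == small_model.K
        assert restored.B == pytest.approx(small_model.B)
        assert restored.pi == pytest.approx(small_model.pi)
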