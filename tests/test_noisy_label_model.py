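import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from intronfun import noisy_label_model as nlm, synthetic_data as sd


def params(w, w0=0.0, theta11=1.0):
    return nlm.ModelParams(w=np.asarray(w, float), w0=w0, theta11=theta11)


class TestProbFunctional:
    def test_symmetric_point(self):
        assert nlm.prob_functional([[0.0]], params([0.0]))[0] == 0.5

    def test_direct_evaluation(self):
        assert nlm.prob_functional([[2.0]], params([1.0]))[0] == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-9)

    def test_offset_enters_with_plus_sign(self):
        # p = sigmoid(w.x - w0): a large positive w0 suppresses p
        assert nlm.prob_functional([[0.0]], params([1.0], w0=5.0))[0] < 0.01
        assert nlm.prob_functional([[0.0]], params([1.0], w0=-5.0))[0] > 0.99

    def test_monotone_in_linear_predictor(self):
        x = np.linspace(-3, 3, 21).reshape(-1, 1)
        p = nlm.prob_functional(x, params([1.0]))
        assert (np.diff(p) > 0).all()

    def test_stable_for_extreme_arguments(self):
        p = nlm.prob_functional([[1e4], [-1e4]], params([1.0]))
        assert p[0] == 1.0 and p[1] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            nlm.prob_functional([[1.0, 2.0]], params([1.0]))


class TestObservedLogLikelihood:
    def test_noiseless_limit_is_standard_logistic(self, rng):
        x = rng.standard_normal((40, 2))
        z = rng.integers(0, 2, 40)
        pr = params([0.5, -1.0], w0=0.3, theta11=1.0)
        p = nlm.prob_functional(x, pr)
        expected = float(np.sum(z * np.log(p) + (1 - z) * np.log(1 - p)))
        data = nlm.TrainingSet(x=x, z=z)
        assert nlm.observed_log_likelihood(data, pr) == pytest.approx(expected, abs=1e-10)

    def test_hand_computed_three_point_sum(self):
        x = np.array([[1.0], [0.0], [-2.0]])
        z = np.array([1, 0, 0])
        pr = params([2.0], w0=0.5, theta11=0.4)
        p = 1 / (1 + np.exp(-(x[:, 0] * 2.0 - 0.5)))
        expected = np.log(0.4 * p[0]) + np.log(1 - 0.4 * p[1]) + np.log(1 - 0.4 * p[2])
        data = nlm.TrainingSet(x=x, z=z)
        assert nlm.observed_log_likelihood(data, pr) == pytest.approx(expected, abs=1e-12)

    def test_never_positive(self, rng):
        x = rng.standard_normal((30, 2))
        z = rng.integers(0, 2, 30)
        pr = params(rng.standard_normal(2), w0=0.1, theta11=0.7)
        assert nlm.observed_log_likelihood(nlm.TrainingSet(x=x, z=z), pr) <= 0.0

    def test_theta_zero_with_positives_is_neg_inf_not_crash(self):
        data = nlm.TrainingSet(x=[[1.0]], z=[1])
        assert nlm.observed_log_likelihood(data, params([1.0], theta11=0.0)) == -np.inf


class TestEStep:
    def test_positive_labels_force_certainty(self, rng):
        x = rng.standard_normal((10, 2))
        data = nlm.TrainingSet(x=x, z=np.ones(10, dtype=int))
        resp = nlm.e_step(data, params([1.0, -1.0], theta11=0.3))
        assert np.allclose(resp[:, 1], 1.0)

    def test_uninformative_labels_return_prior(self, rng):
        x = rng.standard_normal((10, 1))
        pr = params([2.0], theta11=0.0)
        data = nlm.TrainingSet(x=x, z=np.zeros(10, dtype=int))
        resp = nlm.e_step(data, pr)
        assert np.allclose(resp[:, 1], nlm.prob_functional(x, pr))

    def test_hand_evaluated_posterior(self):
        # p1 = 0.8, theta11 = 0.25, z = 0 -> c1 = 0.6/0.8 = 0.75
        w0 = -np.log(4.0)  # sigmoid(-w0) = 0.8 at x = 0
        pr = params([0.0], w0=w0, theta11=0.25)
        data = nlm.TrainingSet(x=[[0.0]], z=[0])
        resp = nlm.e_step(data, pr)
        assert resp[0, 1] == pytest.approx(0.75, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((15, 2))
        z = rng.integers(0, 2, 15)
        pr = params(rng.standard_normal(2), w0=float(rng.normal()),
                    theta11=float(rng.uniform(0.05, 1.0)))
        resp = nlm.e_step(nlm.TrainingSet(x=x, z=z), pr)
        assert np.allclose(resp.sum(axis=1), 1.0)

    def test_degenerate_theta_with_positives_raises(self):
        data = nlm.TrainingSet(x=[[1.0]], z=[1])
        with pytest.raises(nlm.DegenerateLabelsError):
            nlm.e_step(data, params([1.0], theta11=0.0))


class TestMStep:
    def test_theta_update_perfect_agreement(self, rng):
        x = rng.standard_normal((6, 1))
        z = np.array([1, 1, 1, 0, 0, 0])
        resp = np.column_stack([1.0 - z, z]).astype(float)
        out = nlm.m_step(nlm.TrainingSet(x=x, z=z), resp,
                         params([0.0]), nlm.EMConfig())
        assert out.theta11 == pytest.approx(1.0)

    def test_theta_update_hand_case(self, rng):
        x = rng.standard_normal((3, 1))
        z = np.array([1, 0, 0])
        c1 = np.array([1.0, 1.0, 0.5])
        resp = np.column_stack([1 - c1, c1])
        out = nlm.m_step(nlm.TrainingSet(x=x, z=z), resp,
                         params([0.0]), nlm.EMConfig())
        assert out.theta11 == pytest.approx(1 / 2.5, abs=1e-12)

    def test_weighted_objective_never_decreases(self, rng):
        x = rng.standard_normal((50, 2))
        z = rng.integers(0, 2, 50)
        c1 = rng.uniform(0, 1, 50)
        resp = np.column_stack([1 - c1, c1])
        data = nlm.TrainingSet(x=x, z=z)
        start = params([0.3, -0.2], w0=0.1)
        out = nlm.m_step(data, resp, start, nlm.EMConfig())
        design = np.column_stack([x, -np.ones(50)])
        l2_before = nlm._weighted_logistic_objective(
            np.append(start.w, start.w0), design, c1, np.ones(50))
        l2_after = nlm._weighted_logistic_objective(
            np.append(out.w, out.w0), design, c1, np.ones(50))
        assert l2_after >= l2_before - 1e-12

    def test_gradient_ascent_agrees_with_newton(self, rng):
        x = rng.standard_normal((80, 2))
        z = rng.integers(0, 2, 80)
        c1 = rng.uniform(0.1, 0.9, 80)
        resp = np.column_stack([1 - c1, c1])
        data = nlm.TrainingSet(x=x, z=z)
        newton = nlm.m_step(data, resp, params([0.0, 0.0]),
                            nlm.EMConfig(m_step_method="newton"))
        grad = nlm.m_step(data, resp, params([0.0, 0.0]),
                          nlm.EMConfig(m_step_method="gradient",
                                       learning_rate=0.05,
                                       m_step_max_iter=5000))
        assert np.allclose(newton.w, grad.w, atol=1e-3)


def direct_mle(x, z, n_starts=8, seed=0):
    """Independent oracle: maximize the observed likelihood numerically."""
    data = nlm.TrainingSet(x=x, z=z)

    def neg(theta_vec):
        pr = nlm.ModelParams(w=theta_vec[:-2], w0=theta_vec[-2],
                             theta11=float(expit(theta_vec[-1])))
        return -nlm.observed_log_likelihood(data, pr)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = np.append(rng.normal(0, 1, x.shape[1] + 1), rng.normal(0, 2))
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


class TestFitEM:
    def test_trajectory_monotone_everywhere(self):
        for seed in range(3):
            cfg = sd.SimConfig(theta11=0.3, seed=seed, logistic_w=(2.0, -1.0))
            x, y, z, _ = sd.simulate_features(cfg, n=300)
            res = nlm.fit_em(nlm.TrainingSet(x=x, z=z),
                             nlm.EMConfig(n_restarts=3, seed=seed))
            diffs = np.diff(res.trajectory)
            assert (diffs >= -1e-8).all()

    def test_matches_direct_numerical_maximization(self):
        cfg = sd.SimConfig(theta11=0.5, seed=4, logistic_w=(1.5, -1.0))
        x, y, z, _ = sd.simulate_features(cfg, n=150)
        res = nlm.fit_em(nlm.TrainingSet(x=x, z=z),
                         nlm.EMConfig(n_restarts=10, seed=0))
        oracle = direct_mle(x, z)
        assert res.log_likelihood == pytest.approx(oracle, abs=1e-3)

    def test_noiseless_separated_data_reduces_to_logistic(self):
        rng = np.random.default_rng(8)
        n = 400
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(0, 1, (n, 2)) + np.where(y[:, None] == 1, 2.0, -2.0)
        data = nlm.TrainingSet(x=x, z=y)
        res = nlm.fit_em(data, nlm.EMConfig(n_restarts=5, seed=0))
        assert res.params.theta11 > 0.99
        lr = LogisticRegression(C=np.inf, max_iter=10000, tol=1e-10).fit(x, y)
        p_ref = lr.predict_proba(x)[:, 1]
        p_fit = nlm.prob_functional(x, res.params)
        assert np.max(np.abs(p_fit - p_ref)) < 1e-4

    def test_theta_recovery_on_synthetic_data(self):
        cfg = sd.SimConfig(theta11=0.2, seed=3, logistic_w=(3.0, 3.0))
        x, y, z, _ = sd.simulate_features(cfg, n=5000)
        res = nlm.fit_em(nlm.TrainingSet(x=x, z=z),
                         nlm.EMConfig(n_restarts=3, seed=1, tol=1e-7))
        assert res.params.theta11 == pytest.approx(0.2, abs=0.05)

    def test_restart_stability_on_separated_data(self):
        cfg = sd.SimConfig(theta11=0.4, seed=5, logistic_w=(3.0, 3.0))
        x, y, z, _ = sd.simulate_features(cfg, n=2000)
        res = nlm.fit_em(nlm.TrainingSet(x=x, z=z, feature_names=["a", "b"]),
                         nlm.EMConfig(n_restarts=100, seed=2, tol=1e-7))
        cv = res.restart_summary.loc["theta11", "cv"]
        assert abs(cv) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both label values"):
            nlm.fit_em(nlm.TrainingSet(x=[[1.0], [2.0]], z=[0, 0]))


class TestClassify:
    def test_noiseless_reduces_to_thresholding(self):
        x = np.array([[3.0], [-3.0]])
        pr = params([1.0], theta11=1.0)
        assert nlm.classify(x, pr, 0.5).tolist() == [1, 0]

    def test_theta_below_threshold_blocks_all(self, rng):
        x = rng.standard_normal((20, 1)) * 5
        pr = params([1.0], theta11=0.4)
        assert nlm.classify(x, pr, 0.5).sum() == 0

    def test_tie_is_non_functional(self):
        pr = params([1.0], theta11=1.0)
        assert nlm.classify(np.array([[0.0]]), pr, 0.5)[0] == 0

    def test_true_label_flag_uses_hidden_probability(self, rng):
        x = np.array([[4.0]])
        pr = params([1.0], theta11=0.2)
        assert nlm.classify(x, pr, 0.5)[0] == 0
        assert nlm.classify(x, pr, 0.5, on_true_label=True)[0] == 1


class TestEstimateP10:
    def test_complete_labels_mean_no_hidden_function(self, rng):
        x = rng.standard_normal((10, 1))
        data = nlm.TrainingSet(x=x, z=np.zeros(10, dtype=int))
        assert nlm.estimate_p10(data, params([1.0], theta11=1.0)) == 0.0

    def test_uninformative_labels_average_the_prior(self, rng):
        x = rng.standard_normal((200, 1))
        pr = params([1.5], theta11=0.0)
        data = nlm.TrainingSet(x=x, z=np.zeros(200, dtype=int))
        assert nlm.estimate_p10(data, pr) == pytest.approx(
            float(nlm.prob_functional(x, pr).mean()), abs=1e-12)

    def test_hand_case_matches_e_step_example(self):
        w0 = -np.log(4.0)
        pr = params([0.0], w0=w0, theta11=0.25)
        data = nlm.TrainingSet(x=[[0.0]], z=[0])
        assert nlm.estimate_p10(data, pr) == pytest.approx(0.75, abs=1e-12)

    def test_requires_negative_labels(self):
        data = nlm.TrainingSet(x=[[1.0]], z=[1])
        with pytest.raises(ValueError, match="z = 0"):
            nlm.estimate_p10(data, params([1.0], theta11=0.5))


class TestModelIO:
    def test_save_load_round_trip(self, tmp_path):
        pr = params([0.5, -2.0], w0=1.2, theta11=0.3)
        summary = pd.DataFrame({"mean": [0.1], "std": [0.01], "cv": [0.1]},
                               index=["theta11"])
        path = tmp_path / "model.json"
        nlm.save_model(path, pr, feature_names=["a", "b"], threshold=0.5,
                       restart_summary=summary)
        loaded = nlm.load_model(path)
        assert np.allclose(loaded["params"].w, pr.w)
        assert loaded["params"].theta11 == pr.theta11
        assert loaded["feature_names"] == ["a", "b"]
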