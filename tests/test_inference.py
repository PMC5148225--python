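"""Online mean-field filter, explaining away, and the exact oracle."""

import numpy as np
import pytest

from predecode import (
    GenerativeParams,
    InferenceConfig,
    ReceptorObservations,
    evidence_log_ratio,
    exact_filter_oracle,
    firing_rate,
    inference_step,
    predicted_input,
    prior_log_odds,
    run_inference,
    run_no_inhibition,
    sample_features,
    sample_observations,
    stationary_on_probability,
)
from predecode.synthetic import make_spectrogram


class TestPriorLogOdds:
    def test_symmetric_chain_is_neutral(self):
        assert prior_log_odds(0.5, 0.3, 0.3) == pytest.approx(0.0)

    def test_certain_on_state(self):
        # only the on-row of the transition survives
        r = 0.2
        assert prior_log_odds(1.0, 0.07, r) == pytest.approx(np.log((1 - r) / r))

    def test_direct_evaluation(self):
        # p(1-r_off) + (1-p)r_on = 0.8*0.8 + 0.2*0.01 = 0.642
        # p r_off + (1-p)(1-r_on) = 0.8*0.2 + 0.2*0.99 = 0.358
        assert prior_log_odds(0.8, 0.01, 0.2) == pytest.approx(
            np.log(0.642 / 0.358), abs=1e-10
        )

    def test_finite_at_extremes(self):
        assert np.isfinite(prior_log_odds(0.0, 0.0, 1.0))
        assert np.isfinite(prior_log_odds(1.0, 1.0, 0.0))

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            prior_log_odds(1.2, 0.1, 0.1)


class TestPredictedInput:
    def test_all_zero_posteriors_leave_baseline(self):
        Q = np.array([[1.0, 2.0], [0.5, 0.0]])
        q0 = np.array([0.1, 0.3])
        np.testing.assert_allclose(predicted_input(Q, q0, np.zeros(2), 0), q0)

    def test_single_feature_sees_only_baseline(self):
        Q = np.array([[3.0]])
        np.testing.assert_allclose(
            predicted_input(Q, np.array([0.2]), np.array([0.9]), 0), [0.2]
        )

    def test_direct_evaluation(self):
        Q = np.array([[1.0, 2.0]])
        out = predicted_input(Q, np.array([0.1]), np.array([0.5, 0.5]), 0)
        assert out == pytest.approx([0.1 + 2 * 0.5])


class TestEvidenceLogRatio:
    def test_zero_stimulus(self):
        Q = np.array([[0.5], [0.7]])
        q0 = np.array([0.1, 0.1])
        for exact in (True, False):
            cfg = InferenceConfig(use_log1p_exact=exact)
            out = evidence_log_ratio(np.zeros(2), Q, q0, np.array([0.0]), 0, cfg)
            assert out == pytest.approx(-1.2)

    def test_zero_weight_column_is_silent(self):
        Q = np.array([[0.0, 1.0], [0.0, 2.0]])
        out = evidence_log_ratio(
            np.array([3.0, 1.0]), Q, np.array([0.5, 0.5]), np.array([0.5, 0.5]), 0
        )
        assert out == pytest.approx(0.0)

    def test_exact_vs_linearized_forms(self):
        Q = np.array([[0.5]])
        q0 = np.array([1.0])
        p = np.array([0.0])
        s = np.array([3.0])
        exact = evidence_log_ratio(s, Q, q0, p, 0, InferenceConfig())
        linear = evidence_log_ratio(
            s, Q, q0, p, 0, InferenceConfig(use_log1p_exact=False)
        )
        assert exact == pytest.approx(3 * np.log(1.5) - 0.5)
        assert linear == pytest.approx(1.0)


class TestFiringRate:
    def test_perfect_prediction_cancels_input(self):
        """When other detectors fully predict the input, the drive is zero."""
        Q = np.array([[1.0, 1.0], [0.5, 0.5]])
        q0 = np.array([0.1, 0.1])
        p = np.array([0.0, 0.8])
        shat = predicted_input(Q, q0, p, 0)
        assert firing_rate(shat, Q, q0, p, 0) == pytest.approx(0.0, abs=1e-12)

    def test_rectified_log_lik_equals_divisive_form(self):
        """The two published firing-rate forms are algebraically identical."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            M, N = rng.integers(1, 6), rng.integers(1, 5)
            Q = rng.uniform(0, 2, (M, N))
            q0 = rng.uniform(0.05, 1, M)
            p = rng.uniform(0, 1, N)
            s = rng.uniform(0, 5, M)
            j = int(rng.integers(N))
            shat = predicted_input(Q, q0, p, j)
            fd6 = max(np.sum(s * Q[:, j] / shat - Q[:, j]), 0.0)
            fd7 = max(np.sum(Q[:, j] * (s / shat - 1.0)), 0.0)
            assert firing_rate(s, Q, q0, p, j) == pytest.approx(fd6)
            assert fd6 == pytest.approx(fd7)

    def test_surplus_along_own_field_drives_response(self):
        Q = np.array([[1.0]])
        q0 = np.array([0.1])
        assert firing_rate(np.array([5.0]), Q, q0, np.array([0.0]), 0) > 0


class TestInferenceStep:
    def test_prior_fixed_point_without_evidence(self):
        """With no informative input, L converges to the stationary log-odds."""
        par = GenerativeParams(
            Q=np.zeros((2, 3)), q0=np.full(2, 0.5), r_on=1.0, r_off=20.0
        )
        pi = stationary_on_probability(par.r_on_bin, par.r_off_bin)
        L = np.zeros(3)
        for _ in range(300):
            L, p, f = inference_step(L, np.full(2, 0.5), par)
        np.testing.assert_allclose(L, np.log(pi / (1 - pi)), atol=1e-9)

    def test_logistic_consistency(self, small_params):
        L = np.array([0.3, -1.2])
        L_new, p, _ = inference_step(L, np.array([1.0, 0.0, 2.0]), small_params)
        np.testing.assert_allclose(p, 1 / (1 + np.exp(-L_new)))

    def test_rejects_nonfinite_state(self, small_params):
        with pytest.raises(ValueError):
            inference_step(np.array([np.inf, 0.0]), np.zeros(3), small_params)


class TestRunInference:
    def test_empty_trace(self, small_params):
        obs = ReceptorObservations(S=np.zeros((3, 0)))
        trace = run_inference(obs, small_params)
        assert trace.L.shape == (2, 0)

    def test_deterministic(self, small_params):
        traj = sample_features(small_params, 2, 100, seed=0)
        obs = sample_observations(small_params, traj, seed=1)
        a = run_inference(obs, small_params)
        b = run_inference(obs, small_params)
        assert np.array_equal(a.F, b.F)

    def test_posterior_tracks_true_feature_state(self, disjoint_fixture):
        """Mean posterior is higher when the feature is actually on."""
        spec, Q = disjoint_fixture
        par = spec.params(Q)
        traj = sample_features(par, 5, 5000, seed=2)
        obs = sample_observations(par, traj, seed=3)
        trace = run_inference(obs, par)
        for j in range(5):
            on = traj.X[j].astype(bool)
            assert trace.P[j, on].mean() > trace.P[j, ~on].mean()


class TestNoInhibition:
    def test_single_feature_matches_intact(self, disjoint_fixture):
        spec, Q = disjoint_fixture
        par = GenerativeParams(Q=Q[:, :1], q0=np.full(30, spec.baseline))
        traj = sample_features(par, 1, 400, seed=4)
        obs = sample_observations(par, traj, seed=5)
        np.testing.assert_allclose(
            run_inference(obs, par).P, run_no_inhibition(obs, par).P
        )

    def test_identical_fields_respond_identically(self):
        """Without competition, twin detectors cannot break symmetry."""
        q = np.array([2.0, 1.0, 0.0])
        par = GenerativeParams(Q=np.column_stack([q, q]), q0=np.full(3, 0.1))
        obs = ReceptorObservations(S=np.tile(q[:, None], (1, 50)))
        trace = run_no_inhibition(obs, par)
        np.testing.assert_allclose(trace.F[0], trace.F[1])

    def test_explaining_away_only_removes_drive(self, overlapping_fixture):
        """Summed rates without inhibition bound the intact model's."""
        spec, Q = overlapping_fixture
        par = spec.params(Q)
        traj = sample_features(par, 5, 2000, seed=6)
        obs = sample_observations(par, traj, seed=7)
        f_intact = run_inference(obs, par).F.sum()
        f_noinh = run_no_inhibition(obs, par).F.sum()
        assert f_noinh >= f_intact

    def test_competitor_suppressed_only_with_inhibition(self, overlapping_fixture):
        """A detector whose feature is absent fires less when inhibited."""
        spec, Q = overlapping_fixture
        par = spec.params(Q)
        X = np.zeros((5, 2000), dtype=int)
        X[1] = 1  # only feature 1 present
        from predecode import FeatureTrajectory

        obs = sample_observations(par, FeatureTrajectory(X=X), seed=8)
        f_intact = run_inference(obs, par).F
        f_noinh = run_no_inhibition(obs, par).F
        assert f_intact[2].mean() < f_noinh[2].mean()


class TestExactOracle:
    def test_refuses_large_networks(self):
        par = GenerativeParams(Q=np.ones((2, 13)), q0=np.full(2, 0.1))
        obs = ReceptorObservations(S=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            exact_filter_oracle(obs, par)

    def test_uninformative_emission_follows_prior(self):
        par = GenerativeParams(
            Q=np.zeros((2, 2)), q0=np.full(2, 0.5), r_on=1.0, r_off=20.0
        )
        obs = ReceptorObservations(S=np.ones((2, 50)))
        marg = exact_filter_oracle(obs, par)
        pi = stationary_on_probability(par.r_on_bin, par.r_off_bin)
        np.testing.assert_allclose(marg, pi, atol=1e-12)

    def test_disjoint_marginals_factorize(self):
        """Two non-interacting features filter as two independent chains."""
        Q = np.array([[2.0, 0.0], [0.0, 1.5]])
        par = GenerativeParams(Q=Q, q0=np.full(2, 0.1))
        traj = sample_features(par, 2, 200, seed=9)
        obs = sample_observations(par, traj, seed=10)
        joint = exact_filter_oracle(obs, par)
        for j in range(2):
            par1 = GenerativeParams(Q=Q[:, j : j + 1], q0=par.q0)
            single = exact_filter_oracle(obs, par1)
            np.testing.assert_allclose(joint[j], single[0], atol=1e-10)

    def test_mean_field_kl_to_exact_is_finite_with_overlap(self):
        """Overlapping fields: mean-field is approximate but well-behaved."""
        rng = np.random.default_rng(11)
        Q = rng.uniform(0, 1.5, (6, 3))
        par = GenerativeParams(Q=Q, q0=np.full(6, 0.2))
        traj = sample_features(par, 3, 300, seed=12)
        obs = sample_observations(par, traj, seed=13)
        p_mf = np.clip(run_inference(obs, par).P, 1e-12, 1 - 1e-12)
        p_ex = np.clip(exact_filter_oracle(obs, par), 1e-12, 1 - 1e-12)
        kl = p_ex * np.log(p_ex / p_mf) + (1 - p_ex) * np.log(
            (1 - p_ex) / (1 - p_mf)
        )
        assert np.isfinite(kl.mean())
        assert kl.mean() < 1.0  # regression guard, not a derived bound
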