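"""Sticky AR-HMM priors, Gibbs conditionals, staged inference and features."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imukit import arhmm, synthetic
from imukit.errors import InvalidConfigError, InvalidSizeError

from conftest import make_three_state_model


class TestPrior:
    def test_beta_mean(self):
        rng = np.random.default_rng(0)
        hyper = arhmm.ARHMMHyperParams()
        betas = np.array([arhmm.sample_prior(hyper, rng)[0].beta for _ in range(10_000)])
        assert np.abs(betas.mean(axis=0) - 0.2).max() < 0.01

    def test_self_transition_mean(self):
        """E[pi_ii] = (alpha/L + kappa) / (alpha + kappa) = 0.6 at the defaults."""
        rng = np.random.default_rng(1)
        hyper = arhmm.ARHMMHyperParams()
        diags = np.array(
            [np.diag(arhmm.sample_prior(hyper, rng)[0].pi) for _ in range(10_000)]
        )
        assert diags.mean() == pytest.approx(0.6, abs=0.01)

    def test_sigma_positive_definite(self):
        rng = np.random.default_rng(2)
        hyper = arhmm.ARHMMHyperParams()
        for _ in range(50):
            _, dyn = arhmm.sample_prior(hyper, rng)
            for k in range(hyper.L):
                assert np.linalg.eigvalsh(dyn.Sigma[k]).min() > 0


class TestPriorPredictive:
    def test_median_run_length(self):
        """Pooled median run length at the default hyperparameters is two
        12.8 Hz steps = 156.25 ms."""
        stats = arhmm.sample_prior_predictive(n_draws=1000, seed=5)
        assert stats["median_ms"] == pytest.approx(156.25, abs=30)

    def test_total_stickiness_limit(self):
        hyper = arhmm.ARHMMHyperParams(kappa=1e6)
        stats = arhmm.sample_prior_predictive(hyper, n_draws=100, seed=6)
        assert stats["median_ms"] == pytest.approx(384 * 1000 / 12.8)

    def test_no_stickiness_shortens_runs(self):
        sticky = arhmm.sample_prior_predictive(n_draws=300, seed=7)
        loose = arhmm.sample_prior_predictive(
            arhmm.ARHMMHyperParams(kappa=0.0), n_draws=300, seed=7
        )
        assert loose["median_ms"] < sticky["median_ms"]


class TestSampleStates:
    def test_single_state(self):
        hyper = arhmm.ARHMMHyperParams(L=1, n_lags=1)
        dyn = arhmm.ARDynamics(np.zeros((1, 2, 2)), np.array([np.eye(2)]))
        trans = arhmm.TransitionModel(np.ones((1, 1)), np.ones(1))
        y = np.random.default_rng(0).normal(size=(50, 2))
        assert np.all(arhmm.sample_states(y, dyn, trans, seed=1) == 1)

    def test_absorbing_chain_constant(self):
        model = make_three_state_model()
        y, _ = synthetic.generate_from_arhmm(model, 200, seed=2)
        trans = arhmm.TransitionModel(np.eye(3), np.full(3, 1 / 3))
        states = arhmm.sample_states(y, model.dynamics, trans, seed=3)
        assert np.all(states == states[0])

    def test_disjoint_dynamics_recovered(self):
        """Fast vs slow oscillator with 10x noise-scale ratio: per-draw state
        accuracy >= 95% after label matching."""
        hyper = arhmm.ARHMMHyperParams(L=2, n_lags=1)
        A = np.stack([0.95 * np.eye(2), -0.95 * np.eye(2)])
        Sigma = np.stack([0.01 * np.eye(2), 1.0 * np.eye(2)])
        pi = np.array([[0.97, 0.03], [0.03, 0.97]])
        model = arhmm.ARHMMModel(
            hyper, arhmm.TransitionModel(pi, np.full(2, 0.5)), arhmm.ARDynamics(A, Sigma)
        )
        y, truth = synthetic.generate_from_arhmm(model, 2000, seed=4)
        draw = arhmm.sample_states(y, model.dynamics, model.trans, seed=5)
        acc = max(
            (np.asarray([p[s - 1] for s in draw]) == truth).mean()
            for p in itertools.permutations((1, 2))
        )
        assert acc >= 0.95


class TestTransitionPosterior:
    def test_no_data_matches_prior_mean(self):
        rng = np.random.default_rng(0)
        hyper = arhmm.ARHMMHyperParams()
        diags = [
            np.diag(
                arhmm.sample_transition_posterior(
                    np.array([], dtype=int), hyper, np.full(5, 0.2), rng
                ).pi
            )
            for _ in range(4000)
        ]
        assert np.mean(diags) == pytest.approx(0.6, abs=0.015)

    def test_dominant_count_forces_self_transition(self):
        rng = np.random.default_rng(1)
        states = np.ones(1_000_00 * 10 + 1, dtype=int)  # c_11 = 10^6
        hyper = arhmm.ARHMMHyperParams()
        draws = [
            arhmm.sample_transition_posterior(states, hyper, np.full(5, 0.2), rng).pi[0, 0]
            for _ in range(50)
        ]
        assert np.mean(draws) == pytest.approx(1.0, abs=1e-3)

    def test_posterior_mean_is_dirichlet_mean(self):
        """Given the resampled betas, rows are Dirichlet with mean
        (alpha*beta + kappa*delta_i + c_i) / (alpha + kappa + sum c_i)."""
        rng = np.random.default_rng(2)
        hyper = arhmm.ARHMMHyperParams(L=3)
        chain = np.random.default_rng(3).integers(1, 4, size=200)
        counts = np.zeros((3, 3))
        np.add.at(counts, (chain[:-1] - 1, chain[1:] - 1), 1.0)
        pis, betas = [], []
        for _ in range(10_000):
            tm = arhmm.sample_transition_posterior(chain, hyper, np.full(3, 1 / 3), rng)
            pis.append(tm.pi)
            betas.append(tm.beta)
        pi_mean = np.mean(pis, axis=0)
        beta_mean = np.mean(betas, axis=0)
        for i in range(3):
            expected = hyper.alpha * beta_mean + hyper.kappa * np.eye(3)[i] + counts[i]
            expected /= hyper.alpha + hyper.kappa + counts[i].sum()
            assert np.abs(pi_mean[i] - expected).max() < 0.01


class TestDynamicsPosterior:
    def test_no_data_matches_prior_moments(self):
        rng = np.random.default_rng(0)
        hyper = arhmm.ARHMMHyperParams(L=1, n_lags=1)
        y = np.zeros((2, 2))
        states = np.zeros(2, dtype=int)  # no time point assigned to state 1
        As, Sigmas = [], []
        for _ in range(5000):
            dyn = arhmm.sample_dynamics_posterior(y, states, hyper, rng)
            As.append(dyn.A[0])
            Sigmas.append(dyn.Sigma[0])
        assert np.abs(np.mean(As, axis=0) - 0.25).max() < 0.02
        # E[Sigma] = S0 / (nu0 - p - 1) = 0.005 I
        assert np.abs(np.mean(Sigmas, axis=0) - 0.005 * np.eye(2)).max() < 0.001

    def test_matches_ols_on_large_sample(self):
        """Weakly informed posterior mean of A matches ordinary least squares,
        and Sigma matches the OLS residual covariance, at 50k points."""
        hyper = arhmm.ARHMMHyperParams(L=1, n_lags=5)
        rng = np.random.default_rng(2)
        A_true = rng.uniform(-0.3, 0.3, (1, 2, 10))
        Sigma_true = np.array([[[0.5, 0.1], [0.1, 0.4]]])
        model = arhmm.ARHMMModel(
            hyper,
            arhmm.TransitionModel(np.ones((1, 1)), np.ones(1)),
            arhmm.ARDynamics(A_true, Sigma_true),
        )
        y, states = synthetic.generate_from_arhmm(model, 50_000, seed=3)
        draws = [arhmm.sample_dynamics_posterior(y, states, hyper, seed=s) for s in range(20)]
        A_post = np.mean([d.A[0] for d in draws], axis=0)
        Sigma_post = np.mean([d.Sigma[0] for d in draws], axis=0)

        X = np.zeros((50_000, 10))
        for lag in range(1, 6):
            X[5:, (lag - 1) * 2 : lag * 2] = y[5 - lag : 50_000 - lag]
        A_ols, res, *_ = np.linalg.lstsq(X[5:], y[5:], rcond=None)
        resid = y[5:] - X[5:] @ A_ols
        Sigma_ols = resid.T @ resid / (len(resid) - 10)
        assert np.abs(A_post - A_ols.T).max() < 0.02
        assert np.abs(Sigma_post / Sigma_ols - 1).max() < 0.10


class TestStagedInference:
    def test_stage1_recovers_dynamics(self, three_state_data, three_state_stage1):
        """Known 3-state model: posterior-mean A within 0.1 of truth after
        the best state permutation."""
        model, _, _ = three_state_data
        res = three_state_stage1
        best = min(
            np.abs(res.dynamics.A[list(p)] - model.dynamics.A).max()
            for p in itertools.permutations(range(3))
        )
        assert best < 0.1

    def test_stage1_deterministic(self):
        rng_data = np.random.default_rng(0)
        y = rng_data.normal(size=(120, 2))
        hyper = arhmm.ARHMMHyperParams(L=2, n_lags=1)
        r1 = arhmm.fit_stage1([y], hyper, n_iter=30, burn=5, truncate_at=30, seed=9)
        r2 = arhmm.fit_stage1([y], hyper, n_iter=30, burn=5, truncate_at=30, seed=9)
        assert np.array_equal(r1.beta_trace, r2.beta_trace)
        assert np.array_equal(r1.dynamics.A, r2.dynamics.A)

    def test_stage1_trace_length(self):
        y = np.random.default_rng(1).normal(size=(80, 2))
        hyper = arhmm.ARHMMHyperParams(L=2, n_lags=1)
        res = arhmm.fit_stage1([y], hyper, n_iter=50, burn=10, truncate_at=40, seed=2)
        assert res.beta_trace.shape == (30, 2)

    def test_stage1_requires_iterations(self):
        with pytest.raises(InvalidConfigError):
            arhmm.fit_stage1([np.zeros((50, 2))], n_iter=10, burn=10, seed=0)

    def test_stage2_retains_150_draws(self, three_state_data, three_state_stage1):
        _, y, _ = three_state_data
        inf = arhmm.fit_stage2(
            y, three_state_stage1.dynamics, three_state_stage1.trans,
            three_state_stage1.hyper, seed=5,
        )
        assert inf.samples.shape == (150, len(y))
        assert len(inf.modes) == len(y)

    def test_stage2_mode_accuracy(self, three_state_data, three_state_stage1):
        """State modes recover the generating sequence at >= 90% after the
        best label permutation."""
        model, y, truth = three_state_data
        inf = arhmm.fit_stage2(
            y, three_state_stage1.dynamics, three_state_stage1.trans,
            three_state_stage1.hyper, seed=6,
        )
        acc = max(
            (np.asarray([p[m - 1] for m in inf.modes]) == truth).mean()
            for p in itertools.permutations((1, 2, 3))
        )
        assert acc >= 0.90

    def test_stage2_single_state_data(self, three_state_stage1):
        """Data generated from one state's dynamics concentrates the modes."""
        model = make_three_state_model()
        # simulate from state 1 only
        one = arhmm.ARHMMModel(
            arhmm.ARHMMHyperParams(L=1, n_lags=1),
            arhmm.TransitionModel(np.ones((1, 1)), np.ones(1)),
            arhmm.ARDynamics(model.dynamics.A[:1], model.dynamics.Sigma[:1]),
        )
        y, _ = synthetic.generate_from_arhmm(one, 800, seed=8)
        inf = arhmm.fit_stage2(
            y, model.dynamics, model.trans, model.hyper, seed=9
        )
        feats = arhmm.compute_arhmm_features(inf)
        assert max(feats[f"freq_{k}"] for k in (1, 2, 3)) >= 0.9

    def test_geweke_prior_gibbs_agreement(self):
        """Geweke-style joint validity: the successive-conditional Gibbs chain
        (data resimulated each sweep) matches prior moments of pi_ii and A."""
        hyper = arhmm.ARHMMHyperParams(L=2, n_lags=1)
        rng = np.random.default_rng(0)
        prior_pi, prior_A = [], []
        for _ in range(3000):
            tr, dy = arhmm.sample_prior(hyper, rng)
            prior_pi.append(np.diag(tr.pi).mean())
            prior_A.append(dy.A.mean())

        rng2 = np.random.default_rng(1)
        tr, dy = arhmm.sample_prior(hyper, rng2)
        gibbs_pi, gibbs_A = [], []
        for _ in range(3000):
            model = arhmm.ARHMMModel(hyper, tr, dy)
            y, _ = synthetic.generate_from_arhmm(model, 50, seed=rng2)
            states = arhmm.sample_states(y, dy, tr, rng2)
            tr = arhmm.sample_transition_posterior(states, hyper, tr.beta, rng2)
            dy = arhmm.sample_dynamics_posterior(y, states, hyper, rng2)
            gibbs_pi.append(np.diag(tr.pi).mean())
            gibbs_A.append(dy.A.mean())
        gibbs_pi, gibbs_A = gibbs_pi[500:], gibbs_A[500:]

        assert np.mean(gibbs_pi) == pytest.approx(np.mean(prior_pi), abs=0.02)
        assert np.mean(gibbs_pi) == pytest.approx(0.75, abs=0.02)  # analytic
        assert np.mean(gibbs_A) == pytest.approx(np.mean(prior_A), abs=0.01)


class TestEntropyRate:
    def test_identity_chain(self):
        assert arhmm.entropy_rate(np.eye(3), fallback_dist=np.ones(3)) == 0.0

    def test_uniform_two_state(self):
        assert arhmm.entropy_rate(np.full((2, 2), 0.5)) == pytest.approx(1.0)

    def test_sticky_two_state(self):
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert arhmm.entropy_rate(P) == pytest.approx(0.4690, abs=5e-4)

    def test_non_stochastic_rejected(self):
        with pytest.raises(InvalidConfigError):
            arhmm.entropy_rate(np.array([[0.5, 0.2], [0.5, 0.5]]))


class TestRunLengths:
    def test_hand_example(self):
        mean, sd = arhmm.run_length_stats(np.array([1, 1, 2, 2, 2, 1]), 1)
        assert (mean, sd) == (1.5, 0.5)

    def test_absent_state(self):
        assert arhmm.run_length_stats(np.array([1, 1, 2, 2, 2, 1]), 3) == (0.0, 0.0)

    def test_single_run(self):
        assert arhmm.run_length_stats(np.full(7, 4), 4) == (7.0, 0.0)

    @given(st.lists(st.integers(min_value=1, max_value=3), min_size=1, max_size=30))
    def test_matches_brute_force(self, modes):
        """Run statistics agree with direct enumeration of maximal blocks."""
        modes = np.array(modes)
        for state in (1, 2, 3):
            runs, current = [], 0
            for m in list(modes) + [None]:
                if m == state:
                    current += 1
                elif current:
                    runs.append(current)
                    current = 0
            mean, sd = arhmm.run_length_stats(modes, state)
            if runs:
                assert mean == pytest.approx(np.mean(runs))
                assert sd == pytest.approx(np.std(runs))
            else:
                assert (mean, sd) == (0.0, 0.0)


class TestFeatures:
    def test_hand_example_modes_and_concentration(self):
        samples = np.array([[1, 1, 2], [1, 2, 2]])
        inf = arhmm.StateInference(
            samples=samples,
            modes=np.array([1, 1, 2]),
            pi_posterior_mean=np.full((2, 2), 0.5),
        )
        feats = arhmm.compute_arhmm_features(inf)
        assert feats["overall_mode_prop"] == pytest.approx(5 / 6)
        assert feats["mode_conc_1"] == pytest.approx(0.75)
        assert feats["mode_conc_2"] == pytest.approx(1.0)
        # tie at t=1 resolved toward the lowest state index
        counts = np.stack([(samples == k + 1).sum(axis=0) for k in range(2)])
        assert counts[0, 1] == counts[1, 1]

    def test_frequencies_partition_time(self, three_state_data, three_state_stage1):
        _, y, _ = three_state_data
        inf = arhmm.fit_stage2(
            y, three_state_stage1.dynamics, three_state_stage1.trans,
            three_state_stage1.hyper, seed=3,
        )
        feats = arhmm.compute_arhmm_features(inf)
        assert sum(feats[f"freq_{k}"] for k in (1, 2, 3)) == pytest.approx(1.0)
        assert all(0 <= feats[f"self_trans_{k}"] <= 1 for k in (1, 2, 3))

    def test_identical_draws_fully_concentrated(self):
        samples = np.tile(np.array([1, 2, 2, 1]), (10, 1))
        inf = arhmm.StateInference(
            samples=samples,
            modes=np.array([1, 2, 2, 1]),
            pi_posterior_mean=np.full((2, 2), 0.5),
        )
        feats = arhmm.compute_arhmm_features(inf)
        assert feats["overall_mode_prop"] == 1.0
        assert feats["mode_conc_1"] == 1.0 and feats["mode_conc_2"] == 1.0


class TestFeatureTable:
    def test_schema(self):
        cols = arhmm.arhmm_feature_columns()
        assert len(cols) == 162 and len(set(cols)) == 162
        per_block = [c for c in cols if c.startswith("fnf_right_")]
        assert len(per_block) == 27
        assert cols == arhmm.arhmm_feature_columns()

    def test_serialization_roundtrip(self, three_state_stage1, tmp_path):
        path = tmp_path / "model.json"
        arhmm.stage1_to_json(three_state_stage1, path)
        loaded = arhmm.stage1_from_json(path)
        assert np.allclose(loaded.dynamics.A, three_state_stage1.dynamics.A)
        assert np.allclose(loaded.trans.pi, three_state_stage1.trans.pi)
        assert loaded.hyper.L == 3
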