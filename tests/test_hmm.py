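"""State-model contracts: VB fit, pruning, ELBO, transfer, serialization."""

import numpy as np
import pytest
from scipy.stats import multivariate_t

from mdstates import (
    FitConfig,
    RoiTimeSeries,
    SimulationConfig,
    apply_model,
    elbo,
    fit,
    generate_multitask_cohort,
)
from mdstates.hmm import StateModel, deserialize, serialize
from mdstates.containers import BrainState


def _runs_from_gaussian(rng, n_runs=4, T=80, d=3):
    labels = tuple(f"r{i}" for i in range(d))
    return [RoiTimeSeries(values=rng.normal(size=(T, d)), roi_labels=labels,
                          subject_id=f"s{i}") for i in range(n_runs)]


@pytest.fixture(scope="module")
def fitted(small_fit):
    return small_fit


class TestFit:
    def test_effective_states_never_exceed_initial(self, fitted):
        _, model, _ = fitted
        assert model.K_effective <= model.K_init

    def test_single_gaussian_data_collapses_to_one_state(self):
        rng = np.random.default_rng(0)
        runs = _runs_from_gaussian(rng, n_runs=4, T=120, d=3)
        model, _ = fit(runs, K_init=4,
                       config=FitConfig(n_restarts=1, seed=0, max_iter=300,
                                        tol=1e-7))
        assert model.K_effective == 1
        np.testing.assert_allclose(model.transition, [[1.0]])

    def test_elbo_trace_is_monotone(self, fitted):
        _, model, _ = fitted
        for seg in model.fit_diagnostics["elbo_segments"]:
            diffs = np.diff(seg)
            floor = -1e-6 * np.abs(np.asarray(seg[:-1]))
            assert np.all(diffs >= floor - 1e-9)

    def test_posterior_rows_are_distributions(self, fitted):
        _, _, posteriors = fitted
        for p in posteriors:
            np.testing.assert_allclose(p.tpp.sum(axis=1), 1.0, atol=1e-8)

    def test_recovers_planted_states(self, fitted):
        cohort, model, posteriors = fitted
        truth = cohort.truth
        assert abs(model.K_effective - 3) <= 1
        # each true state should have a close fitted state (z-units)
        fm = model.means()
        for k in range(3):
            dists = np.linalg.norm(fm - truth.state_means["ref"][k], axis=1)
            assert dists.min() < 0.5

    def test_mismatched_roi_labels_rejected(self):
        rng = np.random.default_rng(1)
        a = RoiTimeSeries(rng.normal(size=(60, 2)), ("x", "y"))
        b = RoiTimeSeries(rng.normal(size=(60, 2)), ("y", "x"))
        with pytest.raises(ValueError, match="ROI labels"):
            fit([a, b], K_init=2, config=FitConfig(n_restarts=1))

    def test_too_little_data_rejected(self):
        rng = np.random.default_rng(1)
        runs = _runs_from_gaussian(rng, n_runs=1, T=60)
        with pytest.raises(ValueError, match="timepoints"):
            fit(runs, K_init=15)

    def test_roi_permutation_equivariance(self):
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=4, n_timepoints=120,
                               n_states_per_task=2, seed=17)
        cohort = generate_multitask_cohort(cfg)
        runs = cohort.task_runs("a")
        perm = np.array([3, 1, 4, 0, 2, 5, 6, 8, 7, 10, 9])
        runs_p = [
            RoiTimeSeries(values=r.values[:, perm],
                          roi_labels=tuple(r.roi_labels[i] for i in perm),
                          subject_id=r.subject_id)
            for r in runs
        ]
        fc = FitConfig(n_restarts=1, seed=3, max_iter=150, tol=1e-6)
        m1, p1 = fit(runs, K_init=3, config=fc)
        m2, p2 = fit(runs_p, K_init=3, config=fc)
        assert m1.K_effective == m2.K_effective
        np.testing.assert_allclose(m2.means(), m1.means()[:, perm], atol=1e-6)
        for a, b in zip(p1, p2):
            np.testing.assert_allclose(a.tpp, b.tpp, atol=1e-6)


class TestElbo:
    def test_converged_posterior_is_a_fixed_point(self, fitted):
        cohort, model, _ = fitted
        runs = cohort.task_runs("ref")
        e1 = elbo(model, runs)
        e2 = elbo(model, runs)
        assert abs(e1 - e2) < 1e-9
        final = model.fit_diagnostics["final_elbo"]
        assert abs(e1 - final) < 1e-6 * abs(final)

    def test_single_state_elbo_matches_conjugate_evidence(self):
        # oracle: exact log marginal via the sequential multivariate-t
        # posterior predictive of the Normal-(inverse-)Wishart model
        rng = np.random.default_rng(5)
        T, d = 20, 2
        X = rng.normal(size=(T, d))
        run = RoiTimeSeries(values=X, roi_labels=("a", "b"))
        cfg = FitConfig(n_restarts=1, seed=0, max_iter=200, tol=1e-12)
        model, _ = fit([run], K_init=1, config=cfg)
        got = model.fit_diagnostics["final_elbo"]

        kappa, nu0 = cfg.beta0, d + 2.0
        m = X.mean(axis=0)
        psi = np.diag(np.maximum(X.var(axis=0), 1e-12)) * nu0
        logml = 0.0
        for t in range(T):
            df = nu0 - d + 1
            scale = psi * (kappa + 1) / (kappa * df)
            logml += multivariate_t.logpdf(X[t], loc=m, shape=scale, df=df)
            dm = X[t] - m
            psi = psi + (kappa / (kappa + 1)) * np.outer(dm, dm)
            m = (kappa * m + X[t]) / (kappa + 1)
            kappa += 1.0
            nu0 += 1.0
        assert abs(got - logml) < 1.0


class TestApplyModel:
    def test_self_transfer_correlates_with_fit_posteriors(self, fitted):
        cohort, model, posteriors = fitted
        runs = cohort.task_runs("ref")
        transferred = apply_model(model, runs)
        for p_fit, p_tr in zip(posteriors, transferred):
            for k in range(model.K_effective):
                if p_fit.tpp[:, k].std() == 0:
                    continue
                r = np.corrcoef(p_fit.tpp[:, k], p_tr.tpp[:, k])[0, 1]
                assert r > 0.99

    def test_identical_emissions_leave_dynamics_in_charge(self):
        # two states with the same Gaussian: TPP depends only on p and A
        rng = np.random.default_rng(2)
        d = 2
        s = BrainState(0, np.zeros(d), np.eye(d), ("a", "b"))
        s2 = BrainState(1, np.zeros(d), np.eye(d), ("a", "b"))
        model = StateModel(K_init=2, K_effective=2,
                           initial_probs=np.array([0.7, 0.3]),
                           transition=np.array([[0.9, 0.1], [0.2, 0.8]]),
                           states=[s, s2], ard_weights=np.array([0.5, 0.5]),
                           roi_labels=("a", "b"))
        run = RoiTimeSeries(rng.normal(size=(50, d)), ("a", "b"))
        tpp = apply_model(model, [run])[0].tpp
        # emissions uninformative: posterior equals the smoothed chain law,
        # which converges to the stationary distribution of A
        from mdstates import stationary_distribution
        pi = stationary_distribution(model.transition)
        np.testing.assert_allclose(tpp[25], pi, atol=1e-4)

    def test_transfer_of_true_model_decodes_hidden_labels(self, small_cohort):
        truth = small_cohort.truth
        k = truth.n_states_per_task["tgt"]
        states = [truth.brain_state("tgt", i) for i in range(k)]
        model = StateModel(K_init=k, K_effective=k,
                           initial_probs=truth.initial_probs["tgt"],
                           transition=truth.transition_matrices["tgt"],
                           states=states, ard_weights=np.full(k, 1 / k),
                           roi_labels=truth.roi_labels)
        runs = small_cohort.task_runs("tgt")
        posts = apply_model(model, runs)
        agree, total = 0, 0
        for p, sid in zip(posts, small_cohort.subjects()):
            z = small_cohort.hidden_labels[(sid, "tgt")]
            agree += int(np.sum(p.tpp.argmax(axis=1) == z))
            total += len(z)
        assert agree / total > 0.9

    def test_dimension_mismatch_rejected(self, fitted):
        _, model, _ = fitted
        rng = np.random.default_rng(0)
        bad = RoiTimeSeries(rng.normal(size=(60, 2)), ("x", "y"))
        with pytest.raises(ValueError, match="ROI labels"):
            apply_model(model, [bad])


class TestExactInference:
    def test_posteriors_match_independent_forward_backward(self):
        """Frozen-parameter TPP vs an established HMM library's smoother."""
        from hmmlearn.hmm import GaussianHMM

        rng = np.random.default_rng(7)
        for _ in range(10):
            k = rng.integers(2, 5)
            d = rng.integers(2, 6)
            T = rng.integers(50, 201)
            labels = tuple(f"r{i}" for i in range(d))
            means = rng.normal(size=(k, d)) * 2
            covs = np.stack([
                (lambda w: w @ w.T / (2 * d) + 0.3 * np.eye(d))(
                    rng.normal(size=(d, 2 * d)))
                for _ in range(k)
            ])
            A = rng.dirichlet(np.ones(k) * 2, size=k)
            p0 = rng.dirichlet(np.ones(k))
            states = [BrainState(i, means[i], covs[i], labels)
                      for i in range(k)]
            model = StateModel(K_init=k, K_effective=k, initial_probs=p0,
                               transition=A, states=states,
                               ard_weights=np.full(k, 1 / k),
                               roi_labels=labels)
            X = rng.normal(size=(T, d))
            run = RoiTimeSeries(X, labels)
            tpp = apply_model(model, [run])[0].tpp

            ref = GaussianHMM(n_components=k, covariance_type="full",
                              init_params="")
            ref.startprob_ = p0
            ref.transmat_ = A
            ref.means_ = means
            ref.covars_ = covs
            expected = ref.predict_proba(X)
            np.testing.assert_allclose(tpp, expected, atol=1e-8)


class TestSerialization:
    def test_round_trip_is_bit_exact(self, fitted):
        _, model, _ = fitted
        back = deserialize(serialize(model))
        assert back.K_effective == model.K_effective
        assert back.roi_labels == model.roi_labels
        np.testing.assert_array_equal(back.initial_probs, model.initial_probs)
        np.testing.assert_array_equal(back.transition, model.transition)
        np.testing.assert_array_equal(back.means(), model.means())
        np.testing.assert_array_equal(back.covs(), model.covs())
        assert serialize(back) == serialize(model)

    def test_round_trip_preserves_transfer_posteriors(self, fitted):
        cohort, model, _ = fitted
        runs = cohort.task_runs("tgt")
        back = deserialize(serialize(model))
        for a, b in zip(apply_model(model, runs), apply_model(back, runs)):
            np.testing.assert_allclose(a.tpp, b.tpp, atol=1e-12)

    def test_schema_version_is_checked(self, fitted):
        _, model, _ = fitted
        text = serialize(model).replace("mdstates-model-1", "other-schema-9")
        with pytest.raises(ValueError, match="schema"):
            deserialize(text)
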