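"""State-matching contracts: KL closed form, closeness, permutation nulls,
and the combined match verdict."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from mdstates import (
    BrainState,
    FitConfig,
    SimulationConfig,
    fit,
    generate_multitask_cohort,
    jeffreys_divergence,
    kl_gaussian,
    match_states,
    permutation_p_space,
    permutation_p_temporal,
    state_space_closeness,
    temporal_closeness_matrix,
)
from mdstates.containers import StatePosterior
from mdstates.hmm import StateModel
from mdstates.matching import _p_from_null

from conftest import random_spd, random_state


class TestGaussianKld:
    def test_identical_gaussians_have_zero_divergence(self):
        rng = np.random.default_rng(0)
        a = random_state(rng, 4)
        b = BrainState(1, a.mean.copy(), a.cov.copy(), a.roi_labels)
        assert kl_gaussian(a, b) == pytest.approx(0.0, abs=1e-12)
        assert jeffreys_divergence(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        # 1-D N(0,1) vs N(1,1): KL each way 0.5, Jeffreys 1, c = 1
        a = BrainState(0, [0.0], [[1.0]], ("x",))
        b = BrainState(1, [1.0], [[1.0]], ("x",))
        assert kl_gaussian(a, b) == pytest.approx(0.5)
        assert kl_gaussian(b, a) == pytest.approx(0.5)
        res = state_space_closeness(a, b)
        assert res.divergence_value == pytest.approx(1.0)
        assert res.c == pytest.approx(1.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_state(rng, 3), random_state(rng, 3, 1)
            j1 = jeffreys_divergence(a, b)
            j2 = jeffreys_divergence(b, a)
            assert j1 == pytest.approx(j2)
            assert j1 > 0

    def test_label_mismatch_rejected(self):
        a = BrainState(0, [0, 0], np.eye(2), ("x", "y"))
        b = BrainState(1, [0, 0], np.eye(2), ("y", "x"))
        with pytest.raises(ValueError, match="ROI"):
            kl_gaussian(a, b)

    def test_rotation_invariance_of_closeness(self):
        rng = np.random.default_rng(5)
        a, b = random_state(rng, 4), random_state(rng, 4, 1)
        Q = ortho_group.rvs(4, random_state=11)
        ar = BrainState(0, Q @ a.mean, Q @ a.cov @ Q.T, a.roi_labels)
        br = BrainState(1, Q @ b.mean, Q @ b.cov @ Q.T, b.roi_labels)
        assert state_space_closeness(a, b).c == pytest.approx(
            state_space_closeness(ar, br).c, rel=1e-8)


class TestCloseness:
    def test_identical_states_flagged_infinite(self):
        rng = np.random.default_rng(1)
        a = random_state(rng, 3)
        b = BrainState(1, a.mean.copy(), a.cov.copy(), a.roi_labels)
        res = state_space_closeness(a, b)
        assert res.infinite and np.isinf(res.c)

    def test_ordering_reverses_divergence_ordering(self):
        rng = np.random.default_rng(2)
        ref = random_state(rng, 3)
        cands = [random_state(rng, 3, i + 1) for i in range(3)]
        divs = [jeffreys_divergence(ref, c) for c in cands]
        cs = [state_space_closeness(ref, c).c for c in cands]
        assert np.argsort(divs).tolist() == np.argsort(cs)[::-1].tolist()


class TestTemporalCloseness:
    def _posts(self, mats, task="t"):
        return [StatePosterior(tpp=m, subject_id=f"s{i}")
                for i, m in enumerate(mats)]

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        tpp = rng.dirichlet(np.ones(3), size=100)
        r, _ = temporal_closeness_matrix(self._posts([tpp]),
                                         self._posts([tpp]))
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)

    def test_two_state_columns_are_anticorrelated(self):
        rng = np.random.default_rng(1)
        tpp_ref = rng.dirichlet(np.ones(2), size=80)
        tpp_x = rng.dirichlet(np.ones(2), size=80)
        r, _ = temporal_closeness_matrix(self._posts([tpp_ref]),
                                         self._posts([tpp_x]))
        # columns of a 2-state TPP sum to 1, so r(i,1) = -r(i,2)
        np.testing.assert_allclose(r[:, 0], -r[:, 1], atol=1e-12)

    def test_never_visited_state_gives_nan(self):
        tpp_a = np.column_stack([np.ones(50), np.zeros(50)])
        rng = np.random.default_rng(2)
        tpp_b = rng.dirichlet(np.ones(2), size=50)
        r, _ = temporal_closeness_matrix(self._posts([tpp_a]),
                                         self._posts([tpp_b]))
        assert np.isnan(r).all()


class TestPermutation:
    def _models(self, rng, n_states=4, d=3):
        labels = tuple(f"r{i}" for i in range(d))
        out = {}
        for name in ("m1", "m2"):
            states = [random_state(rng, d, i, labels) for i in range(n_states)]
            out[name] = StateModel(
                K_init=n_states, K_effective=n_states,
                initial_probs=np.full(n_states, 1 / n_states),
                transition=np.full((n_states, n_states), 1 / n_states),
                states=states, ard_weights=np.full(n_states, 1 / n_states),
                roi_labels=labels)
        return out

    def test_counting_rule(self):
        null = np.concatenate([np.full(30, 2.0), np.full(70, 0.5)])
        res = _p_from_null(null, 1.0)
        assert res.p_value == pytest.approx(0.30)
        assert res.n_exceed == 30 and not res.floored

    def test_identical_pair_gets_floor_p(self):
        rng = np.random.default_rng(4)
        models = self._models(rng)
        a = models["m1"].states[0]
        b = BrainState(9, a.mean.copy(), a.cov.copy(), a.roi_labels)
        models["m2"].states[1] = b
        res = permutation_p_space(models, (a, b), n_perm=100, seed=0)
        assert res.floored and res.p_value == pytest.approx(0.01)

    def test_temporal_null_mirrors_space_null(self):
        rng = np.random.default_rng(5)
        cols = rng.dirichlet(np.ones(6), size=300)
        res = permutation_p_temporal(cols, (0, 3), n_perm=100, seed=1)
        assert 0 < res.p_value <= 1
        assert len(res.null_samples) <= 100

    def test_null_pvalues_are_roughly_uniform(self):
        """Calibration: observed pair drawn from the null process itself."""
        from scipy.stats import kstest

        rng = np.random.default_rng(6)
        pvals = []
        for rep in range(200):
            models = self._models(np.random.default_rng(1000 + rep),
                                  n_states=6, d=3)
            pool = models["m1"].states + models["m2"].states
            i, j = rng.choice(len(pool), size=2, replace=False)
            res = permutation_p_space(models, (pool[i], pool[j]),
                                      n_perm=100, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.13  # generous for discrete p on a grid of 1/100


class TestMatchStates:
    def test_self_match_is_consistent(self, small_fit):
        cohort, model, posteriors = small_fit
        runs = cohort.task_runs("ref")
        rep = match_states(0, model, model, runs, n_perm=50, seed=0,
                           target_posteriors=posteriors)
        assert rep.matched_state_id == 0
        assert rep.consistent
        assert rep.closeness[0].infinite

    def test_planted_shared_state_is_matched(self, small_fit):
        cohort, ref_model, _ = small_fit
        runs = cohort.task_runs("tgt")
        tgt_model, tgt_post = fit(
            runs, K_init=5,
            config=FitConfig(n_restarts=1, seed=7, max_iter=200, tol=1e-5))
        truth = cohort.truth
        # identify the fitted states closest to the planted shared state
        ref_idx = int(np.argmax([
            state_space_closeness(truth.brain_state("ref", 0), s).c
            for s in ref_model.states]))
        true_tgt_idx = int(np.argmax([
            state_space_closeness(truth.brain_state("tgt", 0), s).c
            for s in tgt_model.states]))
        rep = match_states(ref_idx, ref_model, tgt_model, runs,
                           n_perm=100, seed=0, target_posteriors=tgt_post)
        assert rep.matched_state_id == true_tgt_idx
        assert rep.consistent
        assert rep.space_p.p_value <= 0.05
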