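"""Generator contracts: chain law, stationarity, determinism, race logic."""

import dataclasses

import numpy as np
import pytest

from mdstates import (
    SimulationConfig,
    coupling_for_correlation,
    generate_multitask_cohort,
    generate_race_model_trials,
    generate_task_dataset,
    jeffreys_divergence,
    make_ground_truth,
    stationary_distribution,
)
from mdstates.io import read_run_tsv, write_run_tsv


def _truth(**overrides):
    base = dict(tasks=("a", "b"), reference_task="a", n_subjects=4,
                n_timepoints=200, n_states_per_task=3, seed=1)
    base.update(overrides)
    return make_ground_truth(SimulationConfig(**base))


class TestTaskDataset:
    def test_single_state_truth_yields_constant_labels(self):
        truth = _truth(n_states_per_task=1, shared_state=False)
        runs, motion, labels = generate_task_dataset(truth, "a", 2, 100)
        for z in labels.values():
            assert np.all(z == 0)

    def test_absorbing_chain_stays_in_initial_state(self):
        truth = _truth(shared_state=False)
        truth.transition_matrices["a"] = np.eye(3)
        truth.initial_probs["a"] = np.array([0.0, 0.0, 1.0])
        _, _, labels = generate_task_dataset(truth, "a", 3, 100)
        for z in labels.values():
            assert np.all(z == 2)

    def test_occupancy_matches_stationary_distribution(self):
        truth = _truth(n_states_per_task=4, n_timepoints=2000,
                       occupancy_bias_sd=0.0)
        _, _, labels = generate_task_dataset(truth, "a", 1, 2000)
        z = labels["sub-000"]
        emp = np.bincount(z, minlength=4) / len(z)
        # oracle: stationary eigenvector by brute-force power iteration
        A = truth.transition_matrices["a"]
        pi = np.full(4, 0.25)
        for _ in range(10000):
            pi = pi @ A
        assert np.abs(emp - pi).max() < 0.05
        np.testing.assert_allclose(pi, stationary_distribution(A), atol=1e-8)

    def test_empirical_transitions_match_generator(self):
        truth = _truth(n_timepoints=3000, occupancy_bias_sd=0.0)
        _, _, labels = generate_task_dataset(truth, "a", 1, 3000)
        z = labels["sub-000"]
        k = 3
        counts = np.zeros((k, k))
        np.add.at(counts, (z[:-1], z[1:]), 1.0)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(emp - truth.transition_matrices["a"]).max() < 0.05

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="unknown task"):
            generate_task_dataset(_truth(), "nope", 2, 100)

    def test_nonstochastic_transition_rejected(self):
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=2, seed=1)
        truth = make_ground_truth(cfg)
        truth.transition_matrices["a"][0, 0] += 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            truth.__post_init__()


class TestCohort:
    def test_regeneration_is_bit_identical(self):
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=3, n_timepoints=100,
                               n_states_per_task=2, seed=7)
        c1 = generate_multitask_cohort(cfg)
        c2 = generate_multitask_cohort(cfg)
        for key in c1.runs:
            assert np.array_equal(c1.runs[key].values, c2.runs[key].values)
            assert np.array_equal(c1.hidden_labels[key], c2.hidden_labels[key])
        assert c1.behavior.equals(c2.behavior)

    def test_shared_state_has_zero_divergence_across_tasks(self):
        cohort = generate_multitask_cohort(
            SimulationConfig(tasks=("a", "b"), reference_task="a",
                             n_subjects=2, n_states_per_task=2, seed=3))
        truth = cohort.truth
        d = jeffreys_divergence(truth.brain_state("a", 0),
                                truth.brain_state("b", 0))
        assert d < 1e-12
        # unique states are far apart
        assert jeffreys_divergence(truth.brain_state("a", 1),
                                   truth.brain_state("b", 1)) > 1.0

    def test_null_cohort_has_no_shared_state(self):
        cohort = generate_multitask_cohort(
            SimulationConfig(tasks=("a", "b"), reference_task="a",
                             n_subjects=2, shared_state=False, seed=3))
        assert cohort.truth.shared_state_id is None

    def test_zero_coupling_gives_negligible_correlation(self):
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=200, n_timepoints=100,
                               n_states_per_task=3, behavior_coupling=0.0,
                               seed=21)
        cohort = generate_multitask_cohort(cfg)
        occ = np.array([np.mean(cohort.hidden_labels[(s, "a")] == 0)
                        for s in cohort.subjects()])
        index = cohort.behavior["a_index"].to_numpy()
        assert abs(np.corrcoef(occ, index)[0, 1]) < 0.2

    def test_planted_coupling_has_requested_sign_and_size(self):
        slope, noise = coupling_for_correlation(0.7)
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=300, n_timepoints=150,
                               behavior_coupling=slope,
                               behavior_noise_sd=noise, seed=13)
        cohort = generate_multitask_cohort(cfg)
        occ = np.array([np.mean(cohort.hidden_labels[(s, "a")] == 0)
                        for s in cohort.subjects()])
        r = np.corrcoef(occ, cohort.behavior["a_index"])[0, 1]
        assert 0.5 < r < 0.85

    def test_coupling_without_shared_state_rejected(self):
        with pytest.raises(ValueError, match="shared state"):
            SimulationConfig(tasks=("a", "b"), reference_task="a",
                             shared_state=False, behavior_coupling=1.0)

    def test_occupancy_conservation_and_label_recoverability(self):
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=4, n_timepoints=120, seed=2)
        cohort = generate_multitask_cohort(cfg)
        for key, z in cohort.hidden_labels.items():
            occ = np.bincount(z, minlength=4) / len(z)
            assert abs(occ.sum() - 1.0) < 1e-12
            assert len(z) == cohort.runs[key].n_timepoints

    def test_run_tsv_round_trip(self, tmp_path):
        cfg = SimulationConfig(tasks=("a", "b"), reference_task="a",
                               n_subjects=2, n_timepoints=80, seed=2)
        cohort = generate_multitask_cohort(cfg)
        run = cohort.runs[("sub-000", "a")]
        path = tmp_path / "run.tsv"
        write_run_tsv(run, path)
        back = read_run_tsv(path)
        assert back.roi_labels == run.roi_labels
        np.testing.assert_array_equal(back.values, run.values)


class TestRaceModel:
    def test_unstoppable_stop_process_always_responds(self):
        # stop finishes far too late: the go process always wins the race
        trials = generate_race_model_trials(go_mu=500, go_sd=50,
                                            ssrt_true=1e6, n_go=50,
                                            n_stop=30, seed=1)
        stop = trials[trials.trial_type == "stop"]
        assert stop.responded.all()

    def test_instant_stop_with_zero_ssd_always_inhibits(self):
        trials = generate_race_model_trials(go_mu=500, go_sd=50, ssrt_true=0,
                                            n_go=50, n_stop=30,
                                            staircase_step=1e-6,
                                            ssd_start=0.0, seed=1)
        stop = trials[trials.trial_type == "stop"]
        assert not stop.responded.any()

    def test_staircase_converges_to_half_respond_rate(self):
        trials = generate_race_model_trials(go_mu=500, go_sd=100,
                                            ssrt_true=250, n_go=600,
                                            n_stop=200, staircase_step=25,
                                            seed=4)
        stop = trials[trials.trial_type == "stop"]
        assert 0.4 < stop.responded.mean() < 0.6

    def test_minimum_stop_trials_enforced(self):
        with pytest.raises(ValueError, match="stop"):
            generate_race_model_trials(500, 50, 250, n_go=10, n_stop=5)
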