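import numpy as np
import pytest

from mdstates import (
    BrainState,
    FitConfig,
    SimulationConfig,
    fit,
    generate_multitask_cohort,
)


def random_spd(rng: np.random.Generator, d: int) -> np.ndarray:
    """Random well-conditioned SPD matrix."""
    w = rng.normal(size=(d, 2 * d))
    return w @ w.T / (2 * d) + 0.3 * np.eye(d)


def random_state(rng: np.random.Generator, d: int, state_id: int = 0,
                 labels=None) -> BrainState:
    labels = labels or tuple(f"roi{i}" for i in range(d))
    return BrainState(state_id=state_id, mean=rng.normal(size=d),
                      cov=random_spd(rng, d), roi_labels=labels)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-task planted-shared-state cohort, small enough for fast fits."""
    cfg = SimulationConfig(tasks=("ref", "tgt"), reference_task="ref",
                           n_subjects=8, n_timepoints=150,
                           n_states_per_task=3, seed=5)
    return generate_multitask_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A fitted model plus posteriors on the reference task of small_cohort."""
    runs = small_cohort.task_runs("ref")
    model, post = fit(runs, K_init=5,
                      config=FitConfig(n_restarts=1, seed=2, max_iter=200,
                                       tol=1e-5))
    return small_cohort, model, post
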