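"""Synthetic multi-task cohorts from a Markov-switching Gaussian ground truth.

The generator emulates the data layout of a multi-task fMRI study of the
multiple-demand system: for each task, each subject contributes one run of
T timepoints over D ROIs. Hidden state sequences follow a first-order,
sticky Markov chain; emissions are multivariate Gaussians whose mean is the
state's activation profile and whose covariance its connectivity pattern.
One state (index 0 by convention) can be planted as a *shared* state with
identical Gaussian parameters across tasks, mimicking a domain-general brain
state; the remaining states are task-unique. Per-subject occupancy of the
shared state is modulated by a subject-level bias on its self-transition,
and a behavioral index per task is coupled to that occupancy, so that
brain-behavior analyses have a known planted effect.

Optional nuisance structure (all off by default, enabled per test): linear
drift per ROI, and six smooth motion-like random-walk series linearly mixed
into the data — the removal target of :mod:`mdstates.preprocess`.

Everything is driven by one integer seed; regeneration with the same
configuration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BrainState, MotionRegressors, RoiTimeSeries

__all__ = [
    "DEFAULT_ROI_LABELS",
    "GroundTruth",
    "SimulationConfig",
    "SimulatedCohort",
    "make_ground_truth",
    "generate_task_dataset",
    "generate_multitask_cohort",
    "generate_race_model_trials",
    "coupling_for_correlation",
    "stationary_distribution",
]

# The 11-ROI multiple-demand set: 9 load-positive frontoparietal /
# cingulo-opercular regions plus 2 load-negative default-mode regions.
DEFAULT_ROI_LABELS: tuple[str, ...] = (
    "L_AI", "R_AI", "L_MFG", "R_MFG", "L_FEF", "R_FEF",
    "L_IPS", "R_IPS", "DMPFC", "VMPFC", "PCC",
)


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigvec)."""
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _check_stochastic(A: np.ndarray, name: str) -> None:
    if np.any(A < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError(f"{name} rows do not sum to 1")


@dataclass
class GroundTruth:
    """Generative parameters for a multi-task cohort.

    ``shared_state_id`` maps each task to the index of its planted shared
    state, or is ``None`` for a null cohort without one. ``behavior_coupling``
    is a linear slope from z-scored shared-state occupancy to the behavioral
    index; :func:`coupling_for_correlation` converts a target population
    correlation into the matching (slope, noise sd) pair.
    """

    tasks: tuple[str, ...]
    n_states_per_task: dict[str, int]
    shared_state_id: dict[str, int] | None
    initial_probs: dict[str, np.ndarray]
    transition_matrices: dict[str, np.ndarray]
    state_means: dict[str, np.ndarray]          # task -> (K, D)
    state_covs: dict[str, np.ndarray]           # task -> (K, D, D)
    roi_labels: tuple[str, ...]
    subject_occupancy_bias: np.ndarray          # (n_subjects,)
    behavior_coupling: float
    behavior_noise_sd: float
    noise_sd: float
    drift_amplitude: float
    motion_weight: float
    perturbation_sd: float
    seed: int

    def __post_init__(self) -> None:
        for task in self.tasks:
            k = self.n_states_per_task[task]
            A = np.asarray(self.transition_matrices[task], dtype=float)
            if A.shape != (k, k):
                raise ValueError(f"transition matrix for {task} is not {k}x{k}")
            _check_stochastic(A, f"transition matrix for {task}")
            p = np.asarray(self.initial_probs[task], dtype=float)
            if not math.isclose(p.sum(), 1.0, abs_tol=1e-12) or np.any(p < 0):
                raise ValueError(f"initial probabilities for {task} are not a distribution")
            covs = np.asarray(self.state_covs[task], dtype=float)
            for j in range(k):
                c = covs[j]
                if not np.allclose(c, c.T, atol=1e-10):
                    raise ValueError(f"state {j} covariance for {task} not symmetric")
                if np.linalg.eigvalsh(c)[0] <= 0:
                    raise ValueError(f"state {j} covariance for {task} not PD")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def brain_state(self, task: str, state: int) -> BrainState:
        return BrainState(
            state_id=state,
            mean=self.state_means[task][state],
            cov=self.state_covs[task][state],
            roi_labels=self.roi_labels,
        )

    def subject_transition(self, task: str, subject: int) -> np.ndarray:
        """Transition matrix for one subject: shared-state self-transition
        shifted on the logit scale by the subject's occupancy bias."""
        A = np.array(self.transition_matrices[task], dtype=float)
        if self.shared_state_id is None:
            return A
        s = self.shared_state_id[task]
        bias = float(self.subject_occupancy_bias[subject])
        if bias == 0.0:
            return A
        a = A[s, s]
        a_new = 1.0 / (1.0 + math.exp(-(math.log(a / (1 - a)) + bias)))
        rest = A[s].copy()
        rest[s] = 0.0
        rest_sum = rest.sum()
        A[s] = rest * ((1.0 - a_new) / rest_sum)
        A[s, s] = a_new
        return A


@dataclass
class SimulationConfig:
    """One-stop configuration for :func:`generate_multitask_cohort`."""

    tasks: tuple[str, ...] = ("nback", "axcpt")
    reference_task: str = "nback"
    n_subjects: int = 40
    n_timepoints: int = 300
    n_states_per_task: int = 4
    roi_labels: tuple[str, ...] = DEFAULT_ROI_LABELS
    shared_state: bool = True
    stay_prob: float = 0.85
    mean_scale: float = 1.0
    occupancy_bias_sd: float = 0.6
    behavior_coupling: float = 0.0
    behavior_noise_sd: float = 1.0
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    motion_weight: float = 0.0
    perturbation_sd: float = 0.0
    hemodynamic_convolution: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tasks) < 2:
            raise ValueError("need at least 2 tasks")
        if self.reference_task not in self.tasks:
            raise ValueError("reference task must be in the task list")
        if self.behavior_coupling != 0.0 and not self.shared_state:
            raise ValueError("behavior coupling requires a shared state")


@dataclass
class SimulatedCohort:
    tasks: tuple[str, ...]
    runs: dict[tuple[str, str], RoiTimeSeries]          # (subject, task) -> run
    motion: dict[tuple[str, str], MotionRegressors]
    hidden_labels: dict[tuple[str, str], np.ndarray]
    behavior: pd.DataFrame
    truth: GroundTruth

    def task_runs(self, task: str) -> list[RoiTimeSeries]:
        """Runs of one task in sorted subject order."""
        keys = sorted(k for k in self.runs if k[1] == task)
        return [self.runs[k] for k in keys]

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.runs})


def coupling_for_correlation(r: float) -> tuple[float, float]:
    """(slope, noise sd) giving population correlation ``r`` between z-scored
    occupancy and the behavioral index."""
    if not -1.0 < r < 1.0 or r == 0.0:
        raise ValueError("need 0 < |r| < 1")
    return math.copysign(1.0, r), math.sqrt(1.0 / r**2 - 1.0)


def _random_correlation(rng: np.random.Generator, d: int) -> np.ndarray:
    """Random well-conditioned correlation-like SPD matrix with unit diagonal."""
    w = rng.normal(size=(d, 2 * d))
    c = w @ w.T / (2 * d)
    s = np.sqrt(np.diag(c))
    c = c / np.outer(s, s)
    # shrink toward identity to keep condition numbers moderate
    return 0.6 * c + 0.4 * np.eye(d)


def _sticky_transition(rng: np.random.Generator, k: int, stay: float) -> np.ndarray:
    A = np.empty((k, k))
    for i in range(k):
        off = rng.dirichlet(np.ones(max(k - 1, 1)))
        row = np.insert(off * (1 - stay), i, stay) if k > 1 else np.array([1.0])
        A[i] = row[:k]
    A /= A.sum(axis=1, keepdims=True)
    return A


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw a ground truth consistent with ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    d = len(config.roi_labels)
    k = config.n_states_per_task
    tasks = tuple(config.tasks)

    shared_mean = rng.normal(0.0, config.mean_scale, size=d)
    shared_cov = _random_correlation(rng, d)

    means, covs, trans, inits = {}, {}, {}, {}
    for task in tasks:
        m = rng.normal(0.0, config.mean_scale, size=(k, d))
        c = np.stack([_random_correlation(rng, d) for _ in range(k)])
        if config.shared_state:
            m[0] = shared_mean + rng.normal(0.0, config.perturbation_sd, size=d)
            c[0] = shared_cov
        means[task] = m
        covs[task] = c
        A = _sticky_transition(rng, k, config.stay_prob)
        trans[task] = A
        inits[task] = stationary_distribution(A)

    bias = rng.normal(0.0, config.occupancy_bias_sd, size=config.n_subjects)
    return GroundTruth(
        tasks=tasks,
        n_states_per_task={t: k for t in tasks},
        shared_state_id={t: 0 for t in tasks} if config.shared_state else None,
        initial_probs=inits,
        transition_matrices=trans,
        state_means=means,
        state_covs=covs,
        roi_labels=tuple(config.roi_labels),
        subject_occupancy_bias=bias,
        behavior_coupling=config.behavior_coupling,
        behavior_noise_sd=config.behavior_noise_sd,
        noise_sd=config.noise_sd,
        drift_amplitude=config.drift_amplitude,
        motion_weight=config.motion_weight,
        perturbation_sd=config.perturbation_sd,
        seed=config.seed,
    )


def _run_rng(truth: GroundTruth, task: str, subject: int) -> np.random.Generator:
    task_index = truth.tasks.index(task)
    return np.random.default_rng(
        np.random.SeedSequence([truth.seed, 7919, task_index, subject])
    )


def _sample_chain(rng: np.random.Generator, p0: np.ndarray, A: np.ndarray,
                  T: int) -> np.ndarray:
    k = len(p0)
    z = np.empty(T, dtype=int)
    z[0] = rng.choice(k, p=p0)
    u = rng.random(T - 1)
    cum = np.cumsum(A, axis=1)
    for t in range(1, T):
        z[t] = np.searchsorted(cum[z[t - 1]], u[t - 1], side="right")
    return np.minimum(z, k - 1)


def _smooth_motion(rng: np.random.Generator, T: int) -> np.ndarray:
    """Six smooth random-walk motion series (3 'mm', 3 'rad')."""
    steps = rng.normal(0.0, 1.0, size=(T, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.hanning(9)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 0, walk)
    sm -= sm.mean(axis=0)
    scale = sm.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    sm /= scale
    sm[:, :3] *= 0.2   # translations, mm-scale
    sm[:, 3:] *= 0.002  # rotations, rad-scale
    return sm


def generate_task_dataset(
    truth: GroundTruth, task: str, n_subjects: int, T: int,
) -> tuple[dict[str, RoiTimeSeries], dict[str, MotionRegressors], dict[str, np.ndarray]]:
    """Simulate one task's runs for ``n_subjects`` subjects of length ``T``.

    Returns (runs, motion, hidden label sequences), each keyed by subject id
    ``"sub-NNN"``. Hidden labels are returned for testing only; real data has
    no such column.
    """
    if task not in truth.tasks:
        raise ValueError(f"unknown task {task!r}; known: {truth.tasks}")
    if T < 50:
        raise ValueError("need T >= 50")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if n_subjects > len(truth.subject_occupancy_bias):
        raise ValueError("more subjects requested than biases in ground truth")

    d = truth.n_rois
    runs: dict[str, RoiTimeSeries] = {}
    motions: dict[str, MotionRegressors] = {}
    labels: dict[str, np.ndarray] = {}
    means = truth.state_means[task]
    chols = np.linalg.cholesky(truth.state_covs[task])
    for s in range(n_subjects):
        rng = _run_rng(truth, task, s)
        A = truth.subject_transition(task, s)
        z = _sample_chain(rng, truth.initial_probs[task], A, T)
        eps = rng.normal(size=(T, d))
        x = means[z] + np.einsum("tij,tj->ti", chols[z], eps)
        if truth.noise_sd > 0:
            x = x + rng.normal(0.0, truth.noise_sd, size=(T, d))
        if truth.drift_amplitude > 0:
            slope = rng.normal(0.0, truth.drift_amplitude, size=d)
            t_norm = np.linspace(-0.5, 0.5, T)[:, None]
            x = x + t_norm * slope
        mo = _smooth_motion(rng, T)
        if truth.motion_weight > 0:
            mix = rng.normal(size=(6, d))
            x = x + truth.motion_weight * (mo @ mix)
        sid = f"sub-{s:03d}"
        runs[sid] = RoiTimeSeries(values=x, roi_labels=truth.roi_labels,
                                  subject_id=sid, task_id=task, run_id="run-1")
        motions[sid] = MotionRegressors(values=mo)
        labels[sid] = z
    return runs, motions, labels


def generate_multitask_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate the full cohort: every task for every subject, plus behavior.

    The behavioral index for each task is
    ``index = coupling * z(occupancy of shared state) + noise``; occupancy is
    the realized hidden-label occupancy in that subject's run.
    """
    truth = make_ground_truth(config)
    runs: dict[tuple[str, str], RoiTimeSeries] = {}
    motion: dict[tuple[str, str], MotionRegressors] = {}
    hidden: dict[tuple[str, str], np.ndarray] = {}
    occ: dict[str, np.ndarray] = {}
    for task in config.tasks:
        r, m, z = generate_task_dataset(truth, task, config.n_subjects,
                                        config.n_timepoints)
        for sid in r:
            runs[(sid, task)] = r[sid]
            motion[(sid, task)] = m[sid]
            hidden[(sid, task)] = z[sid]
        if truth.shared_state_id is not None:
            s = truth.shared_state_id[task]
            occ[task] = np.array([
                np.mean(z[sid] == s) for sid in sorted(z)
            ])

    subjects = [f"sub-{i:03d}" for i in range(config.n_subjects)]
    behav = {"subject": subjects}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1709]))
    for task in config.tasks:
        if config.behavior_coupling != 0.0 and truth.shared_state_id is not None:
            o = occ[task]
            zo = (o - o.mean()) / o.std(ddof=0)
            noise = rng.normal(0.0, config.behavior_noise_sd, size=len(subjects))
            behav[f"{task}_index"] = config.behavior_coupling * zo + noise
        else:
            behav[f"{task}_index"] = rng.normal(size=len(subjects))
    behavior = pd.DataFrame(behav)
    return SimulatedCohort(tasks=tuple(config.tasks), runs=runs, motion=motion,
                           hidden_labels=hidden, behavior=behavior, truth=truth)


def generate_race_model_trials(
    go_mu: float, go_sd: float, ssrt_true: float, n_go: int, n_stop: int,
    staircase_step: float = 50.0, seed: int = 0, ssd_start: float = 200.0,
) -> pd.DataFrame:
    """Simulate a stop-signal task under the independent race model.

    Go RTs are truncated-normal (truncated at 0). On stop trials the go
    process races a stop process finishing at SSD + ``ssrt_true``; the subject
    responds iff the go RT is <= that finish time (ties go to the response).
    SSD follows a 1-up/1-down staircase — after a failed stop the SSD is
    lowered (stopping made easier), after a successful stop raised — which
    converges to ~50% respond rate. Times in ms.

    Returns a trial table with columns ``trial_type`` (go/stop), ``rt``
    (NaN when no response), ``ssd`` (NaN on go trials), ``responded``.
    """
    if min(go_mu, go_sd, staircase_step) <= 0 or ssrt_true < 0:
        raise ValueError("durations must be positive")
    if n_stop < 20:
        raise ValueError("need at least 20 stop trials")
    rng = np.random.default_rng(seed)
    n = n_go + n_stop
    is_stop = np.zeros(n, dtype=bool)
    is_stop[rng.choice(n, size=n_stop, replace=False)] = True
    a = (0.0 - go_mu) / go_sd
    go_rts = stats.truncnorm.rvs(a, np.inf, loc=go_mu, scale=go_sd,
                                 size=n, random_state=rng)
    rows = []
    ssd = float(ssd_start)
    for i in range(n):
        if not is_stop[i]:
            rows.append(("go", go_rts[i], np.nan, True))
            continue
        responded = go_rts[i] <= ssd + ssrt_true
        rows.append(("stop", go_rts[i] if responded else np.nan, ssd, responded))
        ssd = max(0.0, ssd - staircase_step) if responded else ssd + staircase_step
    return pd.DataFrame(rows, columns=["trial_type", "rt", "ssd", "responded"])
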