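"""Cross-task state correspondence: space closeness, temporal closeness,
permutation significance, and the combined match report.

Two fitted task models are compared in two independent ways. *State space
closeness* ``c`` is one divided by the Kullback–Leibler divergence between
two states' Gaussians — by default the symmetrized (Jeffreys) divergence,
with both one-way divergences always reported, since the direction is a
convention and the tested contract is the identity of the argmax. *State
temporal closeness* ``r`` is the Pearson correlation between temporal
posterior probability (TPP) time courses evaluated on the *same* runs: the
reference model's globals are transferred onto the target task's data
(:func:`mdstates.hmm.apply_model`), so both models' TPPs live on one common
time axis. A match is *consistent* when both metrics pick the same target
state — the pattern the analysis is designed to test.

Significance for either metric comes from a permutation null: the statistic
recomputed for randomly drawn state pairs from the pooled inventory of both
models (same- or cross-task pairs allowed, the observed pair excluded),
``p = #(null >= observed) / n_perm`` with a ``< 1/n_perm`` floor when no
null sample reaches the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BrainState, StatePosterior
from .hmm import StateModel, apply_model

__all__ = [
    "kl_gaussian", "jeffreys_divergence", "state_divergence",
    "ClosenessResult", "state_space_closeness",
    "temporal_closeness_matrix", "PermutationResult",
    "permutation_p_space", "permutation_p_temporal",
    "MatchReport", "match_states",
]

_DIV_EPS = 1e-12


def _check_pair(a: BrainState, b: BrainState) -> None:
    if a.roi_labels != b.roi_labels:
        raise ValueError("states are defined over different ROI sets/orders")


def kl_gaussian(a: BrainState, b: BrainState) -> float:
    """Closed-form KL( N(mu_a, S_a) || N(mu_b, S_b) )."""
    _check_pair(a, b)
    d = a.dim
    Lb = np.linalg.cholesky(b.cov)
    # tr(S_b^-1 S_a) via triangular solves
    M = np.linalg.solve(Lb, a.cov)
    M = np.linalg.solve(Lb, M.T)
    trace = np.trace(M)
    diff = np.linalg.solve(Lb, b.mean - a.mean)
    mah = float(diff @ diff)
    La = np.linalg.cholesky(a.cov)
    logdet_b = 2.0 * np.log(np.diag(Lb)).sum()
    logdet_a = 2.0 * np.log(np.diag(La)).sum()
    return 0.5 * float(trace + mah - d + logdet_b - logdet_a)


def jeffreys_divergence(a: BrainState, b: BrainState) -> float:
    """Symmetrized KL: KL(a||b) + KL(b||a)."""
    return kl_gaussian(a, b) + kl_gaussian(b, a)


def state_divergence(a: BrainState, b: BrainState,
                     convention: str = "jeffreys") -> float:
    if convention == "jeffreys":
        return jeffreys_divergence(a, b)
    if convention == "forward":
        return kl_gaussian(a, b)
    if convention == "reverse":
        return kl_gaussian(b, a)
    raise ValueError(f"unknown divergence convention {convention!r}")


@dataclass
class ClosenessResult:
    """State space closeness between one pair of states."""

    c: float                       # 1 / divergence (inf when divergence ~ 0)
    divergence_value: float
    kl_ab: float
    kl_ba: float
    direction_convention: str = "jeffreys"
    infinite: bool = False
    p_value: float | None = None
    n_exceed: int | None = None
    null_samples: np.ndarray | None = None


def state_space_closeness(a: BrainState, b: BrainState,
                          convention: str = "jeffreys") -> ClosenessResult:
    """c = 1 / KLD between the two states' Gaussians (higher = more similar)."""
    kl_ab = kl_gaussian(a, b)
    kl_ba = kl_gaussian(b, a)
    div = {"jeffreys": kl_ab + kl_ba, "forward": kl_ab,
           "reverse": kl_ba}[convention]
    if div < _DIV_EPS:
        return ClosenessResult(c=np.inf, divergence_value=div, kl_ab=kl_ab,
                               kl_ba=kl_ba, direction_convention=convention,
                               infinite=True)
    return ClosenessResult(c=1.0 / div, divergence_value=div, kl_ab=kl_ab,
                           kl_ba=kl_ba, direction_convention=convention)


# ---------------------------------------------------------------------------
# temporal closeness

def _concat_tpp(posteriors: list[StatePosterior]) -> np.ndarray:
    """Concatenate TPPs over runs in sorted subject order -> (sum T, K)."""
    order = sorted(range(len(posteriors)),
                   key=lambda i: (posteriors[i].subject_id,
                                  posteriors[i].run_id, i))
    return np.concatenate([posteriors[i].tpp for i in order], axis=0), order


def _pearson_cols(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def temporal_closeness_matrix(
    tpp_ref_on_target: list[StatePosterior],
    tpp_target: list[StatePosterior],
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between every (reference state, target state) TPP pair.

    Both posterior sets must be computed on the same runs. Returns the
    (K_ref, K_target) correlation matrix over runs concatenated in sorted
    subject order, plus the per-run correlation array (n_runs, K_ref,
    K_target) so a few dominating subjects can be spotted. Pairs involving a
    never-visited state (zero-variance TPP column) are NaN.
    """
    if len(tpp_ref_on_target) != len(tpp_target):
        raise ValueError("posterior lists cover different run sets")
    for a, b in zip(tpp_ref_on_target, tpp_target):
        if a.n_timepoints != b.n_timepoints:
            raise ValueError("TPP pairs have mismatched run lengths")
    ref_cat, order = _concat_tpp(tpp_ref_on_target)
    tgt_cat, _ = _concat_tpp(tpp_target)
    k_ref, k_tgt = ref_cat.shape[1], tgt_cat.shape[1]
    r = np.empty((k_ref, k_tgt))
    for i in range(k_ref):
        for j in range(k_tgt):
            r[i, j] = _pearson_cols(ref_cat[:, i], tgt_cat[:, j])
    per_run = np.empty((len(order), k_ref, k_tgt))
    for n, idx in enumerate(order):
        a = tpp_ref_on_target[idx].tpp
        b = tpp_target[idx].tpp
        for i in range(k_ref):
            for j in range(k_tgt):
                per_run[n, i, j] = _pearson_cols(a[:, i], b[:, j])
    return r, per_run


# ---------------------------------------------------------------------------
# permutation significance

@dataclass
class PermutationResult:
    p_value: float
    n_exceed: int
    n_perm: int
    null_samples: np.ndarray
    floored: bool = False          # True when reported p is the < 1/n floor


def _p_from_null(null: np.ndarray, observed: float) -> PermutationResult:
    n = len(null)
    n_exceed = int(np.sum(null >= observed))
    if n_exceed == 0:
        return PermutationResult(p_value=1.0 / n, n_exceed=0, n_perm=n,
                                 null_samples=null, floored=True)
    return PermutationResult(p_value=n_exceed / n, n_exceed=n_exceed,
                             n_perm=n, null_samples=null)


def _pool_pairs(n_pool: int, exclude: tuple[int, int],
                n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly drawn unordered state pairs, observed pair excluded."""
    if n_pool < 2:
        raise ValueError("need at least 2 distinct states in the pool")
    pairs = [(i, j) for i in range(n_pool) for j in range(i + 1, n_pool)
             if (i, j) != tuple(sorted(exclude))]
    if not pairs:
        raise ValueError("no candidate pairs besides the observed one")
    idx = rng.integers(0, len(pairs), size=n_perm)
    return np.array([pairs[i] for i in idx])


def permutation_p_space(models: dict[str, StateModel],
                        observed: tuple[BrainState, BrainState],
                        n_perm: int = 100, seed: int = 0,
                        convention: str = "jeffreys") -> PermutationResult:
    """Permutation p for an observed space closeness.

    The null pool is every state of every model in ``models``; each null
    sample is the closeness of a uniformly drawn state pair (same- or
    cross-task), the observed pair excluded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pool: list[BrainState] = []
    obs_idx = [-1, -1]
    for name in sorted(models):
        for s in models[name].states:
            for w, o in enumerate(observed):
                if o is s:
                    obs_idx[w] = len(pool)
            pool.append(s)
    rng = np.random.default_rng(seed)
    pairs = _pool_pairs(len(pool), (obs_idx[0], obs_idx[1]), n_perm, rng)
    null = np.array([
        state_space_closeness(pool[i], pool[j], convention=convention).c
        for i, j in pairs
    ])
    c_obs = state_space_closeness(*observed, convention=convention).c
    return _p_from_null(null, c_obs)


def permutation_p_temporal(tpp_columns: np.ndarray,
                           observed: tuple[int, int],
                           n_perm: int = 100, seed: int = 0) -> PermutationResult:
    """Permutation p for an observed temporal closeness.

    ``tpp_columns`` stacks the pooled TPP time courses (one column per state
    of either model, all on the same time axis). The null statistic is the
    Pearson r between a uniformly drawn pair of distinct columns, the
    observed pair excluded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = _pool_pairs(tpp_columns.shape[1], observed, n_perm, rng)
    null = np.array([
        _pearson_cols(tpp_columns[:, i], tpp_columns[:, j]) for i, j in pairs
    ])
    r_obs = _pearson_cols(tpp_columns[:, observed[0]],
                          tpp_columns[:, observed[1]])
    return _p_from_null(null[~np.isnan(null)], r_obs)


# ---------------------------------------------------------------------------
# the combined match

@dataclass
class MatchReport:
    """Outcome of matching one reference state against a target model."""

    reference_state_id: int
    closeness: list[ClosenessResult]          # per target state
    temporal_r: np.ndarray                    # (K_target,) row for the ref state
    temporal_matrix: np.ndarray               # full (K_ref, K_target)
    per_run_r: np.ndarray
    matched_state_id: int
    argmax_c: int
    argmax_r: int
    consistent: bool
    tie: bool
    space_p: PermutationResult | None = None
    temporal_p: PermutationResult | None = None

    def summary(self) -> dict:
        best = self.closeness[self.matched_state_id]
        out = dict(
            reference_state_id=self.reference_state_id,
            matched_state_id=self.matched_state_id,
            c=best.c, divergence=best.divergence_value,
            r=float(self.temporal_r[self.argmax_r]),
            argmax_c=self.argmax_c, argmax_r=self.argmax_r,
            consistent=self.consistent, tie=self.tie,
        )
        if self.space_p is not None:
            out["space_p"] = self.space_p.p_value
            out["space_p_floored"] = self.space_p.floored
        if self.temporal_p is not None:
            out["temporal_p"] = self.temporal_p.p_value
            out["temporal_p_floored"] = self.temporal_p.floored
        return out


def match_states(reference_state_id: int, reference_model: StateModel,
                 target_model: StateModel, target_runs,
                 n_perm: int = 100, seed: int = 0,
                 convention: str = "jeffreys",
                 target_posteriors: list[StatePosterior] | None = None,
                 tie_rtol: float = 1e-9) -> MatchReport:
    """Match one reference state to the best-corresponding target state.

    Computes space closeness ``c`` against every target state, the temporal
    closeness row for the reference state (reference globals transferred
    onto the target runs), permutation p-values for the best of each metric,
    and a consistency verdict (argmax c == argmax r). A near-tie in ``c``
    (relative gap below ``tie_rtol``) is broken by temporal r and flagged.
    """
    if reference_model.roi_labels != target_model.roi_labels:
        raise ValueError("models are defined over different ROI sets")
    ref_state = reference_model.states[reference_state_id]
    closeness = [state_space_closeness(ref_state, s, convention=convention)
                 for s in target_model.states]
    c_vals = np.array([r.c for r in closeness])

    tpp_ref = apply_model(reference_model, target_runs)
    if target_posteriors is None:
        target_posteriors = apply_model(target_model, target_runs)
    r_mat, per_run = temporal_closeness_matrix(tpp_ref, target_posteriors)
    r_row = r_mat[reference_state_id]

    argmax_c = int(np.nanargmax(c_vals))
    argmax_r = int(np.nanargmax(r_row))
    top = np.sort(c_vals[np.isfinite(c_vals)])[::-1]
    tie = bool(len(c_vals) > 1 and np.isinf(c_vals).sum() > 1)
    if not tie and len(top) > 1 and top[0] > 0:
        tie = bool((top[0] - top[1]) <= tie_rtol * top[0])
    matched = argmax_c
    if tie:
        near = np.flatnonzero(
            np.isinf(c_vals) if np.isinf(c_vals).sum() > 1
            else c_vals >= top[0] * (1 - tie_rtol))
        matched = int(near[np.argmax(r_row[near])])
    consistent = bool(argmax_c == argmax_r)

    models = {"reference": reference_model, "target": target_model}
    space_p = permutation_p_space(
        models, (ref_state, target_model.states[matched]),
        n_perm=n_perm, seed=seed, convention=convention)
    ref_cat, _ = _concat_tpp(tpp_ref)
    tgt_cat, _ = _concat_tpp(target_posteriors)
    cols = np.concatenate([ref_cat, tgt_cat], axis=1)
    temporal_p = permutation_p_temporal(
        cols, (reference_state_id, ref_cat.shape[1] + argmax_r),
        n_perm=n_perm, seed=seed + 1)
    return MatchReport(
        reference_state_id=reference_state_id, closeness=closeness,
        temporal_r=r_row, temporal_matrix=r_mat, per_run_r=per_run,
        matched_state_id=matched, argmax_c=argmax_c, argmax_r=argmax_r,
        consistent=consistent, tie=tie, space_p=space_p,
        temporal_p=temporal_p)
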