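"""Variational-Bayes Gaussian-emission hidden Markov model of brain states.

The latent brain-state model: multi-subject ROI time series are modeled as a
hidden Markov chain over K states, each state emitting from a multivariate
Gaussian whose mean is the state's activation profile and whose covariance
its functional connectivity. Inference is variational Bayes EM with conjugate
priors — sparse Dirichlet priors on the initial distribution p(i) and on each
row of the transition matrix A(i,j), and Normal–Wishart priors on the state
Gaussians. The sparse Dirichlet priors act as an automatic-relevance
mechanism: states the data do not need lose expected usage across iterations
and are pruned below a usage threshold, so a deliberately generous initial
state count (default 15) collapses to the effective number of states.

The model separates *global* latent variables (p(i), A, state Gaussians),
which transfer across datasets, from *local* ones (the per-timepoint state
posteriors, TPP), which are recomputed for any new data by a single
forward–backward pass given the globals (:func:`apply_model`). Chains restart
from p(i) at every run boundary; one group model is fit per task across all
subjects' runs.

The per-iteration evidence lower bound is exact for this factorization:
``ELBO = sum_runs log Z~ - KL(q(params) || prior)`` where ``log Z~`` comes
from forward-backward under the geometric-mean parameters of q. It is
non-decreasing over iterations, which the fitter asserts in its diagnostics.
"""

from __future__ import annotations

import base64
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln

from .containers import BrainState, RoiTimeSeries, StatePosterior

__all__ = ["FitConfig", "StateModel", "fit", "apply_model", "elbo",
           "serialize", "deserialize", "save_model", "load_model"]

_SCHEMA_VERSION = "mdstates-model-1"


# ---------------------------------------------------------------------------
# configuration and model containers

@dataclass
class FitConfig:
    """Knobs of the variational fit.

    ``alpha_pi`` / ``alpha_trans`` are the sparse Dirichlet concentrations on
    p(i) and on each transition row (small values favor few used states).
    ``prune_threshold`` defaults to 1/(10*K_init): states whose expected
    usage falls below it after convergence are removed and the model refit.
    """

    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-6
    alpha_pi: float = 1e-3
    alpha_trans: float = 1e-3
    beta0: float = 1e-3
    prune: bool = True
    prune_threshold: float | None = None
    merge_refine: bool = True
    max_merge_candidates: int = 2
    seed: int = 0
    verbose: bool = False


@dataclass
class StateModel:
    """Fitted global latent variables of the brain-state model."""

    K_init: int
    K_effective: int
    initial_probs: np.ndarray           # (K,)
    transition: np.ndarray              # (K, K)
    states: list[BrainState]
    ard_weights: np.ndarray             # expected usage per surviving state
    roi_labels: tuple[str, ...]
    fit_diagnostics: dict = field(default_factory=dict)
    variational: dict | None = None     # q-posterior parameters (for elbo())

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.K_effective
        if self.initial_probs.shape != (k,) or self.transition.shape != (k, k):
            raise ValueError("parameter shapes disagree with K_effective")
        if not math.isclose(self.initial_probs.sum(), 1.0, abs_tol=1e-10):
            raise ValueError("initial probabilities do not sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows do not sum to 1")

    @property
    def n_states(self) -> int:
        return self.K_effective

    @property
    def dim(self) -> int:
        return len(self.roi_labels)

    def means(self) -> np.ndarray:
        return np.stack([s.mean for s in self.states])

    def covs(self) -> np.ndarray:
        return np.stack([s.cov for s in self.states])


# ---------------------------------------------------------------------------
# numerics helpers

def _regularize_cov(cov: np.ndarray) -> np.ndarray:
    """Jitter a covariance whose smallest eigenvalue dips below 1e-8."""
    eigmin = np.linalg.eigvalsh(cov)[0]
    if eigmin < 1e-8:
        cov = cov + np.eye(cov.shape[0]) * (1e-6 * np.trace(cov) / cov.shape[0])
    return cov


def _check_runs(runs: list[RoiTimeSeries]) -> tuple[np.ndarray, list[int], tuple[str, ...]]:
    if not runs:
        raise ValueError("no runs given")
    labels = runs[0].roi_labels
    for r in runs:
        if r.roi_labels != labels:
            raise ValueError("ROI labels differ across runs")
    X = np.concatenate([r.values for r in runs], axis=0)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input runs")
    return X, [r.n_timepoints for r in runs], labels


def _forward_backward(log_pi: np.ndarray, log_A: np.ndarray,
                      log_b_runs: list[np.ndarray]):
    """Scaled forward-backward over runs (chain resets at each run start).

    Runs with equal length are processed as one vectorized batch. Returns
    (gammas per run, xi summed over runs/time, first-timepoint counts, logZ).
    """
    K = log_pi.shape[0]
    xi_sum = np.zeros((K, K))
    first = np.zeros(K)
    logZ = 0.0
    gammas: list[np.ndarray | None] = [None] * len(log_b_runs)

    by_len: dict[int, list[int]] = {}
    for i, lb in enumerate(log_b_runs):
        by_len.setdefault(lb.shape[0], []).append(i)

    def _lse(v, axis):
        # logsumexp tolerant of all -inf slices
        m = v.max(axis=axis, keepdims=True)
        m_safe = np.where(np.isfinite(m), m, 0.0)
        out = np.log(np.exp(v - m_safe).sum(axis=axis)) + np.squeeze(m_safe, axis)
        return np.where(np.isfinite(np.squeeze(m, axis)), out, -np.inf)

    def _shift(v):
        m = v.max(axis=1, keepdims=True)
        m_safe = np.where(np.isfinite(m), m, 0.0)
        return np.exp(v - m_safe), m_safe

    with np.errstate(divide="ignore"):
        A_prob = np.exp(log_A)
        for T, idxs in by_len.items():
            log_b = np.stack([log_b_runs[i] for i in idxs])    # (R, T, K)
            R = log_b.shape[0]
            la = np.empty((R, T, K))
            la[:, 0] = log_pi[None, :] + log_b[:, 0]
            for t in range(1, T):
                ah, m = _shift(la[:, t - 1])
                la[:, t] = np.log(ah @ A_prob) + m + log_b[:, t]
            logZ_r = _lse(la[:, T - 1], axis=1)                # (R,)
            logZ += float(logZ_r.sum())

            lbeta = np.zeros((R, K))
            gamma = np.empty((R, T, K))
            gamma[:, T - 1] = np.exp(la[:, T - 1] - logZ_r[:, None])
            for t in range(T - 2, -1, -1):
                w = log_b[:, t + 1] + lbeta                    # (R, K)
                wt, mw = _shift(w)
                ah, _ = _shift(la[:, t])
                # pairwise marginals sum to 1 per run and timepoint, so the
                # joint can be normalized directly in probability domain
                xi_un = ah[:, :, None] * A_prob[None] * wt[:, None, :]
                s = np.maximum(xi_un.sum(axis=(1, 2), keepdims=True), 1e-300)
                xi_sum += (xi_un / s).sum(axis=0)
                lbeta = np.log(wt @ A_prob.T) + mw
                lg = la[:, t] + lbeta
                gh, _ = _shift(lg)
                gamma[:, t] = gh / gh.sum(axis=1, keepdims=True)
            first += gamma[:, 0].sum(axis=0)
            for j, i in enumerate(idxs):
                g = np.clip(gamma[j], 0.0, None)
                gammas[i] = g / g.sum(axis=1, keepdims=True)
    return gammas, xi_sum, first, logZ


def _dirichlet_kl(a: np.ndarray, a0: np.ndarray) -> float:
    sa, sa0 = a.sum(), a0.sum()
    return float(
        gammaln(sa) - gammaln(a).sum() - gammaln(sa0) + gammaln(a0).sum()
        + np.sum((a - a0) * (digamma(a) - digamma(sa)))
    )


def _ln_wishart_B(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(
        -(nu / 2) * logdet - (nu * d / 2) * math.log(2)
        - (d * (d - 1) / 4) * math.log(math.pi)
        - gammaln((nu - np.arange(d)) / 2).sum()
    )


def _e_ln_det_lambda(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    return float(digamma((nu - np.arange(d)) / 2).sum() + d * math.log(2) + logdet)


def _nw_kl(m, beta, W, nu, m0, beta0, W0inv, nu0, lnB0) -> float:
    d = W.shape[0]
    elog = _e_ln_det_lambda(W, nu)
    dm = m - m0
    eq_q_mu = 0.5 * (d * math.log(beta / (2 * math.pi)) + elog - d)
    eq_p_mu = 0.5 * (d * math.log(beta0 / (2 * math.pi)) + elog
                     - d * beta0 / beta - beta0 * nu * float(dm @ W @ dm))
    eq_q_lam = _ln_wishart_B(W, nu) + ((nu - d - 1) / 2) * elog - nu * d / 2
    eq_p_lam = lnB0 + ((nu0 - d - 1) / 2) * elog - 0.5 * nu * float(np.sum(W0inv * W))
    return (eq_q_mu - eq_p_mu) + (eq_q_lam - eq_p_lam)


# ---------------------------------------------------------------------------
# the variational fit

class _Posterior:
    """Variational posterior q over global parameters."""

    __slots__ = ("a_pi", "a_trans", "beta", "m", "W", "nu")

    def __init__(self, a_pi, a_trans, beta, m, W, nu):
        self.a_pi, self.a_trans = a_pi, a_trans
        self.beta, self.m, self.W, self.nu = beta, m, W, nu

    @property
    def K(self) -> int:
        return self.a_pi.shape[0]

    def select(self, keep: np.ndarray) -> "_Posterior":
        return _Posterior(self.a_pi[keep], self.a_trans[np.ix_(keep, keep)],
                          self.beta[keep], self.m[keep], self.W[keep],
                          self.nu[keep])


class _Prior:
    def __init__(self, K: int, X: np.ndarray, cfg: FitConfig):
        d = X.shape[1]
        self.alpha_pi = np.full(K, cfg.alpha_pi)
        self.alpha_trans = np.full((K, K), cfg.alpha_trans)
        self.beta0 = cfg.beta0
        self.m0 = X.mean(axis=0)
        self.nu0 = d + 2.0
        # E[Lambda] under the prior matches the inverse data variances
        var = np.maximum(X.var(axis=0), 1e-12)
        self.W0 = np.diag(1.0 / var) / self.nu0
        self.W0inv = np.diag(var) * self.nu0
        self.lnB0 = _ln_wishart_B(self.W0, self.nu0)

    def resize(self, K: int) -> None:
        self.alpha_pi = np.full(K, self.alpha_pi.flat[0])
        self.alpha_trans = np.full((K, K), self.alpha_trans.flat[0])


def _m_step(X, gammas, xi_sum, first, prior: _Prior) -> _Posterior:
    gamma = np.concatenate(gammas, axis=0)                     # (N, K)
    K = gamma.shape[1]
    d = X.shape[1]
    Nk = gamma.sum(axis=0) + 1e-12
    sum_x = gamma.T @ X                                        # (K, D)
    xbar = sum_x / Nk[:, None]
    sum_xx = np.einsum("tk,ti,tj->kij", gamma, X, X, optimize=True)

    a_pi = prior.alpha_pi + first
    a_trans = prior.alpha_trans + xi_sum
    beta = prior.beta0 + Nk
    m = (prior.beta0 * prior.m0[None, :] + sum_x) / beta[:, None]
    nu = prior.nu0 + Nk
    W = np.empty((K, d, d))
    for k in range(K):
        Sk = sum_xx[k] / Nk[k] - np.outer(xbar[k], xbar[k])
        dm = xbar[k] - prior.m0
        Winv = (prior.W0inv + Nk[k] * Sk
                + (prior.beta0 * Nk[k] / (prior.beta0 + Nk[k])) * np.outer(dm, dm))
        Winv = 0.5 * (Winv + Winv.T)
        W[k] = np.linalg.inv(Winv)
        W[k] = 0.5 * (W[k] + W[k].T)
    return _Posterior(a_pi, a_trans, beta, m, W, nu)


def _expected_log_params(q: _Posterior):
    log_pi = digamma(q.a_pi) - digamma(q.a_pi.sum())
    log_A = digamma(q.a_trans) - digamma(q.a_trans.sum(axis=1, keepdims=True))
    return log_pi, log_A


def _expected_log_emission(X: np.ndarray, q: _Posterior) -> np.ndarray:
    """E_q[ln N(x_t | mu_k, Lambda_k^-1)] for all t, k."""
    n, d = X.shape
    out = np.empty((n, q.K))
    for k in range(q.K):
        elog = _e_ln_det_lambda(q.W[k], q.nu[k])
        L = np.linalg.cholesky(q.W[k])
        y = (X - q.m[k]) @ L
        mah = np.einsum("ti,ti->t", y, y)
        out[:, k] = 0.5 * elog - 0.5 * d * math.log(2 * math.pi) \
            - 0.5 * (d / q.beta[k] + q.nu[k] * mah)
    return out


def _kl_q_prior(q: _Posterior, prior: _Prior) -> float:
    kl = _dirichlet_kl(q.a_pi, prior.alpha_pi)
    for j in range(q.K):
        kl += _dirichlet_kl(q.a_trans[j], prior.alpha_trans[j])
    for k in range(q.K):
        kl += _nw_kl(q.m[k], q.beta[k], q.W[k], q.nu[k], prior.m0,
                     prior.beta0, prior.W0inv, prior.nu0, prior.lnB0)
    return kl


def _split_rows(X: np.ndarray, lengths: list[int]) -> list[np.ndarray]:
    out, i = [], 0
    for L in lengths:
        out.append(X[i:i + L])
        i += L
    return out


def _vb_run(X, lengths, q, prior, cfg: FitConfig):
    """VB EM to convergence from posterior q. Returns (q, gammas, trace)."""
    trace: list[float] = []
    gammas = None
    prev = -np.inf
    for _ in range(cfg.max_iter):
        log_pi, log_A = _expected_log_params(q)
        log_b = _split_rows(_expected_log_emission(X, q), lengths)
        gammas, xi_sum, first, logZ = _forward_backward(log_pi, log_A, log_b)
        F = logZ - _kl_q_prior(q, prior)
        trace.append(F)
        if F - prev < cfg.tol * max(1.0, abs(F)):
            break
        prev = F
        q = _m_step(X, gammas, xi_sum, first, prior)
    return q, gammas, trace


def _init_posterior(X, lengths, K, prior, rng_seed: int) -> _Posterior:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=1, random_state=rng_seed,
                algorithm="lloyd")
    labels = km.fit_predict(X)
    gamma = np.full((X.shape[0], K), 0.1 / K)
    gamma[np.arange(X.shape[0]), labels] += 0.9
    gammas = _split_rows(gamma, lengths)
    xi_sum = np.zeros((K, K))
    first = np.zeros(K)
    for g in gammas:
        first += g[0]
        xi_sum += g[:-1].T @ g[1:]
    return _m_step(X, gammas, xi_sum, first, prior)


def _usage(gammas) -> np.ndarray:
    g = np.concatenate(gammas, axis=0)
    return g.sum(axis=0) / g.shape[0]


def _merge_and_refit(X, lengths, gammas, i, j, cfg: FitConfig):
    """Combine the responsibilities of states i and j and refit by VB."""
    K = gammas[0].shape[1]
    keep = [k for k in range(K) if k != j]
    g2 = []
    for g in gammas:
        gg = g[:, keep].copy()
        gg[:, keep.index(i)] = g[:, i] + g[:, j]
        g2.append(gg)
    prior = _Prior(K - 1, X, cfg)
    xi = np.zeros((K - 1, K - 1))
    first = np.zeros(K - 1)
    for g in g2:
        first += g[0]
        xi += g[:-1].T @ g[1:]
    q = _m_step(X, g2, xi, first, prior)
    q, gammas2, trace = _vb_run(X, lengths, q, prior, cfg)
    return q, gammas2, trace, prior


def _state_overlap_order(q: _Posterior) -> list[tuple[int, int]]:
    """State pairs ordered by ascending symmetrized KL of their expected
    Gaussians (most redundant pair first)."""
    d = q.m.shape[1]
    covs, chols = [], []
    for k in range(q.K):
        cov = np.linalg.inv(q.W[k]) / max(q.nu[k] - d - 1.0, 1e-6)
        cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(d)
        covs.append(cov)
        chols.append(np.linalg.cholesky(cov))
    def skl(a, b):
        out = 0.0
        for x, y in ((a, b), (b, a)):
            My = np.linalg.solve(chols[y], covs[x])
            My = np.linalg.solve(chols[y], My.T)
            diff = np.linalg.solve(chols[y], q.m[y] - q.m[x])
            out += 0.5 * (np.trace(My) + diff @ diff - d
                          + 2 * np.log(np.diag(chols[y])).sum()
                          - 2 * np.log(np.diag(chols[x])).sum())
        return out
    pairs = [(skl(a, b), a, b) for a in range(q.K) for b in range(a + 1, q.K)]
    pairs.sort()
    return [(a, b) for _, a, b in pairs]


def fit(runs: list[RoiTimeSeries], K_init: int = 15,
        config: FitConfig | None = None
        ) -> tuple[StateModel, list[StatePosterior]]:
    """Fit one group-level brain-state model across runs.

    Runs are concatenated with chain resets at run boundaries. Initialization
    is k-means over the pooled timepoints; ``config.n_restarts`` independent
    starts are run and the best final ELBO wins. After convergence, states
    with expected usage below the prune threshold are removed and the model
    refit until the inventory is stable.

    Returns the model plus one :class:`StatePosterior` (TPP) per run, in
    input order.
    """
    cfg = config or FitConfig()
    X, lengths, roi_labels = _check_runs(runs)
    if X.shape[0] < 10 * K_init:
        raise ValueError(
            f"need at least {10 * K_init} total timepoints for K_init={K_init}, "
            f"got {X.shape[0]}")
    threshold = cfg.prune_threshold
    if threshold is None:
        threshold = 1.0 / (10.0 * K_init)

    best = None
    for restart in range(cfg.n_restarts):
        seed_r = (cfg.seed * 7919 + restart * 104729) % (2**31 - 1)
        prior = _Prior(K_init, X, cfg)
        q = _init_posterior(X, lengths, K_init, prior, seed_r)
        q, gammas, trace = _vb_run(X, lengths, q, prior, cfg)
        segments = [trace]
        n_pruned = 0
        while cfg.prune:
            usage = _usage(gammas)
            drop = usage < threshold
            if drop.all():
                drop[np.argmax(usage)] = False   # never prune every state
            if not drop.any() or q.K == 1:
                break
            keep = ~drop
            n_pruned += int(drop.sum())
            q = q.select(keep)
            prior.resize(int(keep.sum()))
            q, gammas, trace = _vb_run(X, lengths, q, prior, cfg)
            segments.append(trace)
        # ELBO-guided merge refinement: redundant near-duplicate states can
        # survive as shallow local optima; merging the most-overlapping pair
        # and refitting escapes them, accepted only when the bound improves.
        n_merged = 0
        F = segments[-1][-1]
        while cfg.merge_refine and q.K > 1:
            accepted = False
            for a, b in _state_overlap_order(q)[:cfg.max_merge_candidates]:
                q2, g2, t2, prior2 = _merge_and_refit(X, lengths, gammas,
                                                      a, b, cfg)
                if t2[-1] > F:
                    q, gammas, prior = q2, g2, prior2
                    segments.append(t2)
                    F = t2[-1]
                    n_merged += 1
                    accepted = True
                    break
            if not accepted:
                break
        if best is None or F > best["F"]:
            best = dict(F=F, q=q, gammas=gammas, segments=segments,
                        n_pruned=n_pruned, n_merged=n_merged,
                        restart=restart, prior=prior)
    assert best is not None

    q = best["q"]
    d = X.shape[1]
    usage = _usage(best["gammas"])
    if usage.max() <= 0:
        raise RuntimeError("all states pruned")
    order = np.argsort(-usage)                 # most-used state first
    q = q.select(order)
    usage = usage[order]
    gammas = [g[:, order] for g in best["gammas"]]

    p = q.a_pi / q.a_pi.sum()
    A = q.a_trans / q.a_trans.sum(axis=1, keepdims=True)
    states = []
    for k in range(q.K):
        # inverse expected precision (E[Lambda] = nu W): the point covariance
        # whose forward-backward pass best matches the variational E-step
        cov = np.linalg.inv(q.W[k]) / q.nu[k]
        cov = _regularize_cov(0.5 * (cov + cov.T))
        states.append(BrainState(state_id=k, mean=q.m[k].copy(), cov=cov,
                                 roi_labels=roi_labels))
    diagnostics = dict(
        elbo_trace=list(best["segments"][-1]),
        elbo_segments=[list(s) for s in best["segments"]],
        final_elbo=float(best["F"]),
        seed=cfg.seed,
        n_restarts=cfg.n_restarts,
        best_restart=int(best["restart"]),
        n_pruned=int(best["n_pruned"]),
        n_merged=int(best["n_merged"]),
        prune_threshold=float(threshold),
        n_iterations=sum(len(s) for s in best["segments"]),
    )
    variational = dict(
        a_pi=q.a_pi, a_trans=q.a_trans, beta=q.beta, m=q.m, W=q.W, nu=q.nu,
        prior=dict(alpha_pi=cfg.alpha_pi, alpha_trans=cfg.alpha_trans,
                   beta0=cfg.beta0, m0=best["prior"].m0,
                   nu0=best["prior"].nu0, W0=best["prior"].W0),
    )
    model = StateModel(K_init=K_init, K_effective=q.K, initial_probs=p,
                       transition=A, states=states, ard_weights=usage,
                       roi_labels=roi_labels, fit_diagnostics=diagnostics,
                       variational=variational)
    # official TPPs come from one forward-backward pass under the exported
    # point parameters, so fit-time and transferred posteriors coincide
    return model, apply_model(model, runs)


# ---------------------------------------------------------------------------
# transfer (global variables frozen, local posteriors recomputed)

def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mean.shape[0]
    L = np.linalg.cholesky(cov)
    y = np.linalg.solve(L, (X - mean).T).T
    mah = np.einsum("ti,ti->t", y, y)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * math.log(2 * math.pi) + logdet + mah)


def apply_model(model: StateModel, runs: list[RoiTimeSeries]
                ) -> list[StatePosterior]:
    """Compute state posteriors (TPP) for new runs under a frozen model.

    The global latent variables — p(i), A(i,j) and the state Gaussians — are
    held fixed; local posteriors come from one exact forward–backward pass
    per run. This is the transfer mechanism behind cross-task state temporal
    closeness.
    """
    X, lengths, labels = _check_runs(runs)
    if labels != model.roi_labels:
        raise ValueError("ROI labels of runs do not match the model")
    log_b_all = np.stack(
        [_log_gauss(X, s.mean, s.cov) for s in model.states], axis=1)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(model.initial_probs, 1e-300))
        log_A = np.log(np.maximum(model.transition, 1e-300))
    gammas, _, _, _ = _forward_backward(log_pi, log_A,
                                        _split_rows(log_b_all, lengths))
    return [
        StatePosterior(tpp=g, subject_id=r.subject_id, task_id=r.task_id,
                       run_id=r.run_id)
        for g, r in zip(gammas, runs)
    ]


def elbo(model: StateModel, runs: list[RoiTimeSeries]) -> float:
    """Evidence lower bound of the fitted variational posterior on ``runs``.

    With the stored q-posterior this is the exact variational objective (one
    E-step from the converged posterior). For a model without variational
    state (e.g. built from ground truth), falls back to the point-parameter
    log-likelihood, which upper-bounds the ELBO.
    """
    X, lengths, labels = _check_runs(runs)
    if labels != model.roi_labels:
        raise ValueError("ROI labels of runs do not match the model")
    if model.variational is None:
        log_b_all = np.stack(
            [_log_gauss(X, s.mean, s.cov) for s in model.states], axis=1)
        with np.errstate(divide="ignore"):
            log_pi = np.log(np.maximum(model.initial_probs, 1e-300))
            log_A = np.log(np.maximum(model.transition, 1e-300))
        _, _, _, logZ = _forward_backward(log_pi, log_A,
                                          _split_rows(log_b_all, lengths))
        return float(logZ)
    v = model.variational
    q = _Posterior(np.asarray(v["a_pi"], float), np.asarray(v["a_trans"], float),
                   np.asarray(v["beta"], float), np.asarray(v["m"], float),
                   np.asarray(v["W"], float), np.asarray(v["nu"], float))
    pr = v["prior"]
    prior = _Prior.__new__(_Prior)
    K = q.K
    prior.alpha_pi = np.full(K, float(pr["alpha_pi"]))
    prior.alpha_trans = np.full((K, K), float(pr["alpha_trans"]))
    prior.beta0 = float(pr["beta0"])
    prior.m0 = np.asarray(pr["m0"], float)
    prior.nu0 = float(pr["nu0"])
    prior.W0 = np.asarray(pr["W0"], float)
    prior.W0inv = np.linalg.inv(prior.W0)
    prior.lnB0 = _ln_wishart_B(prior.W0, prior.nu0)
    log_pi, log_A = _expected_log_params(q)
    log_b = _split_rows(_expected_log_emission(X, q), lengths)
    _, _, _, logZ = _forward_backward(log_pi, log_A, log_b)
    return float(logZ - _kl_q_prior(q, prior))


# ---------------------------------------------------------------------------
# serialization

def _arr(a) -> dict:
    a = np.ascontiguousarray(np.asarray(a, dtype=float))
    return {"shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _unarr(d) -> np.ndarray:
    a = np.frombuffer(base64.b64decode(d["data"]), dtype=float)
    return a.reshape(d["shape"]).copy()


def serialize(model: StateModel) -> str:
    """Serialize a model to a JSON string (bit-exact round trip)."""
    doc = {
        "schema": _SCHEMA_VERSION,
        "K_init": model.K_init,
        "K_effective": model.K_effective,
        "roi_labels": list(model.roi_labels),
        "initial_probs": _arr(model.initial_probs),
        "transition": _arr(model.transition),
        "means": _arr(model.means()),
        "covs": _arr(model.covs()),
        "ard_weights": _arr(model.ard_weights),
        "fit_diagnostics": model.fit_diagnostics,
    }
    if model.variational is not None:
        v = model.variational
        doc["variational"] = {
            "a_pi": _arr(v["a_pi"]), "a_trans": _arr(v["a_trans"]),
            "beta": _arr(v["beta"]), "m": _arr(v["m"]), "W": _arr(v["W"]),
            "nu": _arr(v["nu"]),
            "prior": {
                "alpha_pi": float(v["prior"]["alpha_pi"]),
                "alpha_trans": float(v["prior"]["alpha_trans"]),
                "beta0": float(v["prior"]["beta0"]),
                "m0": _arr(v["prior"]["m0"]),
                "nu0": float(v["prior"]["nu0"]),
                "W0": _arr(v["prior"]["W0"]),
            },
        }
    return json.dumps(doc, sort_keys=True)


def deserialize(text: str) -> StateModel:
    doc = json.loads(text)
    if doc.get("schema") != _SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema {doc.get('schema')!r}; "
            f"expected {_SCHEMA_VERSION!r}")
    labels = tuple(doc["roi_labels"])
    means = _unarr(doc["means"])
    covs = _unarr(doc["covs"])
    states = [BrainState(state_id=k, mean=means[k], cov=covs[k],
                         roi_labels=labels) for k in range(means.shape[0])]
    variational = None
    if "variational" in doc:
        v = doc["variational"]
        variational = dict(
            a_pi=_unarr(v["a_pi"]), a_trans=_unarr(v["a_trans"]),
            beta=_unarr(v["beta"]), m=_unarr(v["m"]), W=_unarr(v["W"]),
            nu=_unarr(v["nu"]),
            prior=dict(alpha_pi=v["prior"]["alpha_pi"],
                       alpha_trans=v["prior"]["alpha_trans"],
                       beta0=v["prior"]["beta0"], m0=_unarr(v["prior"]["m0"]),
                       nu0=v["prior"]["nu0"], W0=_unarr(v["prior"]["W0"])),
        )
    return StateModel(K_init=doc["K_init"], K_effective=doc["K_effective"],
                      initial_probs=_unarr(doc["initial_probs"]),
                      transition=_unarr(doc["transition"]), states=states,
                      ard_weights=_unarr(doc["ard_weights"]),
                      roi_labels=labels,
                      fit_diagnostics=doc.get("fit_diagnostics", {}),
                      variational=variational)


def save_model(model: StateModel, path: str | Path) -> None:
    Path(path).write_text(serialize(model))


def load_model(path: str | Path) -> StateModel:
    return deserialize(Path(path).read_text())
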