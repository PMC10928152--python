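"""Brain-behavior statistics: CCA, leave-one-out predictive CCA, and
univariate occupancy-behavior correlations.

The multivariate route is canonical correlation analysis between per-subject
state occupancy rates (X) and behavioral measures (Y). The implementation
whitens both blocks (Cholesky of the regularized covariance) and takes the
SVD of the whitened cross-covariance; singular values are the canonical
correlations. Significance comes from permuting subject rows of Y (1000
permutations by default). Component selection is operationalized as the
component whose behavioral canonical scores align best (largest absolute
correlation) with a supplied cognitive-control orientation index; without
one, the first component is used. All components' statistics are always
returned.

The predictive check refits the CCA with each subject held out, projects the
held-out subject onto the training weights (sign-aligned to the full-sample
weights), and correlates the held-out brain scores with the held-out
behavior scores — an out-of-sample canonical correlation that shrinks
toward zero when the in-sample one is overfit.

Following the source analyses this package emulates, p-values here are not
adjusted for multiple comparisons by default; a Benjamini–Hochberg option
exists on the specificity screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CCAResult", "cca", "predictive_cca_loo",
           "univariate_state_behavior", "specificity_screen"]


def _standardize(M: np.ndarray, mean=None, sd=None):
    M = np.asarray(M, dtype=float)
    if mean is None:
        mean = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (M - mean) / sd, mean, sd


def _whitener(S: np.ndarray, ridge: float) -> np.ndarray:
    """Inverse Cholesky factor of S + ridge*I (so W.T @ S @ W = I)."""
    S = S + ridge * np.eye(S.shape[0])
    L = np.linalg.cholesky(S)
    return np.linalg.inv(L).T


def _cca_core(X: np.ndarray, Y: np.ndarray, ridge: float):
    """Canonical weights and correlations of standardized blocks."""
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    Wx = _whitener(Sxx, ridge)
    Wy = _whitener(Syy, ridge)
    U, svals, Vt = np.linalg.svd(Wx.T @ Sxy @ Wy)
    ncomp = min(X.shape[1], Y.shape[1])
    wx = Wx @ U[:, :ncomp]
    wy = Wy @ Vt.T[:, :ncomp]
    return wx, wy, np.clip(svals[:ncomp], 0.0, 1.0)


@dataclass
class CCAResult:
    brain_weights: np.ndarray            # (n_states, ncomp)
    behavior_weights: np.ndarray         # (n_measures, ncomp)
    correlations: np.ndarray             # canonical r per component
    selected_component: int
    selection_rule: str
    p_value: float | None = None
    n_perm: int | None = None
    ridge_applied: bool = False
    loo_predicted_r: float | None = None
    loo_p: float | None = None
    x_scores: np.ndarray | None = None
    y_scores: np.ndarray | None = None


def _select_component(Y_scores: np.ndarray, orientation: np.ndarray | None
                      ) -> tuple[int, str]:
    if orientation is None:
        return 0, "first-component (no orientation index supplied)"
    align = np.array([
        abs(np.corrcoef(Y_scores[:, j], orientation)[0, 1])
        if Y_scores[:, j].std() > 0 else 0.0
        for j in range(Y_scores.shape[1])
    ])
    return int(np.nanargmax(align)), "max |corr| with control orientation index"


def cca(X: np.ndarray, Y: np.ndarray, orientation: np.ndarray | None = None,
        n_perm: int = 1000, seed: int = 0, ridge: float = 0.0) -> CCAResult:
    """Canonical correlation between occupancy (X) and behavior (Y).

    Columns are standardized internally. If either block is numerically rank
    deficient, a small ridge is applied and flagged. The permutation p-value
    refers the selected component's canonical r to the null of row-permuted
    Y (statistic: same-index canonical r of the permuted solve).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y disagree on the number of subjects")
    if n <= max(X.shape[1], Y.shape[1]) + 2:
        raise ValueError("need n > max(dim X, dim Y) + 2 subjects")
    Xs, _, _ = _standardize(X)
    Ys, _, _ = _standardize(Y)
    ridge_applied = ridge > 0
    if ridge == 0.0:
        for M in (Xs, Ys):
            s = np.linalg.svd(M, compute_uv=False)
            if s[-1] < 1e-8 * s[0]:
                ridge = 1e-6
                ridge_applied = True
    wx, wy, r = _cca_core(Xs, Ys, ridge)
    x_scores = Xs @ wx
    y_scores = Ys @ wy
    comp, rule = _select_component(y_scores, orientation)
    # orient so the behavior score correlates positively with the index
    if orientation is not None:
        s = np.corrcoef(y_scores[:, comp], orientation)[0, 1]
        if s < 0:
            wx[:, comp] *= -1
            wy[:, comp] *= -1
            x_scores[:, comp] *= -1
            y_scores[:, comp] *= -1

    p_value = None
    if n_perm:
        rng = np.random.default_rng(seed)
        obs = r[comp]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, _, r_null = _cca_core(Xs, Ys[perm], ridge)
            if r_null[comp] >= obs:
                exceed += 1
        p_value = max(exceed, 1) / n_perm if exceed == 0 else exceed / n_perm
    return CCAResult(brain_weights=wx, behavior_weights=wy, correlations=r,
                     selected_component=comp, selection_rule=rule,
                     p_value=p_value, n_perm=n_perm or None,
                     ridge_applied=ridge_applied,
                     x_scores=x_scores, y_scores=y_scores)


def predictive_cca_loo(X: np.ndarray, Y: np.ndarray,
                       orientation: np.ndarray | None = None,
                       ridge: float = 0.0) -> tuple[float, float]:
    """Leave-one-out predictive canonical correlation.

    Returns (loo_predicted_r, two-tailed p) over the n held-out (brain score,
    behavior score) pairs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    full = cca(X, Y, orientation=orientation, n_perm=0, ridge=ridge)
    comp = full.selected_component
    wx_ref = full.brain_weights[:, comp]
    wy_ref = full.behavior_weights[:, comp]
    bs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ori = orientation[mask] if orientation is not None else None
        Xt, mx, sx = _standardize(X[mask])
        Yt, my, sy = _standardize(Y[mask])
        r_ridge = ridge
        if r_ridge == 0.0:
            for M in (Xt, Yt):
                s = np.linalg.svd(M, compute_uv=False)
                if s[-1] < 1e-8 * s[0]:
                    r_ridge = 1e-6
        wx, wy, _ = _cca_core(Xt, Yt, r_ridge)
        y_tr_scores = Yt @ wy
        c, _ = _select_component(y_tr_scores, ori)
        wxc, wyc = wx[:, c], wy[:, c]
        # align fold weights with the full-sample solution to fix sign flips
        if wxc @ wx_ref + wyc @ wy_ref < 0:
            wxc, wyc = -wxc, -wyc
        bs[i] = ((X[i] - mx) / np.where(sx > 0, sx, 1.0)) @ wxc
        ys[i] = ((Y[i] - my) / np.where(sy > 0, sy, 1.0)) @ wyc
    if bs.std() == 0 or ys.std() == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(bs, ys)
    return float(r), float(p)


def univariate_state_behavior(occupancy: np.ndarray, index: np.ndarray
                              ) -> tuple[float, float]:
    """Two-tailed Pearson correlation between one state's occupancy and a
    behavioral (or symptom) index."""
    occupancy = np.asarray(occupancy, dtype=float)
    index = np.asarray(index, dtype=float)
    if occupancy.shape != index.shape or occupancy.ndim != 1:
        raise ValueError("need two equal-length vectors")
    if len(occupancy) < 5:
        raise ValueError("need n >= 5")
    if not (np.all(np.isfinite(occupancy)) and np.all(np.isfinite(index))):
        raise ValueError("non-finite values")
    if occupancy.std() == 0 or index.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(occupancy, index)
    return float(r), float(p)


def specificity_screen(occupancy_table: np.ndarray, index: np.ndarray,
                       alpha: float = 0.05, bh_correct: bool = False
                       ) -> pd.DataFrame:
    """Correlate every state's occupancy with the index.

    Returns a table (state, r, p, significant_positive) plus the
    ``exactly_one`` attribute-style column; with ``bh_correct`` the p-values
    are Benjamini–Hochberg adjusted before thresholding.
    """
    occ = np.asarray(occupancy_table, dtype=float)
    rows = []
    for k in range(occ.shape[1]):
        if occ[:, k].std() == 0:
            rows.append((k, math.nan, math.nan))
            continue
        r, p = stats.pearsonr(occ[:, k], index)
        rows.append((k, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["state", "r", "p"])
    pvals = df["p"].to_numpy()
    if bh_correct:
        order = np.argsort(pvals)
        m = np.sum(np.isfinite(pvals))
        adj = np.full_like(pvals, np.nan)
        prev = 1.0
        for rank, i in list(enumerate(order, start=1))[::-1]:
            if not np.isfinite(pvals[i]):
                continue
            prev = min(prev, pvals[i] * m / rank)
            adj[i] = prev
        df["p_adjusted"] = adj
        pvals = adj
    df["significant_positive"] = (pvals < alpha) & (df["r"] > 0)
    df.attrs["exactly_one"] = bool(df["significant_positive"].sum() == 1)
    return df
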