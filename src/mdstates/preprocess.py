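"""ROI time-series cleaning before state-model fitting.

The cleaning chain mirrors standard task-fMRI practice for ROI series:
(1) regress out the 6 realignment parameters (3 translations, 3 rotations),
(2) remove a per-column linear trend, (3) z-score each column. The order is
fixed; ``preprocess_run`` applies all three.

Conventions: the nuisance regression includes an intercept (residuals would
otherwise keep mean structure), and the z-score uses the sample standard
deviation (ddof=1).
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import MotionRegressors, RoiTimeSeries

__all__ = ["regress_nuisance", "detrend_linear", "zscore", "preprocess_run"]


def regress_nuisance(ts: RoiTimeSeries, motion: MotionRegressors) -> RoiTimeSeries:
    """Residualize each ROI column on [intercept, 6 motion regressors].

    Degenerate motion columns (zero variance, e.g. a run with no recorded
    rotation) are dropped with a warning rather than making the design
    rank-deficient.
    """
    if motion.n_timepoints != ts.n_timepoints:
        raise ValueError(
            f"motion has {motion.n_timepoints} timepoints, run has {ts.n_timepoints}"
        )
    m = motion.values
    keep = m.std(axis=0) > 0
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        warnings.warn(
            f"dropping constant motion column(s) {dropped.tolist()} from nuisance design",
            stacklevel=2,
        )
        m = m[:, keep]
    design = np.column_stack([np.ones(ts.n_timepoints), m])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the best-fit line (on sample index) from each column."""
    if ts.n_timepoints < 3:
        raise ValueError("linear detrend needs T >= 3")
    t = np.arange(ts.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def zscore(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize each column to mean 0, sample sd (ddof=1) 1."""
    mu = ts.values.mean(axis=0)
    sd = ts.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.roi_labels[i] for i in bad]
        raise ValueError(f"zero-variance ROI column(s): {names}")
    return ts.with_values((ts.values - mu) / sd)


def preprocess_run(ts: RoiTimeSeries, motion: MotionRegressors | None = None) -> RoiTimeSeries:
    """Full cleaning chain: nuisance regression, linear detrend, z-score.

    The nuisance and trend terms are projected out in a single joint
    least-squares step (design [intercept, t, motion]); sequential
    projections would let the detrend step reintroduce motion components,
    breaking idempotence. The result is exactly orthogonal to every motion
    regressor and to the linear trend, then z-scored.
    """
    t = np.arange(ts.n_timepoints, dtype=float)
    cols = [np.ones_like(t), t]
    if motion is not None:
        if motion.n_timepoints != ts.n_timepoints:
            raise ValueError(
                f"motion has {motion.n_timepoints} timepoints, run has {ts.n_timepoints}"
            )
        m = motion.values
        keep = m.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping constant motion column(s) "
                f"{np.flatnonzero(~keep).tolist()} from nuisance design",
                stacklevel=2,
            )
            m = m[:, keep]
        cols.append(m)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return zscore(ts.with_values(ts.values - design @ beta))
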