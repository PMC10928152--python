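"""Core in-memory containers shared across the pipeline.

A run of task fMRI is reduced upstream to one time series per region of
interest (ROI); everything in this package operates on those T x D matrices.
A latent brain state is a multivariate Gaussian over the D ROIs: its mean is
read as an activation profile, its covariance as functional connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "MotionRegressors",
    "BrainState",
    "StatePosterior",
]


@dataclass
class RoiTimeSeries:
    """One run's T x D ROI time-series matrix.

    Parameters
    ----------
    values : (T, D) array
        One column per ROI. Arbitrary BOLD-like units before preprocessing,
        z-units after.
    roi_labels : sequence of str
        Ordered ROI names, length D.
    tr : float
        Sampling interval in seconds.
    """

    values: np.ndarray
    roi_labels: tuple[str, ...]
    tr: float = 1.0
    subject_id: str = ""
    task_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = tuple(str(r) for r in self.roi_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        t, d = self.values.shape
        if t < 2 or d < 2:
            raise ValueError(f"need T >= 2 and D >= 2, got T={t}, D={d}")
        if d != len(self.roi_labels):
            raise ValueError(
                f"{d} columns but {len(self.roi_labels)} ROI labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "RoiTimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class MotionRegressors:
    """Per-run head-motion parameters: 3 translations (mm), 3 rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion regressors must be a T x 6 matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion regressors contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


def _check_spd(cov: np.ndarray, label: str = "covariance") -> None:
    if not np.allclose(cov, cov.T, atol=1e-10 * (1.0 + np.abs(cov).max())):
        raise ValueError(f"{label} is not symmetric")
    eigmin = np.linalg.eigvalsh(cov)[0]
    if eigmin <= 0:
        raise ValueError(f"{label} is not positive definite (min eig {eigmin:g})")


@dataclass
class BrainState:
    """A latent brain state: Gaussian over ROIs.

    ``mean`` is the activation profile (z-units), ``cov`` the functional
    connectivity pattern. ``cov`` must be symmetric positive definite.
    """

    state_id: int
    mean: np.ndarray
    cov: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        self.roi_labels = tuple(str(r) for r in self.roi_labels)
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError("mean and cov dimensions disagree")
        if len(self.roi_labels) != d:
            raise ValueError("roi_labels length must equal dimension")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("state mean contains non-finite values")
        _check_spd(self.cov, f"state {self.state_id} covariance")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class StatePosterior:
    """Temporal posterior probability (TPP): T x K matrix for one run.

    Row t gives p(state k at time t | run, model); rows sum to 1.
    """

    tpp: np.ndarray
    subject_id: str = ""
    task_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.tpp = np.asarray(self.tpp, dtype=float)
        if self.tpp.ndim != 2:
            raise ValueError("tpp must be T x K")
        if np.any(self.tpp < -1e-12) or np.any(self.tpp > 1 + 1e-12):
            raise ValueError("tpp entries must lie in [0, 1]")
        rowsum = self.tpp.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-8):
            raise ValueError("tpp rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.tpp.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.tpp.shape[0]
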