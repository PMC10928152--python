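"""Temporal and spatial summaries of fitted brain states.

Occupancy rate (OR) is the fraction of a run's time a state occurs. The
primary variant hard-assigns each timepoint to its maximum-posterior state;
the mean-posterior variant averages the TPP column instead. Both sum to one
across states and both are reported, since soft occupancy is the natural
reading when posteriors are diffuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import StatePosterior
from .hmm import StateModel

__all__ = ["occupancy_rates", "occupancy_table", "state_sequence",
           "empirical_transition_matrix", "export_state_profiles"]

log = logging.getLogger(__name__)


def occupancy_rates(posterior: StatePosterior) -> tuple[np.ndarray, np.ndarray]:
    """(hard OR, mean-posterior OR) for one run, each a K-vector summing to 1.

    Ties at a timepoint go to the lowest state index (argmax convention);
    the tie count is logged.
    """
    tpp = posterior.tpp
    k = tpp.shape[1]
    row_max = tpp.max(axis=1, keepdims=True)
    n_ties = int(np.sum((tpp == row_max).sum(axis=1) > 1))
    if n_ties:
        log.info("occupancy_rates: %d timepoint(s) with tied posteriors; "
                 "lowest state index wins", n_ties)
    labels = tpp.argmax(axis=1)
    hard = np.bincount(labels, minlength=k).astype(float) / tpp.shape[0]
    soft = tpp.mean(axis=0)
    return hard, soft


def occupancy_table(posteriors: list[StatePosterior],
                    kind: str = "hard") -> pd.DataFrame:
    """Subjects x states occupancy table (rows ordered by subject id)."""
    if kind not in ("hard", "soft"):
        raise ValueError("kind must be 'hard' or 'soft'")
    rows = []
    for p in sorted(posteriors, key=lambda p: (p.subject_id, p.run_id)):
        hard, soft = occupancy_rates(p)
        occ = hard if kind == "hard" else soft
        rows.append({"subject": p.subject_id,
                     **{f"state_{k}": occ[k] for k in range(len(occ))}})
    return pd.DataFrame(rows)


def state_sequence(posterior: StatePosterior) -> np.ndarray:
    """Hard (argmax-TPP) state label sequence for one run."""
    return posterior.tpp.argmax(axis=1)


def empirical_transition_matrix(labels: np.ndarray, n_states: int | None = None
                                ) -> np.ndarray:
    """Row-normalized transition counts of a label sequence.

    Rows of never-left states (zero outgoing counts) become uniform and are
    logged — they carry no information, not probability mass.
    """
    labels = np.asarray(labels, dtype=int)
    k = int(n_states if n_states is not None else labels.max() + 1)
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    rowsum = counts.sum(axis=1)
    empty = rowsum == 0
    if empty.any():
        log.info("empirical_transition_matrix: state(s) %s never visited "
                 "before the final timepoint; rows set uniform",
                 np.flatnonzero(empty).tolist())
        counts[empty] = 1.0
        rowsum[empty] = k
    return counts / rowsum[:, None]


def export_state_profiles(model: StateModel, outdir: str | Path) -> list[Path]:
    """Write each state's activation profile and connectivity matrix as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    means = pd.DataFrame(model.means(), columns=model.roi_labels)
    means.insert(0, "state", [s.state_id for s in model.states])
    p = outdir / "state_means.tsv"
    means.to_csv(p, sep="\t", index=False, float_format="%.17g")
    written.append(p)
    for s in model.states:
        cov = pd.DataFrame(s.cov, columns=model.roi_labels)
        cov.insert(0, "roi", model.roi_labels)
        p = outdir / f"state_{s.state_id}_cov.tsv"
        cov.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)
    return written
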