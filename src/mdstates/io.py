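"""Plain-text I/O: ROI runs as TSV, motion as whitespace text, tables as TSV.

All on-disk formats are text so that simulated cohorts and fitted results can
be inspected, versioned and diffed. Floats are written with repr-level
precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MotionRegressors, RoiTimeSeries

_FLOAT_FMT = "%.17g"


def write_run_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a run as TSV: header row of ROI labels, T rows x D columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(ts.roi_labels)
    np.savetxt(path, ts.values, fmt=_FLOAT_FMT, delimiter="\t",
               header=header, comments="")


def read_run_tsv(path: str | Path, tr: float = 1.0, **ids: str) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return RoiTimeSeries(values=df.to_numpy(dtype=float),
                         roi_labels=tuple(df.columns), tr=tr, **ids)


def write_motion_txt(motion: MotionRegressors, path: str | Path) -> None:
    """Write motion parameters as 6 whitespace-delimited columns, no header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, motion.values, fmt=_FLOAT_FMT)


def read_motion_txt(path: str | Path) -> MotionRegressors:
    return MotionRegressors(values=np.loadtxt(path, ndmin=2))


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_jsonify(obj), sort_keys=True))


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())
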