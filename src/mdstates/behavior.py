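"""Task cognitive-control indices, race-model SSRT, and paired contrasts.

Each task contributes one scalar control index per subject, oriented so that
*larger always means better cognitive control*:

====================  =====================================================
task                  index
====================  =====================================================
axcpt                 z(AY RT) - z(BX RT)  (proactive-control composite)
cuedts / stroop       -(incongruent - congruent) RT  (negated congruency cost)
sternberg / rp        accuracy / RT on the demanding condition, z-scored
sst                   1000 / SSRT  (stopping speed, 1/s)
====================  =====================================================

The congruency-cost sign is negated so that a smaller cost (better control)
yields a larger index; the raw signed cost is also returned. SSRT uses the
integration method of the independent race model: the n-th percentile of the
go RT distribution at n = P(respond | stop), minus the mean stop-signal
delay, with go omissions replaced by the maximum go RT (the consensus
convention). A mean-method variant is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["estimate_ssrt", "control_index", "paired_condition_test",
           "SsrtResult", "PairedTestResult"]

TASKS = ("axcpt", "cuedts", "sternberg", "stroop", "sst", "rp")


@dataclass
class SsrtResult:
    ssrt: float                  # ms; NaN when inestimable
    p_respond: float
    mean_ssd: float
    n_stop: int
    estimable: bool
    method: str = "integration"


def estimate_ssrt(trials: pd.DataFrame, method: str = "integration") -> SsrtResult:
    """Race-model SSRT from a trial table.

    ``trials`` needs columns ``trial_type`` (go/stop), ``rt`` (ms; NaN for
    omissions and successful stops), ``ssd`` (ms, stop trials) and
    ``responded`` (bool). Inestimable when P(respond|stop) is 0 or 1.
    """
    stop = trials[trials["trial_type"] == "stop"]
    go = trials[trials["trial_type"] == "go"]
    n_stop = len(stop)
    if n_stop < 20:
        raise ValueError(f"need >= 20 stop trials, got {n_stop}")
    p_resp = float(stop["responded"].mean())
    mean_ssd = float(stop["ssd"].mean())
    if p_resp <= 0.0 or p_resp >= 1.0:
        return SsrtResult(ssrt=math.nan, p_respond=p_resp, mean_ssd=mean_ssd,
                          n_stop=n_stop, estimable=False, method=method)
    go_rts = go["rt"].to_numpy(dtype=float)
    if len(go_rts) == 0:
        raise ValueError("no go trials")
    # omissions take the maximum observed go RT before the percentile
    if np.isnan(go_rts).all():
        raise ValueError("all go trials are omissions")
    go_rts = np.where(np.isnan(go_rts), np.nanmax(go_rts), go_rts)
    go_sorted = np.sort(go_rts)
    if method == "integration":
        idx = max(int(math.ceil(p_resp * len(go_sorted))) - 1, 0)
        ssrt = float(go_sorted[idx] - mean_ssd)
    elif method == "mean":
        ssrt = float(go_sorted.mean() - mean_ssd)
    else:
        raise ValueError(f"unknown SSRT method {method!r}")
    return SsrtResult(ssrt=ssrt, p_respond=p_resp, mean_ssd=mean_ssd,
                      n_stop=n_stop, estimable=True, method=method)


def _z(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("zero variance across subjects; cannot standardize")
    return (x - x.mean()) / sd


def _need(table: pd.DataFrame, cols: list[str], task: str) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"{task}: missing required column(s) {missing}")


def control_index(task: str, table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cognitive-control index for one task.

    ``table`` has one row per subject with the task's summary fields (see
    module docstring). Returns a frame with ``subject``, ``index`` and any
    task-specific raw values (e.g. the signed congruency cost).
    """
    task = task.lower()
    out = pd.DataFrame({"subject": table["subject"]})
    if task == "axcpt":
        _need(table, ["ay_rt", "bx_rt"], task)
        out["index"] = _z(table["ay_rt"]) - _z(table["bx_rt"])
    elif task in ("cuedts", "stroop"):
        _need(table, ["congruent_rt", "incongruent_rt"], task)
        cost = table["incongruent_rt"] - table["congruent_rt"]
        out["congruency_cost"] = cost
        out["index"] = -cost
    elif task in ("sternberg", "rp"):
        acc_col = "high_load_acc" if task == "sternberg" else "relational_acc"
        rt_col = "high_load_rt" if task == "sternberg" else "relational_rt"
        _need(table, [acc_col, rt_col], task)
        eff = table[acc_col] / table[rt_col]
        out["efficiency"] = eff
        out["index"] = _z(eff)
    elif task == "sst":
        _need(table, ["ssrt"], task)
        if (table["ssrt"] <= 0).any():
            raise ValueError("sst: non-positive SSRT")
        out["index"] = 1000.0 / table["ssrt"]     # 1/s
    else:
        raise ValueError(f"unknown task {task!r}; known: {TASKS}")
    return out


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    defined: bool = True


def paired_condition_test(x: np.ndarray, y: np.ndarray,
                          d_kind: str = "dz") -> PairedTestResult:
    """Two-tailed paired t-test with Cohen's d.

    Default effect size is d_z = mean(diff)/sd(diff); ``d_kind='pooled'``
    divides by the pooled condition sd instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of n >= 3")
    diff = x - y
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        return PairedTestResult(t=math.nan, df=n - 1,
                                p=1.0 if np.allclose(diff, 0) else math.nan,
                                cohens_d=0.0 if np.allclose(diff, 0) else math.nan,
                                mean_diff=float(diff.mean()), defined=False)
    t = float(diff.mean() / (sd / math.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    if d_kind == "dz":
        d = float(diff.mean() / sd)
    elif d_kind == "pooled":
        pooled = math.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        d = float(diff.mean() / pooled)
    else:
        raise ValueError(f"unknown d_kind {d_kind!r}")
    return PairedTestResult(t=t, df=n - 1, p=p, cohens_d=d,
                            mean_diff=float(diff.mean()))
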