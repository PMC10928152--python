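"""End-to-end orchestration: simulate -> preprocess -> fit -> transfer ->
match -> lesion -> metrics -> relate, from one seeded configuration.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same configuration reproduces the outputs byte for byte. The stage order
mirrors the analysis design: a reference task's model supplies the reference
state, every other task is fit independently, and correspondence is decided
by state space closeness and state temporal closeness together.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .brain_behavior import cca, predictive_cca_loo, specificity_screen, \
    univariate_state_behavior
from .containers import RoiTimeSeries
from .dynamics import occupancy_table
from .hmm import FitConfig, StateModel, apply_model, fit, save_model
from .io import write_json, write_run_tsv, write_table_tsv
from .lesion import lesion_profile
from .matching import MatchReport, match_states, state_space_closeness
from .preprocess import preprocess_run
from .simulate import SimulationConfig, SimulatedCohort, generate_multitask_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reference_task: str | None = None      # defaults to simulation.reference_task
    reference_state: int | str = "auto"    # fitted state index, or "auto"
    K_init: int = 15
    n_restarts: int = 5
    n_perm: int = 100
    seed: int = 0
    preprocess: bool = True
    alpha: float = 0.05
    output_dir: str | None = None

    def resolved_reference_task(self) -> str:
        return self.reference_task or self.simulation.reference_task


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: SimulatedCohort
    models: dict[str, StateModel]
    posteriors: dict[str, list]
    reference_state_id: int
    matches: dict[str, MatchReport]
    occupancy: dict[str, pd.DataFrame]
    lesions: dict[str, pd.DataFrame]
    relations: dict[str, dict]
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _auto_reference_state(model: StateModel, cohort: SimulatedCohort,
                          task: str) -> int:
    """Fitted state closest (smallest symmetrized KL) to the planted one."""
    truth = cohort.truth
    if truth.shared_state_id is None:
        raise ValueError("reference_state='auto' needs a planted shared state")
    target = truth.brain_state(task, truth.shared_state_id[task])
    c = [state_space_closeness(target, s).c for s in model.states]
    return int(np.argmax(c))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on a simulated cohort; optionally write all outputs."""
    sim = config.simulation
    ref_task = config.resolved_reference_task()
    if ref_task not in sim.tasks:
        raise ValueError(f"reference task {ref_task!r} not in {sim.tasks}")

    log.info("stage simulate: %d subjects x %d tasks", sim.n_subjects,
             len(sim.tasks))
    cohort = generate_multitask_cohort(sim)

    runs: dict[str, list[RoiTimeSeries]] = {}
    for task in sim.tasks:
        task_runs = cohort.task_runs(task)
        if config.preprocess:
            keys = sorted(k for k in cohort.runs if k[1] == task)
            task_runs = [
                preprocess_run(r, cohort.motion[k])
                for r, k in zip(task_runs, keys)
            ]
        runs[task] = task_runs

    models: dict[str, StateModel] = {}
    posteriors: dict[str, list] = {}
    for i, task in enumerate(sim.tasks):
        fc = FitConfig(n_restarts=config.n_restarts,
                       seed=(config.seed * 613 + i) % (2**31 - 1))
        log.info("stage fit: task %s (K_init=%d)", task, config.K_init)
        models[task], posteriors[task] = fit(runs[task], K_init=config.K_init,
                                             config=fc)
        log.info("  K_effective=%d, pruned=%d", models[task].K_effective,
                 models[task].fit_diagnostics["n_pruned"])

    if config.reference_state == "auto":
        ref_state = _auto_reference_state(models[ref_task], cohort, ref_task)
    else:
        ref_state = int(config.reference_state)

    matches: dict[str, MatchReport] = {}
    lesions: dict[str, pd.DataFrame] = {}
    for j, task in enumerate(t for t in sim.tasks if t != ref_task):
        log.info("stage match: %s vs reference %s", task, ref_task)
        matches[task] = match_states(
            ref_state, models[ref_task], models[task], runs[task],
            n_perm=config.n_perm, seed=(config.seed * 271 + j) % (2**31 - 1),
            target_posteriors=posteriors[task])
        rep = matches[task]
        lesions[task] = lesion_profile(
            models[ref_task].states[ref_state],
            models[task].states[rep.matched_state_id]).table()

    occupancy = {task: occupancy_table(posteriors[task]) for task in sim.tasks}

    relations: dict[str, dict] = {}
    for task in sim.tasks:
        occ = occupancy[task].drop(columns="subject").to_numpy()
        index = cohort.behavior[f"{task}_index"].to_numpy()
        state_id = (ref_state if task == ref_task
                    else matches[task].matched_state_id)
        rel: dict = {"matched_state": state_id}
        r, p = univariate_state_behavior(occ[:, state_id], index)
        rel["univariate_r"], rel["univariate_p"] = r, p
        screen = specificity_screen(occ, index, alpha=config.alpha)
        rel["specificity"] = screen.to_dict(orient="list")
        rel["specificity_exactly_one"] = screen.attrs["exactly_one"]
        if occ.shape[0] > occ.shape[1] + 2:
            res = cca(occ, index[:, None], orientation=index,
                      n_perm=config.n_perm, seed=config.seed)
            loo_r, loo_p = predictive_cca_loo(occ, index[:, None],
                                              orientation=index)
            rel["cca_r"] = float(res.correlations[res.selected_component])
            rel["cca_p"] = res.p_value
            rel["loo_predicted_r"], rel["loo_p"] = loo_r, loo_p
        relations[task] = rel

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "tasks": list(sim.tasks),
        "reference_task": ref_task,
        "reference_state": ref_state,
        "K_effective": {t: models[t].K_effective for t in sim.tasks},
        "pruned_states": {t: models[t].fit_diagnostics["n_pruned"]
                          for t in sim.tasks},
    }
    result = PipelineResult(config=config, cohort=cohort, models=models,
                            posteriors=posteriors, reference_state_id=ref_state,
                            matches=matches, occupancy=occupancy,
                            lesions=lesions, relations=relations,
                            manifest=manifest)
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for task, model in result.models.items():
        save_model(model, outdir / f"model_{task}.json")
    for task, rep in result.matches.items():
        write_json(rep.summary(), outdir / f"match_{task}.json")
        write_table_tsv(
            pd.DataFrame({
                "target_state": range(len(rep.closeness)),
                "c": [c.c for c in rep.closeness],
                "divergence": [c.divergence_value for c in rep.closeness],
                "r": rep.temporal_r,
            }),
            outdir / f"match_{task}_metrics.tsv")
    for task, occ in result.occupancy.items():
        write_table_tsv(occ, outdir / f"occupancy_{task}.tsv")
    for task, les in result.lesions.items():
        write_table_tsv(les, outdir / f"lesion_{task}.tsv")
    write_json(result.relations, outdir / "relations.json")
    for task, rel in result.relations.items():
        occ = result.occupancy[task]
        write_table_tsv(
            pd.DataFrame({
                "subject": occ["subject"],
                "occupancy": occ[f"state_{rel['matched_state']}"],
                "behavior_index": result.cohort.behavior[f"{task}_index"],
            }),
            outdir / f"scatter_{task}.tsv")
    write_table_tsv(result.cohort.behavior, outdir / "behavior.tsv")
    write_json(result.manifest, outdir / "manifest.json")
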