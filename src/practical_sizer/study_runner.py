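"""Orchestrate the simulation study: scenarios x sample sizes x replicates.

For each grid cell, `run_study` simulates ``replicates`` trials, analyzes
each with the appropriate ranking model, scores the three performance
measures, and aggregates them.  Each replicate draws its random stream from
a seed sequence derived deterministically from (master seed, scenario, n,
replicate index), so every replicate is individually reproducible and
results do not depend on the parallelism degree or scheduling.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .estimation import (
    fit_pattern_adjusted_logistic,
    fit_two_stage_weighted_logistic,
    predict_risks,
)
from .performance import (
    DEFAULT_KAPPAS,
    PerformanceSummary,
    ReplicateMeasures,
    estimated_best,
    replicate_measures,
    single_stage_truth,
    strategy_truth,
    summaries_to_frame,
    summarize,
)
from .practical_simulator import simulate_single_stage_trial
from .scenario_model import (
    SingleStageScenario,
    SmartScenario,
    build_strategy_risk_table,
    load_scenario,
    preset_scenario,
)
from .smart_simulator import simulate_smart_trial

__all__ = ["StudyConfig", "run_study", "run_cell", "export_figure_data", "FIGURES"]

logger = logging.getLogger(__name__)

# Figure -> (design, measure, kappa, canonical scenario set)
FIGURES: dict[str, dict] = {
    "F1": {"design": "practical", "measure": "percent_reduction", "kappa": None},
    "F2": {"design": "practical", "measure": "near_best", "kappa": 0.02},
    "F3": {"design": "practical", "measure": "improvement_over_random", "kappa": None},
    "F5": {"design": "smart", "measure": "percent_reduction", "kappa": None},
    "F6": {"design": "smart", "measure": "near_best", "kappa": 0.02},
    "F7": {"design": "smart", "measure": "improvement_over_random", "kappa": None},
}
_FIGURE_SCENARIOS = {
    "practical": (
        "base_case", "larger_effects", "smaller_effects", "reversed_effects",
        "pattern4", "sparse", "unequal_frequencies",
    ),
    "smart": ("smart_base_q25", "smart_unequal", "smart_q10", "smart_q50", "smart_q75"),
}


@dataclass
class StudyConfig:
    """Configuration of one simulation study run."""

    design: str                      # "practical" | "smart"
    scenarios: Sequence[str]         # preset names or JSON file paths
    n_grid: Sequence[int]
    replicates: int = 1000
    seed: int = 0
    kappas: Sequence[float] = DEFAULT_KAPPAS
    n_jobs: int = 1
    clone_outcomes: str = "copied"

    def __post_init__(self) -> None:
        if self.design not in ("practical", "smart"):
            raise ValueError("design must be 'practical' or 'smart'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(int(n) < 1 for n in self.n_grid):
            raise ValueError("sample sizes must be positive integers")

    def manifest(self) -> dict:
        return {
            "version": __version__,
            "design": self.design,
            "scenarios": list(self.scenarios),
            "n_grid": [int(n) for n in self.n_grid],
            "replicates": self.replicates,
            "seed": self.seed,
            "kappas": list(self.kappas),
            "clone_outcomes": self.clone_outcomes,
        }


def _resolve(name: str):
    try:
        return preset_scenario(name)
    except Exception:
        return load_scenario(name)


def _replicate_seed(master_seed: int, scenario_name: str, n: int, r: int):
    tag = zlib.crc32(scenario_name.encode())
    return np.random.SeedSequence((int(master_seed), tag, int(n), int(r)))


def _one_single_stage(scenario, truth, n, seed, kappas) -> ReplicateMeasures:
    data = simulate_single_stage_trial(scenario, n, seed)
    fit = fit_pattern_adjusted_logistic(data)
    choice = estimated_best(predict_risks(fit, scenario))
    return replicate_measures(
        truth, choice, data.lambda_hat, kappas,
        penalized=fit.penalized, converged=fit.converged,
    )


def _one_smart(smart, truth, n, seed, kappas, clone_outcomes) -> ReplicateMeasures:
    data = simulate_smart_trial(smart, n, seed, clone_outcomes=clone_outcomes)
    fit = fit_two_stage_weighted_logistic(data)
    choice = estimated_best(predict_risks(fit, smart))
    return replicate_measures(
        truth, choice, data.lambda_hat, kappas,
        penalized=fit.penalized, converged=fit.converged,
    )


def _never_raise(func):
    """Per-replicate guard: a failed fit (e.g. a tiny trial whose observed
    design is disconnected) is logged and dropped, never aborts the grid."""

    def wrapped(*a):
        try:
            return func(*a)
        except Exception as exc:  # noqa: BLE001 - any replicate-level failure
            logger.warning("replicate failed: %s", exc)
            return None

    return wrapped


def run_cell(
    scenario,
    n: int,
    replicates: int,
    master_seed: int,
    kappas: Sequence[float] = DEFAULT_KAPPAS,
    n_jobs: int = 1,
    clone_outcomes: str = "copied",
) -> PerformanceSummary:
    """Simulate, analyze and score ``replicates`` trials of size ``n``."""
    smart = isinstance(scenario, SmartScenario)
    name = scenario.name
    seeds = [_replicate_seed(master_seed, name, n, r) for r in range(replicates)]
    if smart:
        truth = strategy_truth(build_strategy_risk_table(scenario))
        func = _one_smart
        args = [(scenario, truth, n, s, kappas, clone_outcomes) for s in seeds]
    else:
        truth = single_stage_truth(scenario)
        func = _one_single_stage
        args = [(scenario, truth, n, s, kappas) for s in seeds]
    safe = _never_raise(func)
    if n_jobs == 1:
        measures = [safe(*a) for a in args]
    else:
        measures = Parallel(n_jobs=n_jobs)(delayed(safe)(*a) for a in args)
    failed = sum(m is None for m in measures)
    measures = [m for m in measures if m is not None]
    if not measures:
        raise RuntimeError(f"all {replicates} replicate fits failed for {name} at n={n}")
    summary = summarize(
        measures, scenario=name, design="smart" if smart else "practical", n=n
    )
    if failed:
        logger.warning("scenario=%s n=%d: %d replicate fit(s) failed and were dropped",
                       name, n, failed)
    logger.info(
        "scenario=%s n=%d replicates=%d penalized=%d nonconverged=%d failed=%d",
        name, n, len(measures), summary.n_penalized, summary.n_nonconverged, failed,
    )
    return summary


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full grid and return long-format results.

    Columns: scenario, design, n, measure, kappa, estimate, mc_se,
    replicates.  Fully determined by (config, seed).
    """
    summaries: list[PerformanceSummary] = []
    for name in config.scenarios:
        scenario = _resolve(name)
        is_smart = isinstance(scenario, SmartScenario)
        if is_smart != (config.design == "smart"):
            raise ValueError(
                f"scenario {name!r} is a {'SMART' if is_smart else 'single-stage'} "
                f"scenario but the study design is {config.design!r}"
            )
        for n in config.n_grid:
            summaries.append(
                run_cell(
                    scenario, int(n), config.replicates, config.seed,
                    kappas=tuple(config.kappas), n_jobs=config.n_jobs,
                    clone_outcomes=config.clone_outcomes,
                )
            )
    return summaries_to_frame(summaries)


def export_figure_data(
    summary: pd.DataFrame,
    figure: str,
    scenarios: Sequence[str] | None = None,
    path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Extract one figure's plot-ready table: one curve per scenario over n.

    ``figure`` is one of F1-F3 (single-stage percent reduction, near-best
    within 2 pp, improvement over random) or F5-F7 (the SMART analogues).
    Requested scenarios missing from the summary abort the export with an
    error listing them.  ``plot_path`` optionally renders a simple line plot
    (requires matplotlib).
    """
    if figure not in FIGURES:
        raise ValueError(f"unknown figure {figure!r}; known: {', '.join(FIGURES)}")
    spec_ = FIGURES[figure]
    scenarios = tuple(scenarios) if scenarios is not None else _FIGURE_SCENARIOS[spec_["design"]]
    sel = summary[
        (summary["design"] == spec_["design"]) & (summary["measure"] == spec_["measure"])
    ]
    if spec_["kappa"] is not None:
        sel = sel[np.isclose(sel["kappa"].astype(float), spec_["kappa"])]
    missing = [s for s in scenarios if s not in set(sel["scenario"])]
    if missing:
        raise ValueError(f"summary is missing scenarios for {figure}: {', '.join(missing)}")
    out = (
        sel[sel["scenario"].isin(scenarios)][["scenario", "n", "estimate", "mc_se"]]
        .rename(columns={"estimate": spec_["measure"]})
        .sort_values(["scenario", "n"])
        .reset_index(drop=True)
    )
    if path is not None:
        out.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, grp in out.groupby("scenario"):
            ax.plot(grp["n"], grp[spec_["measure"]], marker="o", label=name)
        ax.set_xlabel("sample size n")
        ax.set_ylabel(spec_["measure"])
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return out


def write_manifest(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.manifest(), fh, indent=2)
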