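"""Canned experiment drivers behind the results tables.

These functions bundle task generation, training and evaluation for the
standard experiment grids: performance tables for the three tasks and the
connection-fraction table.  The full protocol (100 / 20,000 steps per
alternation, 200 alternations) is the published schedule; the reduced
protocol used for routine runs keeps the stage structure but shortens the
second stage and the number of alternations (100 alternations of
100 + 1,500 steps), which pilot runs showed is where the scaled model's
reward and connection fraction have plateaued.
"""

from __future__ import annotations

import numpy as np

from .config import NetworkConfig, PlasticityToggles, TrainProtocol
from .evaluation import EvalReport, report_from_inference
from .tasks import (MOTION_GENERATION, MOTION_PREDICTION,
                    make_counting_sequence, make_motion_sequence)
from .training import Model, TrainHistory, infer, train


def full_protocol() -> TrainProtocol:
    """The published two-stage schedule."""
    return TrainProtocol(stage1_steps=100, stage2_steps=20000,
                         alternations=200)


def reduced_protocol(alternations: int = 100,
                     stage2_steps: int = 1500) -> TrainProtocol:
    """Shortened schedule for routine runs; same stage structure."""
    return TrainProtocol(stage1_steps=100, stage2_steps=stage2_steps,
                         alternations=alternations)


def default_p_c(n_excitatory: int) -> float:
    """Best-performing initial connection fraction per network size."""
    return 0.05 if n_excitatory <= 200 else 0.0125


def make_task(task: str, n: int, m: int = 500):
    if task == "counting":
        return make_counting_sequence(n, m)
    if task == "motion":
        return make_motion_sequence(n, m, MOTION_PREDICTION)
    if task == "generation":
        return make_motion_sequence(n, m, MOTION_GENERATION)
    raise ValueError(f"unknown task {task!r}")


def run_experiment(task: str, n: int, n_excitatory: int, seed: int,
                   p_c: float | None = None,
                   protocol: TrainProtocol | None = None,
                   eval_steps: int = 600, eval_warmup: int = 120,
                   config_overrides: dict | None = None,
                   ) -> tuple[EvalReport, TrainHistory, Model]:
    """Train one network on one task and evaluate it with plasticity off."""
    seq = make_task(task, n)
    cfg = NetworkConfig(
        n_excitatory=n_excitatory,
        p_c=p_c if p_c is not None else default_p_c(n_excitatory),
        seed=seed,
        **(config_overrides or {}),
    )
    model = Model.for_task(cfg, seq)
    proto = protocol or reduced_protocol()
    history = train(model, proto, seq)
    result = infer(model, seq, steps=eval_steps, warmup=eval_warmup)
    report = report_from_inference(result, N=n_excitatory, seed=seed)
    return report, history, model


def performance_grid(task: str, n_values, n_excitatory: int, seeds,
                     protocol: TrainProtocol | None = None,
                     p_c: float | None = None) -> dict:
    """Mean +/- std of the task metric over seeds, per n."""
    metric = {"counting": "counting", "motion": "overall",
              "generation": "generation"}[task]
    out = {}
    for n in n_values:
        vals = []
        for seed in seeds:
            report, _, _ = run_experiment(task, n, n_excitatory, seed,
                                          p_c=p_c, protocol=protocol)
            vals.append(getattr(report, metric))
        out[n] = (float(np.mean(vals)), float(np.std(vals)))
    return out


def connection_fraction_experiment(p_c0: float, n_values, seeds,
                                   n_excitatory: int = 200,
                                   protocol: TrainProtocol | None = None,
                                   ) -> dict:
    """Final E-E connection fraction after training, per (n, seed)."""
    out = {}
    for n in n_values:
        for seed in seeds:
            _, history, model = run_experiment(
                "counting", n, n_excitatory, seed, p_c=p_c0,
                protocol=protocol)
            out[(n, seed)] = model.connection_fraction()
    return out


def sp_ablation(n: int, n_excitatory: int, p_c0: float, seeds,
                protocol: TrainProtocol | None = None) -> dict:
    """Counting performance with vs. without structural plasticity."""
    out = {"sp_on": [], "sp_off": []}
    base = protocol or reduced_protocol()
    for key, structural in (("sp_on", True), ("sp_off", False)):
        proto = base.replace(
            toggles=PlasticityToggles(structural=structural))
        for seed in seeds:
            report, _, _ = run_experiment("counting", n, n_excitatory,
                                          seed, p_c=p_c0, protocol=proto)
            out[key].append(report.counting)
    return out


_TABLE_GRIDS = {
    "table2": ("counting", [4, 8, 12, 16, 20]),
    "table3": ("motion", [4, 8, 12, 16, 20]),
    "table4": ("generation", [4, 8, 12, 16, 20]),
}


def reproduce_table(table_id: str, reduced: bool = True,
                    n_seeds: int = 2) -> str:
    """Re-run one results-table grid; returns a TSV-formatted table."""
    seeds = list(range(n_seeds))
    proto = reduced_protocol() if reduced else full_protocol()
    lines = []
    if table_id in _TABLE_GRIDS:
        task, n_values = _TABLE_GRIDS[table_id]
        if reduced:
            n_values = n_values[:2]
        lines.append("N\t" + "\t".join(f"n={n}" for n in n_values))
        for N in (200, 400):
            cells = []
            for n in n_values:
                grid = performance_grid(task, [n], N, seeds, protocol=proto)
                mean, std = grid[n]
                cells.append(f"{100 * mean:.2f}+-{100 * std:.2f}")
            lines.append(f"{N}\t" + "\t".join(cells))
    elif table_id == "table5":
        n_values = [4, 8] if reduced else [4, 8, 12, 16, 20, 24, 28, 32]
        lines.append("p_c(0)\tp_c(1)\trel_change")
        for p0 in (0.002, 0.01, 0.1, 0.2):
            res = connection_fraction_experiment(p0, n_values, seeds)
            vals = np.array(list(res.values()))
            rel = (vals.mean() - p0) / p0
            lines.append(f"{p0}\t{vals.mean():.4f}\t{100 * rel:+.0f}%")
    else:
        raise ValueError(f"unknown table id {table_id!r}")
    return "\n".join(lines) + "\n"
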