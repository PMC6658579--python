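"""Scenario orchestration: dispatch, trace collection, outputs.

`run_scenario` executes one validated scenario end-to-end and returns a
RunSummary whose key metrics are all traceable to the collected trace
tables; `write_outputs` persists traces as CSV, the summary as JSON, and
echoes the effective config next to them so every default is auditable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from itertools import repeat
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig, write_config
from .dialogue import Agent, perturb_agent, run_dialogue
from .drive import compare_conditions
from .inversion import (
    InversionConfig,
    invert,
    operator_from_component,
    stability_map,
)
from .loop import run_external, run_internal_dialogue
from .quality import inversion_quality
from .rng import stream

__all__ = ["RunSummary", "run_scenario", "write_outputs"]

log = logging.getLogger("fitloop")


@dataclass
class RunSummary:
    """Key metrics of one scenario run, traceable to its trace tables."""

    scenario_id: str
    config_hash: str
    seed: int
    metrics: dict
    wall_time_s: float
    traces: dict = field(default_factory=dict, repr=False)


def _inversion_cfg(config: ScenarioConfig, **over) -> InversionConfig:
    cfg = config.inversion.build()
    return replace(cfg, **over) if over else cfg


def _run_invert(config: ScenarioConfig) -> tuple[dict, dict]:
    comp = config.bank.components[0].build(config.seed)
    S = operator_from_component(comp)
    p = np.asarray(
        config.probe if config.probe is not None else np.ones(comp.n), dtype=float
    )
    gains = config.gains or [config.inversion.gain]
    rows = []
    for g in gains:
        res = invert(S, p, _inversion_cfg(config, gain=float(g)))
        log.debug("invert gain=%g residual=%g", g, res.residual)
        rows.append(
            {
                "gain": float(g),
                "residual": res.residual,
                "iterations": res.iterations,
                "converged": res.converged,
                "diverged": res.diverged,
                **{f"q_{i}": v for i, v in enumerate(res.q)},
            }
        )
    frame = pd.DataFrame(rows)
    metrics = {
        "gains": [float(g) for g in gains],
        "residuals": frame["residual"].tolist(),
        "all_converged": bool(frame["converged"].all()),
    }
    return metrics, {"inversions": frame}


def _run_loop(config: ScenarioConfig) -> tuple[dict, dict]:
    comp = config.bank.components[0].build(config.seed)
    loop_cfg = config.loop.build(_inversion_cfg(config))
    u = np.asarray(
        config.u_init if config.u_init is not None else np.ones(comp.m), dtype=float
    )
    trace = run_external(
        comp, repeat(u), config.n_cycles, loop_cfg, rng=stream(config.seed, "loop")
    )
    frame = trace.to_frame()
    rts = frame["roundtrip_error"].dropna()
    metrics = {
        "n_cycles": len(frame),
        "median_roundtrip_error": float(rts.median()) if len(rts) else float("nan"),
        "max_roundtrip_error": float(rts.max()) if len(rts) else float("nan"),
    }
    if trace.records and trace.records[-1]["u_hat"] is not None:
        last = trace.records[-1]
        eps_inv, q_inv = inversion_quality(last["x"], comp, last["u_hat"])
        metrics["quality"] = {"eps_inv": eps_inv, "Q_inv": q_inv}
    return metrics, {"loop_trace": frame}


def _run_internal(config: ScenarioConfig) -> tuple[dict, dict]:
    comp = config.bank.components[0].build(config.seed)
    loop_model = config.loop.model_copy(update={"mode": "internal_dialogue"})
    loop_cfg = loop_model.build(_inversion_cfg(config))
    u0 = np.asarray(
        config.u_init if config.u_init is not None else 0.5 * np.ones(comp.m),
        dtype=float,
    )
    trace = run_internal_dialogue(
        comp, u0, config.n_cycles, loop_cfg, rng=stream(config.seed, "loop")
    )
    u_hats = [r["u_hat"] for r in trace.records if r["u_hat"] is not None]
    changes = [
        float(np.linalg.norm(b - a)) for a, b in zip(u_hats[:-1], u_hats[1:])
    ]
    frame = trace.to_frame()
    frame["change"] = [np.nan] + changes if len(frame) == len(changes) + 1 else np.nan
    metrics = {
        "n_cycles": len(frame),
        "final_change": changes[-1] if changes else float("nan"),
        "truncated": trace.truncated,
    }
    return metrics, {"internal_trace": frame}


def _run_dialogue(config: ScenarioConfig) -> tuple[dict, dict]:
    bank = config.bank.build(config.seed)
    loop_cfg = config.loop.build(_inversion_cfg(config))
    sender = Agent(bank=bank, loop=loop_cfg, role="sender")
    rng = stream(config.seed, "dialogue")
    receiver = replace(
        perturb_agent(sender, config.mismatch_delta, rng), role="receiver"
    )
    channel = config.channel.build()
    u0 = None if config.u_init is None else np.asarray(config.u_init, dtype=float)
    trace = run_dialogue(sender, receiver, channel, config.n_turns, rng, u_init=u0)
    frame = trace.to_frame()
    metrics = {
        "n_turns": len(frame),
        "median_reconstruction_error": float(frame["reconstruction_error"].median()),
        "max_reconstruction_error": float(frame["reconstruction_error"].max()),
        "any_flagged": bool(frame["flagged"].any()),
    }
    return metrics, {"dialogue_trace": frame}


def _run_drive(config: ScenarioConfig) -> tuple[dict, dict]:
    world_cfg = config.world.build()
    drive_cfg = config.drive.build()
    summary = compare_conditions(
        world_cfg, drive_cfg, config.n_seeds, base_seed=config.seed
    )
    frame = pd.DataFrame(
        {
            "seed": [config.seed + i for i in range(config.n_seeds)],
            "f_plus_modulated": summary["f_plus_modulated"],
            "f_plus_control": summary["f_plus_control"],
        }
    )
    metrics = {
        "mean_paired_difference": summary["mean_paired_difference"],
        "p_value_one_sided": summary["p_value_one_sided"],
        "n_seeds": summary["n_seeds"],
    }
    return metrics, {"drive_comparison": frame}


def _run_stability(config: ScenarioConfig) -> tuple[dict, dict]:
    comp = config.bank.components[0].build(config.seed)
    S = operator_from_component(comp)
    p = None if config.probe is None else np.asarray(config.probe, dtype=float)
    table = stability_map(
        S,
        config.gains or [config.inversion.gain],
        config.delays or [0],
        _inversion_cfg(config, mode="dynamical"),
        p=p,
    )
    boundaries = {}
    for g, grp in table.groupby("gain"):
        div = grp[grp["diverged"]]
        boundaries[str(g)] = int(div["delay"].min()) if len(div) else -1
    metrics = {
        "n_cells": len(table),
        "n_diverged": int(table["diverged"].sum()),
        "monotone_violations": int(table["monotone_violation"].sum()),
        "divergence_boundary_delay_per_gain": boundaries,
    }
    return metrics, {"stability_map": table}


_DISPATCH = {
    "invert": _run_invert,
    "loop": _run_loop,
    "internal_dialogue": _run_internal,
    "dialogue": _run_dialogue,
    "drive": _run_drive,
    "stability": _run_stability,
}


def run_scenario(config: ScenarioConfig) -> RunSummary:
    """Execute one scenario and collect its metrics and traces."""
    t0 = time.perf_counter()
    log.info("running scenario %s (%s)", config.id, config.scenario)
    metrics, traces = _DISPATCH[config.scenario](config)
    return RunSummary(
        scenario_id=config.id,
        config_hash=config.config_hash(),
        seed=config.seed,
        metrics=metrics,
        wall_time_s=time.perf_counter() - t0,
        traces=traces,
    )


def write_outputs(
    summary: RunSummary, config: ScenarioConfig, out_dir: str | Path
) -> list[Path]:
    """Persist traces (CSV), summary (JSON) and the effective config.

    Filenames embed the scenario id and seed.  Returns the written paths.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    stem = f"{summary.scenario_id}_seed{summary.seed}"
    written = []
    for name, frame in summary.traces.items():
        p = out / f"{stem}_{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p)
    payload = {
        "scenario_id": summary.scenario_id,
        "config_hash": summary.config_hash,
        "seed": summary.seed,
        "metrics": summary.metrics,
        "wall_time_s": summary.wall_time_s,
    }
    sp = out / f"{stem}_summary.json"
    sp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(sp)
    written.append(write_config(config, out / f"{stem}_config.json"))
    return written
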