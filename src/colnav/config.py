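"""Run configuration, serialization and reporting glue.

A :class:`RunConfig` gathers every tunable parameter with its default, round-
trips losslessly through YAML, and fans one master seed out to per-agent,
per-module child seeds through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maze import Maze, build_tolman_maze, make_fixture_maze  # noqa: F401
from .columns import NetworkParams
from .protocol import ExperimentConfig

log = logging.getLogger("colnav")


@dataclass
class RunConfig:
    """All module parameters with defaults plus the master seed."""

    scale: int = 1
    n_agents: int = 40
    master_seed: int = 0
    use_level2: bool = True
    epsilon_day1: float = 0.5
    epsilon_later: float = 0.05
    trial_timeout_s: float = 600.0
    pc_spacing: float = 5.0
    pc_sigma: float = 7.5
    pc_peak_rate: float = 10.0
    recruit_threshold: float = 0.8
    learning_rate: float = 0.5
    f0: float = 3.0
    noise_floor: float = 0.01
    turn_threshold: float = 0.5
    kmeans_k: int = 3
    out_dir: str = "results"

    def to_experiment_config(self) -> ExperimentConfig:
        params = NetworkParams(
            recruit_threshold=self.recruit_threshold,
            learning_rate=self.learning_rate, f0=self.f0,
            noise_floor=self.noise_floor, turn_threshold=self.turn_threshold)
        return ExperimentConfig(
            scale=self.scale, n_agents=self.n_agents,
            master_seed=self.master_seed, epsilon_day1=self.epsilon_day1,
            epsilon_later=self.epsilon_later, use_level2=self.use_level2,
            trial_timeout_s=self.trial_timeout_s, params=params,
            pc_spacing=self.pc_spacing, pc_sigma=self.pc_sigma,
            pc_peak_rate=self.pc_peak_rate)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())


def load_config(path) -> RunConfig:
    """Load a YAML config; missing keys take defaults, unknown keys warn."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as e:
        raise ValueError(f"malformed config {path}: {e}") from e
    if not isinstance(data, dict):
        raise ValueError(f"malformed config {path}: expected a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        log.warning("ignoring unknown config keys: %s", sorted(unknown))
    return RunConfig(**{k: v for k, v in data.items() if k in known})


def agent_seed(master_seed: int, agent_idx: int) -> int:
    return int(np.random.SeedSequence(
        [master_seed, agent_idx]).generate_state(1)[0] % (2 ** 31))


# -- maze serialization ----------------------------------------------------

def maze_to_text(maze: Maze) -> str:
    """Structured-text maze description (waypoints, corridor cells, blocks,
    gate); YAML so it stays both human-readable and machine-parsable."""
    return yaml.safe_dump({
        "scale_factor": maze.scale_factor,
        "cell_size_cm": maze.cell_size,
        "waypoints": {k: list(v) for k, v in maze.waypoints.items()},
        "segments": [[list(a), list(b)] for a, b in maze.segments],
        "start": list(maze.start), "goal": list(maze.goal),
        "food_box": list(maze.food_box),
        "blocks": {k: {"position": list(v["node"]), "present": v["present"]}
                   for k, v in maze.blocks.items()},
        "gate": (None if maze.gate is None
                 else {"position": list(maze.gate["node"]),
                       "permitted_heading": maze.gate["heading"]}),
        "corridor_cells": sorted(map(list, maze.corridor_cells)),
    }, sort_keys=True)


def save_trajectories(records, path) -> None:
    frames = []
    for r in records:
        if r.trajectory is None:
            continue
        df = r.trajectory.to_frame()
        df.insert(0, "trial", r.trial)
        df.insert(0, "day", r.day)
        df.insert(0, "agent", r.agent)
        frames.append(df)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# -- reporting -------------------------------------------------------------

def report(result_dir) -> dict:
    """Summarize a simulation output directory into one JSON + text pair.

    Requires trials.csv, selection_tables.csv and anova.json as written by
    the ``simulate`` command; deterministic given its inputs.
    """
    d = Path(result_dir)
    missing = [n for n in ("trials.csv", "selection_tables.csv", "anova.json")
               if not (d / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing simulation outputs: {missing}")
    trials = pd.read_csv(d / "trials.csv")
    tables = pd.read_csv(d / "selection_tables.csv")
    anova = json.loads((d / "anova.json").read_text())
    summary = {
        "n_trials": int(len(trials)),
        "n_agents": int(trials["agent"].nunique()),
        "completed_fraction": float((trials["route"] != "incomplete").mean()),
        "selection": {
            phase: grp.drop(columns=["phase"]).mean(numeric_only=True).to_dict()
            for phase, grp in tables.groupby("phase")
        },
        "anova": anova,
    }
    extra = d / "population_info.json"
    if extra.exists():
        summary["population_info"] = json.loads(extra.read_text())
    (d / "summary.json").write_text(json.dumps(summary, indent=2,
                                               sort_keys=True))
    lines = [f"trials: {summary['n_trials']} "
             f"({summary['completed_fraction']:.1%} completed, "
             f"{summary['n_agents']} agents)"]
    for phase, props in summary["selection"].items():
        pretty = ", ".join(f"{k}={v:.2f}" for k, v in sorted(props.items())
                           if k.startswith("P"))
        lines.append(f"{phase}: {pretty}")
    for phase, st in anova.items():
        lines.append(f"ANOVA {phase}: F={st['F']:.2f} p={st['p']:.3g} "
                     f"preferred={st['preferred']}")
    (d / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
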