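"""Tolman & Honzik detour-task protocol.

Fifteen simulated days: Day 1 holds 3 forced runs (one per path) plus 9 free
exploration runs; Days 2-14 each mix 10 block-A runs (with the entrances to
Paths 2 and 3 doored off until the agent has bounced off the block and
returned to the first intersection) with 2 non-successive free runs; Day 15
is a 7-trial probe with block B severing the segment shared by Paths 1 and
2.  A trial ends when the agent crosses the food-box entrance or times out.

Learning is online: every step imprints/adapts the level-1 state code,
updates lateral topology weights, feeds the turn-probability signal to the
level-2 map, and a block encounter immediately depresses the blocked edge
and triggers replanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maze import (DT, OPPOSITE, AgentPose, Trajectory, build_tolman_maze)
from .place_cells import seed_place_cells
from .columns import ColumnNetwork, NetworkParams, is_sharp_turn
from . import planner as pl

ROUTES = ("P1", "P2", "P3")


@dataclass
class ExperimentConfig:
    scale: int = 1
    n_agents: int = 40
    master_seed: int = 0
    epsilon_day1: float = 0.5
    epsilon_later: float = 0.05
    use_level2: bool = True
    trial_timeout_s: float = 600.0
    params: NetworkParams = field(default_factory=NetworkParams)
    pc_spacing: float = 5.0
    pc_sigma: float = 7.5
    pc_peak_rate: float = 10.0
    record_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("need at least one agent")


@dataclass
class TrialRecord:
    agent: int
    day: int
    trial: int
    forced: str | None
    blocks: tuple
    route: str
    duration_s: float
    n_block_encounters: int
    choice: str | None = None  # P2-vs-P3 decision at the first intersection
    trajectory: Trajectory | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "agent": r.agent, "day": r.day, "trial": r.trial,
            "forced": r.forced or "", "blocks": "+".join(r.blocks),
            "route": r.route, "choice": r.choice or "",
            "duration_s": r.duration_s,
            "block_encounters": r.n_block_encounters,
        } for r in self.records])


class Agent:
    """One simulated rat: its maze instance, place code, column network."""

    def __init__(self, maze: Maze, config: ExperimentConfig, seed: int):
        ss = np.random.SeedSequence(seed)
        pc_seed, net_seed, pol_seed = (int(s.generate_state(1)[0] % (2**31))
                                       for s in ss.spawn(3))
        self.maze = maze
        self.config = config
        self.place_cells = seed_place_cells(
            maze, spacing=config.pc_spacing, sigma=config.pc_sigma,
            peak_rate=config.pc_peak_rate, seed=pc_seed)
        self.net = ColumnNetwork(self.place_cells, params=config.params,
                                 seed=net_seed, use_level2=config.use_level2)
        self.rng = np.random.default_rng(pol_seed)
        self.goal_column: int | None = None


def _goal_field_ascent(agent: Agent, pose: AgentPose, avail: set,
                       goal_col: int) -> str:
    """Action that maximizes the goal column's state response one step on."""
    from .maze import ACTION_VECTORS, NODE_SPACING
    node = agent.maze.snap(pose.position)
    best_a, best_v = None, -np.inf
    for a in sorted(avail):
        dx, dy = ACTION_VECTORS[a]
        nb = (round(node[0] + dx * NODE_SPACING, 6),
              round(node[1] + dy * NODE_SPACING, 6))
        v = float(agent.net.similarities(
            agent.place_cells.rates_at_node(nb))[goal_col])
        if v > best_v:
            best_a, best_v = a, v
    return best_a


def _exit_homing(agent: Agent, pose: AgentPose, avail: set, plan, cid: int,
                 epsilon: float, rng) -> str | None:
    """Walk toward a column's exit when the winning action is not physically
    available at the current node.

    Receptive fields span several grid nodes; the transition carrying the
    strongest action value was experienced at one particular node of the
    field, so the agent path-integrates toward that site.  Returns None when
    ordinary winner-take-all selection applies.
    """
    from .maze import ACTIONS
    net = agent.net
    nu = net.params.noise_floor
    nbrs = net.neighbors(cid)
    if not nbrs:
        return None
    a_star = max(nbrs, key=lambda a: (plan.d.get((cid, a), nu),
                                      -ACTIONS.index(a)))
    if plan.d.get((cid, a_star), nu) <= nu or a_star in avail:
        return None
    site = net.edge_sites.get((cid, a_star, nbrs[a_star]))
    node = agent.maze.snap(pose.position)
    if site is None or site == node:
        return None
    best, best_key = None, None
    from .maze import ACTION_VECTORS, NODE_SPACING
    for a in avail:
        dx, dy = ACTION_VECTORS[a]
        nb = (node[0] + dx * NODE_SPACING, node[1] + dy * NODE_SPACING)
        dist = abs(nb[0] - site[0]) + abs(nb[1] - site[1])
        key = (dist, a != pose.heading, ACTIONS.index(a))
        if best_key is None or key < best_key:
            best, best_key = a, key
    return best


def _perceive(agent: Agent, node, prev_cid, action, prev_heading, heading,
              prev_node=None):
    """One step of online learning at ``node``.

    Returns (active column id, similarity vector over columns)."""
    net = agent.net
    hp = agent.place_cells.rates_at_node(node)
    cid, sims = net.observe(hp)
    net.columns[cid].s = float(np.clip(sims[cid], 0, 1) * 10.0)
    if prev_cid is not None and cid != prev_cid and action is not None:
        net.learn_transition(prev_cid, action, cid, site=prev_node)
    cell = agent.maze.cell_of(node)
    net.record_visit(cell, is_sharp_turn(prev_heading, heading))
    if net.use_level2:
        net.update_level2(cid, net.turn_probability(cell), action)
    return cid, sims


def run_trial(agent: Agent, *, forced_route: str | None = None,
              blocks: tuple = (), doors_until_return: bool = False,
              epsilon: float = 0.05, record_units=None) -> TrialRecord:
    """Run one trial: perceive -> learn -> plan -> act until the goal.

    ``doors_until_return``: wall off the Path-2/3 entrances until the agent
    has encountered a block and come back to the first intersection (the
    forcing device of the block-A training trials).  After a block encounter
    under closed doors the agent retraces its steps to the intersection, as
    in the original protocol.
    """
    maze, net, rng = agent.maze, agent.net, agent.rng
    for b in maze.blocks:
        maze.set_block(b, b in blocks)
    i1 = maze.waypoints.get("I1")
    if doors_until_return and i1 is not None:
        maze.doors = {(i1[0] - 5.0, i1[1]), (i1[0] + 5.0, i1[1])}
    else:
        maze.doors = set()

    net.reset_l2_context()
    pose = AgentPose(maze.snap(maze.start), "N", 0.0)
    traj = Trajectory()
    cid, sims = _perceive(agent, pose.position, None, None, "N", "N")

    plan = None
    if agent.goal_column is not None and forced_route is None:
        plan = pl.backpropagate_goal(net, pl.inject_goal(net, agent.goal_column))

    def _route_actions(route, stop_node=None):
        nodes = maze.route_nodes(route)
        if stop_node is not None and stop_node in nodes:
            nodes = nodes[:nodes.index(stop_node) + 1]
        acts = []
        for a, b in zip(nodes[:-1], nodes[1:]):
            dx, dy = b[0] - a[0], b[1] - a[1]
            acts.append(
                "N" if dy > 0 else "S" if dy < 0 else "E" if dx > 0 else "W")
        return acts

    script = None
    if forced_route is not None:
        script = iter(_route_actions(forced_route))
    elif doors_until_return and "A" in blocks:
        # the closed doors channel the agent along Path 1 up to the block
        script = iter(_route_actions("P1", maze.blocks["A"]["node"]))

    max_steps = int(round(agent.config.trial_timeout_s / DT))
    n_blocks_hit = 0
    backtrack: list[str] | None = None
    path_nodes = [maze.snap(pose.position)]
    path_moves: list[str] = []
    reached = False
    for _ in range(max_steps):
        action = next(script, None) if script is not None else None
        if action is None and script is not None:
            if forced_route is not None:
                break  # forced run fully executed
            script = None  # scripted approach over; plan freely from here
        if action is not None:
            pass
        elif backtrack:
            action = backtrack.pop()
        else:
            avail = maze.available_actions(pose, ignore_blocks=True)
            if plan is not None and cid == plan.goal:
                # inside the goal column the lateral field carries no
                # gradient; climb the goal column's own receptive field
                action = _goal_field_ascent(agent, pose, avail, plan.goal)
            elif plan is not None:
                action = _exit_homing(agent, pose, avail, plan, cid,
                                      epsilon, rng)
                if action is None:
                    action = pl.select_action(net, plan, cid, epsilon, rng,
                                              available=avail,
                                              heading=pose.heading)
            else:
                acts = sorted(avail)
                action = acts[rng.integers(len(acts))]
        prev_heading = pose.heading
        prev_cid = cid
        prev_node = maze.snap(pose.position)
        pose, event = maze.step_agent(pose, action)
        node = maze.snap(pose.position)
        if node != prev_node:
            cid, sims = _perceive(agent, node, prev_cid, action, prev_heading,
                                  pose.heading, prev_node=prev_node)
            path_nodes.append(node)
            path_moves.append(action)
        if event == "block_encounter":
            n_blocks_hit += 1
            net.unlearn_blocked(cid, action)
            if agent.goal_column is not None:
                plan = pl.backpropagate_goal(
                    net, pl.inject_goal(net, agent.goal_column))
            if i1 is not None and forced_route is None:
                # scripted return to the first intersection, retracing the
                # path taken so far (pop() yields the most recent move first)
                backtrack = [OPPOSITE[a] for a in path_moves] or None
        elif backtrack is not None and event == "collision":
            backtrack = None  # cannot retrace further; resume planning
        traj.append(pose.time, pose.position, pose.heading, action, event)
        at_i1 = i1 is not None and node == maze.snap(i1)
        if maze.doors and n_blocks_hit > 0 and at_i1:
            maze.doors = set()
        if backtrack is not None and at_i1:
            backtrack = None
        if record_units is not None:
            record_units(pose.time, node, net, plan, sims)
        if event == "goal_reached":
            reached = True
            break

    if reached:
        hp = agent.place_cells.rates_at_node(maze.snap(pose.position))
        gc = net.recruit_or_adapt(hp)
        if agent.goal_column is None:
            agent.goal_column = gc
    route = maze.classify_route(traj)
    return TrialRecord(agent=0, day=0, trial=0, forced=forced_route,
                       blocks=tuple(blocks), route=route,
                       duration_s=pose.time,
                       n_block_encounters=n_blocks_hit,
                       choice=maze.classify_choice(traj),
                       trajectory=traj)


def day_schedule(day: int, rng: np.random.Generator) -> list[dict]:
    """Trial descriptors for one day of the 15-day protocol."""
    if day == 1:
        sched = [{"forced": r, "blocks": (), "doors": False}
                 for r in ("P1", "P2", "P3")]
        sched += [{"forced": None, "blocks": (), "doors": False}] * 9
        return sched
    if 2 <= day <= 14:
        # 10 block-A runs mixed with 2 non-successive free runs
        while True:
            free = sorted(rng.choice(12, size=2, replace=False))
            if free[1] - free[0] > 1:
                break
        return [{"forced": None,
                 "blocks": () if i in free else ("A",),
                 "doors": i not in free}
                for i in range(12)]
    if day == 15:
        return [{"forced": None, "blocks": ("B",), "doors": False}] * 7
    raise ValueError(f"no day {day} in the protocol")


def run_agent(agent_idx: int, config: ExperimentConfig,
              days: range = range(1, 16)) -> tuple[Agent, list]:
    seed = int(np.random.SeedSequence(
        [config.master_seed, agent_idx]).generate_state(1)[0] % (2**31))
    maze = build_tolman_maze(config.scale)
    agent = Agent(maze, config, seed)
    sched_rng = np.random.default_rng(
        int(np.random.SeedSequence([config.master_seed, agent_idx, 7])
            .generate_state(1)[0] % (2**31)))
    records = []
    for day in days:
        eps = config.epsilon_day1 if day == 1 else config.epsilon_later
        for t, desc in enumerate(day_schedule(day, sched_rng), start=1):
            rec = run_trial(agent, forced_route=desc["forced"],
                            blocks=desc["blocks"],
                            doors_until_return=desc["doors"], epsilon=eps)
            rec.agent, rec.day, rec.trial = agent_idx, day, t
            if not config.record_trajectories:
                rec.trajectory = None
            records.append(rec)
    return agent, records


def run_tolman_protocol(config: ExperimentConfig,
                        days: range = range(1, 16)) -> ExperimentResult:
    result = ExperimentResult(config=config)
    for a in range(config.n_agents):
        _, records = run_agent(a, config, days)
        result.records.extend(records)
    return result


# -- behavioral statistics -------------------------------------------------

PHASES = {"Day1": (1, 1), "Days2_14": (2, 14), "Day15": (15, 15)}


def path_selection_table(result: ExperimentResult, phase: str) -> pd.DataFrame:
    """Per-agent selection proportions per route for one protocol phase.

    Day 1 scores completed free runs by the route actually taken.  The
    block phases (Days 2-14 and Day 15) score the P2-vs-P3 decision taken
    on returning to the first intersection -- the selection of a blocked
    trial even when the chosen arm turns out to be interrupted -- and
    exclude the physically interrupted Path 1 from the denominator.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    lo, hi = PHASES[phase]
    routes = list(ROUTES) if phase == "Day1" else ["P2", "P3"]
    rows = {}
    for r in result.records:
        if not (lo <= r.day <= hi) or r.forced:
            continue
        label = r.route if phase == "Day1" else (r.choice or r.route)
        if label not in routes:
            continue
        rows.setdefault(r.agent, {rt: 0 for rt in routes})
        rows[r.agent][label] += 1
    if not rows:
        raise ValueError(f"no completed free trials in phase {phase}")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table = table.div(table.sum(axis=1), axis=0)
    table.index.name = "agent"
    return table


def anova_path_preference(table: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA across agents on per-route selection proportions."""
    groups = [table[c].dropna().to_numpy() for c in table.columns]
    if len(groups) < 2:
        raise ValueError("need at least two routes")
    if len(table) < 2:
        raise ValueError("need at least two agents")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # identical everywhere: no effect at all
        return 0.0, 1.0
    if all(np.ptp(g) == 0 for g in groups):
        return float("inf"), 0.0  # distinct means, zero within-group spread
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def phase_preference(result: ExperimentResult, phase: str) -> dict:
    """Preferred route in a phase with its ANOVA significance."""
    table = path_selection_table(result, phase)
    f, p = anova_path_preference(table)
    means = table.mean()
    return {"phase": phase, "preferred": str(means.idxmax()),
            "proportions": means.to_dict(), "F": f, "p": p,
            "n_agents": int(len(table))}
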