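"""Unit-trace recording sessions.

Two kinds of session: (i) online recording of the level-1 state units during
the Day-1 schedule, used for the population place-code analyses, and (ii) a
scripted probe session after learning in which every route is traversed
under each block condition, yielding traces for state, goal, action-value,
motor, and path units for the task-phase and unit-clustering analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maze import DT, scripted_trajectory
from .columns import ColumnNetwork
from .protocol import Agent, day_schedule, run_trial
from . import planner as pl


@dataclass
class RecordingSession:
    """Time-stamped unit rates aligned to positions."""

    times: np.ndarray
    positions: np.ndarray            # (n, 2) cm
    trial_ids: np.ndarray
    traces: dict = field(default_factory=dict)   # kind -> (n, units)
    phases: np.ndarray | None = None

    def n_samples(self) -> int:
        return len(self.times)


def record_day1(agent: Agent, sched_rng: np.random.Generator) -> RecordingSession:
    """Run the Day-1 schedule (3 forced + 9 free runs) recording the level-1
    state-unit population vector at every step."""
    rows: list[tuple[int, float, tuple, np.ndarray]] = []
    trial_idx = {"i": 0}

    def cb(time, node, net: ColumnNetwork, plan, sims):
        rows.append((trial_idx["i"], time, node,
                     np.clip(sims, 0, 1) * 10.0))

    for desc in day_schedule(1, sched_rng):
        run_trial(agent, forced_route=desc["forced"], blocks=desc["blocks"],
                  doors_until_return=desc["doors"],
                  epsilon=agent.config.epsilon_day1, record_units=cb)
        trial_idx["i"] += 1

    n_units = len(agent.net.columns)
    s1 = np.zeros((len(rows), n_units))
    for k, (_t, _time, _node, s) in enumerate(rows):
        s1[k, :len(s)] = s
    return RecordingSession(
        times=np.array([r[1] for r in rows]),
        positions=np.array([r[2] for r in rows], dtype=float),
        trial_ids=np.array([r[0] for r in rows]),
        traces={"s1": s1},
    )


def add_hp_traces(session: RecordingSession, agent: Agent) -> None:
    """Hippocampal input rates along the recorded positions (post hoc)."""
    hp = np.array([agent.place_cells.rates_at_node(tuple(p))
                   for p in session.positions])
    session.traces["hp"] = hp


def add_level2_traces(session: RecordingSession, agent: Agent) -> None:
    """Level-2 state rates: relay (max) of the member level-1 state units."""
    net = agent.net
    s1 = session.traces["s1"]
    n2 = len(net.l2_columns)
    s2 = np.zeros((s1.shape[0], n2))
    for l2 in range(n2):
        members = [m for m in net.W_21.get(l2, set()) if m < s1.shape[1]]
        if members:
            s2[:, l2] = s1[:, members].max(axis=1)
    session.traces["s2"] = s2


def _edges_through(net: ColumnNetwork, agent: Agent, block_node) -> list:
    """Level-1 forward edges passing through the column covering a block."""
    hp = agent.place_cells.rates_at_node(tuple(block_node))
    col = net.winner(hp)
    return [k for k in net.W_fwd if col in (k[0], k[2])]


class _removed_edges:
    """Temporarily remove forward/backward level-1 edges from a network."""

    def __init__(self, net: ColumnNetwork, edges):
        self.net = net
        self.edges = list(edges)
        self.stash = {}

    def __enter__(self):
        for (i, a, j) in self.edges:
            if (i, a, j) in self.net.W_fwd:
                self.stash[(i, a, j)] = self.net.W_fwd.pop((i, a, j))
                self.net.W_back.pop((j, a, i), None)
        return self.net

    def __exit__(self, *exc):
        for (i, a, j), w in self.stash.items():
            self.net.W_fwd[(i, a, j)] = w
            self.net.W_back[(j, a, i)] = w
        return False


PHASE_BLOCKS = {"none": (), "A": ("A",), "AB": ("A", "B")}


def record_probe_session(agent: Agent, routes=("P1", "P2", "P3"),
                         conditions=("none", "A", "AB")) -> RecordingSession:
    """Scripted traversal of every route under every block condition.

    Goal and action-value fields are recomputed per condition on the learned
    map with the blocked edges silenced; the same routes are walked in each
    condition so task phase is not confounded with position.  Motor units
    are winner-gated (the losing minicolumns are suppressed by the local
    competition); path units follow the forward-plan schedule.
    """
    net = agent.net
    maze = agent.maze
    if agent.goal_column is None:
        raise ValueError("agent has not found the goal yet")
    U = len(net.columns)
    times, positions, trials, phases = [], [], [], []
    S, G, D, M, P = [], [], [], [], []
    trial = 0
    t0 = 0.0
    for phase in conditions:
        edges = []
        for b in PHASE_BLOCKS[phase]:
            edges.extend(_edges_through(net, agent, maze.blocks[b]["node"]))
        with _removed_edges(net, edges):
            plan = pl.backpropagate_goal(
                net, pl.inject_goal(net, agent.goal_column))
            gvec = np.array([plan.g.get(c.id, net.params.noise_floor)
                             for c in net.columns])
            dvec = np.array([max([plan.d.get((c.id, a), net.params.noise_floor)
                                  for a in ("N", "E", "S", "W")])
                             for c in net.columns])
            for route in routes:
                traj = scripted_trajectory(maze, route)
                for k, (tt, node, act) in enumerate(zip(
                        traj.times, traj.positions, traj.actions)):
                    t = t0 + tt
                    hp = agent.place_cells.rates_at_node(node)
                    s = np.clip(net.similarities(hp), 0, 1) * 10.0
                    cur = int(np.argmax(s))
                    m = np.zeros(U)
                    m[cur] = s[cur] * plan.d.get((cur, act),
                                                 net.params.noise_floor)
                    # forward propagation recurs as the agent advances: the
                    # path signal anticipates the columns about to be visited
                    p = np.full(U, net.params.noise_floor)
                    pl.forward_propagate_path(net, plan, cur, onset=t)
                    for col, (rank, t_arr) in plan.schedule.items():
                        p[col] = pl.path_unit_rate(net, plan, rank, t, t_arr)
                    times.append(t)
                    positions.append(node)
                    trials.append(trial)
                    phases.append(phase)
                    S.append(s)
                    G.append(gvec)
                    D.append(dvec)
                    M.append(m)
                    P.append(p)
                trial += 1
                t0 = times[-1] + DT
    session = RecordingSession(
        times=np.asarray(times), positions=np.asarray(positions, dtype=float),
        trial_ids=np.asarray(trials),
        traces={"s1": np.asarray(S), "g1": np.asarray(G),
                "d1": np.asarray(D), "m1": np.asarray(M),
                "p1": np.asarray(P)},
        phases=np.asarray(phases),
    )
    add_hp_traces(session, agent)
    add_level2_traces(session, agent)
    return session
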