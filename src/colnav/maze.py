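"""Discrete 2-D corridor world reproducing Tolman & Honzik's three-path detour maze.

The maze is represented as a lattice of nodes spaced ``NODE_SPACING`` cm apart
along corridor midlines.  An agent occupies a node, moves between adjacent
nodes with compass actions (N, E, S, W) at constant speed, and corridors are
two grid cells (10 cm) wide for occupancy/rate-map purposes.  Two removable
blocks (A on the Path-1-exclusive segment, B on the segment shared by Paths 1
and 2) and a one-way gate near the second intersection implement the detour
task contingencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

ACTIONS = ("N", "E", "S", "W")
#: displacement (dx, dy) in cm per NODE_SPACING step
ACTION_VECTORS = {"N": (0, 1), "E": (1, 0), "S": (0, -1), "W": (-1, 0)}
OPPOSITE = {"N": "S", "S": "N", "E": "W", "W": "E"}

SPEED_CM_S = 15.0  # constant locomotion speed
CELL_SIZE = 5.0  # analysis grid, cm
NODE_SPACING = 5.0  # lattice pitch along corridor midlines, cm
DT = NODE_SPACING / SPEED_CM_S  # one step = one lattice node (1/3 s)


class MazeError(ValueError):
    """Invalid maze construction or query."""


@dataclass(frozen=True)
class AgentPose:
    """Agent state: position (cm), compass heading, and simulation time (s)."""

    position: tuple[float, float]
    heading: str = "N"
    time: float = 0.0


@dataclass
class Trajectory:
    """Ordered record of one run: (time, position, heading, action, event)."""

    times: list[float] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)
    headings: list[str] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def append(self, time: float, position: tuple[float, float], heading: str,
               action: str, event: str) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("trajectory times must be strictly increasing")
        self.times.append(time)
        self.positions.append(tuple(position))
        self.headings.append(heading)
        self.actions.append(action)
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Total recorded duration assuming one DT dwell per sample."""
        return len(self.times) * DT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "x_cm": [p[0] for p in self.positions],
            "y_cm": [p[1] for p in self.positions],
            "heading": self.headings,
            "action": self.actions,
            "event": self.events,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        traj = cls()
        for row in df.itertuples(index=False):
            traj.append(row.time_s, (row.x_cm, row.y_cm), row.heading,
                        row.action, row.event)
        return traj


@dataclass
class Maze:
    """Corridor graph + grid geometry with removable blocks and a one-way gate.

    ``segments`` are midline polyline endpoints in cm; nodes are derived on a
    ``NODE_SPACING`` lattice.  ``blocks`` maps block id -> (node, present).
    ``gate`` is (node, permitted heading): crossing the gate node along the
    corridor axis is only allowed in the permitted direction.  ``doors`` is a
    mutable set of temporarily walled-off nodes (protocol forcing devices);
    they restrict movement like walls and are never learned as blocks.
    """

    scale_factor: int
    segments: list[tuple[tuple[float, float], tuple[float, float]]]
    waypoints: dict[str, tuple[float, float]]
    start: tuple[float, float]
    goal: tuple[float, float]  # entrance to the food box
    food_box: tuple[float, float]
    blocks: dict[str, dict] = field(default_factory=dict)
    gate: dict | None = None
    route_exclusive: dict[str, set] = field(default_factory=dict)
    cell_size: float = CELL_SIZE
    doors: set = field(default_factory=set)

    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)
    nodes: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            self._build_lattice()

    # -- construction ------------------------------------------------------

    def _build_lattice(self) -> None:
        nodes: set[tuple[float, float]] = set()
        for (x0, y0), (x1, y1) in self.segments:
            if x0 != x1 and y0 != y1:
                raise MazeError("segments must be axis-aligned")
            n = int(round(max(abs(x1 - x0), abs(y1 - y0)) / NODE_SPACING))
            for k in range(n + 1):
                t = k / max(n, 1)
                nodes.add((round(x0 + t * (x1 - x0), 6),
                           round(y0 + t * (y1 - y0), 6)))
        nodes.add(self.food_box)
        self.nodes = nodes
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for node in nodes:
            for a, (dx, dy) in ACTION_VECTORS.items():
                nb = (round(node[0] + dx * NODE_SPACING, 6),
                      round(node[1] + dy * NODE_SPACING, 6))
                if nb in nodes:
                    g.add_edge(node, nb)
        self.graph = g

    # -- geometry ----------------------------------------------------------

    def snap(self, position: Sequence[float]) -> tuple[float, float]:
        node = (round(position[0], 6), round(position[1], 6))
        if node not in self.nodes:
            raise MazeError(f"position {position} is not on the corridor")
        return node

    def on_corridor(self, position: Sequence[float]) -> bool:
        try:
            self.snap(position)
            return True
        except MazeError:
            return False

    @property
    def corridor_cells(self) -> set:
        """0-based (col, row) grid cells covered by the 10 cm wide corridors."""
        cells: set[tuple[int, int]] = set()
        for (x, y) in self.nodes:
            ci, ri = int(x // self.cell_size), int(y // self.cell_size)
            # each midline node touches the 2x2 block of cells around it
            for dc in (-1, 0):
                for dr in (-1, 0):
                    cells.add((ci + dc, ri + dr))
        return cells

    def cell_of(self, position: Sequence[float]) -> tuple[int, int]:
        return (int(position[0] // self.cell_size),
                int(position[1] // self.cell_size))

    @property
    def extent(self) -> tuple[float, float]:
        xs = [p[0] for p in self.nodes]
        ys = [p[1] for p in self.nodes]
        return (max(xs) + self.cell_size, max(ys) + self.cell_size)

    def midline_length(self) -> float:
        return sum(abs(x1 - x0) + abs(y1 - y0)
                   for (x0, y0), (x1, y1) in self.segments)

    # -- blocks, gate, doors ----------------------------------------------

    def set_block(self, block_id: str, present: bool) -> "Maze":
        if block_id not in self.blocks:
            raise MazeError(f"unknown block id {block_id!r}")
        self.blocks[block_id]["present"] = bool(present)
        return self

    def block_at(self, node: tuple[float, float]) -> str | None:
        for bid, info in self.blocks.items():
            if info["present"] and info["node"] == node:
                return bid
        return None

    def _gate_forbids(self, src, action: str, dst) -> bool:
        """True when moving src->dst crosses the gate against its valve."""
        if self.gate is None:
            return False
        gnode, permitted = self.gate["node"], self.gate["heading"]
        # minimal one-way valve: passing onward from the gate node against
        # its permitted heading is forbidden; every other move is free
        return src == gnode and action == OPPOSITE[permitted]

    # -- agent interface ---------------------------------------------------

    def available_actions(self, pose: AgentPose, *,
                          ignore_blocks: bool = False) -> set[str]:
        """Compass actions not leading into a wall, present block, door,
        or against the gate's permitted direction."""
        node = self.snap(pose.position)
        out = set()
        for a, (dx, dy) in ACTION_VECTORS.items():
            nb = (round(node[0] + dx * NODE_SPACING, 6),
                  round(node[1] + dy * NODE_SPACING, 6))
            if nb not in self.nodes or nb in self.doors:
                continue
            if self._gate_forbids(node, a, nb):
                continue
            if not ignore_blocks and self.block_at(nb) is not None:
                continue
            out.add(a)
        return out

    def step_agent(self, pose: AgentPose, action: str,
                   dt: float = DT) -> tuple[AgentPose, str]:
        """Advance the agent by ``SPEED_CM_S * dt`` cm along ``action``.

        Illegal moves leave the position unchanged and report an event:
        ``block_encounter`` for a present block, ``collision`` for walls,
        doors, or the gate.  Entering the food box reports ``goal_reached``.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        node = self.snap(pose.position)
        dist = SPEED_CM_S * dt
        n_steps = int(round(dist / NODE_SPACING))
        if abs(n_steps * NODE_SPACING - dist) > 1e-9 or n_steps < 1:
            raise ValueError("dt must advance a whole number of lattice nodes")
        dx, dy = ACTION_VECTORS[action]
        cur = node
        t = pose.time
        for _ in range(n_steps):
            nb = (round(cur[0] + dx * NODE_SPACING, 6),
                  round(cur[1] + dy * NODE_SPACING, 6))
            t += NODE_SPACING / SPEED_CM_S
            if nb not in self.nodes or nb in self.doors or \
                    self._gate_forbids(cur, action, nb):
                return AgentPose(cur, action, t), "collision"
            if self.block_at(nb) is not None:
                return AgentPose(cur, action, t), "block_encounter"
            cur = nb
            if cur == self.food_box:
                return AgentPose(cur, action, t), "goal_reached"
        return AgentPose(cur, action, t), "none"

    # -- routes ------------------------------------------------------------

    def route_nodes(self, route: str) -> list[tuple[float, float]]:
        """Node sequence start -> food box along the named route (P1/P2/P3)."""
        try:
            vias = self._route_vias[route]
        except KeyError:
            raise MazeError(f"unknown route {route!r}") from None
        path = [self.snap(self.start)]
        for wp in vias + [self.goal, self.food_box]:
            cur = path[-1]
            tgt = self.snap(wp)
            while cur != tgt:
                if cur[0] != tgt[0]:
                    step = NODE_SPACING if tgt[0] > cur[0] else -NODE_SPACING
                    cur = (round(cur[0] + step, 6), cur[1])
                else:
                    step = NODE_SPACING if tgt[1] > cur[1] else -NODE_SPACING
                    cur = (cur[0], round(cur[1] + step, 6))
                path.append(cur)
        return path

    def route_length(self, route: str) -> float:
        """Length in cm from the start to the goal entrance (food box excluded)."""
        return (len(self.route_nodes(route)) - 2) * NODE_SPACING

    def reachable_routes(self) -> set[str]:
        """Routes whose node sequence avoids every present block."""
        blocked = {info["node"] for info in self.blocks.values()
                   if info["present"]}
        return {r for r in self._route_vias
                if not blocked.intersection(self.route_nodes(r))}

    def classify_route(self, traj: Trajectory) -> str:
        """Label a trajectory P1/P2/P3 by the exclusive segment traversed on
        the final approach to the goal; 'incomplete' if it never arrives."""
        if len(traj) == 0:
            raise MazeError("empty trajectory")
        if "goal_reached" not in traj.events:
            return "incomplete"
        end = traj.events.index("goal_reached")
        # walk backwards; a route counts once two *consecutive distinct*
        # positions lie on its exclusive segment (a traversal, not a bounce)
        prev = None
        for pos in reversed(traj.positions[:end + 1]):
            node = (round(pos[0], 6), round(pos[1], 6))
            for route, cells in self.route_exclusive.items():
                if node in cells and prev in cells and prev != node:
                    return route
            prev = node
        return "incomplete"

    def classify_choice(self, traj: Trajectory) -> str | None:
        """The P2-vs-P3 decision taken at the first intersection.

        Scans forward from the first arrival at I1 after the first block
        encounter (or from the trial start when nothing was encountered)
        and returns the first detour arm actually traversed -- the
        selection a blocked trial scores even when the agent later backs
        out.  None when no decision point was reached.
        """
        if len(traj) == 0 or "I1" not in self.waypoints:
            return None
        i1 = self.snap(self.waypoints["I1"])
        start = 0
        if "block_encounter" in traj.events:
            first_b = traj.events.index("block_encounter")
            start = None
            for k in range(first_b + 1, len(traj)):
                pos = traj.positions[k]
                if (round(pos[0], 6), round(pos[1], 6)) == i1:
                    start = k
                    break
            if start is None:
                return None
        prev = None
        for pos in traj.positions[start:]:
            node = (round(pos[0], 6), round(pos[1], 6))
            for route in ("P2", "P3"):
                cells = self.route_exclusive[route]
                if node in cells and prev in cells and prev != node:
                    return route
            prev = node
        return None


# -- canonical Tolman & Honzik layout -------------------------------------

def build_tolman_maze(scale_factor: int = 1) -> Maze:
    """Canonical three-path detour maze.

    Schematic waypoints at 1:1 scale (cm): S=(60,10), I1=(60,40), A=(60,80),
    J2=(60,100), B=(60,120), G=(60,140); Path 2 detours via x=30, Path 3 via
    x=100.  Route lengths 130/190/210 cm including the 30 cm common stem;
    the 4:1 maze multiplies every coordinate by 4 with the cell size kept at
    5 cm so route-length ratios are preserved.
    """
    if scale_factor not in (1, 4):
        raise MazeError(f"unsupported scale factor {scale_factor}")
    f = float(scale_factor)

    def pt(x, y):
        return (x * f, y * f)

    waypoints = {
        "S": pt(60, 10), "I1": pt(60, 40), "A": pt(60, 80),
        "J2": pt(60, 100), "B": pt(60, 120), "G": pt(60, 140),
    }
    segments = [
        (pt(60, 10), pt(60, 140)),    # Path-1 spine incl. common stem
        (pt(30, 40), pt(60, 40)),     # Path-2 west arm
        (pt(30, 40), pt(30, 100)),
        (pt(30, 100), pt(60, 100)),
        (pt(60, 40), pt(100, 40)),    # Path-3 east arm
        (pt(100, 40), pt(100, 140)),
        (pt(60, 140), pt(100, 140)),
        # food box: one node past the goal entrance at every scale
        (pt(60, 140), (60 * f, 140 * f + NODE_SPACING)),
    ]
    maze = Maze(
        scale_factor=scale_factor,
        segments=segments,
        waypoints=waypoints,
        start=pt(60, 10),
        goal=pt(60, 140),
        food_box=(60 * f, 140 * f + NODE_SPACING),
        blocks={
            "A": {"node": pt(60, 80), "present": False},
            "B": {"node": pt(60, 120), "present": False},
        },
        gate={"node": pt(60, 100), "heading": "N"},
    )
    s = NODE_SPACING

    def span(x0, y0, x1, y1):
        out = set()
        n = int(round(max(abs(x1 - x0), abs(y1 - y0)) / s))
        for k in range(n + 1):
            t = k / max(n, 1)
            out.add((round(x0 + t * (x1 - x0), 6), round(y0 + t * (y1 - y0), 6)))
        return out

    # exclusive segments (junction nodes excluded)
    maze.route_exclusive = {
        "P1": span(60 * f, 40 * f + s, 60 * f, 100 * f - s),
        "P2": (span(30 * f, 40 * f, 30 * f, 100 * f)
               | span(30 * f + s, 40 * f, 60 * f - s, 40 * f)
               | span(30 * f + s, 100 * f, 60 * f - s, 100 * f)),
        "P3": (span(100 * f, 40 * f, 100 * f, 140 * f)
               | span(60 * f + s, 40 * f, 100 * f - s, 40 * f)
               | span(60 * f + s, 140 * f, 100 * f - s, 140 * f)),
    }
    maze._route_vias = {
        "P1": [waypoints["I1"], waypoints["J2"]],
        "P2": [waypoints["I1"], pt(30, 40), pt(30, 100), waypoints["J2"]],
        "P3": [waypoints["I1"], pt(100, 40), pt(100, 140)],
    }
    return maze


def make_fixture_maze(kind: str) -> Maze:
    """Small unit-test environments: 'linear' (one 100 cm segment),
    'L' (two segments, one turn), 'T' (three segments, one junction)."""
    if kind == "linear":
        segments = [((10.0, 10.0), (110.0, 10.0))]
        start, goal = (10.0, 10.0), (105.0, 10.0)
        food = (110.0, 10.0)
    elif kind == "L":
        segments = [((10.0, 10.0), (60.0, 10.0)), ((60.0, 10.0), (60.0, 60.0))]
        start, goal = (10.0, 10.0), (60.0, 55.0)
        food = (60.0, 60.0)
    elif kind == "T":
        segments = [((10.0, 10.0), (90.0, 10.0)), ((50.0, 10.0), (50.0, 60.0))]
        start, goal = (10.0, 10.0), (50.0, 55.0)
        food = (50.0, 60.0)
    else:
        raise MazeError(f"unknown fixture maze kind {kind!r}")
    return Maze(scale_factor=1, segments=segments, waypoints={},
                start=start, goal=goal, food_box=food)


# -- module-level operation wrappers (functional surface) ------------------

def set_block(maze: Maze, block_id: str, present: bool) -> Maze:
    return maze.set_block(block_id, present)


def available_actions(maze: Maze, pose: AgentPose, **kw) -> set[str]:
    return maze.available_actions(pose, **kw)


def step_agent(maze: Maze, pose: AgentPose, action: str,
               dt: float = DT) -> tuple[AgentPose, str]:
    return maze.step_agent(pose, action, dt)


def classify_route(maze: Maze, traj: Trajectory) -> str:
    return maze.classify_route(traj)


def rasterize_occupancy(maze: Maze, trajs: Iterable[Trajectory],
                        bin_cm: float = CELL_SIZE) -> np.ndarray:
    """Occupancy grid (seconds per bin); one DT dwell per trajectory sample."""
    w, h = maze.extent
    nx_, ny_ = int(np.ceil(w / bin_cm)), int(np.ceil(h / bin_cm))
    grid = np.zeros((nx_, ny_))
    for traj in trajs:
        for (x, y) in traj.positions:
            grid[int(x // bin_cm), int(y // bin_cm)] += DT
    return grid


def scripted_trajectory(maze: Maze, route: str) -> Trajectory:
    """Follow a named route exactly (a 'forced run' trajectory)."""
    nodes = maze.route_nodes(route)
    traj = Trajectory()
    t = 0.0
    heading = "N"
    for prev, cur in zip(nodes[:-1], nodes[1:]):
        dx, dy = cur[0] - prev[0], cur[1] - prev[1]
        for a, (ax, ay) in ACTION_VECTORS.items():
            if (np.sign(dx), np.sign(dy)) == (ax, ay):
                heading = a
                break
        t += DT
        event = "goal_reached" if cur == maze.food_box else "none"
        traj.append(t, cur, heading, heading, event)
    return traj
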