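"""Two-level cortical column network.

Level-1 columns become selective to places by Hebbian imprinting of the
hippocampal population vector (one-shot recruitment, slow tracking
afterwards); directed lateral weights learn the forward and reverse
associations between adjacent places, i.e. the environment's topology.
Level-2 columns compress the level-1 map into straight-corridor segments,
driven by a proprioceptive turn-probability signal that stays flat along a
corridor and jumps at turning points.

Each column carries three units -- s (state), g (goal back-propagation),
p (path / prospective) -- and one minicolumn per motor action with units
d (action value) and m (motor).  Unit rates are plain floats in Hz; the
network is a rate model, not a spiking one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

from .maze import ACTIONS, OPPOSITE
from .place_cells import PlaceCellPopulation

S_PEAK_RATE = 10.0  # Hz, nominal peak of the state units


class NetworkError(ValueError):
    pass


@dataclass
class NetworkParams:
    """Dynamics and plasticity constants.

    The goal-signal attenuations are calibrated so that after 10 synaptic
    relays the back-propagated signal sits at 0.35 Hz through level-1 links
    (lambda_u) and 0.90 Hz through level-2 shortcut links (lambda_m), from a
    3.0 Hz source.
    """

    # cosine similarity below which a new column is recruited; yields ~10 cm
    # level-1 field spacing over sigma = 7.5 cm input fields
    recruit_threshold: float = 0.8
    # slow post-imprint tracking of the afferent templates; fast tracking
    # drags fields along travel paths and distorts the relay-count metric
    afferent_tracking_rate: float = 0.05
    learning_rate: float = 0.5              # eta; lateral weights saturate at 1
    f0: float = 3.0                         # Hz, goal source rate
    lambda_u: float = (0.35 / 3.0) ** 0.1   # per level-1 relay, ~0.8067
    lambda_m: float = (0.90 / 3.0) ** 0.1   # per level-2 relay, ~0.8866
    noise_floor: float = 0.01               # Hz (nu)
    turn_threshold: float = 0.5             # level-2 recruitment on |d phi|
    f_p0: float = 3.0                       # Hz, path-unit base rate
    beta: float = 0.05                      # path-unit gain per plan rank
    # path-unit rise time constant: sets how far ahead of arrival a column's
    # prospective signal becomes visible (~1-2 upcoming columns)
    tau_p: float = 0.7
    epsilon: float = 0.05                   # exploration rate
    init_weight_scale: float = 0.05         # plastic weights start in [0, 0.05]

    def __post_init__(self) -> None:
        if not (0 < self.lambda_u < self.lambda_m < 1):
            raise NetworkError("require 0 < lambda_u < lambda_m < 1")
        if self.noise_floor >= self.f0:
            raise NetworkError("noise floor must sit below the source rate")


@dataclass
class Minicolumn:
    action: str
    d: float = 0.0  # goal back-propagation / action value
    m: float = 0.0  # motor


@dataclass
class Column:
    id: int
    level: int
    s: float = 0.0
    g: float = 0.0
    p: float = 0.0
    minicolumns: dict = field(default_factory=dict)

    def minicolumn(self, action: str) -> Minicolumn:
        if action not in self.minicolumns:
            if len(self.minicolumns) >= len(ACTIONS):
                raise NetworkError("more minicolumns than actions")
            self.minicolumns[action] = Minicolumn(action)
        return self.minicolumns[action]


class ColumnNetwork:
    """Plastic two-level columnar map over a place-cell input population."""

    def __init__(self, place_cells: PlaceCellPopulation,
                 params: NetworkParams | None = None,
                 seed: int = 0, use_level2: bool = True):
        self.place_cells = place_cells
        self.params = params or NetworkParams()
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.use_level2 = use_level2

        self.columns: list[Column] = []          # level-1, id = row index
        self.l2_columns: list[Column] = []       # level-2, id = index
        self.W_in = np.zeros((0, len(place_cells)))  # level-1 afferents
        # lateral weights, keyed (source id, action, target id); W_back mirrors
        # W_fwd from the target's side: W_back[(j, a, i)] pairs W_fwd[(i, a, j)]
        self.W_fwd: dict[tuple, float] = {}
        self.W_back: dict[tuple, float] = {}
        self.W_fwd2: dict[tuple, float] = {}
        self.W_back2: dict[tuple, float] = {}
        self.W_12: dict[int, int] = {}           # level-1 id -> level-2 id
        self.W_21: dict[int, set] = {}           # level-2 id -> member set
        # where each lateral edge was experienced (receptive fields span
        # several grid nodes; the exit of a column is a particular node)
        self.edge_sites: dict[tuple, tuple] = {}
        # turn-probability statistics per grid cell
        self.visit_counts: dict[tuple, int] = {}
        self.turn_counts: dict[tuple, int] = {}
        self._current_l2: int | None = None
        self._ref_phi: float | None = None
        self._pending_new = False

    # -- state coding ------------------------------------------------------

    def similarities(self, hp: np.ndarray) -> np.ndarray:
        """Cosine similarity of ``hp`` with every imprinted afferent vector."""
        hp = np.asarray(hp, dtype=float)
        if hp.shape[0] != self.W_in.shape[1]:
            raise NetworkError("input dimension mismatch")
        if len(self.columns) == 0:
            return np.zeros(0)
        norm = np.linalg.norm(hp)
        if norm == 0:
            return np.zeros(len(self.columns))
        return self.W_in @ (hp / norm)  # W_in rows are unit-norm

    def state_activation(self, hp: np.ndarray) -> np.ndarray:
        """Per-column s rates: clipped cosine scaled to a 10 Hz nominal peak."""
        s = np.clip(self.similarities(hp), 0.0, 1.0) * S_PEAK_RATE
        for col, rate in zip(self.columns, s):
            col.s = float(rate)
        return s

    def winner(self, hp: np.ndarray) -> int:
        sims = self.similarities(hp)
        if sims.size == 0:
            raise NetworkError("no columns recruited yet")
        return int(np.argmax(sims))

    def observe(self, hp: np.ndarray) -> tuple[int, np.ndarray]:
        """Recruit-or-adapt in one pass; returns (active column, similarities).

        Recruits a new level-1 column (one-shot imprint of the normalized
        input) when no existing column is similar enough; otherwise slowly
        nudges the winner's afferent template toward the input.
        """
        hp = np.asarray(hp, dtype=float)
        sims = self.similarities(hp)
        hp_hat = hp / np.linalg.norm(hp)
        thr = self.params.recruit_threshold
        if sims.size == 0 or float(np.max(sims)) < thr:
            cid = len(self.columns)
            self.columns.append(Column(id=cid, level=1))
            self.W_in = np.vstack([self.W_in, hp_hat[None, :]])
            return cid, np.append(sims, 1.0)
        w = int(np.argmax(sims))
        eta = self.params.afferent_tracking_rate
        v = (1 - eta) * self.W_in[w] + eta * hp_hat
        self.W_in[w] = v / np.linalg.norm(v)
        return w, sims

    def recruit_or_adapt(self, hp: np.ndarray) -> int:
        return self.observe(hp)[0]

    # -- lateral topology learning ----------------------------------------

    def _stores(self, level: int):
        if level == 1:
            return self.W_fwd, self.W_back
        return self.W_fwd2, self.W_back2

    def _check_id(self, cid: int, level: int) -> None:
        pool = self.columns if level == 1 else self.l2_columns
        if not (0 <= cid < len(pool)):
            raise NetworkError(f"unknown level-{level} column id {cid}")

    def learn_transition(self, prev: int, action: str, nxt: int,
                         level: int = 1, site: tuple | None = None) -> None:
        if prev == nxt:
            raise NetworkError("self-transitions are not learned")
        self._check_id(prev, level)
        self._check_id(nxt, level)
        fwd, back = self._stores(level)
        eta = self.params.learning_rate
        k_f, k_b = (prev, action, nxt), (nxt, action, prev)
        if k_f not in fwd:
            fwd[k_f] = float(self.rng.uniform(0, self.params.init_weight_scale))
            back[k_b] = fwd[k_f]
        fwd[k_f] = min(1.0, fwd[k_f] + eta)
        back[k_b] = fwd[k_f]
        if level == 1 and site is not None:
            self.edge_sites[k_f] = site

    def unlearn_blocked(self, col: int, action: str) -> None:
        """Depress the outgoing edge(s) (col, action, *) to zero at level 1.

        The level-2 map follows: a cut inside a segment splits its level-2
        column into one column per surviving connected part, and the level-2
        edge set is rebuilt from the remaining level-1 crossings (so an edge
        with no surviving level-1 support disappears).
        """
        removed_targets = []
        for (i, a, j) in [k for k in self.W_fwd
                          if k[0] == col and k[1] == action]:
            self.W_fwd.pop((i, a, j))
            self.W_back.pop((j, a, i), None)
            removed_targets.append(j)
        # the obstacle stands between the two places: sever the remaining
        # associations between the column pair in both directions
        for j in removed_targets:
            for (x, a, y) in [k for k in self.W_fwd
                              if {k[0], k[2]} == {col, j}]:
                self.W_fwd.pop((x, a, y))
                self.W_back.pop((y, a, x), None)
        if not removed_targets:
            return
        touched = {self.W_12.get(col)} | {self.W_12.get(j)
                                          for j in removed_targets}
        split = False
        for seg in touched:
            if seg is not None:
                split |= self._split_level2(seg)
        if self.l2_columns:
            self._rebuild_l2_edges()

    def _split_level2(self, seg: int) -> bool:
        """Split a level-2 column whose member subgraph fell apart."""
        members = self.W_21.get(seg, set())
        if len(members) < 2:
            return False
        adj: dict[int, set] = {m: set() for m in members}
        for (i, _a, j) in self.W_fwd:
            if i in members and j in members:
                adj[i].add(j)
                adj[j].add(i)
        comps = []
        seen: set[int] = set()
        for m in sorted(members):
            if m in seen:
                continue
            comp, stack = {m}, [m]
            seen.add(m)
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        comp.add(v)
                        stack.append(v)
            comps.append(comp)
        if len(comps) == 1:
            return False
        comps.sort(key=len, reverse=True)
        self.W_21[seg] = comps[0]
        for comp in comps[1:]:
            nid = len(self.l2_columns)
            self.l2_columns.append(Column(id=nid, level=2))
            self.W_21[nid] = comp
            for m in comp:
                self.W_12[m] = nid
        return True

    def _rebuild_l2_edges(self) -> None:
        """Re-derive level-2 lateral edges from level-1 crossings."""
        self.W_fwd2.clear()
        self.W_back2.clear()
        for (i, a, j) in self.W_fwd:
            ci, cj = self.W_12.get(i), self.W_12.get(j)
            if ci is not None and cj is not None and ci != cj:
                self.W_fwd2[(ci, a, cj)] = 1.0
                self.W_back2[(cj, a, ci)] = 1.0

    def fwd_edges(self, level: int = 1):
        return (self._stores(level)[0]).keys()

    def neighbors(self, col: int, level: int = 1) -> dict:
        """action -> target id for existing forward edges out of ``col``."""
        fwd = self._stores(level)[0]
        return {a: j for (i, a, j) in fwd if i == col}

    # -- turn statistics & level 2 ----------------------------------------

    def record_visit(self, cell: tuple, sharp_turn: bool) -> None:
        self.visit_counts[cell] = self.visit_counts.get(cell, 0) + 1
        if sharp_turn:
            self.turn_counts[cell] = self.turn_counts.get(cell, 0) + 1

    def turn_probability(self, cell: tuple) -> float:
        n = self.visit_counts.get(cell, 0)
        if n < 1:
            raise NetworkError(f"cell {cell} never visited")
        return self.turn_counts.get(cell, 0) / n

    def reset_l2_context(self) -> None:
        """Forget the within-walk running phi (call at trial starts)."""
        self._current_l2 = None
        self._ref_phi = None
        self._pending_new = False

    def update_level2(self, active_l1: int, phi: float,
                      action: str | None = None) -> int:
        """Map the active level-1 column to a level-2 column.

        Along a corridor phi stays near its running reference and successive
        level-1 columns join the same level-2 column; a rising jump beyond
        ``turn_threshold`` (entering a turning point) starts a new one, which
        the turning point and the following corridor share.  Existing
        assignments are stable: a level-1 column already covered keeps its
        level-2 column.
        """
        self._check_id(active_l1, 1)
        prev_l2 = self._current_l2
        crossing = (self._ref_phi is not None
                    and phi - self._ref_phi > self.params.turn_threshold)
        if active_l1 in self.W_12:
            l2 = self.W_12[active_l1]
            # a crossing on already-covered ground defers the recruitment
            # to the next uncovered column (entering a fresh corridor)
            self._pending_new = self._pending_new or crossing
        elif prev_l2 is not None and not crossing and not self._pending_new:
            l2 = prev_l2
            self._assign(active_l1, l2)
        else:
            l2 = len(self.l2_columns)
            self.l2_columns.append(Column(id=l2, level=2))
            self._assign(active_l1, l2)
            self._pending_new = False
        self._ref_phi = phi
        if prev_l2 is not None and prev_l2 != l2:
            self.learn_transition(prev_l2, action or "N", l2, level=2)
        self._current_l2 = l2
        return l2

    def _assign(self, l1: int, l2: int) -> None:
        self.W_12[l1] = l2
        self.W_21.setdefault(l2, set()).add(l1)

    def level2_of(self, l1: int) -> int | None:
        return self.W_12.get(l1)

    def boundary_columns(self, l2: int) -> set[int]:
        """Members of a level-2 segment with a lateral edge to another segment."""
        members = self.W_21.get(l2, set())
        out = set()
        for (i, _a, j) in self.W_fwd:
            if i in members and self.W_12.get(j) is not None \
                    and self.W_12[j] != l2:
                out.add(i)
        return out

    # -- bookkeeping -------------------------------------------------------

    def counts(self) -> dict:
        return {"hp": len(self.place_cells),
                "level1": len(self.columns),
                "level2": len(self.l2_columns)}

    def snapshot(self) -> str:
        """JSON snapshot of the learned structure (reproducibility aid)."""
        def enc(d):
            return {"|".join(map(str, k)): v for k, v in d.items()}
        return json.dumps({
            "seed": self.seed,
            "params": vars(self.params),
            "n_columns": len(self.columns),
            "n_l2": len(self.l2_columns),
            "W_in": self.W_in.tolist(),
            "W_fwd": enc(self.W_fwd), "W_back": enc(self.W_back),
            "W_fwd2": enc(self.W_fwd2), "W_back2": enc(self.W_back2),
            "W_12": {str(k): v for k, v in self.W_12.items()},
        }, sort_keys=True)


# -- functional wrappers ---------------------------------------------------

def state_activation(net: ColumnNetwork, hp) -> np.ndarray:
    return net.state_activation(hp)


def recruit_or_adapt(net: ColumnNetwork, hp) -> int:
    return net.recruit_or_adapt(hp)


def learn_transition(net: ColumnNetwork, prev: int, action: str,
                     nxt: int) -> ColumnNetwork:
    net.learn_transition(prev, action, nxt)
    return net


def unlearn_blocked(net: ColumnNetwork, col: int, action: str) -> ColumnNetwork:
    net.unlearn_blocked(col, action)
    return net


def turn_probability_signal(net: ColumnNetwork, cell: tuple) -> float:
    return net.turn_probability(cell)


def update_level2(net: ColumnNetwork, active_l1: int, phi: float) -> int:
    return net.update_level2(active_l1, phi)


def is_sharp_turn(prev_heading: str, heading: str) -> bool:
    """Heading change of 90 degrees or more."""
    return prev_heading != heading
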