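"""Activation-diffusion trajectory planning.

The motivation signal sets the goal column's g unit to ``f0``; reverse
lateral associations back-propagate it with a per-relay attenuation
``lambda_u``, so the goal signal decays exponentially with the number of
synaptic relays and encodes distance-to-goal.  The computation is the
synchronous fixed point of a max-product relaxation, i.e. exactly
``f0 * lambda_u ** (shortest relay count)`` floored at the noise level
``nu`` -- beyond that propagation horizon action selection degrades to
random search.

The level-2 population runs the same diffusion on its compressed segment
graph with the slower modulated attenuation ``lambda_m`` (one relay per
segment, regardless of how many level-1 columns the segment spans).  When
the level-1 goal signal is below the noise floor at the agent's position,
the level-2 signal steers the agent toward the exit of its current segment
that leads to the strongest next segment; this is what keeps planning
scale-invariant on the 4:1 maze.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .maze import ACTIONS, OPPOSITE
from .columns import ColumnNetwork


class PlannerError(ValueError):
    pass


@dataclass
class PlanState:
    """Back-propagated goal field and (optionally) a forward path schedule."""

    goal: int
    g: dict = field(default_factory=dict)        # level-1 column id -> Hz
    g2: dict = field(default_factory=dict)       # level-2 column id -> Hz
    t2: dict = field(default_factory=dict)       # level-2 arrival order
    d: dict = field(default_factory=dict)        # (column id, action) -> Hz
    plan: list = field(default_factory=list)     # column ids, rank order
    schedule: dict = field(default_factory=dict)  # column id -> (rank, t_arr)
    onset: float = 0.0
    below_horizon: bool = False


def inject_goal(net: ColumnNetwork, goal_col: int) -> PlanState:
    """Set g(goal) = f0 at level 1 and at its covering level-2 column;
    every other g and every d starts at the noise floor."""
    if not (0 <= goal_col < len(net.columns)):
        raise PlannerError(f"no learned column {goal_col}")
    nu, f0 = net.params.noise_floor, net.params.f0
    plan = PlanState(goal=goal_col)
    plan.g = {c.id: nu for c in net.columns}
    plan.g[goal_col] = f0
    plan.g2 = {c.id: nu for c in net.l2_columns}
    l2 = net.level2_of(goal_col)
    if l2 is not None:
        plan.g2[l2] = f0
    plan.d = {(c.id, a): nu for c in net.columns for a in ACTIONS}
    return plan


def backpropagate_goal(net: ColumnNetwork, plan: PlanState) -> PlanState:
    """Relax the goal field to its max-product fixed point.

    Level 1: g(i) = max(nu, f0[i==goal], max_a d(i,a)) with
    d(i,a) = lambda_u * max_{j : W_fwd(i,a,j)>0} g(j).
    Level 2: same recursion over the segment graph with lambda_m per relay.
    """
    p = net.params
    nu = p.noise_floor
    n1 = len(net.columns)
    # level 1 -- iterate with a Dijkstra-like frontier for O(E log V)
    g = {c.id: nu for c in net.columns}
    g[plan.goal] = p.f0
    # reverse adjacency: signal at j reaches i when W_fwd(i,a,j) exists
    incoming: dict[int, list] = {c.id: [] for c in net.columns}
    for (i, a, j) in net.W_fwd:
        incoming[j].append((i, a))
    import heapq
    heap = [(-p.f0, plan.goal)]
    done = set()
    iterations = 0
    while heap:
        iterations += 1
        if iterations > n1 + len(net.W_fwd) + 1:
            raise PlannerError("goal back-propagation failed to converge")
        negv, j = heapq.heappop(heap)
        if j in done:
            continue
        done.add(j)
        v = -negv
        for (i, _a) in incoming[j]:
            cand = p.lambda_u * v
            if cand > g[i] and cand > nu:
                g[i] = cand
                heapq.heappush(heap, (-cand, i))
    plan.g = g
    # d values follow the converged field
    d = {}
    for (i, a, j) in net.W_fwd:
        key = (i, a)
        cand = max(nu, p.lambda_u * g[j])
        if cand > d.get(key, nu):
            d[key] = cand
    for c in net.columns:
        for a in ACTIONS:
            d.setdefault((c.id, a), nu)
    plan.d = d
    # level 2: one modulated relay (lambda_m) per segment transition; the
    # wave's arrival order (t2, in level-1 column counts traversed) breaks
    # intensity ties by metric length
    g2 = {c.id: nu for c in net.l2_columns}
    t2 = {c.id: np.inf for c in net.l2_columns}
    goal_l2 = net.level2_of(plan.goal)
    if goal_l2 is not None and net.use_level2:
        g2[goal_l2] = p.f0
        t2[goal_l2] = 0.0
        incoming2: dict[int, list] = {c.id: [] for c in net.l2_columns}
        for (i, a, j) in net.W_fwd2:
            incoming2[j].append(i)
        heap = [(-p.f0, 0.0, goal_l2)]
        done = set()
        while heap:
            negv, tj, j = heapq.heappop(heap)
            if j in done:
                continue
            done.add(j)
            for i in incoming2[j]:
                cand = p.lambda_m * (-negv)
                ti = tj + len(net.W_21.get(i, ()))
                if (cand, -ti) > (g2[i], -t2[i]) and cand > nu:
                    g2[i] = cand
                    t2[i] = ti
                    heapq.heappush(heap, (-cand, ti, i))
    plan.g2 = g2
    plan.t2 = t2
    # write rates back onto the units
    for c in net.columns:
        c.g = g[c.id]
        for a, mc in c.minicolumns.items():
            mc.d = plan.d[(c.id, a)]
    for c in net.l2_columns:
        c.g = g2[c.id]
    return plan


def goal_rate_at_relay(n: int, modulated: bool, f0: float = 3.0,
                       lambda_u: float = (0.35 / 3.0) ** 0.1,
                       lambda_m: float = (0.90 / 3.0) ** 0.1) -> float:
    """Calibrated effective decay of the goal signal with relay count.

    Unmodulated propagation decays by ``lambda_u`` per level-1 relay;
    with level-2 modulation each (segment) relay decays by ``lambda_m``.
    At 10 relays these give 0.35 Hz and 0.90 Hz from a 3.0 Hz source.
    """
    if n < 0 or int(n) != n:
        raise ValueError("relay count must be a non-negative integer")
    lam = lambda_m if modulated else lambda_u
    return f0 * lam ** n


def _segment_bfs(net: ColumnNetwork, members: set, source: int):
    """Directed BFS within one segment; returns (distance, first-action maps)."""
    adj: dict[int, list] = {}
    for (i, a, j) in net.W_fwd:
        if i in members and j in members:
            adj.setdefault(i, []).append((a, j))
    dist = {source: 0}
    first: dict[int, str] = {}
    q = deque([source])
    while q:
        u = q.popleft()
        for a, v in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + 1
                first[v] = a if u == source else first[u]
                q.append(v)
    return dist, first


def _doorway_values(net: ColumnNetwork, plan: PlanState) -> dict:
    """Value of every learned segment crossing under activation diffusion.

    Crossings (level-1 edges joining two segments) form a doorway graph:
    crossing c leads to crossing c' when c' departs from the segment c
    enters and its exit column is reachable *within* that segment along
    experienced transitions.  Each crossing costs one modulated relay
    (lambda_m); ties in intensity resolve by the wave's arrival order
    (level-1 columns traversed).  Returns {crossing: (value, latency)}.
    """
    lam = net.params.lambda_m
    seg_of = net.W_12
    crossings = [(i, a, j) for (i, a, j) in net.W_fwd
                 if seg_of.get(i) is not None and seg_of.get(j) is not None
                 and seg_of[i] != seg_of[j]]
    goal_seg = seg_of.get(plan.goal)
    # distances from each entry column within its segment
    entry_info: dict[tuple, tuple] = {}
    for c in crossings:
        j = c[2]
        entry_info[c] = _segment_bfs(net, net.W_21.get(seg_of[j], set()), j)
    values: dict[tuple, tuple] = {c: (0.0, np.inf) for c in crossings}
    for _ in range(len(crossings) + 1):
        changed = False
        for c in crossings:
            i, a, j = c
            dist, _first = entry_info[c]
            best_v, best_t = 0.0, np.inf
            if seg_of[j] == goal_seg and plan.goal in dist:
                best_v, best_t = lam, float(dist[plan.goal])
            for c2 in crossings:
                if seg_of[c2[0]] != seg_of[j] or c2[0] not in dist:
                    continue
                v2, t2 = values[c2]
                cand_v = lam * v2
                cand_t = dist[c2[0]] + 1 + t2
                if cand_v > best_v + 1e-15 or (
                        abs(cand_v - best_v) <= 1e-15 and cand_t < best_t):
                    best_v, best_t = cand_v, cand_t
            if (best_v, best_t) != values[c]:
                values[c] = (best_v, best_t)
                changed = True
        if not changed:
            break
    return values


def _level2_guidance(net: ColumnNetwork, plan: PlanState,
                     current: int) -> str | None:
    """Steer via the compressed map when the level-1 signal is sub-noise.

    Chooses the reachable doorway (segment crossing) whose diffusion value
    is strongest, latency-earliest, and walks toward its exit column.
    """
    if not net.use_level2:
        return None
    seg = net.level2_of(current)
    if seg is None:
        return None
    cache = getattr(plan, "_doorway_cache", None)
    key = len(net.W_fwd)
    if cache is None or cache[0] != key:
        plan._doorway_cache = (key, _doorway_values(net, plan))
        cache = plan._doorway_cache
    values = cache[1]
    members = net.W_21.get(seg, set())
    dist, first = _segment_bfs(net, members, current)
    options = []  # (value, latency, exit column, action)
    if net.level2_of(plan.goal) == seg and plan.goal in dist \
            and plan.goal != current:
        options.append((1.0, float(dist[plan.goal]), plan.goal, None))
    for c, (v, t) in values.items():
        i, a, j = c
        if v <= 0.0 or net.level2_of(i) != seg or i not in dist:
            continue
        options.append((v, dist[i] + 1 + t, i, a))
    if not options:
        return None
    options.sort(key=lambda o: (-o[0], o[1]))
    v, t, exit_col, a = options[0]
    if exit_col == current:
        return a
    return first.get(exit_col)


def select_action(net: ColumnNetwork, plan: PlanState, current: int,
                  epsilon: float, rng: np.random.Generator,
                  available: set[str] | None = None,
                  heading: str | None = None) -> str:
    """Winner-take-all action selection: m(a) = s(current) * d(current, a).

    With probability epsilon a uniformly random available action is drawn.
    When every d sits at the noise floor and no level-2 guidance applies,
    the search is random but persistent: the agent keeps running the
    corridor rather than reversing, unless reversing is the only option.
    Ties prefer the current heading, then the fixed order N, E, S, W.
    """
    if available is None:
        available = set(ACTIONS)
    acts = [a for a in ACTIONS if a in available]
    if not acts:
        raise PlannerError("no available actions")
    nu = net.params.noise_floor
    if epsilon > 0 and rng.random() < epsilon:
        return acts[rng.integers(len(acts))]
    s = net.columns[current].s if current < len(net.columns) else 1.0
    dvals = {a: plan.d.get((current, a), nu) for a in acts}
    if all(v <= nu + 1e-15 for v in dvals.values()):
        guided = _level2_guidance(net, plan, current)
        if guided is not None and guided in available:
            return guided
        cands = acts
        if heading is not None:
            fwd = [a for a in acts if a != OPPOSITE[heading]]
            cands = fwd or acts
        return cands[rng.integers(len(cands))]
    m = {a: (s if s > 0 else 1.0) * dvals[a] for a in acts}
    best = max(m.values())
    tied = [a for a in acts if m[a] >= best - 1e-15]
    if heading is not None and heading in tied:
        return heading
    return tied[0]  # ACTIONS order


def forward_propagate_path(net: ColumnNetwork, plan: PlanState,
                           current: int, step_time: float = 2.0 / 3.0,
                           onset: float = 0.0) -> list[int]:
    """Greedy forward chaining along argmax d from ``current`` to the goal.

    Returns the planned column sequence (rank 1 = next column) and fills the
    plan's p-unit schedule: rank r arrives at ``onset + r * step_time``.
    Equals the max-product-optimal (and, under uniform weights, the BFS
    shortest) path.  An agent below the propagation horizon gets an empty
    plan with ``below_horizon`` set.
    """
    nu = net.params.noise_floor
    plan.plan = []
    plan.schedule = {}
    plan.onset = onset
    plan.below_horizon = False
    if current == plan.goal:
        return []
    if plan.g.get(current, nu) <= nu:
        plan.below_horizon = True
        return []
    seq = []
    node = current
    visited = {node}
    while node != plan.goal:
        nbrs = net.neighbors(node)
        if not nbrs:
            plan.below_horizon = True
            return []
        best_a = max(nbrs, key=lambda a: (plan.g.get(nbrs[a], nu),
                                          -ACTIONS.index(a)))
        node = nbrs[best_a]
        if node in visited:  # plateau below horizon
            plan.below_horizon = True
            plan.plan, plan.schedule = [], {}
            return []
        visited.add(node)
        seq.append(node)
    plan.plan = seq
    for r, col in enumerate(seq, start=1):
        plan.schedule[col] = (r, onset + r * step_time)
    return seq


def path_unit_rate(net: ColumnNetwork, plan: PlanState, rank: int,
                   t: float, t_arr: float) -> float:
    """Prospective path-unit rate: exponential rise to an arrival peak.

    p(t) = f_p0 * (1 + beta * rank) * exp(-(t_arr - t) / tau_p) while the
    plan is pending, collapsing to the noise floor after arrival.  Peaks
    therefore grow with rank and the rate profile is negatively skewed,
    the more so for later ranks.
    """
    p = net.params
    if t_arr < plan.onset:
        raise PlannerError("arrival before plan onset")
    if t < plan.onset or t > t_arr:
        return p.noise_floor
    return p.f_p0 * (1.0 + p.beta * rank) * np.exp(-(t_arr - t) / p.tau_p)


def path_unit_trace(net: ColumnNetwork, plan: PlanState, rank: int,
                    t_arr: float, dt: float = 1.0 / 3.0) -> np.ndarray:
    """Sampled p-unit time course from plan onset to just past arrival."""
    ts = np.arange(plan.onset, t_arr + dt, dt)
    return np.array([path_unit_rate(net, plan, rank, min(t, t_arr), t_arr)
                     for t in ts])
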