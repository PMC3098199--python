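import networkx as nx
import numpy as np
import pytest

from colnav.columns import NetworkParams
from colnav.planner import (PlannerError, backpropagate_goal,
                            forward_propagate_path, goal_rate_at_relay,
                            inject_goal, path_unit_rate, path_unit_trace,
                            select_action)

from conftest import make_bare_network, make_chain_net

LAM_U = (0.35 / 3.0) ** 0.1
LAM_M = (0.90 / 3.0) ** 0.1
NU = 0.01


class TestDecayRelation:
    def test_no_relay_returns_source_rate(self):
        assert goal_rate_at_relay(0, False) == pytest.approx(3.0)
        assert goal_rate_at_relay(0, True) == pytest.approx(3.0)

    def test_ten_relays_unmodulated(self):
        assert goal_rate_at_relay(10, modulated=False) == \
               pytest.approx(0.35, abs=0.01)

    def test_ten_relays_modulated(self):
        assert goal_rate_at_relay(10, modulated=True) == \
               pytest.approx(0.90, abs=0.01)

    def test_negative_relay_count_rejected(self):
        with pytest.raises(ValueError):
            goal_rate_at_relay(-1, True)

    def test_modulated_always_dominates(self):
        for n in range(30):
            assert goal_rate_at_relay(n, True) >= goal_rate_at_relay(n, False)


class TestInjection:
    def test_goal_rate_and_floor(self):
        net = make_chain_net(4)
        plan = inject_goal(net, 3)
        assert plan.g[3] == pytest.approx(3.0)
        assert all(plan.g[i] == NU for i in range(3))
        assert all(v == NU for v in plan.d.values())

    def test_goal_membership_lifts_level2(self):
        net = make_chain_net(3)
        for i in range(3):
            net.update_level2(i, 0.0, "N")
        plan = inject_goal(net, 2)
        assert plan.g2[0] == pytest.approx(3.0)

    def test_missing_goal_column_rejected(self):
        net = make_chain_net(2)
        with pytest.raises(PlannerError):
            inject_goal(net, 9)


class TestBackPropagation:
    def test_chain_closed_form(self):
        net = make_chain_net(3)
        plan = backpropagate_goal(net, inject_goal(net, 2))
        expect = [3 * LAM_U ** 2, 3 * LAM_U, 3.0]
        for i, e in enumerate(expect):
            assert plan.g[i] == pytest.approx(e, rel=1e-9)

    def test_goal_adjacent_cut_floors_downstream(self):
        net = make_chain_net(4)
        net.unlearn_blocked(2, "N")
        plan = backpropagate_goal(net, inject_goal(net, 3))
        assert plan.g[0] == plan.g[1] == plan.g[2] == NU

    def test_monotone_decay_along_optimal_path(self):
        net = make_chain_net(12)
        plan = backpropagate_goal(net, inject_goal(net, 11))
        gs = [plan.g[i] for i in range(12)]
        above = [g for g in gs if g > NU]
        assert above == sorted(above)

    def test_unreached_columns_sit_at_floor(self):
        net = make_chain_net(40)  # beyond the ~26-relay horizon
        plan = backpropagate_goal(net, inject_goal(net, 39))
        assert plan.g[0] == NU
        assert plan.g[38] > NU

    def test_modulation_only_adds_signal(self):
        params = NetworkParams()
        net = make_chain_net(8, params)
        for i in range(8):
            net.update_level2(i, 0.0, "N")
        with_l2 = backpropagate_goal(net, inject_goal(net, 7))
        net.use_level2 = False
        without = backpropagate_goal(net, inject_goal(net, 7))
        for i in range(8):
            assert with_l2.g[i] >= without.g[i] - 1e-12


def random_connected_digraph(rng, n):
    """Random connected graph with degree <= 4 (one minicolumn per action),
    experienced in both directions."""
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        candidates = [u for u in g.nodes if g.degree[u] < 4]
        g.add_edge(int(rng.choice(candidates)), v)
    for _ in range(int(rng.integers(0, n))):
        free = [u for u in g.nodes if g.degree[u] < 4]
        if len(free) < 2:
            break
        u, v = rng.choice(free, size=2, replace=False)
        if u != v:
            g.add_edge(int(u), int(v))
    return g


def wire(net, g):
    """Load an undirected graph into a network with per-node action labels."""
    used = {u: [] for u in g.nodes}
    actions = ["N", "E", "S", "W"]
    for (u, v) in g.edges:
        a_uv = next(a for a in actions if a not in used[u])
        a_vu = next(a for a in actions if a not in used[v])
        used[u].append(a_uv)
        used[v].append(a_vu)
        net.learn_transition(int(u), a_uv, int(v))
        net.learn_transition(int(v), a_vu, int(u))


class TestOracleEquivalence:
    def test_max_product_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(3, 13))
            g = random_connected_digraph(rng, n)
            net = make_bare_network(n)
            wire(net, g)
            goal = int(rng.integers(n))
            plan = backpropagate_goal(net, inject_goal(net, goal))
            for i in range(n):
                best = 0.0
                for path in nx.all_simple_paths(g, i, goal):
                    best = max(best, LAM_U ** (len(path) - 1))
                expect = max(NU, 3.0 * best) if i != goal else 3.0
                assert plan.g[i] == pytest.approx(expect, rel=1e-9), \
                    f"graph {trial}, node {i}"

    def test_planned_route_is_bfs_shortest(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(3, 13))
            g = random_connected_digraph(rng, n)
            net = make_bare_network(n)
            wire(net, g)
            goal = int(rng.integers(n))
            start = int(rng.integers(n))
            plan = backpropagate_goal(net, inject_goal(net, goal))
            seq = forward_propagate_path(net, plan, start)
            assert len(seq) == nx.shortest_path_length(g, start, goal)


class TestActionSelection:
    def _with_d(self, dvals):
        net = make_bare_network(2)
        for a in dvals:
            net.learn_transition(0, a, 1)
        plan = backpropagate_goal(net, inject_goal(net, 1))
        plan.d = {(0, a): v for a, v in dvals.items()}
        return net, plan

    def test_greedy_argmax(self, rng):
        net, plan = self._with_d({"N": 0.5, "E": 0.2, "S": 0.1})
        assert select_action(net, plan, 0, 0.0, rng) == "N"

    def test_floor_values_fall_back_to_uniform(self):
        net = make_chain_net(2)
        plan = inject_goal(net, 1)
        plan.d = {(0, a): NU for a in "NESW"}
        rng = np.random.default_rng(3)
        counts = {a: 0 for a in "NESW"}
        for _ in range(2000):
            counts[select_action(net, plan, 0, 0.0, rng)] += 1
        assert min(counts.values()) > 350  # roughly uniform

    def test_full_exploration_is_uniform(self, rng):
        net, plan = self._with_d({"N": 0.5, "E": 0.2})
        draws = [select_action(net, plan, 0, 1.0, rng,
                               available={"N", "E", "S"})
                 for _ in range(9999)]
        freqs = {a: draws.count(a) / len(draws) for a in "NES"}
        for f in freqs.values():
            assert abs(f - 1 / 3) < 0.02  # ~4 binomial sigma

    def test_no_actions_rejected(self, rng):
        net, plan = self._with_d({"N": 0.5})
        with pytest.raises(PlannerError):
            select_action(net, plan, 0, 0.0, rng, available=set())


class TestForwardPath:
    def test_chain_plan_ranks(self):
        net = make_chain_net(5)
        plan = backpropagate_goal(net, inject_goal(net, 4))
        seq = forward_propagate_path(net, plan, 0)
        assert seq == [1, 2, 3, 4]
        assert [plan.schedule[c][0] for c in seq] == [1, 2, 3, 4]

    def test_at_goal_plan_empty(self):
        net = make_chain_net(3)
        plan = backpropagate_goal(net, inject_goal(net, 2))
        assert forward_propagate_path(net, plan, 2) == []
        assert not plan.below_horizon

    def test_below_horizon_flagged(self):
        net = make_chain_net(40)
        plan = backpropagate_goal(net, inject_goal(net, 39))
        assert forward_propagate_path(net, plan, 0) == []
        assert plan.below_horizon


class TestPathUnits:
    def test_rate_at_arrival_rank_zero_is_base_rate(self):
        net = make_chain_net(2)
        plan = backpropagate_goal(net, inject_goal(net, 1))
        plan.onset = 0.0
        assert path_unit_rate(net, plan, 0, 5.0, 5.0) == \
               pytest.approx(net.params.f_p0)

    def test_onset_rates_decrease_with_rank(self):
        net = make_chain_net(8)
        plan = backpropagate_goal(net, inject_goal(net, 7))
        forward_propagate_path(net, plan, 0)
        onset_rates = [path_unit_rate(net, plan, r, 0.0, plan.schedule[c][1])
                       for c, (r, _t) in sorted(plan.schedule.items(),
                                                key=lambda kv: kv[1][0])]
        assert all(a > b for a, b in zip(onset_rates, onset_rates[1:]))

    def test_skewness_negative_and_growing_with_rank(self):
        from colnav.analysis import tuning_skewness
        net = make_chain_net(7)
        plan = backpropagate_goal(net, inject_goal(net, 6))
        forward_propagate_path(net, plan, 0)
        skews = []
        for c, (r, t_arr) in sorted(plan.schedule.items(),
                                    key=lambda kv: kv[1][0]):
            trace = path_unit_trace(net, plan, r, t_arr, dt=0.05)
            ts = np.arange(len(trace)) * 0.05
            skews.append(tuning_skewness(ts, trace))
        assert all(s < 0 for s in skews)
        assert all(abs(b) > abs(a) for a, b in zip(skews, skews[1:]))
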