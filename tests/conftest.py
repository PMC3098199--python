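import copy

import numpy as np
import pytest

from colnav.columns import Column, ColumnNetwork, NetworkParams
from colnav.config import agent_seed
from colnav.maze import build_tolman_maze
from colnav.place_cells import PlaceCellPopulation
from colnav.protocol import Agent, ExperimentConfig, run_agent


@pytest.fixture
def tolman():
    return build_tolman_maze(1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_bare_network(n_columns: int, params: NetworkParams | None = None,
                      seed: int = 0) -> ColumnNetwork:
    """A network with ``n_columns`` level-1 columns and no afferent code;
    lateral edges are added by the caller (planner unit tests)."""
    pop = PlaceCellPopulation(centers=np.zeros((1, 2)))
    net = ColumnNetwork(pop, params=params, seed=seed)
    for i in range(n_columns):
        net.columns.append(Column(id=i, level=1))
    net.W_in = np.zeros((n_columns, 1))
    return net


def make_chain_net(n: int, params: NetworkParams | None = None):
    """Chain 0 -> 1 -> ... -> n-1 (actions all N), goal at the end."""
    net = make_bare_network(n, params)
    for i in range(n - 1):
        net.learn_transition(i, "N", i + 1)
        net.learn_transition(i + 1, "S", i)
    return net


@pytest.fixture(scope="session")
def day1_agent():
    """One agent after the Day-1 schedule on the 1:1 maze (seeded)."""
    cfg = ExperimentConfig(scale=1, n_agents=1, master_seed=1)
    agent, records = run_agent(0, cfg, days=range(1, 2))
    return agent, records


@pytest.fixture(scope="session")
def trained_agent():
    """One agent after the full 15-day protocol on the 1:1 maze."""
    cfg = ExperimentConfig(scale=1, n_agents=1, master_seed=3)
    agent, records = run_agent(0, cfg)
    return agent, records


@pytest.fixture
def day1_agent_copy(day1_agent):
    agent, _ = day1_agent
    return copy.deepcopy(agent)


def fresh_agent(seed: int, scale: int = 1, **kw) -> Agent:
    cfg = ExperimentConfig(scale=scale, n_agents=1, master_seed=seed, **kw)
    return Agent(build_tolman_maze(scale), cfg, agent_seed(seed, 0))
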