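# colnav

A rate-model simulator of goal-directed spatial planning in a prefrontal
columnar network, tested on Tolman & Honzik's three-path detour maze.

Hippocampal place cells provide a dense, redundant spatial code (Gaussian
fields, σ = 7.5 cm, 10 Hz peak).  A population of cortical columns learns a
**topological map** on top of it: a column is recruited by one-shot Hebbian
imprinting of the place-cell population vector wherever no existing column
responds above a similarity threshold, and directed lateral weights learn
the forward and reverse associations between adjacent places as the agent
moves.  A second column population compresses this map into straight-alley
**segments**, driven by a proprioceptive signal φ that estimates the
probability of sharp heading changes at each location and jumps at turning
points.

Planning is **activation diffusion**: a motivation signal sets the goal
column's g unit to f₀ = 3 Hz, and reverse associations back-propagate it
with attenuation λ per synaptic relay, so

    g(i) = max(ν, f₀ · λᵤⁿ⁽ⁱ⁾),   λᵤ = (0.35/3)^(1/10) ≈ 0.807,

with n(i) the relay count of the shortest learned path to the goal and
ν = 0.01 Hz the noise floor.  Action selection is a local winner-take-all
over m = s·d, where d(i,a) = λᵤ·max_j g(j) over learned edges (i,a,j).
Beyond ~26 relays the signal drowns in the floor and search degrades to
(persistent) random exploration — unless the level-2 map relays the signal
across whole segments at the slower modulated attenuation
λₘ = (0.9/3)^(1/10) ≈ 0.887 per segment, which is what keeps planning
scale-invariant when the maze is four times larger.  Blocking a corridor
depresses the blocked association immediately, so replanning within a trial
follows from the same diffusion on the edited graph.

## Worked example

```python
from colnav import ExperimentConfig, run_tolman_protocol, phase_preference

result = run_tolman_protocol(ExperimentConfig(scale=1, n_agents=10,
                                              master_seed=1))
for phase in ("Day1", "Days2_14", "Day15"):
    print(phase_preference(result, phase))
```

prints (master seed 1):

```
{'phase': 'Day1', 'preferred': 'P1', 'proportions': {'P1': 1.0, 'P2': 0.0, 'P3': 0.0}, 'F': inf, 'p': 0.0, 'n_agents': 10}
{'phase': 'Days2_14', 'preferred': 'P2', 'proportions': {'P2': 0.99936, 'P3': 0.00064}, 'F': 1213682.0, 'p': 6.4e-45, 'n_agents': 10}
{'phase': 'Day15', 'preferred': 'P3', 'proportions': {'P2': 0.0, 'P3': 1.0}, 'F': inf, 'p': 0.0, 'n_agents': 10}
```

i.e. the canonical detour pattern: with no blocks the agents run the
shortest path P1; when block A interrupts P1 they detour through P2 (the
shorter alternative); and when the Day-15 block B interrupts the segment
shared by P1 *and* P2, they infer the detour and switch to P3 — the
"insight" result the task was designed to probe.  `proportions` are mean
per-agent selection rates over free choices (P1 is excluded from the
denominator in the blocked phases), and `p` is a one-way ANOVA across
agents.

The same protocol from a shell:

```
colnav simulate --scale 1 --agents 10 --seed 1 --out results/
colnav report results/
```

writes `trials.csv`, `selection_tables.csv`, `anova.json` and a summary.
`--scale 4` runs the 4:1 maze; `--no-level2` ablates the second column
population, which abolishes the detour discrimination at 4:1 but not 1:1.

## Layout

| module | contents |
| --- | --- |
| `colnav.maze` | discrete corridor world: three-path layout (1:1 / 4:1), blocks, one-way gate, agent kinematics, route classification, fixture mazes |
| `colnav.place_cells` | Gaussian place-field population |
| `colnav.columns` | two-level column network: recruitment, lateral topology learning, turn-probability signal, segment compression |
| `colnav.planner` | goal injection, attenuated back-propagation, level-2 doorway guidance, winner-take-all selection, prospective path units |
| `colnav.protocol` | the 15-day detour schedule, trial runner, selection tables, ANOVA |
| `colnav.analysis` | rate maps, spatial/phase information, sparseness, skewness, anticipation lags, PCA + k-means unit clustering |
| `colnav.recording` | Day-1 and probe recording sessions |
| `colnav.config`, `colnav.cli` | configuration, serialization, reporting, the `colnav` command |

See `docs/methods.md` for the model description, parameter table and known
limitations.
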