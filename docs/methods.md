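# Methods

## Environment

The maze is a lattice of nodes spaced 5 cm along corridor midlines;
corridors are 10 cm wide for occupancy and rate-map purposes.  The
three-path layout is schematic (the historical apparatus is only known to
fit a 1.20 × 1.55 m box): start S = (60, 10), first intersection
I1 = (60, 40), block A = (60, 80), second intersection J2 = (60, 100),
block B = (60, 120), goal entrance G = (60, 140), food box one node north
of G; Path 2 detours west via x = 30, Path 3 east via x = 100.  Route
lengths are 130 / 190 / 210 cm including the 30 cm common stem, scaled ×4
in the 4:1 maze (cell size unchanged).  Block A interrupts only Path 1;
block B interrupts the final segment shared by Paths 1 and 2.  A one-way
gate at J2 forbids moving south *out of* the gate node; the weaker reading
(no southward passage at all) would make the Day-15 return from block B to
the first intersection physically impossible, contradicting the protocol.
The agent moves at 15 cm/s; with Δt = 1/3 s one step is one node.  Illegal
moves are events (collision, block encounter), not errors.

Routes are classified from the final approach to the goal: walking the
trajectory backwards, the first pair of consecutive distinct positions
lying on one path's exclusive segment labels the trial (a single-node
bounce into an arm does not count as a traversal).

## Input code

87 place cells (1:1 maze) tile the midlines at 5 cm spacing with ≤1 cm
seeded jitter; rate = 10·exp(−d²/2σ²) Hz with σ = 7.5 cm.  Fields are
fixed and noise-free: cortical learning is assumed to start only once the
hippocampal code is stable, and Poisson spiking is synthesized downstream
only where spike-based statistics require it.

## Column network

**State coding.** A level-1 column's afferent weight vector is imprinted in
one shot as the normalized place-cell vector at recruitment; its state
rate is the clipped cosine similarity scaled to a 10 Hz peak.  Recruitment
fires when no column exceeds cosine 0.8 — with σ = 7.5 cm inputs this
tiles the corridor at ~10 cm, giving ~40 columns for the full 1:1 maze.
After imprinting the template tracks its inputs *slowly* (rate 0.05):
fast tracking drags fields along travel paths, makes spacing uneven across
routes, and thereby breaks the relay-count ≈ metric-distance relation the
planner relies on.

**Topology.** Moving between the fields of two columns potentiates the
forward and the reverse association (+0.5 per traversal, saturating at 1;
plastic weights start uniformly in [0, 0.05] from the seeded generator).
The planner needs edge existence, not graded strength.  Each level-1 edge
also remembers the node where it was experienced: receptive fields span
several grid nodes, so when the winning action is not physically available
at the agent's current node it path-integrates toward that exit site.

**Blocks.** A block encounter immediately depresses every association
between the two columns it separates, in both directions — the obstacle
stands between the places.  This is what lets action values at the first
intersection flip within a single trial.

**Level 2.** The turn-probability signal φ(cell) = sharp-turn count /
visit count (a sharp turn is a ≥90° heading change).  While φ stays flat,
successive level-1 columns bind to one level-2 column; a rising jump
> 0.5 (entering a turning point) starts a new one, which the turning point
and the following corridor share (an L-track therefore yields one column
per arm).  When the jump lands on already-covered ground the recruitment
defers to the next uncovered column.  Assignments are stable on revisits.
Level-2 lateral edges mirror experienced level-1 crossings between
segments; when a block cuts a segment internally the level-2 column splits
into its surviving connected parts and the level-2 edge set is rebuilt, so
the compressed map reflects the interruption — this is how the Day-15
"insight" (a block on the shared segment invalidates two routes at once)
reaches the planning level.

## Planning

Goal injection sets g(goal) = f₀ = 3 Hz (also at its covering level-2
column); back-propagation relaxes the field to the max-product fixed point
g(i) = max(ν, f₀·λᵤ^n(i)) with λᵤ = (0.35/3)^{1/10} per level-1 relay and
ν = 0.01 Hz, computed with a Dijkstra-style frontier (identical to
brute-force max-product over simple paths; the test suite checks this on
random graphs).  Action values are d(i,a) = λᵤ·max_j g(j); the
winner-take-all reads out m = s·d, with exact ties resolved first by the
current heading (pure fixed-order tie-breaking can trap the agent in
symmetric corridors) and then by the fixed order N, E, S, W; with
probability ε an available action is drawn uniformly.

The two attenuations are calibrated so that ten relays leave 0.35 Hz
(level-1, λᵤ) or 0.90 Hz (level-2-modulated, λₘ = (0.9/3)^{1/10}) from the
3 Hz source; `goal_rate_at_relay` exposes this decay relation.  The floor
ν puts the unmodulated horizon at ~26 relays: the 1:1 maze is entirely
inside it, the 4:1 maze is not — which is the point of the ablation.

**Level-2 guidance.** Where g sits at the floor, the compressed map steers
the agent.  Level-2 diffusion attenuates λₘ per segment relay; ties in
intensity resolve by the wave's arrival order (total level-1 columns
traversed, a conduction-delay proxy), so equally-compact routes still rank
by metric length.  Guidance operates on the *doorway graph*: crossings
between segments are nodes, connected only when the within-segment path
from entry to exit actually exists along experienced transitions.  This
reachability condition matters: a naive per-segment greedy rule can chase
a value that is unrealizable behind a fresh block and oscillate at a
segment boundary.  The agent walks toward the exit of the
strongest-then-earliest reachable doorway.  Where neither level carries
signal, search is random but persistent (no reversing unless at a dead
end): an unbiased Brownian walk is both unlike corridor running and
asymmetric in outcome, because it diffuses into the goal's capture region
more often via the nearer arm.

**Prospective path units.** Once the back-propagated signal reaches the
agent, forward propagation chains greedily along argmax d to the goal,
ranking the columns of the planned route.  A planned column's p unit rises
exponentially toward its scheduled arrival,
p(t) = f_p0·(1+β·rank)·exp(−(t_arr−t)/τ_p), then collapses to the floor;
f_p0 = 3 Hz, β = 0.05, τ_p = 0.7 s.  These constants are free parameters
of the model, calibrated once against its qualitative prospective-coding
signatures — path activity leads state activity by a positive lag
(~0.8 s), peak rates grow with rank, the time course is negatively skewed
with the magnitude increasing in rank, and path/motor units form a
cluster of transient units distinct from state units and from goal/value
units — and then frozen.  The plan recurs as the agent advances, which is
what makes the path signal anticipatory rather than tonic.

## Protocol

Day 1: forced runs through P1, P2, P3, then 9 free runs (ε = 0.5).  Days
2–14: per day, 10 block-A runs mixed with 2 non-successive free runs
(ε = 0.05); on block runs the entrances to P2/P3 are doored off, which
channels the agent along Path 1 to the block; after the bounce it retraces
its path to the first intersection (the protocol's forced return), where
the doors open.  Day 15: 7 probe trials with block B only.  175 trials per
agent; trials end at the food-box entrance or at 600 s, and timed-out
trials are labeled incomplete and excluded from selection tables.  Each
agent draws its place-cell jitter, weight initialization and policy noise
from child seeds spawned from one master seed.

Behavioral statistics: per-agent selection proportions per phase, compared
by one-way ANOVA across agents (forced runs excluded).  Day 1 scores
completed free runs by the route taken.  The blocked phases score the
*decision between P2 and P3 taken on returning to the first intersection*
— the first detour arm actually traversed after the first block
encounter's return (or from the trial start when nothing was encountered)
— because that is what a blocked trial selects: on Day 15 every completed
trajectory is physically forced through P3, so completed-route counting
cannot distinguish an agent that infers the detour from one that blunders
into it, whereas the intersection decision can.  P1 is excluded from the
blocked-phase denominator.  Zero-spread degenerate tables short-circuit to
(F = 0, p = 1) when all values coincide and (F = ∞, p = 0) when groups are
distinct constants.

## Analyses

Rate maps are occupancy-normalized over 5 × 5 cm bins; field size counts
visited bins ≥ 20% of the map peak (a convention, exposed as a
parameter).  Single-unit spatial information uses the plug-in MI between
8-quantile-binned rates and position bins, plus the Skaggs per-spike
measure.  Population information is the decoder lower bound — a
leave-one-trial-out nearest-centroid population-vector decoder over 5 cm
bins, with I(decoded; true) compared to the occupancy entropy as the
"theoretical upper bound" (direct high-dimensional plug-in estimation is
infeasible).  Sparseness: excess kurtosis over time (lifetime) and across
units per location (population), and the ratio of population MI to summed
single-unit MI.  Tuning skewness is the third standardized moment of the
rate-weighted coordinate; anticipation lag is the cross-correlation peak
(positive = first trace leads).  Unit clustering standardizes six per-unit
statistics (mean rate, SD, skewness, lifetime kurtosis, information per
spike, spatial MI), projects onto the first three principal components and
runs seeded k-means with 10 restarts; k = 3 by default ("three main
groups": goal/value, state, transient path/motor).

The probe recording session walks every route under each block condition
(blocked edges silenced on the learned map), so task phase is not
confounded with position; motor units are winner-gated, the losing
minicolumns being suppressed by the local competition.

## What the synthetic setting does and does not show

All inputs are generated: the maze is ideal (no sensory noise, perfect
self-localization through noise-free place fields), place fields neither
remap nor drift, and rates are deterministic unless spikes are synthesized.
Passing tests therefore demonstrate the *mechanistic* claims — topology
learning, diffusion planning, segment compression, detour inference, the
coding signatures — under clean conditions; they do not show robustness to
sensory noise, remapping, or real rats' behavioral variability.  Problem
sizes used by the test suite and the acceptance script (10 agents per
behavioral comparison, 5 agents for the population-information estimate)
are scaled down from the 40-agent populations the full protocol defaults
to; the statistics are across-agent and remain valid at the smaller n.

## Known limitations

No spiking dynamics, interneuron diversity, theta phase or sleep
consolidation; reward is a scalar motivation signal; a single goal at a
time; the turn-probability estimator never forgets, so a radically
rearranged maze would segment poorly; the level-2 guidance readout
(doorway graph) is an algorithmic idealization of recurrent dynamics the
source architecture leaves unspecified.
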