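# Methods

## Model

Navigation is modelled as an episodic pathfinding MDP on a 4-neighbour
maze graph: states are nodes, actions are the compass directions with an
existing edge (no wall-bump self-loops), transitions are deterministic,
the reward is −1 per step and the goal is absorbing with reward 0. The
value of a policy is therefore −(expected steps to goal), computed exactly
by solving the absorption linear system — never by sampling.

The *default policy* ρ encodes a habitual, extensively trained route: at
route nodes the trained action has probability 1 − ε and the remaining ε
is split over the other available actions; nodes the route never visits
get a uniform distribution. The smoothing is required for the construct to
make sense: with a strictly deterministic route, any deviation — including
travelling the route backwards, a behaviour that plainly occurs — would
carry infinite information cost. ε defaults to 0.05 and is a single
documented knob; larger ε compresses the cost difference between on-route
and off-route steps.

*Control information* is the expected cumulative KL divergence of the
executed policy from ρ, in nats. For each β ≥ 0, minimising the free
energy F = I − βV yields the soft Bellman fixed point

    F*(s) = −log Σ_a ρ(a|s) exp(β R(s,a) − F*(P(s,a))),   F*(goal) = 0,

whose minimiser is π*(a|s) ∝ ρ(a|s) exp(βR − F*(succ)). The frontier is
the curve of (I, V) pairs of π*_β over a β grid; it is concave, runs from
(0, V_ρ) at β = 0 to (I_min(V*), V*) as β → ∞, and upper-bounds every
achievable policy. Empirically scored trials are placed in the same plane
and classified by Euclidean distance from the piecewise-linear frontier
(extended horizontally right of its last point — information spent beyond
the optimum buys nothing).

## Estimator conventions

A recorded trial is a single trajectory, not a policy expectation. The
per-trial policy estimate π̂ comes from the state–action co-occurrence
counts of that trial (a state visited twice with different actions gets a
split estimate). The empirical control information sums per-state KL terms
along the trajectory; by default once per *time step* (`per_visit`, the
accumulation that defines the expected cost), optionally once per unique
state (`per_state`). The two coincide for simple paths; `per_visit`
dominates otherwise.

Two consequences are worth keeping in mind when interpreting results:

- For a trial that follows the default route exactly, π̂ is a point mass,
  so each on-route step still costs −ln(1 − ε) ≈ 0.051 nats. The
  estimate is biased upward by ≈ 0.051 × path length relative to the true
  I = 0 of the default policy itself.
- The estimate of a *stochastic* policy's single trajectory is not that
  policy's expectation, so a trial's point may land marginally above the
  frontier interpolant. The distance computation treats points within a
  small tolerance (1e-4, absorbing the chordal undershoot of the finite β
  grid) as on-curve; the trial-metrics layer clamps any remaining
  overshoot to distance 0.

## Tunable parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| ε (default-policy smoothing) | 0.05 | probability | finite off-route cost |
| β grid | {0} ∪ 60 points geometric in [1e-3, 1e3] | — | frontier resolution |
| solver tolerance | 1e-12 | sup-norm nats | fixed-point stop; keeps F = I − βV to <1e-8 |
| τ (on-curve classification) | 0.05 | distance units (nats/steps plane) | strategy classes |
| β_RGI | 50 | — | near-optimal goal-conditioned policies, numerically smooth |
| goal prior | uniform over the 12 landmarks | — | RGI mixture |
| v_threshold | 1 | distance units / frame | VTE halt detection |
| θ̇_threshold | 10 | degrees / frame | VTE sweep detection |
| frame rate | 10 | Hz | resampling before per-frame thresholds |
| initiation threshold | 0.5 | grid units | first departure from start |
| trial cutoff | 40 | s | cohort-level exclusion |

Relevant goal information uses shortest-path action values
Q_g(s, a) = −1 − d(P(s,a), g) and alternating updates
p(a|s,g) ∝ p(a|s) exp(β_RGI Q_g), p(a|s) = Σ_g p(g) p(a|s,g), initialised
from uniform marginals; the rate-distortion objective I(G;A|s) − β_RGI E[Q]
decreases monotonically and iteration stops when its change is below
1e-12. A goal colocated with the evaluated state poses no action demand
and is dropped there, with the prior renormalised — the only convention
that keeps RGI well defined without inventing a "stay" action. Values are
nats internally, bits on request.

The "closeness" reported alongside betweenness is the harmonic form
Σ_t 1/d(s, t) — what the centrality literature calls harmonic centrality —
implemented exactly as such; betweenness is endpoint-excluding and
normalised by (n−1)(n−2)/2 (normalisation does not affect correlations).

## Synthetic data

The bundled maze is a 66-node map with 12 landmarks on the periphery and
6 intersections: a rectangular peripheral ring (the training route, a
closed clockwise loop visiting every landmark), two internal corridors
crossing the middle (the shortcuts) and two internal dead-end stubs. The
published description of the environment it emulates fixes only these
counts, not the exact wall layout, so the fixture is faithful to the
counts (asserted in tests) rather than edge-for-edge identical to any
particular map.

Agents are bounded-rational by construction: they sample π*_β. The cohort
generator emulates a two-group instruction design with planted effects:

- "Go To Goal" (GTG): β = β₀ + c·(reward gap), β₀ = 0.3, c = 0.04 —
  resource investment scales with what a shortcut could earn on that
  start–goal pair. The *reward gap* is the shortest-route reward minus the
  exact default-policy value.
- "Take Shortcut" (TS): β ~ max(N(5, 1), 3), independent of the gap —
  uniformly high investment.
- Genders are assigned at random with no planted effect.

The renderer converts a discrete path to frames at 10 Hz: an initial
stationary initiation period (truncated normal, mean 1.95 s, sd 0.5 s),
constant-speed motion at 2.5 grid units/s (4 frames per edge), heading
turning toward the travel direction at no more than 10°/frame, positional
jitter uniform within ±0.08 grid units, and — with probability
logistic(−3 + 2.5·RGI(node)) at each interior node — a planted
pause-and-sweep block (an even number of zero-speed frames alternating
±45° heading jumps). Because normal motion never exceeds the angular
threshold and sweep frames always do, a render's detected VTE frames are
exactly the planted ones, which makes the detector testable frame-for-
frame. Trials longer than 40 s are dropped and logged. All randomness
descends hierarchically (participant → trial) from one master seed.

What the generator does *not* emulate: perceptual noise and drift in the
continuous traces, dead-reckoning errors, learning within the session,
head movements outside decision points, and any within-participant
consistency beyond the instruction rule. Passing tests therefore show that
the pipeline recovers planted structure of this generative family — not
that real navigators follow Boltzmann policies.

Two construct-level couplings surfaced by the synthetic cohorts are worth
recording. First, the information-per-step of a reward-optimal path is
mechanically an increasing function of the reward gap (a larger gap means
a larger off-route fraction of the shortest path), so even the
gap-independent TS group shows a positive regression slope of information
per step on reward gap; a flat slope, as reported for human shortcut
takers, indicates behaviour outside the optimal-β-agent family. Second,
the single-trajectory estimator bias (0.051 nats per on-route step) is
largest for low-β wanderers, which is why mean empirical information at
β = 0 can exceed that at β = 0.5 on easy tasks; the recovery test
stratifies start–goal pairs across the gap range so each β regime is
represented. Third, the per-state VTE mean at rarely-visited states rests
on one or two trials, so a single planted pause inside a cul-de-sac can
produce an extreme per-state value and destabilise the RGI–VTE
correlation; `graph_metrics.dead_end_states` (iterative leaf pruning of
the dead-end arms) provides the exclusion list the correlation analyses
use, mirroring the usual removal of dead-end states from such maps.

## Numerical choices

- Log-sum-exp with max shift everywhere; the solver iterates from F = 0
  and stops at sup-norm change < 1e-12 (max 100 000 iterations; the
  fixture needs < 200). β = 0 terminates immediately with F = 0 and
  π* = ρ exactly.
- Exact linear solves (dense, 66 states) for values and accumulated
  information; impropriety (a recurrent class missing the goal) is
  detected on the policy's support digraph and raised, not silently
  diverged.
- Nearest-node snapping breaks ties by lowest node id; lenient
  discretization bridges non-adjacent jumps by the unique shortest path
  and errors on ambiguity; trials not ending at the goal are retained and
  flagged incomplete.
- Heading arithmetic wraps differences to (−180°, 180°]; resampling of
  irregular timestamps interpolates headings on the circle (shortest arc).
- Frontier distance is measured in raw units (nats on x, steps on y);
  axis scales are exposed for callers who prefer a normalised plane.
- The dependent-correlation contrast (e.g. RGI–VTE vs betweenness–VTE)
  uses the Meng–Rosenthal–Rubin z for overlapping correlations, validated
  in the tests against a direct Monte-Carlo reference.

## Problem sizes

The test suite and the acceptance script use the study-sized cohort
(30 participants × 40 trials per group; ~2 400 trials) on the 66-node
fixture; the large-sample oracle for the RGI–VTE correlation uses a 10×
cohort (300 participants per group), at which the oracle correlation is
stable to ~0.01. Frontier caches solve 61 β values per goal
(12 goals). The full suite runs in under two minutes on one CPU.

## Known limitations

- The exact ε, β grid, distance metric and RGI temperature of the study
  the package emulates are not published; all are exposed as configuration
  with the defaults above.
- Deterministic transitions only: no slip noise, no continuous-space MDP.
- The frontier assumes the trained route as the zero-cost default;
  alternative defaults (uniform, vector-based) can be supplied as any
  full-support `Policy`, but the cohort generator always trains the
  peripheral loop.
- Strategy classification depends on τ and on the estimator conventions
  above; counts are comparable within a configuration, not across ones.
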