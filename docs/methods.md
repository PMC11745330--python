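# Methods

## Scope

`t6sim` simulates contact-dependent antagonism between rod-shaped bacteria
armed with type VI secretion systems (T6SS), and the evolution of
resistance to single- and multi-toxin arsenals. It has three layers:

1. a 2-D agent-based engine (rod-cell mechanics, stochastic needle firing,
   multi-toxin intoxication, corpse lysis);
2. replicated spatial competitions with the standard summary statistics
   (competitive advantage, Malthusian fitness, extinction flags,
   cross-protection sweeps);
3. a mutate–select–replace adaptive-walk engine with two selection
   backends: spatial competitions (`abm`) and an analytic fixation rule
   (`simplified`).

## Toxin response model

Each cell carries per-toxin sensitivities `a_i ∈ [0, 1]` and accumulates
intracellular toxin amounts `x_i` (one hit from an attacker with arsenal
`d` adds `d_i` to each `x_i`). Integrity is

    I = 1 − Σ_i a_i x_i − Σ_i Σ_j B_ij x_i x_j ,

with death at `I ≤ 0`. The interaction matrix `B` is zero by default
(additive toxins); positive entries encode synergy, negative entries
antagonism, and a non-zero diagonal a nonlinear single-toxin
dose–response. The double sum runs over all ordered pairs, so a symmetric
off-diagonal pair contributes twice.

With additive toxins, phenotypic resistance has the closed form
`N_hits = ⌈1 / Σ_i a_i d_i⌉` (infinite when the arsenal misses every
sensitivity). The ceiling is evaluated in the same floating-point
arithmetic the engine's integrity bookkeeping uses, so the closed form and
repeated dosing agree even at knife-edge reciprocals. With `B ≠ 0` the
closed form is invalid and hits-to-death is computed by direct repeated
dosing; under net antagonism integrity is an upward parabola in the hit
count, and a cell past the vertex while still alive is reported as
unkillable (`∞`).

The death threshold is `I ≤ 0` (not strictly below): the fully sensitive
cell (`a = 1`) receiving one unit dose reaches `I = 0` exactly and must
die for `N_hits = 1` to hold.

## Cell biophysics

Cells are spherocylinders of fixed radius `R = 0.5 µm` and variable axis
length `L`. In 2-D we take "volume" to be the capsule footprint area
`V = 2RL + πR²`, making the `V ↔ L` conversion closed-form. Volume grows
exponentially, `dV/dt = k_grow·V`; the default `k_grow = ln 2 / 2.5 h⁻¹`
gives four doublings over a 10 h competition. At `V ≥ 2V₀ + η` (birth
volume `V₀`, division noise `η ~ U[−0.1·V₀, 0.1·V₀]`) the cell splits
into two equal-volume daughters placed end-to-end along the parent axis.
Daughters record their own birth volume, draw fresh noise, and inherit the
parent's accumulated toxin load unchanged (no dilution and no healing; the
model is agnostic about intracellular toxin turnover, which is assumed
constant on simulation timescales). Newborn default geometry is
`L₀ = 1 µm` (total tip-to-tip length 2 µm, a typical newborn rod).

Mechanical exclusion is a position-based relaxation: candidate capsule
pairs come from an unbounded square grid (10 µm bins; every cell is
registered in all bins overlapped by its slack-inflated bounding box), and
each iteration pushes every overlapping pair apart symmetrically along the
contact normal by half the damped penetration depth (damping 0.7), with
the matching torque applied as a small rotation. Iteration stops when no
pair overlaps by more than the tolerance (0.02 µm, 4 % of the cell radius)
or after 100 iterations. The inner loop is a compiled (numba) kernel; the
surrounding Python refreshes the candidate list only when accumulated
per-cell travel could make it stale.

In a confluent growing colony this bounded solve saturates: radial
expansion propagates roughly one contact layer per iteration, so large
colonies end each step with a small stable residual overlap
(≈ 0.05–0.08 µm in the largest runs). We treat this as the numerical
signature of compressive stress in a packed colony; it does not grow over
time and does not measurably affect the population-level statistics. The
competition loop therefore silences the per-step saturation warning;
direct calls to `relax_overlaps` still warn.

The plane is unbounded (no periodic boundary): colonies seeded in a disc
expand freely.

## T6SS engine

Every timestep each living attacker fires `Poisson(k_fire·Δt)` needles
from uniform-random points on its membrane. Needles have length one cell
radius and point along the outward surface normal at their base (a
uniform outward-half-plane direction is available via
`direction_mode="uniform"`). A line-segment test finds, per needle, the
first capsule the segment enters (smallest entry parameter), excluding the
firer; the struck cell receives the firer strain's full dose vector unless
it belongs to the same strain (clonemates are perfectly immune; attackers
are additionally immune to everything by carrying all-zero sensitivities).
Dead-but-unlysed cells absorb hits — a "corpse barrier" that can shield
cells behind them — and are removed `1/k_lysis` hours after death
(default `k_lysis = 2 h⁻¹`, i.e. 0.5 h corpse persistence). Overkill doses
on corpses accumulate harmlessly.

The step order is fixed: grow → divide → relax → fire → resolve hits →
intoxicate → cull/lyse.

### Firing-rate calibration

The population firing rate `k_fire` is the one biophysical rate we
calibrated in-repo rather than taking from a source: its default must
reproduce the qualitative structure of the single- vs two-toxin selection
maps at desk scale. Because a fully sensitive cell dies after one hit,
any `k_fire ≳ 2 h⁻¹` exterminates the susceptible strain in essentially
every 10 h replicate (the mutant:susceptible advantage is then undefined
everywhere), while `k_fire = 1 h⁻¹` leaves the susceptible strain
decimated but countable, giving a well-defined selection map: a rare
toxin-A-immune mutant gains a large advantage against a single-toxin-A
attacker and none against a two-toxin attacker. `k_fire = 1.0` is
therefore the default; both rates are ordinary config fields.

## Competitions

Competitions seed the strains uniformly at random (positions, orientations,
and initial volumes `U[V₀, 2V₀)` so division is desynchronised) in a disc
— canonically 500 attackers : 90 susceptible : 10 mutant cells in a 50 µm
radius — then run the timestep loop (default `Δt = 0.025 h`) for 10 h,
terminating early if every non-attacker strain is extinct. Summaries:

* competitive advantage `CA = (N_mut/N_sus)_final / (N_mut/N_sus)_initial`,
  with degenerate outcomes encoded explicitly (mutant extinct → 0,
  susceptible-only extinct → +∞, both → NaN) so means can be taken over
  replicates where the statistic is defined;
* absolute fitness `log₂(N_final/N_start) / Δt` in divisions per hour
  (−∞ on extinction);
* per-strain and all-target extinction flags.

Replicate `r` of a run with seed `s` draws its RNG stream from
`SeedSequence([s, r])`, so results are reproducible and independent of
scheduling.

The cross-protection sweep runs single-toxin competitions over a grid of
attacker density, target density, mutant frequency, and growth-cost
coefficient, comparing each grid point against a control in which the
"mutant" is itself fully susceptible; cross-protection is flagged when the
susceptible strain's fitness is significantly higher alongside the
resistant mutant (one-sided Welch test across replicates).

## Adaptive walks

A walk starts from full susceptibility `(1, …, 1)`. Each step proposes a
mutant by perturbing every sensitivity with independent `Normal(0, σ²)`
draws (default `σ = 0.1`); any vector leaving `[0, 1]` is redrawn whole,
so accepted proposals follow the truncated joint distribution. Selection:

* **abm** — a tripartite competition (attacker : resident : mutant,
  500:90:10 by default, 1.5 h). The mutant replaces the resident iff its
  competitive advantage over the resident strictly exceeds 1; stochastic
  advantages let near-neutral mutants drift to fixation. If no target cell
  survives, the walk terminates as an extinction.
* **simplified** — the mutant fixes iff its phenotypic resistance strictly
  increases (`Δ N_hits > 0`). Drift and extinction are absent, so the
  fixation barrier is higher; at `σ = 0.1` against a single toxin the walk
  typically plateaus at `N_hits = 2`, because climbing further requires a
  single ≳4σ jump (the staircase between resistance levels widens as
  `1/n`). Larger σ lets walks descend much deeper.

With `B ≠ 0`, the simplified rule compares brute-force hits-to-death
instead of the additive closed form. With a resistance cost, it compares a
net-fitness score: cost-discounted growth rate minus an intoxication
hazard `hit_rate / N_hits` (defaults: growth `ln 2 / 2.5 h⁻¹`,
`hit_rate = 1 h⁻¹`). At zero cost this reduces exactly to the `Δ > 0`
rule. Growth costs are linear in total insensitivity,
`max(0, 1 − c·Σ(1−a_i))`, clipped at zero.

Per-step randomness derives from `SeedSequence([walk seed, step])`;
replicate walks derive their seeds by spawning from the run seed.

## Problem sizes

Full-scale settings (600-cell discs, 20–30 replicates, 10 h) are the
package defaults. The test-suite and the reproduction script use
proportionally scaled instances chosen to preserve the canonical seeding
density (e.g. 150:27:3 cells in a `50·√0.3 ≈ 27.4 µm` disc) and, for the
agent-based walk contrasts, a denser/deadlier regime (100:9:1 cells,
16 µm, `k_fire = 6`) in which per-step extinction is possible, so the
extinction-frequency contrast between single- and two-toxin attackers is
measurable with 12 walks of 12 steps.

## What the synthetic conditions do and do not show

All inputs are synthetic configurations; there is no external data. The
generator reproduces the study conditions (seeding ratios, disc geometry,
durations, mutation kernel) but idealises real communities: no nutrient
gradients or growth-rate heterogeneity, no macroscale structure beyond one
disc, perfect clonemate immunity, no immunity-protein exchange, no clonal
interference (one mutant lineage at a time), and 2-D monolayer mechanics.
Passing tests therefore demonstrate the internal logic of the model —
which mutations are selected, when lineages go extinct, how arsenals
interact — not quantitative predictions for any particular organism.

## Known limitations

* The relaxation is a bounded-iteration position-based solver, not an
  energy minimiser; its residual stress in packed colonies is tolerance-
  and budget-dependent.
* `N_hits` treats hits as whole units; fractional or stochastic dose
  delivery is not modelled.
* The simplified backend's cost score is a mean-field proxy; its
  `hit_rate` is a free parameter, not fitted to the spatial engine.
* Extinction in the `abm` backend is assessed at the end of each 1.5 h
  selection episode; rescue dynamics within an episode are not tracked.
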