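# Methods

## The model

`pillarsim` simulates non-interacting bacteria as single-pixel agents on a
square lattice field (default 256 × 256 px) containing circular obstacles
("pillars", radius 6 px) that represent soil particles.  Empty pixels are
pore space.  The dynamics are asynchronous: each global time step processes
the agents sequentially in a freshly shuffled random order, and each agent
undergoes, in order,

1. **death** with probability δ (default 0.01 per agent per step; the pixel
   is freed immediately),
2. **movement**: one of the 8 Moore neighbours is drawn uniformly; the agent
   relocates iff the target is inside the field, not a pillar, and
   unoccupied.  A blocked draw is not resampled, so the per-step movement
   probability equals the fraction of free neighbours.  Walls are closed
   (moves off the field fail like pillar hits) and are not part of any
   periphery band,
3. **energy update**: the duplication energy E_D ∈ [0, 1] gains the growth
   rate g (default 0.1) and loses the movement cost c if and only if the
   agent actually moved this step and energy consumption is enabled; the
   result is clamped to [0, 1],
4. **duplication**: an agent whose (post-clamp) E_D has reached 1 and that
   has at least one empty Moore neighbour places a daughter (E_D = 0, move
   count 0) on a uniformly drawn empty neighbour and resets its own E_D
   to 0.  An agent at E_D = 1 with no empty neighbour keeps E_D = 1 and
   retries on later steps — near carrying capacity most agents are parked at
   E_D = 1, which is what lets death-created vacancies refill within a step
   or two and holds steady-state occupancy near 99%.

Daughters created during a step do not act until the next step.  Sequential
(asynchronous) updating avoids move-collision ambiguity entirely; the
alternative synchronous scheme would need a conflict-resolution rule with no
observable benefit at these densities.

Floating-point detail: energies are sums of g and c, so "E_D = 1" is tested
with a 1e-9 tolerance (ten increments of 0.1 fall one ulp short of 1.0 in
binary floating point).  A stationary agent therefore duplicates first at
exactly step ⌈1/g⌉ = 10.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| field size | 256 | px | standard study condition |
| pillar radius | 6 | px | standard study condition |
| growth rate g | 0.1 | energy/step | standard study condition |
| death probability δ | 0.01 | 1/step | standard study condition |
| initial cells | 100 | agents | standard study condition |
| movement cost c | 0.09 | energy/move | replacement balance, see below |
| array gap | 8 | px | block arrangement with d = 8 must equal the array |
| fractal min gap | 3 | px | stated minimum pore width |
| periphery band | 3 | px (Euclidean) | see below |

**Movement cost.**  The cost is the one load-bearing unknown.  A freely
moving agent (move probability ≈ 1) gains g − c per step, so its duplication
interval is 1/(g − c) while its expected lifetime is 1/δ; the replacement
threshold is c* = g − δ = 0.09.  At c = 0.09 the open (bulk) field is
non-growing, while agents whose movement is partially blocked by pillars are
super-critical — growth then nucleates at pillar peripheries and in pore
throats, fastest in the fractal arrangement, slower in the array, and not at
all in bulk, reproducing the qualitative arrangement ordering.  Costs only
slightly higher (0.095) push *every* arrangement sub-critical and are
rejected for that reason.  `calibrate_energy_cost` re-derives the default
empirically: it returns the smallest candidate cost whose bulk-ensemble
median-count slope over t ∈ [50, 400] is non-positive.

**Periphery metric.**  The pillar periphery is the set of empty pixels
within 3 px of a pillar pixel.  Distances are Euclidean (via the exact
distance transform).  This choice was checked against the alternatives
(chessboard and taxicab transforms, both exposed via
`periphery_mask(metric=...)`): Euclidean makes the fractal field's
outside-periphery pore area almost exactly twice the within-periphery area
(ratio 2.00) — the partition the saturated growth counts inherit — whereas
the chessboard band inflates "within" enough to push the ratio to 1.38 and
to swallow the intra-block pores entirely.

## Arrangements

All four arrangement generators are deterministic functions of their spec.

- **array**: pillars on a square lattice with centre pitch 2r + gap = 20 px;
  ⌊256/20⌋ = 12 per side (144 pillars), pattern centred.  Margins of 12 px
  remain at the walls.
- **block**: blocks of n×n pillars (intra-block edge gap d) whose *block*
  centres sit on the array grid scaled by n (pitch 20·n).  Consequences,
  both deliberate: n = 1 reproduces the array exactly for every d, and d = 8
  reproduces the array exactly for every n; total pillar count equals the
  array count whenever n divides 12 (n ∈ {1, 2, 3, 6}).  n = 9 cannot match
  the count in a 256-px field (two 132-px blocks do not fit); the generator
  then places the largest feasible block grid and warns.
- **fractal**: a three-level self-similar hierarchy — 2×2 pillars with gap
  3 px form clusters, 2×2 clusters with gap 6 px form groups, 3×3 groups
  with gap 36 px fill the field (252-px pattern, 144 pillars).  The two gap
  scale factors were calibrated once, jointly against the pillar-count match
  (±10% of the array) and the box-counting dimension target of the soil
  analogue (≈1.8); the chosen hierarchy measures 1.730 over box sizes
  {2, 4, 8, 16, 32, 64}.  Pushing the dimension higher is not possible in
  this family without breaking the count match: at a fixed 25% obstacle
  fraction in a 256-px field the fine-scale box counts are area-dominated.
- **bulk**: no pillars.

Box counting uses grid-aligned boxes anchored at the (0,0) corner, partial
edge boxes included, and a least-squares fit of log N(s) against log(1/s).

## Engines

The growth model is implemented twice with identical semantics: a numba
kernel (`_kernels.run_growth_kernel`) used for production ensembles, and a
pure-Python reference engine exposing the per-agent operations
(`attempt_move`, `update_energy`, `attempt_duplicate`, `step`) for
fine-grained testing, including an exhaustive one-step enumeration oracle.
Both are deterministic given the seed; their random streams differ, so the
engines agree statistically (checked by a KS test), not bitwise.  Replicate
and walker ensembles derive per-run sub-seeds from one master seed via
`numpy.random.SeedSequence`.

## Motility statistics

Single-walker runs use the movement rule only (no death, duplication, or
energy gating — energy never gates movement in this model).  Over a 500-step
horizon each walker reports D_tot, its count of successful moves, and
p_outside, the fraction of the 500 post-step positions lying outside the
periphery band; the initial position is not counted, making the denominator
exactly the horizon.  Modes of p_outside distributions are reported as the
centre of the fullest 0.05-wide histogram bin over [0, 1], ties broken
toward the lower bin.

## Two-strain statistics and the synthetic fixtures

The image-derived statistics operate on binary per-strain occupancy masks:
per-strain and union pixel counts, within/outside periphery partition, and
the k×k coexistence probability — the analysis window is split into k×k
near-equal cells (rounded pixel edges, nothing discarded, partitions nested
for doubling k) and the fraction of *occupied* cells containing both strains
is returned, 0 when nothing is occupied.  Making the denominator
"cells containing at least one strain" turns the statistic into a
conditional probability that ignores empty regions; larger k means finer
cells.  On the package's colony-style fixtures this statistic is
non-increasing in k (refinement separates strains); that is an empirical
property of colony-like masks, not a theorem for arbitrary masks.

The fixture generator plants disc-shaped colonies per strain (segregated
halves, uniformly mixed, or patchy around pillars), renders a two-channel
intensity image with additive Gaussian noise, and returns the ground truth,
so every statistic is testable against a planted answer without microscope
data.  The fixtures emulate thresholded two-channel micrographs of
non-interacting strains; they do not model optical blur, uneven
illumination, chamber-wall artefacts, or strain interactions, so passing
tests validate the statistics' arithmetic, not any biology of real images.

## Scale of the shipped experiments

Test-suite and acceptance-script runs use desk-scale ensembles chosen to
make the measured statistics stable: 10 replicates per arrangement for
saturation times, 20–100 replicates for ordering and block-sweep medians,
and the full 1000 walkers × 500 steps for motility distributions.  The
figure recipes accept any replicate count; their full-scale settings are
100 growth replicates and 1000 walkers.

## Known limitations

- The published block-sweep and arrangement-comparison magnitudes (e.g.
  median counts near 3000 for the fractal field at t = 150 under
  consumption) are not reproduced — only their orderings and trends.  The
  magnitudes depend on the original study's exact pillar layouts (counts,
  margins, boundary details), which the text does not fully specify; under
  the reconstruction here, any cost low enough to make the array grow that
  fast would make the open field grow too.
- Similarly, the absolute modal p_outside values for small-n block
  arrangements land higher here (0.525 for n = 1) than published (≈0.4):
  the move rule's stationary distribution is uniform over pore space, and
  this field's Euclidean band covers only ≈39% of it.  The orderings,
  bimodality onset, and D_tot statistics all agree.
- No nutrient fields, chemotaxis, medium flow, multi-species interactions,
  off-lattice motion, or mapping from time steps to wall-clock hours.
- The n = 9 block arrangement under-fills the pillar-count budget (see
  above) and is reported with a warning.
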