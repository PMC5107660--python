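# Methods

## The model

The scaffold is a cubic lattice of 32×32×32 patches with integer coordinates
−16..15 per axis. Each patch holds at most one cell and a substrate
concentration, initialized to the radial field
`c(x, y, z) = 20·√(x² + y²)/21.2` (arbitrary concentration units; no
z-dependence). The substrate stands in for an unidentified bioactive factor
(oxygen or matrix components are plausible candidates) that is richest at the
slice border; its biochemical identity is out of scope. Axis bounds of −16..15
keep the patch count at exactly 32³; the one-unit asymmetry is immaterial
because the field itself is an arbitrary modeling choice.

At t = 0, 30,000 agents are placed on distinct random patches and each
engrafts with probability 0.95 (a uniform draw N on [0, 100] with engraftment
when N > N_crit = 5). Non-engrafters are eliminated at seeding by default
(`seeding_mode="instant_cull"`); the alternative `one_step_grace` reading —
they stay motile for one full step, attempt to attach, and are then culled —
is a config switch. The model then runs for 80 steps; within each step every
agent executes its rules once, in a freshly randomized sequential order (the
NetLogo-style update discipline: interleaved, not synchronous).

Per-step rules:

1. **Movement** (motile cells only). The heading is re-randomized to a
   uniform 3D unit vector each step and quantized to the nearest of the 26
   lattice directions; "ahead-left"/"ahead-right" are the quantized ±45°
   rotations of the heading about the axis perpendicular to it in the plane
   spanned by the heading and a fixed up-reference (+z, or +x when the
   heading is near vertical). The three ahead concentrations are weighted by
   independent U[0, 1] draws; if the weighted sum S exceeds 1 the cell moves
   to the unoccupied ahead patch with the largest concentration, otherwise to
   a uniformly random unoccupied neighbor. S = 1 (a measure-zero tie) takes
   the random branch; a fully blocked cell stays put. There is no wraparound:
   the lattice border is the scaffold edge.
2. **Attachment**. N ~ U[0, 100]; if N > N_crit the cell becomes an immobile
   engrafted cell, draws (T_life, T_prol), and deposits c_amount = 1 of
   substrate on its patch.
3. **Death**. N_life advances by one; when N_life ≥ T_life the cell is
   removed, its patch freed, and its substrate deposit withdrawn (floored at
   0). The ≥ comparison (rather than strict equality) lets the smallest
   draws (T_life = 0) fire on the first step instead of creating
   accidentally immortal cells.
4. **Proliferation**. N_prol advances by one (held at T_prol once reached);
   when N_prol ≥ T_prol the cell places one offspring on a uniformly chosen
   unoccupied neighbor patch that itself has at most 6 occupied neighbors.
   If no eligible patch exists the attempt is retried each step (the counter
   is held rather than reset, so crowding does not penalize the odds twice).
   Each cell divides **at most once**: an equality-triggered counter fires a
   single time, and unlimited re-division would make the high-substrate
   border self-sustaining under Hypothesis 1, contradicting the near-total
   population collapse both rule sets are meant to show by step 80.
5. **Substrate bookkeeping**. The engraftment deposit is applied once and
   withdrawn at death (`substrate_deposit_mode="once"`); a `per_step`
   accumulation variant is provided for the alternative reading of the rule.

### Rule-set parameters

| parameter | Hypothesis 1 | Hypothesis 2 | units |
| --- | --- | --- | --- |
| N_crit | 5 | 5 | 0–100 scale |
| c_envfactor | 1.9 | 1.9 | – |
| c_amount | 1 | 1 | conc. units |
| initial T_life | U[0, 36] | U[0, 45] | steps |
| initial T_prol | U[33, 87] | U[41, 103] | steps |
| offspring T_life | U[0, 18] | (c/1.9) + U[0, 45] | steps |
| offspring T_prol | (33 − c/1.9) + U[0, 54] | U[41, 103] | steps |

Draws are integers, uniform inclusive on the interval endpoints — the
counters advance in whole steps and are compared with ≥, so fractional draws
would add nothing. Environment-coupled formulas are evaluated at the target
patch's current concentration (before the offspring's own deposit), rounded
to the nearest integer, and floored at 1 so the trigger can always fire.

Under Hypothesis 1 offspring proliferate sooner where substrate is high
(matched to mesenchymal stromal cells); under Hypothesis 2 offspring live
longer where substrate is high (matched to C10 alveolar epithelial cells).
The two rule sets differ in nothing else.

### Time calibration

With 32 patches spanning a ~1,000 μm slice and 80 steps covering 28 days,
one patch is 31.25 μm, one minute is ≈0.002 steps, and a cell moving one
patch per step travels ≈0.06 μm/min — the right order of magnitude for cells
on lung scaffolds.

## Quantification

Slices one patch thick are recorded every 10 steps on 30 fixed interior
z-indices (−15..14); using fixed indices keeps replicates comparable. For
each slice we record the engrafted-cell count and the CVHV: the Voronoi
tessellation of the in-plane cell positions is clipped to the slice rectangle
(clipping by mirror reflection of the sites across the four frame edges, so
tile areas exactly partition the frame), and

    CVHV = sample variance of tile areas (n − 1 denominator) × cell count.

The variance is taken over the tile-area distribution itself, not over binned
frequencies — binned variance would depend on an arbitrary bin width. The
count correction compensates for denser images having smaller mean tile
areas. A slice with fewer than 2 cells carries no area-variance information
and is recorded as CVHV = 0 in trajectories (the standalone `cvhv()` raises
instead); this convention is what makes mean CVHV decay once the population
dies out.

For micrographs, nuclei are detected before tessellation: foreground is
intensity *below* threshold (hematoxylin-dark nuclei on a light background),
masks are dark components ≥ 300 px at threshold 125, nuclei are components
≤ 20 px at threshold 125 outside masks and at the stricter 85 inside them
(8-connectivity; 4-connectivity is a switch). Interactive centroid editing is
replaced by a logged programmatic operation for reproducibility. Duplicate
centroids are merged with a warning before tessellation.

CVHV magnitudes carry units of (length²)² × count and therefore depend
entirely on the coordinate units (pixels vs patch units); only normalized or
within-unit comparisons are meaningful. Trajectory series are normalized to
percent of the first recorded time point.

## Statistics

Group comparisons use a fixed-effects two-way ANOVA on the normalized
per-replicate series with factors group and time, type-II sums of squares,
no interaction term; the group main effect is the headline p-value (the
normalized response, and the single reported p, mirror how such trajectories
are usually presented). The sensitivity protocol multiplies one parameter at
a time by 1 ± 0.05 — interval parameters scale both endpoints, and the
additive base of an environment-coupled formula scales too, the only reading
that preserves interval shape — then compares CVHV at a probe time point
(step 40 for Hypothesis 1, step 50 for Hypothesis 2, where the populations
are in their post-collapse, proliferation-dominated regime) against the
unperturbed control by one-way ANOVA at α = 0.05, with no multiplicity
adjustment across the table.

## Synthetic data

The fixture generator emulates the *detection-relevant* features of stained
slice images: dark nucleus discs (radius 2 px → 13 px components, under the
20 px cap), large clump bodies at intensity 110 (between the 85 in-mask and
125 thresholds, so only their darker sub-nuclei are detected), mid-size
debris that neither rule should count, optional additive Gaussian noise, and
exact ground-truth centroid lists. It does not attempt photorealism — no
staining variability, uneven illumination, focus blur, or overlapping
nuclei — so pipeline tests establish correctness of the algorithm, not
performance on difficult real micrographs. Point-pattern generators (uniform
vs Gaussian-clustered) probe the CVHV's clustering response, and a renderer
turns model slices into images so the coordinate-direct and rendered-image
paths can be cross-validated.

## Engine and numerics

The stepping engine vectorizes the order-independent counter updates and
serializes, in a random order, only the actions that touch shared state
(deaths, proliferations, motile turns); a plain per-agent reference loop is
kept and checked against it statistically in the test suite. All randomness
flows from a single seed per run (replicates use spawned seed sequences), so
identical seeds give bit-identical trajectories. Substrate is clamped at 0
from below. Concentration ties during chemotactic moves resolve to the first
candidate in scan order (sub-float-precision event).

## Problem sizes used in the checks

The test suite runs the full study conditions where the claim depends on
them: 30 replicates per hypothesis (30,000 seeds, 80 steps) for the count
and CVHV trajectory checks, and 5 repetitions × 10 replicates per condition
for the sensitivity protocol. The acceptance script averages 5 replicate
runs per hypothesis for the step-10 slice counts. Unit-level behavior is
exercised on reduced lattices (10³–12³) where scale is irrelevant.

## Known limitations

* The published step-10 slice counts (568.90 and 596.73 cells) were obtained
  by screenshot-based detection, which merges touching nuclei at high
  density and undercounts accordingly; direct counts of engrafted agents —
  what this package reports — run ~10–14% higher, with the denser
  Hypothesis 2 more affected. The lifespan intervals alone fix the
  H2:H1 count ratio at step 10 near 1.08–1.09.
* Absolute experimental CVHV magnitudes are not reproducible without the
  original image dimensions; only trajectory shapes and relative comparisons
  are meaningful.
* No differentiation, detachment, migration of engrafted cells, or
  mechanical/fluid coupling; single generic substrate with an idealized
  radial profile.
* The NetLogo cone-of-vision geometry for "ahead-left/right" is
  under-specified on a lattice; the quantized ±45° construction here is one
  faithful reading, and early-time dynamics are insensitive to it because
  motile cells exist only briefly under the default seeding.
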