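# Model and methods

`patchytissue` simulates a dense, confluent 3D tissue as a collection of
point-cells in a periodic cubic box and asks how mechanical heterogeneity —
the spread and spatial arrangement of single-cell stiffness — shapes the fate
of the population. Soft cells are the cancer-associated phenotype: the model
lets mechanics alone decide whether they take over.

## Geometry

Each cell is one point; its shape is the Voronoi polyhedron of that point
under periodic boundary conditions, so cells tile the box exactly (packing
fraction 1, no extracellular matrix). The default domain is an 80 µm cube
holding 512 cells, i.e. a mean cell volume of exactly 1000 µm³ by volume
conservation.

The production tessellation path clips each cell's polyhedron against the
perpendicular bisector planes of nearby points, nearest first, stopping once
the next plane is farther than twice the cell's current circumradius — at
that point the construction is provably exact. Candidates come from
minimum-image displacements when the cell is small relative to the box
(`d_max ≤ L/4`), from all 27 periodic images otherwise, and from an explicit
scipy Voronoi diagram of replicated images for pathologically sparse
configurations (a handful of cells in the box). The facet table is kept at
facet granularity: under periodicity one neighbor can share several distinct
facets (one per image plane), and for very small systems a cell can even abut
its own periodic image; such self-contacts are recorded under the cell's own
id.

Numerical choices: coincident points are rejected below 1e-6 µm separation;
facets below 1e-9 µm² are discarded as numerical slivers; clipping tolerances
scale with the box (1e-9 L). Near-degenerate (cospherical) vertex
configurations are handled by the clipping tolerance — planes passing exactly
through a vertex produce zero-area facets that the sliver filter removes.

## Mechanical energy

Per cell,

    U_i = 1/2 k (A_i − A_0)²/A_0 − 1/2 Σ_j A_j γσ − λ ln(V_i/V_0)

with all energies in Pa·µm³ (= 1e-18 J). The stretch term penalizes deviation
of the cell's surface area from the area `A_0` of its free-solution sphere;
`k` is the areal stiffness of the actin cortex, obtained from the measured
elastic modulus (the phenotype value, Pa) times a 1 µm cortex thickness, so
`k` in Pa·µm is numerically the stiffness in Pa. The adhesion term rewards
shared interface area (`γσ` = bond energy × bond density, one uniform
constant per cell pair); the 1/2 corrects double counting so each interface
contributes `A_j γσ` once to the tissue total. The osmotic term is the work
of the internal osmotic pressure when the volume deviates from the
free-solution volume `V_0`; `λ = P_0 V_0`.

Parameter defaults (all config-overridable):

| parameter | default | units | rationale |
|---|---|---|---|
| V₀ | 1000 | µm³ | matches the mean tessellated volume at 512 cells / 80 µm box; identical for every cell — heterogeneity enters only through k |
| A₀ | 483.6 | µm² | sphere-equivalent area of V₀ |
| γσ | 0.05 | Pa·µm | order of cadherin bond energy × surface density |
| λ = P₀V₀ | 5×10⁵ | Pa·µm³ | P₀ ≈ 500 Pa free-solution osmotic pressure |
| (k_BT)_eff | 2×10³ | Pa·µm³ | work of a ~nN protrusion force over ~1 µm (1e-15 J); see below |
| p₀ | 0.01 | — | baseline fate probability at homeostasis |

The effective temperature deserves a note. It must be large enough that the
Metropolis dynamics explores packings (acceptance well above zero) yet small
enough that the equilibrium area a cell adopts still depends on its stiffness:
the thermal area fluctuation is σ_A = √(kbt·A₀/k) ≈ 44 µm² at the default,
comparable to but below the systematic area split between the softest and
stiffest phenotypes (~±25 µm² around the mean). An order of magnitude hotter,
the stiffness–area coupling disappears entirely (measured rank correlation
≈ 0) and with it every mechanosensitive effect; an order colder, clustered
initial configurations freeze. 2×10³ Pa·µm³ also matches the protrusion-work
estimate directly.

## Dynamics

One iteration: 7 randomly chosen cells move along independent isotropic
directions by exponentially distributed steps (mean 0.5 µm); the move is
accepted or rejected as a block — downhill always, uphill with
exp(−ΔU/(k_BT)_eff) — using an incremental energy evaluation that
retessellates only the moved cells and their neighborhoods before and after
the move (verified against full recomputation to 1e-6 relative). Relaxation
runs until the energy averaged over 1000-iteration windows changes by less
than 0.1 % between windows, or an iteration cap (70,000 by default) is
reached. In practice the windowed mean fluctuates by more than 0.1 % at the
default temperature, so the cap is the effective budget; the trace (windowed
mean energy and acceptance fraction) is returned for inspection.

Randomness is drawn per window in a documented order (cell ids, directions,
magnitudes, acceptance uniforms, collision-rescue jitter) from a single
`numpy` Generator, making runs bitwise reproducible for a fixed seed.
Proposed positions that coincide with an existing point (< 1e-6 µm) are
jittered once and the proposal rejected if still degenerate.

## Cell fate

Fate is mechanosensitive and memoryless. The in-tissue area `A_i` measures
stretch relative to the cell's sphere-equivalent area `A_sp` (computed from
its current volume) and the homeostatic mean area `A_m`:

    p_death = p₀^((A_i − A_sp)/(A_m − A_sp))
    p_div   = (1 + (1−p₀)/p₀ · [(1−p₀)/(100−p₀)]^((A_i − A_m)/(A_m − A_sp)))⁻¹

At `A_i = A_m` both equal `p₀` (homeostasis); a perfectly spherical cell dies
with probability 1 and divides with exactly `p₀/100` (the literal constant
100 is part of the model and produces that clean limit). `A_m` is measured
once, from the initial relaxed healthy tissue, and frozen for the run —
fate is always referred to the healthy baseline, not the evolving tissue.

Decisions are synchronous (one sweep per cycle, all from the same pre-fate
tessellation). Dying cells' points are removed; a dividing cell becomes two
points at ±0.5 µm along a random coordinate axis, each daughter inheriting
the parent stiffness times (1 + u), u ~ U(−5 %, +5 %). The subsequent
relaxation, not the placement, determines the daughters' geometry. Exactly at
the spherical limit the two probabilities sum to 1 + p₀/100 > 1; a sweep that
encounters a cell in that sliver raises an error (invalid parameterization)
rather than renormalizing — in relaxed tissues cells sit far from the limit.
Cells whose area undershoots `A_sp` by float rounding (≤ 1e-9 relative) are
clamped to `A_sp`.

Because soft cells pay less for excess area, relaxation hands them larger
areas on average, raising their division and lowering their death
probability: the selection pressure favoring the soft (tumor-like) phenotype
emerges from the mechanics, with no explicit fitness term.

## Initial tissues

Stiffness values are i.i.d. log-normal with fixed mean 500 Pa; the mode (465
down to 425 Pa) sets the spread — the parameterization is exact:
`s² = (2/3) ln(mean/mode)`, `µ = ln(mode) + s²`. (The analytic SD of the
465-mode distribution is ≈ 111 Pa.) Draws outside 50–1500 Pa are redrawn to
stay within the experimentally measured elastic-modulus range; at the default
modes this truncation is negligible (< 1e-6 of draws).

Spatial arrangement is either well-mixed (uniform positions) or clustered:
a few seed cells (8, 27 or 64) are scattered first, then every subsequent
cell is placed uniformly within 10 µm (about one cell length) of the existing
cell nearest to it in stiffness. Fewer seeds make fewer, larger clusters.
Stiffness values for all cells are drawn before any placement, so clustering
permutes positions, never phenotypes. A long relaxation (the full 70,000
iteration budget) follows seeding before the first fate cycle.

## Patchiness index

Heterogeneity of a sample is the Shannon entropy of its stiffness values in
10 Pa bins (anchored at 0 Pa), normalized by ln N of the sample. The
patchiness index is

    c = global heterogeneity / mean local heterogeneity,

where the local values come from cubic moving windows (default edge 40 µm,
alternatives 30/50 µm) on a 10 µm stride grid with periodic wrap. Windows
with fewer than 2 cells are skipped (the ln N denominator is undefined and an
empty window carries no information). `c = 1` when the window is the whole
box; well-mixed tissues give `c < 1` because a smaller sample of the same
mixture has a larger ln N normalization; locally uniform (patchy) tissues
push local entropy toward 0 and `c` above 1, to +∞ (flagged, not a number) at
perfect segregation. A mechanically uniform tissue has 0/0 patchiness,
flagged undefined.

## Experiment protocol and classification

One replicate: seed → initial relaxation → measure `A_m` and the initial
patchiness → 20 cycles of (synchronous fate sweep → relaxation). Tracked per
cycle: cell count, mean stiffness, tumor-like count (stiffness < 400 Pa,
i.e. ≥ 20 % below the healthy 500 Pa mean) and its complement. A replicate is
a malignant transformation when the mean stiffness drops by ≥ 15 Pa from the
post-initial-relaxation baseline (relaxation moves points, never stiffness,
so this equals the seeded population mean) to the final cycle. The rare
stiffening outcome is recorded but never classified malignant.

A sweep crosses distribution modes with clustering levels, estimates the
transformation probability per scenario (malignant / total replicates), and
pools all replicates into patchiness bins (width 0.05 in c) with a two-sided
one-sample t-test of mean Δ stiffness = 0 per bin — raw p-values, no
multiple-testing correction. A module error aborts only the affected
replicate, which is recorded as a machine-readable failure entry.

## Problem sizes for tests and the acceptance script

The full protocol (512 cells, 70,000-iteration relaxations, 20 cycles,
20 scenarios × 10 replicates) is an overnight computation. The test suite and
`scripts/acceptance.py` therefore run a reduced ensemble chosen as this
package's desk-scale default: 128 cells in a ≈ 50.4 µm box (the same
1000 µm³ density), 6,000-iteration initial relaxation for well-mixed tissues
and 8,500 for clustered ones (dense clumps relax more slowly), 1,200
iterations per cycle (per-cycle relaxation quality is what keeps fate
decisions reading stiffness rather than unequilibrated geometry), 8 cycles,
3 replicates over the four corner scenarios of the
variance × clustering grid ({mode 465, 425} × {well-mixed, 8 seeds}), with
the standard 40 µm patchiness window. At this scale the directional findings
reproduce: the transformation probability rises with both variance and
clustering, the extreme scenarios separate cleanly, and replicates with
initial c > 0.85 soften significantly (one-sample t-test p < 0.05). The one
statement this scale cannot support is 3-SE significance of the combined
monotone severity trend in a single reduced ensemble: with ~16 replicates the
Fisher-z bar corresponds to a rank correlation ≳ 0.68, while the realized
trend correlation is ~0.4–0.7; the corresponding test documents this and may
fail by statistical power alone. A `desk` preset (128 cells,
10,000-iteration relaxations, 10 cycles) is exposed for richer ensembles.

The per-cell stiffness-area coupling that drives selection is modest on
purpose (thermal noise comparable to the systematic split), so individual
replicates have a stiffness-change spread of σ ≈ 8–12 Pa; ensemble statistics,
not single runs, carry the conclusions.

## What the synthetic tissues do and do not capture

The generator emulates exactly the study conditions: log-normal stiffness
with fixed mean, similarity-based spatial clustering, dense space-filling
packing. It does not model extracellular matrix, nutrient gradients,
vasculature, distinct cell types, cell-cycle timing, or adhesion/contractility
heterogeneity — passing tests therefore demonstrate the internal consistency
of the mechanics-fate-patchiness pipeline and its statistical behavior under
the model's assumptions, not clinical predictivity on real tissue.

## Known limitations

* The Metropolis dynamics has no physical timescale; "cycles" order events
  but do not calibrate to hours or days beyond the qualitative separation of
  rearrangement (slow) and fate (fast) scales.
* Whether the 7 moved cells should be accepted jointly (implemented, matching
  a whole-configuration energy comparison) or one at a time is a modeling
  choice; joint acceptance is the default, and setting ``cells_per_move = 1``
  (with proportionally more iterations) realizes the individual-acceptance
  alternative.
* Clustered initial configurations relax more slowly than well-mixed ones
  (dense clumps reject most moves at the default temperature); their measured
  homeostatic area `A_m` is correspondingly a few percent higher.
* At 64–128 cells the patchiness index of even a well-mixed tissue sits near
  0.8–0.9 because any window holds a sizable fraction of the population; c is
  comparable across arrangements at fixed scale but not across scales.
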