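# Methods

## The model

`marshca` treats a belt-structured coastal wetland as a dated categorical
lattice (30 m cells by default) whose *dynamic* classes — *Suaeda salsa*
marsh, *Phragmites australis* marsh, and open mudflat — exchange cells
under a first-order Markov chain, while *static* classes (water, roads,
aquaculture ponds, and optionally the invader *Spartina alterniflora*) are
frozen in place. One annual step of the coupled CA-Markov model is:

1. **Quantity (Markov).** From the current class counts nᵢ and the annual
   row-stochastic matrix P, the expected next-year counts are n·P. These
   are rounded to whole cells by largest-remainder apportionment, which
   conserves the dynamic-cell total exactly. The same rounding applied to
   each row nᵢ·P[i,:] yields an integer *flow matrix* F[i → j]; single
   units are then shifted between columns (within the rows that least
   disturb the real-valued flows) until the column margins equal the
   aggregate demands. F is therefore an integer transportation rounding of
   the real flows with both margins exact.
2. **Allocation (cellular automaton).** Each off-diagonal flow F[i → j]
   converts the F[i → j] cells of class i most suitable for class j.
   Suitability of a cell for class j is the frequency of j among dynamic
   cells in the centred 5 × 5 window (truncated at the frame edge, no
   wraparound) multiplied by P[current → j]; static and nodata cells score
   zero. Claims proceed over 20 rounds per step, and the window statistics
   are recomputed from the provisionally updated map each round, so a
   front can advance further than one window radius per year. Ties are
   broken by a seeded random key. Cells no flow claims keep their class
   (the diagonal of F). A final pass forces any flow that never found a
   positively suitable cell onto randomly chosen remaining source cells,
   so the accounting identity — output per-class counts equal the rounded
   demands — holds unconditionally.

Allocating *gross flows* rather than per-destination totals is essential:
a persisting class always outranks its competitors on its own cells
(P[c → c] dominates every off-diagonal entry of realistic matrices), so
any scheme in which each destination class greedily claims cells collapses
the gross transitions to net ones. The belt geometry then deadlocks — the
landward belt can never advance into its neighbour — and surplus demand is
scattered onto zero-suitability interior. With flow allocation the model
reproduces the expected travelling-wave behaviour: under the published
annual matrix both native belts drift seaward strictly monotonically over
a 22-year simulation.

"Number of iterations = 20" is the per-step allocation/filter schedule,
*not* a number of simulated years; the simulated span is the separate
`n_years` argument (a 1995–2017 run is 22 annual steps).

## Annualization

A matrix estimated over a k-year interval is converted to an annual step
by the principal k-th eigenvalue root: A = V·diag(λ^{1/k})·V⁻¹. Roots with
imaginary magnitude above 1e-6, or matrices whose eigenvector basis is
numerically singular (condition number > 1e12), raise — such matrices are
not embeddable at the requested step. Small negative entries of a valid
root are clipped to zero and rows renormalized; the Frobenius
reconstruction residual ‖Aᵏ − P‖_F is stored on the result rather than
hidden (0 for exact roots, e.g. diagonal matrices). Input rows that sum to
slightly less than one (printed round-off, e.g. a published mudflat row
summing to 0.9999) are renormalized with a logged warning; rows off by
more than 1 % are rejected as data errors.

## Zonation geometry

All distances are perpendicular to the *baseline edge* (the raster edge
standing in for the seawall), measured to cell centres: (index + 0.5) ×
cell size, increasing seaward. For a class, each baseline-perpendicular
transect containing it contributes its nearest and farthest class-cell
distances. The mean boundary distance is L = S/D with S = Σ(boundary
distance × cell size) and D = (number of occupied transects) × cell size —
algebraically the unweighted mean of the per-transect boundary distances,
which the tests verify against an independent brute-force scan to machine
precision. The centroid is the area-weighted mean distance of *all* class
cells (a 1-D centroid along the land→sea axis, matching how belt positions
are reported as single distances). Movements between dates are
seaward-positive, with rate × interval ≡ displacement by construction.

For filled bands L_near ≤ centroid ≤ L_far holds exactly; for arbitrary
patterns it can fail (the centroid weights transects by cell count, the
boundary means do not), so it is a documented property of banded inputs
rather than an enforced invariant. An optional minimum-patch filter
(8-connected, default off) excludes sporadic specks from boundary
statistics, since isolated outlier patches are a genuine ambiguity in
boundary definitions.

## Synthetic landscapes

The generator emulates the study system's banded structure: belts ordered
land → sea as *P. australis* → *S. salsa* → (optional invader strip) →
mudflat, any remaining depth open water. Defaults are the study
conditions: 30 m cells, belt shares matched to the observed 1985
landscape (*P. australis* 21 %, *S. salsa* 16 %, remainder mudflat), and
the published 1985–1990 annual matrix driving transitions. The default
frame is 200 × 200 cells (3,600 ha) — a scaled-down stand-in for the
~23,830 ha study strip chosen so a 22-year simulation completes in
seconds; the belt-to-frame proportions, not the absolute extent, carry the
dynamics. Belt boundaries are jittered per transect by a mean-centred
Gaussian random walk (σ = 2 cells by default), clipped so the belt order
never inverts — ragged but well-ordered fronts.

`evolve` is the ground-truth process for parameter recovery: each year
every dynamic cell redraws its class from (1 − w)·P[current → ·] +
w·(local 5 × 5 class frequencies). At contagion weight w = 0 this is
exactly the cell-independent chain, so cross-tabulating consecutive years
must recover P to binomial precision — the pipeline's end-to-end
recovery test. w > 0 sharpens fronts; it is kept at 0 wherever an
analytic check is asserted.

What the generator does *not* emulate: tides, sediment transport,
elevation or salinity gradients, classification error in the source maps,
and the invader's own spread dynamics (the invader strip is static).
Passing tests therefore demonstrate the correctness of the estimation,
simulation and measurement machinery under known dynamics — not that the
Markov assumption is adequate for any particular real coast.

## Agreement statistics

Cross-tabulation over jointly valid (non-nodata) cells, reference map on
rows. Overall accuracy is the confusion-matrix trace over the total;
Cohen's kappa is (p₀ − pₑ)/(1 − pₑ) with pₑ from the row/column marginals.
The degenerate case pₑ = 1 (both maps constant) is defined as κ = 1 if the
maps agree and 0 otherwise, with a warning. Published validation figures
for the original study (accuracy 0.9152, κ > 0.8 for the simulated vs
interpreted 1995 map) depend on the original Landsat classifications and
are treated as method context, not reproducible targets; the package's own
calibration checks are κ = 1 on identical maps, mean κ within ±0.01 of 0
over 100 independent map pairs, and a hand-computed 2 × 2 example
(κ = 0.70), plus the requirement that a simulated held-out year beats a
spatially shuffled control.

## Numerical and design choices

* Aggregate demands, flow margins and per-round quotas all use
  largest-remainder rounding (ties to the lower index), so every total is
  conserved exactly at every step.
* All randomness flows through `numpy.random.Generator` seeded from the
  run configuration; identical (grid, matrix, config, seed) give
  byte-identical outputs.
* Grids entering any pairwise operation must share shape and cell size;
  there is no reprojection or resampling — the study frame is fixed.
* Transition estimation counts only cells dynamic at *both* dates;
  source classes with zero cells get an identity row so sparse synthetic
  inputs stay well-defined.
* Published tables used as worked-example inputs live in
  `marshca.reference`, including two internal inconsistencies of the
  published record that are kept side by side on purpose (the 1985
  invader area 214.53 vs 514.53 ha, and the 2017 *P. australis* area
  8751.37 vs 8571.37 ha; in each case only one value is consistent with
  the published derived percentages, and that value feeds the examples).
* Problem sizes in the test-suite and acceptance runs (100–300 squared
  cells, 1–22 year spans) are the package's own scaling choice: large
  enough that every class keeps ≥ 10⁴ source cells where binomial
  precision is asserted, small enough that the whole suite runs in well
  under a minute.

## Known limitations

* The Markov matrix is stationary: no climate, policy or invader
  feedback. The no-invasion counterfactual inherits this assumption.
* Suitability uses only the contiguity filter and the transition row — no
  external driver layers (elevation, salinity, hydrology), and no
  multi-criteria evaluation.
* The k-th-root annualization is a pragmatic regularization, not a
  generator estimate; strongly non-embeddable matrices are rejected
  rather than approximated.
* Boundary metrics assume the belt axis is parallel to a raster edge;
  oblique coasts would need rotation before analysis.
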