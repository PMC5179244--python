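# Methods

## The pairwise overlap model

The unit of analysis is a binary species × site matrix read as a bipartite
network. For two nodes on one axis with degrees `d_i`, `d_j` among `n`
possible neighbors, the shared-neighbor count `S` under random, independent
placement of the two neighbor sets follows the hypergeometric law, with
expectation `P = d_i·d_j/n`. The package evaluates the defining summation
`Σ k·C(d_j,k)·C(n−d_j,d_i−k)/C(n,d_i)` in log-gamma space (stable to a few
hundred sites) and also exposes the closed form; the test suite proves the
two equal to 1e−10 over an exhaustive sweep, and matrix-level scoring uses
the closed form for speed.

The pair score standardizes the deviation `S − P` by the maximum feasible
deviation of the same sign, so the score is +1 exactly at `S = min(d_i,d_j)`
(one range contained in the other) and −1 exactly at
`S = max(0, d_i+d_j−n)` (minimum possible overlap). The standardization is
**sign-dependent**: a single positive-side constant cannot bound negative
deviations at −1, and the score's defined range demands both bounds be
attainable. When the feasible range of `S` collapses to a single point —
equivalently, when the larger degree equals `n` — no deviation is definable
and the pair is **excluded** from averaging rather than scored zero;
scoring it would dilute the mean arbitrarily.

Matrix-level statistics over the pooled pair scores (species pairs and site
pairs together by default — overlap reads equally as two species' shared
range and two sites' shared composition; single-axis modes are options):

* `nbar` = mean pair score, in [−1, 1];
* `modularity` = **population** standard deviation of the pair scores. The
  population (not sample) form guarantees the [0, 1] range: the extreme is
  an equal split of +1 and −1 scores, whose population SD is exactly 1.
* `Z` = `nbar / (sd/√n_pairs)`, a one-sample Z of the mean against zero
  using the same population SD. Zero-variance score sets leave Z undefined;
  it is reported as NaN (flagged), never fabricated. `Z > 2` is read as
  significant nestedness at about p < 0.05.

Matrices with fewer than two informative pairs are flagged non-computable.

## Windowing

The moving window is 1° × 1°, split into a 10 × 10 grid of 0.1° cells, and
advances in 0.1° steps (the cell size) across the extent; statistics are
assigned to the window centroid, giving a 0.1° result lattice. Conventions
the analysis needs but that are otherwise free:

* **Binning** is half-open, `[a, a + 0.1)` on both axes, implemented as
  `floor((x − a)/0.1 + 1e−9)`: a coordinate within ~1e−10° of a cell
  boundary lands deterministically in the upper cell, which both avoids
  double counting and makes the convention robust to floating-point noise.
  Coordinates are plain geographic degrees; cells are degree-rectangles
  (no projection, no great-circle areas).
* The **anchor lattice origin** defaults to the data bounding box's
  south-west corner snapped down to a 0.1° multiple; origin and extent are
  configurable. Within a sweep, records are binned once on the global
  lattice; window anchors sit on the same lattice, so per-window binning
  and global binning agree exactly.
* **Retention**: after collapsing within-cell duplicates and pruning empty
  rows/columns, matrices with fewer than 5 species or fewer than 5 occupied
  cells are rejected, with the reason recorded. Rejection is a normal
  outcome, not an error.
* Windows are scored independently; results are invariant to record order
  and to evaluation order, and a whole-dataset translation (coordinates and
  origin shifted together) shifts centroids without changing any statistic.

Point-in-polygon stages (habitat-class mask, PNV projection, ecoregion and
intact-forest assignment) use boundary-inclusive containment with ties —
points on shared edges, overlapping polygons — resolved by the first
feature in file order, which keeps every stage deterministic.

## Synthetic landscapes

The generator produces occurrence tables on the same 0.1° lattice the
window uses, in four archetypes: **nested** (a shared latitudinal
suitability field with strictly ordered per-species thresholds, so occupied
cell sets form exact subset chains), **modular** (longitudinal blocks with
disjoint species pools), **segregated** (round-robin cell ownership, i.e.
checkerboard), and **random** (the metric's null). `n_points` counts plot
visits at random cells; a nested-mode visit records the cell's full
eligible assemblage (an exhaustive inventory, which preserves the chains
exactly), other modes record one species per visit. The defaults — a 3° × 3°
extent, 30 species, 10⁴ visits — give a per-cell record density comparable
to a large national-inventory compilation at desk scale.

The PNV-map generator tiles the extent into latitudinal bands, each with a
species pool; nested pools (richness declining northward) are the default,
mirroring the expectation that potential vegetation is strongly nested,
with disjoint pools available for a modular benchmark.

**Disturbance** is modelled as two orthogonal noise channels — random
record deletion and random relocation within the data's bounding box — both
scaled by an intensity in [0, 1]. Deletion alone emulates incomplete
sampling (and, at 50%, is the subsampling step of the sensitivity
protocol); relocation emulates structure-destroying land-use churn. Counts
are exact (`round(fraction × n)`), all draws seed-reproducible.
`disturbance_gradient` applies the operator in longitudinal strips of
linearly increasing intensity, emulating a management-intensity gradient
from intact to heavily altered landscapes.

What the generator does *not* emulate: realistic species-distribution
shapes, climate covariates, dispersal, abundances, or observation bias that
correlates with structure. Passing tests therefore demonstrate that the
pipeline recovers the structure it defines, under sampling noise — not that
any real landscape is structured.

## Comparison stages

* **Difference map**: the actual-vegetation and PNV window tables are
  joined on integer lattice coordinates of their centroids (robust to
  floating-point centroid representation); differences are ACV − PNV, and
  one-sided centroids are kept with a missing-side flag rather than
  dropped.
* **Ecoregion aggregation**: unweighted arithmetic means of the windows
  whose centroid falls in each region. Moving windows overlap spatially by
  construction; no overlap weighting is attempted.
* **Intact-forest contrast**: Welch's unequal-variance t with
  Welch–Satterthwaite degrees of freedom, computed per statistic with the
  **non-intact group first**, so higher nestedness inside intact forest
  appears as negative t and lower modularity as positive t. Window-level
  values are the test units.
* **Sensitivity**: the sweep is run on the full table and on a
  seed-reproducible subsample (default: 50% of records deleted); windows
  retained in both runs are paired on their centroid and the subsample
  statistic is regressed on the full-data statistic (ordinary least
  squares; the half-data value is the response). A zero-variance regressor
  is flagged degenerate, fewer than 10 pairs flagged low-power. Note the
  regression needs between-window variance in the full-data values: on a
  perfectly nested landscape every window scores exactly 1 and the
  regression is degenerate by construction, which is why the robustness
  demonstration runs on a landscape spanning a disturbance gradient.
* **Summaries**: min / 1st quartile / median / mean / 3rd quartile / max
  per statistic and dataset, with quartiles by linear interpolation (the
  common "type 7" rule, recorded in output metadata). NaN Z values (zero
  variance windows) are ignored in summaries and region means.

## Determinism and numerics

Every random stage takes a mandatory seed, recorded in output headers and
manifests; given one configuration, every output byte is reproducible
(verified end to end). Lattice joins use integer keys; centroids are
rounded to 1e−9° when emitted. The Monte-Carlo oracle draws uniformly
random degree-constrained rows via rank thresholding of iid uniforms, and
the exact oracles use rational arithmetic on binomial coefficients — both
deliberately share no code with the production path.

## Problem sizes

The bundled tests and demonstration runs use desk-scale problems — extents
of 1.5°–3°, 10–30 species, 10³–10⁴ sampling events, a few hundred windows
per sweep — chosen so the full structure of the method (window retention,
degenerate-pair handling, both comparison directions) is exercised while a
complete run stays in the seconds-to-minutes range. Continental-scale
inputs (hundreds of species, ~10⁶ records) exceed what the synthetic
conditions are meant to represent, though the sweep's vectorized scoring
handles them in principle.

## Known limitations

* The pooled row+column default is one reading of "all pairs"; analyses
  keyed to a single axis should set `axis_mode` explicitly.
* Cells are degree-rectangles, so physical cell area varies with latitude;
  at continental scale a projected grid would be preferable.
* First-match polygon tie-breaking is deterministic but file-order
  dependent; reordering a polygon layer can reassign boundary points.
* The Z test treats pair scores as independent, which overlapping pairs on
  one matrix are not; Z is a screening statistic, not an exact p-value.
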