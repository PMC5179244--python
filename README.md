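# nbarscan

Moving-window analysis of the spatial co-occurrence structure of species
assemblages: nestedness, segregation and modularity from presence-absence
matrices, with tooling to compare *actual* vegetation against a
*potential-natural-vegetation* (PNV) benchmark.

The package is aimed at community ecologists and macroecologists who want to
quantify how strongly structured a species-by-site incidence pattern is,
map that structure across a landscape, and test whether disturbance has
eroded it — all from plain point-occurrence tables and GeoJSON polygon
layers, with a first-class synthetic-landscape generator so every stage can
be exercised without external data.

## The statistic

A binary species × site matrix is treated as a bipartite network. For two
nodes on the same axis (two species, or two sites) with degrees $d_i$,
$d_j$ out of $n$ possible neighbors, the observed shared-neighbor count
$S_{ij}$ is compared with its expectation under random placement,

$$P_{ij} = \sum_k k\,\frac{\binom{d_j}{k}\binom{n-d_j}{d_i-k}}{\binom{n}{d_i}} = \frac{d_i d_j}{n},$$

and standardized by the maximum feasible deviation of the same sign:

$$\mathcal{N}_{ij} = \frac{S_{ij}-P_{ij}}{\min(d_i,d_j)}\cdot\frac{1}{\Omega_{ij}},\qquad
\Omega_{ij}^{+}=\frac{\min(d)-P_{ij}}{\min(d)},\quad
\Omega_{ij}^{-}=\frac{P_{ij}-\max(0,\,d_i+d_j-n)}{\min(d)}.$$

Each pair score lies in $[-1, 1]$: $+1$ means one neighbor set contains the
other (nestedness), $-1$ means the sets overlap as little as the degrees
allow (segregation). The matrix-level statistics are

* **nbar** — the mean of all pair scores (species pairs and site pairs
  pooled by default),
* **modularity** — the population standard deviation of the same scores
  (high when internally-similar, mutually-dissimilar clusters coexist),
* **Z** — a one-sample Z test of the mean against zero; $Z > 2$ indicates
  significant nestedness at roughly $p < 0.05$.

Pairs whose shared count is forced by the degrees (one degree equal to $n$)
carry no information and are excluded from all three.

The landscape machinery slides a 1° × 1° window of one hundred 0.1° cells
across the study extent in 0.1° steps, builds the presence-absence matrix
in each position (half-open cell binning, empty rows/columns pruned,
matrices smaller than 5 species × 5 sites rejected), and georeferences the
statistics at the window centroid. Downstream stages difference an
actual-vegetation run against a PNV run, average per ecoregion, contrast
intact-forest windows with Welch's t-test, and regress half-data statistics
on full-data statistics (the 50%-removal sensitivity analysis).

## Worked example

```python
import numpy as np
from nbarscan import PresenceAbsenceMatrix, matrix_structure

chain = PresenceAbsenceMatrix(np.tril(np.ones((5, 5), dtype=int)))
print(matrix_structure(chain))
# MatrixStructureResult(nbar=1.0, modularity=0.0, z=nan, n_pairs=12, axis_mode='both')
```

Species *i* occupying sites 1..*i* is a strict subset chain — every
informative pair scores exactly +1, so nbar is 1 (perfect nestedness) and
modularity 0; the Z test is undefined at zero variance and flagged NaN
rather than fabricated. The `examples/` directory holds one short script
per capability; `examples/actual_vs_potential.py` prints, for a nested
landscape versus its disturbed counterpart:

```
mean nbar: PNV 1.000 vs ACV 0.574
mean modularity: PNV 0.000 vs ACV 0.436
nbar difference (ACV - PNV) <= 0 at 100% of matched centroids
```

— disturbance lowers nestedness and raises modularity everywhere, the
signature separating managed from potential vegetation. A thin CLI mirrors
the library (`nbarscan simulate | score | sweep | run | compare |
sensitivity | summarize`); `nbarscan run` executes the whole workflow from
an occurrence table and three polygon layers, deterministically for a given
seed.

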