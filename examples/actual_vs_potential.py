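"""Compare actual vegetation against a potential-vegetation projection.

Simulates the study's core comparison: a nested landscape stands in for the
potential natural vegetation (PNV); the same landscape degraded by random
deletion and relocation stands in for the actual vegetation (ACV). Both are
swept with the moving window; the per-centroid differences and per-region
means are printed.
"""

from nbarscan import (
    DisturbanceConfig, LandscapeConfig, difference_map, disturb,
    ecoregion_aggregate, generate_landscape, generate_regions, sweep,
)
import pandas as pd

extent = (0.0, 45.0, 2.0, 47.0)
occ = generate_landscape(LandscapeConfig(extent=extent, n_species=15,
                                         n_points=5000, seed=7))
acv_occ = disturb(occ, DisturbanceConfig(intensity=0.5, deletion_fraction=0.5,
                                         swap_fraction=0.5, seed=8))

pnv = sweep(occ, extent=extent, dataset_tag="PNV")
acv = sweep(acv_occ, extent=extent, dataset_tag="ACV")
print(f"mean nbar: PNV {pnv['nbar'].mean():.3f} vs ACV {acv['nbar'].mean():.3f}")
print(f"mean modularity: PNV {pnv['modularity'].mean():.3f} "
      f"vs ACV {acv['modularity'].mean():.3f}")

diff = difference_map(acv, pnv)
print(f"nbar difference (ACV - PNV) <= 0 at "
      f"{(diff['d_nbar'].dropna() <= 1e-12).mean():.0%} of matched centroids")

ecoregions, _ = generate_regions(extent, 4, 0.0, seed=1)
summary = ecoregion_aggregate(pd.concat([acv, pnv]), ecoregions)
print(summary.round(3))

# Disturbance lowers nestedness and raises modularity everywhere, the
# qualitative signature separating managed from potential vegetation.
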