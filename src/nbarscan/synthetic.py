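"""Synthetic landscapes with controllable co-occurrence structure.

Stands in for real occurrence and polygon data so the whole pipeline is
testable end to end. Four archetypes of spatial structure are generated on
the same 0.1-degree cell lattice the moving window uses:

``nested``
    One shared latent suitability field (a south-to-north gradient); species
    ``k`` is present wherever suitability exceeds its threshold, thresholds
    strictly ordered. Occupied-cell sets therefore form exact subset chains
    — the signature of mature, undisturbed vegetation.
``modular``
    The extent is cut into longitudinal blocks, each populated only from its
    own disjoint species pool: distinct internally-similar clusters.
``segregated``
    Every lattice cell is owned by exactly one species (round-robin
    interleaving), giving checkerboard-style non-overlap.
``random``
    Uniform independent placement; the metric's own null.

A disturbance operator (random record deletion plus random relocation)
degrades structure the way mixed human disturbance regimes erode the
spatial consistency of species associations; deletion alone at 50% is the
subsampling step of the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from shapely.geometry import box

__all__ = [
    "LandscapeConfig",
    "DisturbanceConfig",
    "generate_landscape",
    "generate_pnv_map",
    "generate_regions",
    "disturb",
    "species_names",
]

Extent = Tuple[float, float, float, float]  # lon_min, lat_min, lon_max, lat_max

#: lattice pitch, matching the moving window's cell size (degrees)
CELL = 0.1


def species_names(n: int) -> List[str]:
    return [f"sp{k:02d}" for k in range(n)]


@dataclass(frozen=True)
class LandscapeConfig:
    """Recipe for one synthetic landscape.

    ``n_points`` counts sampling events (plot visits at random lattice
    cells). In nested mode each visit records the full assemblage eligible
    at the visited cell, emulating exhaustive plot inventories (and keeping
    occupied-cell sets exact subset chains); in the other modes each visit
    yields a single record. The default extent (3 x 3 degrees) and density
    (10^4 visits over 900 cells) mirror the per-area record density of a
    large national-inventory compilation at desk scale.
    """

    extent: Extent = (0.0, 45.0, 3.0, 48.0)
    n_species: int = 30
    n_points: int = 10_000
    structure: str = "nested"
    structure_params: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 5:
            raise ValueError("n_species must be >= 5")
        w = self.extent[2] - self.extent[0]
        h = self.extent[3] - self.extent[1]
        if w < 1.0 - 1e-9 or h < 1.0 - 1e-9:
            raise ValueError("extent must be at least 1 x 1 degrees")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.structure not in ("nested", "modular", "segregated", "random"):
            raise ValueError(f"unknown structure {self.structure!r}")


@dataclass(frozen=True)
class DisturbanceConfig:
    """Record deletion plus relocation noise, both scaled by ``intensity``."""

    intensity: float = 1.0
    deletion_fraction: float = 0.0
    swap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("intensity", "deletion_fraction", "swap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _lattice(extent: Extent) -> Tuple[int, int]:
    nx = int(round((extent[2] - extent[0]) / CELL))
    ny = int(round((extent[3] - extent[1]) / CELL))
    return nx, ny


def _cell_points(
    extent: Extent, cx: np.ndarray, cy: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform jitter within each (cx, cy) lattice cell."""
    lon = extent[0] + (cx + rng.random(cx.size)) * CELL
    lat = extent[1] + (cy + rng.random(cy.size)) * CELL
    return lon, lat


def generate_landscape(config: LandscapeConfig) -> pd.DataFrame:
    """Generate an occurrence table with the configured spatial structure.

    Returns columns ``species_id, lon, lat, source`` (source = structure
    name); bit-reproducible given the config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    nx, ny = _lattice(config.extent)
    n_cells = nx * ny
    names = np.array(species_names(config.n_species))
    params = config.structure_params

    cx = rng.integers(0, nx, size=config.n_points)
    cy = rng.integers(0, ny, size=config.n_points)

    if config.structure == "nested":
        # suitability = normalized latitude of the cell row; species k needs
        # suitability >= k / n_species, so lower-threshold species occupy
        # supersets of higher-threshold ones (exact chains by construction)
        thresholds = np.arange(config.n_species) / config.n_species
        suit = (cy + 0.5) / ny
        eligible = suit[:, None] >= thresholds[None, :]
        visit_idx, sp_idx = np.nonzero(eligible)
        lon, lat = _cell_points(config.extent, cx[visit_idx], cy[visit_idx], rng)
        sp = names[sp_idx]
    elif config.structure == "modular":
        n_modules = int(params.get("n_modules", 3))
        if n_modules < 1 or n_modules > nx or n_modules > config.n_species:
            raise ValueError(
                f"n_modules={n_modules} infeasible for {nx} columns and "
                f"{config.n_species} species"
            )
        pools = np.array_split(np.arange(config.n_species), n_modules)
        module = np.minimum((cx * n_modules) // nx, n_modules - 1)
        sp_idx = np.array(
            [pools[m][rng.integers(0, len(pools[m]))] for m in module]
        )
        lon, lat = _cell_points(config.extent, cx, cy, rng)
        sp = names[sp_idx]
    elif config.structure == "segregated":
        if config.n_species > n_cells:
            raise ValueError("more species than lattice cells")
        owner = (cx * ny + cy) % config.n_species  # round-robin cell ownership
        lon, lat = _cell_points(config.extent, cx, cy, rng)
        sp = names[owner]
    else:  # random
        sp = names[rng.integers(0, config.n_species, size=config.n_points)]
        lon = rng.uniform(config.extent[0], config.extent[2], size=config.n_points)
        lat = rng.uniform(config.extent[1], config.extent[3], size=config.n_points)

    return pd.DataFrame(
        {
            "species_id": sp,
            "lon": np.round(lon, 6),
            "lat": np.round(lat, 6),
            "source": config.structure,
        }
    )


def generate_pnv_map(
    extent: Extent,
    n_units: int,
    pools: Union[str, Sequence[Sequence[str]]] = "nested",
    species: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> dict:
    """Latitudinal-band polygon map with a species pool per band.

    Emulates an expert potential-vegetation map: ``n_units`` horizontal
    bands tile the extent, each carrying a species list. ``pools='nested'``
    (default) gives richness declining northward with strictly nested pools,
    so projected matrices are subset chains; ``pools='disjoint'`` splits the
    species evenly for a modular map; an explicit list of lists is used
    verbatim. Band construction is deterministic; ``seed`` is accepted for
    interface uniformity with the other generators.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if species is None:
        species = species_names(30)
    species = list(species)
    n = len(species)
    if isinstance(pools, str):
        if pools == "nested":
            sizes = np.linspace(n, max(2, n // 3), n_units).round().astype(int)
            pool_lists = [species[: int(s)] for s in sizes]
        elif pools == "disjoint":
            pool_lists = [list(p) for p in np.array_split(np.array(species), n_units)]
        else:
            raise ValueError(f"pools must be 'nested', 'disjoint' or explicit lists")
    else:
        pool_lists = [list(p) for p in pools]
        if len(pool_lists) != n_units:
            raise ValueError("explicit pools must match n_units")
    if any(len(p) == 0 for p in pool_lists):
        raise ValueError("species pools must be non-empty")

    from shapely.geometry import mapping

    lat_edges = np.linspace(extent[1], extent[3], n_units + 1)
    features = []
    for b in range(n_units):
        geom = box(extent[0], lat_edges[b], extent[2], lat_edges[b + 1])
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"unit_id": f"U{b}", "species": pool_lists[b]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def disturb(occurrences: pd.DataFrame, config: DisturbanceConfig) -> pd.DataFrame:
    """Delete and relocate random records, destroying spatial structure.

    Deletes exactly ``round(intensity * deletion_fraction * n)`` records
    without replacement, then relocates ``round(intensity * swap_fraction *
    n_remaining)`` of the survivors to uniform random positions within the
    data bounding box. ``intensity = 0`` is the identity. Seed-reproducible.
    """
    out = occurrences.reset_index(drop=True)
    if config.intensity == 0.0 or out.empty:
        return out.copy()
    rng = np.random.default_rng(config.seed)
    n = len(out)
    n_del = int(round(config.intensity * config.deletion_fraction * n))
    keep = np.ones(n, dtype=bool)
    if n_del > 0:
        keep[rng.choice(n, size=n_del, replace=False)] = False
    out = out.loc[keep].reset_index(drop=True)
    m = len(out)
    n_swap = int(round(config.intensity * config.swap_fraction * m))
    if n_swap > 0 and m > 0:
        lon_lo, lon_hi = occurrences["lon"].min(), occurrences["lon"].max()
        lat_lo, lat_hi = occurrences["lat"].min(), occurrences["lat"].max()
        idx = rng.choice(m, size=n_swap, replace=False)
        out = out.copy()
        out.loc[idx, "lon"] = np.round(rng.uniform(lon_lo, lon_hi, size=n_swap), 6)
        out.loc[idx, "lat"] = np.round(rng.uniform(lat_lo, lat_hi, size=n_swap), 6)
    return out


def disturbance_gradient(
    occurrences: pd.DataFrame,
    extent: Extent,
    n_levels: int = 6,
    max_intensity: float = 1.0,
    deletion_fraction: float = 0.5,
    swap_fraction: float = 0.5,
    seed: int = 0,
    axis: str = "lon",
) -> pd.DataFrame:
    """Apply disturbance whose intensity increases across the extent.

    Splits the extent into ``n_levels`` equal strips along ``axis`` and
    disturbs strip ``i`` with intensity ``max_intensity * i / (n_levels-1)``
    (the first strip is untouched). Emulates a management-intensity
    gradient — landscapes range from intact to heavily altered — which is
    what gives real actual-vegetation data its wide between-window spread
    of structure values. Seed-reproducible (one derived seed per strip).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    lo, hi = (extent[0], extent[2]) if axis == "lon" else (extent[1], extent[3])
    edges = np.linspace(lo, hi, n_levels + 1)
    coord = occurrences[axis].to_numpy(dtype=float)
    strip = np.clip(
        np.searchsorted(edges, coord, side="right") - 1, 0, n_levels - 1
    )
    parts = []
    for i in range(n_levels):
        part = occurrences.loc[strip == i]
        if part.empty:
            continue
        parts.append(
            disturb(
                part,
                DisturbanceConfig(
                    intensity=max_intensity * i / (n_levels - 1),
                    deletion_fraction=deletion_fraction,
                    swap_fraction=swap_fraction,
                    seed=seed + i,
                ),
            )
        )
    return pd.concat(parts, ignore_index=True)


def _grid_shape(n_regions: int, width: float, height: float) -> Tuple[int, int]:
    """Factor n_regions into the nx x ny grid closest to square tiles."""
    best = (n_regions, 1)
    best_cost = float("inf")
    for nx in range(1, n_regions + 1):
        if n_regions % nx:
            continue
        ny = n_regions // nx
        cost = abs(np.log((width / nx) / (height / ny)))
        if cost < best_cost:
            best, best_cost = (nx, ny), cost
    return best


def generate_regions(
    extent: Extent, n_regions: int, intact_fraction: float, seed: int = 0
) -> Tuple[dict, dict]:
    """Rectangular ecoregion tiling plus an intact-forest subset.

    Returns ``(ecoregions, intact)`` FeatureCollections; every point of the
    extent is covered by exactly one ecoregion (boundary ties resolved by
    first match in file order downstream). ``round(intact_fraction *
    n_regions)`` regions, chosen at random, are flagged intact and exported
    separately.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not 0.0 <= intact_fraction <= 1.0:
        raise ValueError("intact_fraction must be in [0, 1]")
    from shapely.geometry import mapping

    rng = np.random.default_rng(seed)
    width = extent[2] - extent[0]
    height = extent[3] - extent[1]
    nx, ny = _grid_shape(n_regions, width, height)
    xs = np.linspace(extent[0], extent[2], nx + 1)
    ys = np.linspace(extent[1], extent[3], ny + 1)
    n_intact = int(round(intact_fraction * n_regions))
    intact_ids = set(
        rng.choice(n_regions, size=n_intact, replace=False).tolist()
        if n_intact
        else []
    )
    eco_features, intact_features = [], []
    rid = 0
    for j in range(ny):
        for i in range(nx):
            geom = mapping(box(xs[i], ys[j], xs[i + 1], ys[j + 1]))
            props = {"region_id": f"R{rid}", "intact": rid in intact_ids}
            eco_features.append(
                {"type": "Feature", "geometry": geom, "properties": dict(props)}
            )
            if rid in intact_ids:
                intact_features.append(
                    {"type": "Feature", "geometry": geom, "properties": dict(props)}
                )
            rid += 1
    return (
        {"type": "FeatureCollection", "features": eco_features},
        {"type": "FeatureCollection", "features": intact_features},
    )
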