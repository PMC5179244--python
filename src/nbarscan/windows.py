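"""Moving-window construction of presence-absence matrices from occurrences.

The analysis frame is a 1° x 1° window of one hundred 0.1° x 0.1° cells,
stepped across the study extent at 0.1° increments. At each position the
in-window occurrences are binned into cells (half-open intervals
[a, a + 0.1) on both axes), the binary species x cell matrix is built and
pruned of empty rows/columns, and matrices with fewer than 5 species or 5
occupied cells are rejected. Retained matrices are scored with
:func:`nbarscan.score.matrix_structure` and georeferenced at the window
centroid.

Also houses the two point-in-polygon stages that precede windowing: the
habitat-mask filter (keep occurrences inside polygons of allowed classes)
and the potential-vegetation projection (replace each plot location with
the species list of the containing vegetation polygon).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely

from nbarscan.io import load_features
from nbarscan.score import AxisMode, PresenceAbsenceMatrix, matrix_structure

__all__ = [
    "WindowSpec",
    "BuildOutcome",
    "EmptyMaskError",
    "mask_filter",
    "pnv_project",
    "build_window_matrix",
    "sweep",
]

logger = logging.getLogger(__name__)

#: tolerance used to snap coordinates sitting on a cell boundary upward,
#: realizing the half-open [a, a+0.1) convention under floating point
_EPS = 1e-9


class EmptyMaskError(ValueError):
    """The mask polygon layer contains no features (distinct from an empty result)."""


@dataclass(frozen=True)
class WindowSpec:
    """One placement of the moving window.

    ``anchor_lon``/``anchor_lat`` is the south-west corner in decimal
    degrees; the window spans ``window_size`` degrees split into
    ``window_size / cell_size`` cells per axis (exactly 10 at the defaults).
    The sweep step equals the cell size.
    """

    anchor_lon: float
    anchor_lat: float
    window_size: float = 1.0
    cell_size: float = 0.1

    def __post_init__(self):
        ratio = self.window_size / self.cell_size
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"window_size must be an integer multiple of cell_size "
                f"(got {self.window_size} / {self.cell_size})"
            )

    @property
    def n_cells_per_axis(self) -> int:
        return int(round(self.window_size / self.cell_size))

    @property
    def centroid(self) -> Tuple[float, float]:
        half = self.window_size / 2.0
        return (self.anchor_lon + half, self.anchor_lat + half)


class BuildOutcome(NamedTuple):
    """Result of building one window matrix: the matrix, or a rejection reason."""

    matrix: Optional[PresenceAbsenceMatrix]
    reason: Optional[str]

    @property
    def retained(self) -> bool:
        return self.matrix is not None


def _cell_indices(values: np.ndarray, anchor: float, cell: float) -> np.ndarray:
    """Half-open binning [a, a+cell): boundary values land in the upper cell."""
    return np.floor((np.asarray(values, dtype=float) - anchor) / cell + _EPS).astype(
        np.int64
    )


def _first_containing(points_lon, points_lat, features) -> np.ndarray:
    """Index of the first feature (file order) covering each point; -1 if none.

    ``covers`` includes the boundary, so a point on a shared edge of two
    abutting polygons is assigned to exactly one: the first in file order.
    """
    pts = shapely.points(np.asarray(points_lon, float), np.asarray(points_lat, float))
    assigned = np.full(len(pts), -1, dtype=np.int64)
    for idx, (geom, _props) in enumerate(features):
        todo = assigned == -1
        if not todo.any():
            break
        hit = shapely.covers(geom, pts[todo])
        assigned[np.flatnonzero(todo)[hit]] = idx
    return assigned


def mask_filter(
    occurrences: pd.DataFrame,
    mask_polygons,
    allowed_classes: Iterable[str],
) -> pd.DataFrame:
    """Keep occurrences inside mask polygons whose ``class`` is allowed.

    Emulates restricting plots to forested land-cover classes: records
    outside every polygon, or inside a polygon of a disallowed class, are
    dropped. Raises :class:`EmptyMaskError` when the mask layer has no
    features.
    """
    features = load_features(mask_polygons)
    if not features:
        raise EmptyMaskError("mask polygon layer contains no features")
    allowed = set(allowed_classes)
    if occurrences.empty:
        return occurrences.copy()
    assigned = _first_containing(
        occurrences["lon"].to_numpy(), occurrences["lat"].to_numpy(), features
    )
    classes = np.array(
        [props.get("class") for _geom, props in features], dtype=object
    )
    keep = (assigned >= 0) & np.isin(
        np.where(assigned >= 0, classes[assigned], None), list(allowed)
    )
    out = occurrences.loc[keep].reset_index(drop=True)
    logger.info(
        "mask_filter: %d of %d records retained (%d allowed classes)",
        len(out), len(occurrences), len(allowed),
    )
    return out


def pnv_project(occurrence_locations: pd.DataFrame, pnv_polygons) -> pd.DataFrame:
    """Project plot locations onto a potential-vegetation polygon map.

    Each location inherits the full species list of the first polygon (file
    order) that covers it — one output record per species. Locations outside
    every polygon emit nothing; a covering polygon with an empty species
    list triggers a warning and emits nothing.
    """
    features = load_features(pnv_polygons)
    locs = occurrence_locations[["lon", "lat"]].drop_duplicates().reset_index(drop=True)
    if locs.empty or not features:
        return pd.DataFrame(columns=["species_id", "lon", "lat", "source"])
    assigned = _first_containing(locs["lon"].to_numpy(), locs["lat"].to_numpy(), features)
    n_multi = 0
    species_lists = []
    for _geom, props in features:
        species_lists.append(list(props.get("species") or []))
        if not species_lists[-1]:
            warnings.warn(
                "pnv_project: polygon with empty species list emits no records",
                stacklevel=2,
            )
    rows = {"species_id": [], "lon": [], "lat": []}
    for k in range(len(locs)):
        idx = assigned[k]
        if idx < 0:
            continue
        for sp in species_lists[idx]:
            rows["species_id"].append(sp)
            rows["lon"].append(locs["lon"].iloc[k])
            rows["lat"].append(locs["lat"].iloc[k])
    out = pd.DataFrame(rows)
    out["source"] = "pnv"
    logger.info(
        "pnv_project: %d locations -> %d projected records", len(locs), len(out)
    )
    return out


def build_window_matrix(
    occurrences: pd.DataFrame,
    window: WindowSpec,
    min_species: int = 5,
    min_sites: int = 5,
) -> BuildOutcome:
    """Bin in-window occurrences into cells and build the binary matrix.

    Within-cell multiplicity is collapsed ((species, cell) deduplication);
    empty rows and columns cannot arise by construction. Matrices with
    fewer than ``min_species`` rows or ``min_sites`` occupied cells after
    pruning are rejected with a reason; rejection is a normal outcome.
    """
    k = window.n_cells_per_axis
    if occurrences.empty:
        return BuildOutcome(None, f"rows < {min_species}")
    ix = _cell_indices(occurrences["lon"].to_numpy(), window.anchor_lon, window.cell_size)
    iy = _cell_indices(occurrences["lat"].to_numpy(), window.anchor_lat, window.cell_size)
    inside = (ix >= 0) & (ix < k) & (iy >= 0) & (iy < k)
    if not inside.any():
        return BuildOutcome(None, f"rows < {min_species}")
    sp = occurrences["species_id"].to_numpy()[inside]
    cell = ix[inside] * k + iy[inside]
    return _matrix_from_bins(sp, cell, k, min_species, min_sites)


def _matrix_from_bins(
    species: np.ndarray, cell: np.ndarray, k: int, min_species: int, min_sites: int
) -> BuildOutcome:
    """Binary matrix from parallel (species, cell-id) arrays, deduplicated."""
    sp_labels, sp_codes = np.unique(species.astype(str), return_inverse=True)
    cell_ids, cell_codes = np.unique(cell, return_inverse=True)
    if len(sp_labels) < min_species:
        return BuildOutcome(None, f"rows < {min_species}")
    if len(cell_ids) < min_sites:
        return BuildOutcome(None, f"cols < {min_sites}")
    entries = np.zeros((len(sp_labels), len(cell_ids)), dtype=np.int8)
    entries[sp_codes, cell_codes] = 1
    col_labels = tuple(f"c{int(c) // k}_{int(c) % k}" for c in cell_ids)
    return BuildOutcome(
        PresenceAbsenceMatrix(entries, tuple(sp_labels), col_labels), None
    )


def sweep(
    occurrences: pd.DataFrame,
    origin: Optional[Tuple[float, float]] = None,
    extent: Optional[Tuple[float, float, float, float]] = None,
    window_size: float = 1.0,
    cell_size: float = 0.1,
    min_species: int = 5,
    min_sites: int = 5,
    axis_mode: AxisMode = "both",
    dataset_tag: str = "data",
    rejections: Optional[List] = None,
) -> pd.DataFrame:
    """Slide the window across the extent and score every retained matrix.

    Anchors are enumerated on a ``cell_size`` lattice starting at ``origin``
    (default: the data bounding box's south-west corner snapped down to the
    lattice), row-major from south-west to north-east, keeping the window
    inside ``extent`` (default: the data bounding box). Windows are
    independent, so the output is invariant to input record order and to
    evaluation order. Returns one row per retained window:
    ``dataset, centroid_lon, centroid_lat, n_species, n_sites, nbar, z,
    modularity``. Pass a list as ``rejections`` to collect
    ``(anchor_lon, anchor_lat, reason)`` for every rejected window.
    """
    columns = [
        "dataset", "centroid_lon", "centroid_lat",
        "n_species", "n_sites", "nbar", "z", "modularity",
    ]
    empty = pd.DataFrame(columns=columns)
    if occurrences.empty:
        warnings.warn("sweep: empty occurrence set, no windows", stacklevel=2)
        return empty

    lon = occurrences["lon"].to_numpy(dtype=float)
    lat = occurrences["lat"].to_numpy(dtype=float)
    if extent is None:
        extent = (lon.min(), lat.min(), lon.max(), lat.max())
    if origin is None:
        origin = (
            np.floor(extent[0] / cell_size + _EPS) * cell_size,
            np.floor(extent[1] / cell_size + _EPS) * cell_size,
        )
    ox, oy = float(origin[0]), float(origin[1])
    k = WindowSpec(ox, oy, window_size, cell_size).n_cells_per_axis

    # global lattice cells; window (wx, wy) covers cells [wx, wx+k) x [wy, wy+k),
    # identical to per-window binning because anchors sit on the same lattice
    gx = _cell_indices(lon, ox, cell_size)
    gy = _cell_indices(lat, oy, cell_size)
    uniq = pd.DataFrame(
        {"species_id": occurrences["species_id"].astype(str), "gx": gx, "gy": gy}
    ).drop_duplicates()
    uniq = uniq.sort_values(["species_id", "gx", "gy"]).reset_index(drop=True)
    ugx = uniq["gx"].to_numpy()
    ugy = uniq["gy"].to_numpy()
    usp = uniq["species_id"].to_numpy()

    n_anchors_x = int(np.floor((extent[2] - ox - window_size) / cell_size + _EPS)) + 1
    n_anchors_y = int(np.floor((extent[3] - oy - window_size) / cell_size + _EPS)) + 1
    rows = []
    for wy in range(max(n_anchors_y, 0)):
        in_y = (ugy >= wy) & (ugy < wy + k)
        for wx in range(max(n_anchors_x, 0)):
            sel = in_y & (ugx >= wx) & (ugx < wx + k)
            anchor_lon = round(ox + wx * cell_size, 9)
            anchor_lat = round(oy + wy * cell_size, 9)
            if not sel.any():
                if rejections is not None:
                    rejections.append((anchor_lon, anchor_lat, f"rows < {min_species}"))
                continue
            local_cell = (ugx[sel] - wx) * k + (ugy[sel] - wy)
            outcome = _matrix_from_bins(usp[sel], local_cell, k, min_species, min_sites)
            if not outcome.retained:
                if rejections is not None:
                    rejections.append((anchor_lon, anchor_lat, outcome.reason))
                continue
            res = matrix_structure(outcome.matrix, axis_mode)
            rows.append(
                {
                    "dataset": dataset_tag,
                    "centroid_lon": round(anchor_lon + window_size / 2.0, 9),
                    "centroid_lat": round(anchor_lat + window_size / 2.0, 9),
                    "n_species": outcome.matrix.shape[0],
                    "n_sites": outcome.matrix.shape[1],
                    "nbar": res.nbar,
                    "z": res.z,
                    "modularity": res.modularity,
                }
            )
    if not rows:
        warnings.warn("sweep: no windows retained", stacklevel=2)
        return empty
    out = pd.DataFrame(rows, columns=columns)
    logger.info(
        "sweep[%s]: %d windows retained of %d anchor positions",
        dataset_tag, len(out), max(n_anchors_x, 0) * max(n_anchors_y, 0),
    )
    return out
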