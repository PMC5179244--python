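"""Reading and writing the package's plain-text formats.

Occurrences travel as delimited text with header ``species_id,lon,lat[,source]``;
polygon layers (potential-vegetation units, habitat masks, ecoregions,
intact-forest masks) as GeoJSON FeatureCollections; presence-absence
matrices as TSV (rows = species, header = site labels, 0/1 cells); window
results as CSV. Writers prepend ``# key: value`` metadata lines (seeds,
conventions); readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from nbarscan.score import PresenceAbsenceMatrix

__all__ = [
    "SchemaError",
    "read_occurrences",
    "write_occurrences",
    "load_features",
    "write_geojson",
    "read_matrix",
    "write_matrix",
    "read_window_results",
    "write_window_results",
    "window_results_to_geojson",
]

OCCURRENCE_COLUMNS = ("species_id", "lon", "lat")

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """Input file violates the expected schema; message names the row."""


def _write_metadata_header(fh, metadata: Optional[Mapping]) -> None:
    for key, value in (metadata or {}).items():
        fh.write(f"# {key}: {value}\n")


def read_occurrences(path: PathLike) -> pd.DataFrame:
    """Read a species occurrence table, validating every row.

    Raises :class:`SchemaError` naming the offending line for missing
    columns, non-numeric coordinates, or out-of-range lon/lat.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    # locate the first data line to translate frame rows into file lines
    with open(path) as fh:
        header_line = 1
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                break
            header_line += 1
    for col in ("lon", "lat"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}, line {header_line + 1 + row}: "
                f"malformed {col} value {df[col].iloc[row]!r}"
            )
        df[col] = vals
    if df["species_id"].isna().any():
        row = int(np.flatnonzero(df["species_id"].isna().to_numpy())[0])
        raise SchemaError(f"{path}, line {header_line + 1 + row}: empty species_id")
    out_of_range = (
        (df["lon"] < -180) | (df["lon"] > 180) | (df["lat"] < -90) | (df["lat"] > 90)
    )
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise SchemaError(
            f"{path}, line {header_line + 1 + row}: coordinates out of range "
            f"(lon={df['lon'].iloc[row]}, lat={df['lat'].iloc[row]})"
        )
    keep = [c for c in ("species_id", "lon", "lat", "source") if c in df.columns]
    return df[keep].reset_index(drop=True)


def write_occurrences(
    df: pd.DataFrame, path: PathLike, metadata: Optional[Mapping] = None
) -> None:
    """Write an occurrence table with optional ``# key: value`` header lines."""
    with open(path, "w") as fh:
        _write_metadata_header(fh, metadata)
        df.to_csv(fh, index=False)


def _as_feature_list(features) -> list:
    """Normalize a FeatureCollection dict / feature list to [(geom, props)]."""
    if isinstance(features, Mapping) and features.get("type") == "FeatureCollection":
        features = features["features"]
    out = []
    for feat in features:
        if isinstance(feat, tuple):
            geom, props = feat
        else:
            geom = feat["geometry"]
            props = feat.get("properties") or {}
        if isinstance(geom, Mapping):
            geom = shapely_shape(geom)
        out.append((geom, dict(props)))
    return out


def load_features(source) -> list:
    """Load GeoJSON features as ``[(shapely geometry, properties dict)]``.

    ``source`` may be a path, a FeatureCollection dict, or an existing
    feature list; file order is preserved (containment ties are broken by
    first match in this order).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = json.load(fh)
    return _as_feature_list(source)


def write_geojson(features, path: PathLike, metadata: Optional[Mapping] = None) -> None:
    """Write ``[(geometry, properties)]`` as a GeoJSON FeatureCollection."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": shapely_mapping(geom) if not isinstance(geom, Mapping) else geom,
                "properties": props,
            }
            for geom, props in _as_feature_list(features)
        ],
    }
    if metadata:
        collection["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_matrix(path: PathLike) -> PresenceAbsenceMatrix:
    """Read a presence-absence matrix from TSV (rows=species, cols=sites)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return PresenceAbsenceMatrix(
        df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns))
    )


def write_matrix(
    m: PresenceAbsenceMatrix, path: PathLike, metadata: Optional[Mapping] = None
) -> None:
    """Write a presence-absence matrix as TSV."""
    df = pd.DataFrame(m.entries, index=list(m.row_labels), columns=list(m.col_labels))
    with open(path, "w") as fh:
        _write_metadata_header(fh, metadata)
        df.to_csv(fh, sep="\t")


WINDOW_RESULT_COLUMNS = (
    "dataset",
    "centroid_lon",
    "centroid_lat",
    "n_species",
    "n_sites",
    "nbar",
    "z",
    "modularity",
)


def write_window_results(
    df: pd.DataFrame, path: PathLike, metadata: Optional[Mapping] = None
) -> None:
    """Write per-window statistics as CSV with a metadata header."""
    cols = [c for c in WINDOW_RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    with open(path, "w") as fh:
        _write_metadata_header(fh, metadata)
        df[cols].to_csv(fh, index=False, float_format="%.10g")


def read_window_results(path: PathLike) -> pd.DataFrame:
    """Read a per-window statistics table written by :func:`write_window_results`."""
    return pd.read_csv(path, comment="#")


def window_results_to_geojson(df: pd.DataFrame) -> dict:
    """Per-window statistics as a GeoJSON FeatureCollection of centroid points."""
    features = []
    for _, row in df.iterrows():
        props = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in row.items()
            if k not in ("centroid_lon", "centroid_lat")
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [row["centroid_lon"], row["centroid_lat"]],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
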