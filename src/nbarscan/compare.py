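"""Downstream comparison stages: differencing, aggregation, contrasts.

Takes per-window structure tables (from :func:`nbarscan.windows.sweep`) for
an actual-vegetation (ACV) run and a potential-natural-vegetation (PNV)
run and implements the analysis endpoints: the per-centroid ACV - PNV
difference map, unweighted per-ecoregion averaging, the Welch-t contrast of
intact versus non-intact forest windows, the 50%-removal sensitivity
regression, and six-number descriptive summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from nbarscan.synthetic import DisturbanceConfig, disturb
from nbarscan.windows import _first_containing, sweep
from nbarscan.io import load_features

__all__ = [
    "ContrastReport",
    "SensitivityReport",
    "difference_map",
    "ecoregion_aggregate",
    "intact_contrast",
    "sensitivity_run",
    "summary_table",
]

logger = logging.getLogger(__name__)

STATISTICS = ("nbar", "z", "modularity")


def _lattice_key(values: pd.Series, cell: float = 0.1) -> pd.Series:
    """Integer lattice coordinate of a centroid (robust join key)."""
    return (np.round(np.asarray(values, dtype=float) / cell)).astype(np.int64)


def difference_map(
    acv_results: pd.DataFrame, pnv_results: pd.DataFrame, cell: float = 0.1
) -> pd.DataFrame:
    """Per-centroid differences (ACV - PNV) of nbar, z and modularity.

    Joins the two window tables on their centroid lattice coordinates.
    Centroids present on one side only are kept with a ``missing_side``
    flag ('acv' / 'pnv' names the absent side) and NaN differences; fully
    disjoint lattices raise ``ValueError``.
    """
    frames = []
    for tag, df in (("acv", acv_results), ("pnv", pnv_results)):
        d = df.copy()
        d["_kx"] = _lattice_key(d["centroid_lon"], cell)
        d["_ky"] = _lattice_key(d["centroid_lat"], cell)
        d = d[["_kx", "_ky", "centroid_lon", "centroid_lat", *STATISTICS]]
        d = d.rename(columns={s: f"{s}_{tag}" for s in STATISTICS})
        frames.append(d)
    merged = frames[0].merge(
        frames[1],
        on=["_kx", "_ky"],
        how="outer",
        suffixes=("_acv", "_pnv"),
    )
    matched = merged["nbar_acv"].notna() & merged["nbar_pnv"].notna()
    has_acv = merged["centroid_lon_acv"].notna()
    has_pnv = merged["centroid_lon_pnv"].notna()
    if not (has_acv & has_pnv).any():
        raise ValueError("difference_map: the two window lattices are disjoint")
    merged["centroid_lon"] = merged["centroid_lon_acv"].fillna(
        merged["centroid_lon_pnv"]
    )
    merged["centroid_lat"] = merged["centroid_lat_acv"].fillna(
        merged["centroid_lat_pnv"]
    )
    for s in STATISTICS:
        merged[f"d_{s}"] = merged[f"{s}_acv"] - merged[f"{s}_pnv"]
    merged["missing_side"] = np.where(
        has_acv & has_pnv, "", np.where(has_acv, "pnv", "acv")
    )
    cols = (
        ["centroid_lon", "centroid_lat"]
        + [f"{s}_{t}" for s in STATISTICS for t in ("acv", "pnv")]
        + [f"d_{s}" for s in STATISTICS]
        + ["missing_side"]
    )
    out = merged[cols].sort_values(["centroid_lat", "centroid_lon"]).reset_index(drop=True)
    return out


def _nanmean_or_nan(v) -> float:
    arr = np.asarray(v, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def ecoregion_aggregate(
    window_results: pd.DataFrame, ecoregions
) -> pd.DataFrame:
    """Unweighted per-ecoregion means of the window statistics.

    Each window contributes to the first region (file order) whose polygon
    covers its centroid; overlapping moving windows are averaged without
    weighting. Windows outside every region are logged and excluded; regions
    containing no window are omitted with a warning. Returns one row per
    (dataset, region) with ``mean_nbar, mean_z, mean_modularity, n_windows``.
    """
    features = load_features(ecoregions)
    if window_results.empty:
        raise ValueError("ecoregion_aggregate: empty window results")
    assigned = _first_containing(
        window_results["centroid_lon"].to_numpy(),
        window_results["centroid_lat"].to_numpy(),
        features,
    )
    region_ids = [
        props.get("region_id", f"R{i}") for i, (_g, props) in enumerate(features)
    ]
    n_outside = int((assigned < 0).sum())
    if n_outside:
        logger.warning(
            "ecoregion_aggregate: %d window centroid(s) in no region, excluded",
            n_outside,
        )
    df = window_results.loc[assigned >= 0].copy()
    df["region_id"] = [region_ids[a] for a in assigned[assigned >= 0]]
    if "dataset" not in df.columns:
        df["dataset"] = "data"
    grouped = (
        df.groupby(["dataset", "region_id"], sort=True)
        .agg(
            mean_nbar=("nbar", "mean"),
            mean_z=("z", _nanmean_or_nan),
            mean_modularity=("modularity", "mean"),
            n_windows=("nbar", "size"),
        )
        .reset_index()
    )
    seen = set(grouped["region_id"])
    empty_regions = [r for r in region_ids if r not in seen]
    if empty_regions:
        warnings.warn(
            f"ecoregion_aggregate: region(s) with no windows omitted: {empty_regions}",
            stacklevel=2,
        )
    return grouped


@dataclass(frozen=True)
class ContrastReport:
    """Welch's unequal-variance t-test of one statistic between two groups.

    Group 1 is the non-intact windows, group 2 the intact ones, so a
    statistic elevated inside intact forest yields a negative t.
    """

    variable: str
    t: float
    df: float
    p: float
    n_group1: int
    n_group2: int
    mean_group1: float
    mean_group2: float


def _welch(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df, two-sided p for mean(x) - mean(y)."""
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def intact_contrast(
    window_results: pd.DataFrame,
    intact_polygons,
    variables: Sequence[str] = ("nbar", "modularity"),
) -> Dict[str, ContrastReport]:
    """Contrast window statistics inside vs outside intact-forest polygons.

    Windows are classified by centroid containment in any intact polygon.
    For each requested statistic, Welch's unequal-variance t-test is
    computed with the non-intact group first, so the expected signature of
    naturalness — higher nestedness, lower modularity inside intact forest —
    appears as a negative t for nbar and a positive t for modularity.
    Raises ``ValueError`` when either group has fewer than 2 windows.
    """
    features = load_features(intact_polygons)
    assigned = _first_containing(
        window_results["centroid_lon"].to_numpy(),
        window_results["centroid_lat"].to_numpy(),
        features,
    )
    intact = assigned >= 0
    reports: Dict[str, ContrastReport] = {}
    for var in variables:
        vals = window_results[var].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        g1 = vals[ok & ~intact]  # non-intact
        g2 = vals[ok & intact]
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(
                f"intact_contrast[{var}]: need >= 2 windows per group "
                f"(got {len(g1)} non-intact, {len(g2)} intact)"
            )
        t, df, p = _welch(g1, g2)
        reports[var] = ContrastReport(
            variable=var, t=t, df=df, p=p,
            n_group1=len(g1), n_group2=len(g2),
            mean_group1=float(g1.mean()), mean_group2=float(g2.mean()),
        )
    return reports


@dataclass(frozen=True)
class SensitivityReport:
    """Half-data vs full-data regression of the window statistics.

    Ordinary least squares of the subsampled-run value (response) on the
    full-run value (regressor) across windows retained in both runs.
    ``degenerate_*`` flags a regressor with zero variance (regression
    undefined); ``low_power`` flags fewer than 10 paired windows.
    """

    slope_nbar: float
    intercept_nbar: float
    r2_nbar: float
    slope_modularity: float
    intercept_modularity: float
    r2_modularity: float
    n_windows_paired: int
    seed: int
    deletion_fraction: float
    low_power: bool
    degenerate_nbar: bool
    degenerate_modularity: bool


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, bool]:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0.0:
        return float("nan"), float("nan"), float("nan"), True
    if np.ptp(y) == 0.0 and np.allclose(y, x):
        return 1.0, 0.0, 1.0, False
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), False


def sensitivity_run(
    occurrences: pd.DataFrame,
    seed: int,
    deletion_fraction: float = 0.5,
    sweep_kwargs: Optional[dict] = None,
) -> SensitivityReport:
    """Robustness of the window statistics to random record removal.

    Runs the moving-window sweep on the full occurrence table and on a
    seed-reproducible random subsample (default: 50% of records removed),
    pairs windows retained in both runs on their centroid, and regresses
    the subsample statistic on the full-data statistic for nbar and
    modularity. Identical lattices are enforced by deriving the sweep
    origin and extent from the full data once and using them for both runs.
    """
    kwargs = dict(sweep_kwargs or {})
    if "extent" not in kwargs:
        kwargs["extent"] = (
            float(occurrences["lon"].min()),
            float(occurrences["lat"].min()),
            float(occurrences["lon"].max()),
            float(occurrences["lat"].max()),
        )
    full = sweep(occurrences, dataset_tag="full", **kwargs)
    if deletion_fraction > 0.0:
        half_occ = disturb(
            occurrences,
            DisturbanceConfig(deletion_fraction=deletion_fraction, seed=seed),
        )
    else:
        half_occ = occurrences
    sub = sweep(half_occ, dataset_tag="subsample", **kwargs)

    for df in (full, sub):
        df["_kx"] = _lattice_key(df["centroid_lon"])
        df["_ky"] = _lattice_key(df["centroid_lat"])
    paired = full.merge(sub, on=["_kx", "_ky"], suffixes=("_full", "_sub"))
    n = len(paired)
    if n < 10:
        warnings.warn(
            f"sensitivity_run: only {n} paired windows, low statistical power",
            stacklevel=2,
        )
    s_n, i_n, r2_n, deg_n = _ols(
        paired["nbar_full"].to_numpy(float), paired["nbar_sub"].to_numpy(float)
    )
    s_m, i_m, r2_m, deg_m = _ols(
        paired["modularity_full"].to_numpy(float),
        paired["modularity_sub"].to_numpy(float),
    )
    return SensitivityReport(
        slope_nbar=s_n, intercept_nbar=i_n, r2_nbar=r2_n,
        slope_modularity=s_m, intercept_modularity=i_m, r2_modularity=r2_m,
        n_windows_paired=n, seed=seed, deletion_fraction=deletion_fraction,
        low_power=n < 10, degenerate_nbar=deg_n, degenerate_modularity=deg_m,
    )


SUMMARY_ROWS = ("Min", "1st Qu", "Median", "Mean", "3rd Qu", "Max")


def summary_table(
    window_results: pd.DataFrame, statistics: Sequence[str] = STATISTICS
) -> pd.DataFrame:
    """Six-number descriptive summaries per statistic and dataset tag.

    Rows Min / 1st Qu / Median / Mean / 3rd Qu / Max; one column per
    (statistic, dataset) pair. Quartiles use linear interpolation (the
    'type 7' convention); NaN values (e.g. Z of zero-variance windows) are
    ignored.
    """
    if window_results.empty:
        raise ValueError("summary_table: empty window results")
    df = window_results.copy()
    if "dataset" not in df.columns:
        df["dataset"] = "data"
    tags = list(dict.fromkeys(df["dataset"]))
    data = {}
    for s in statistics:
        for tag in tags:
            v = df.loc[df["dataset"] == tag, s].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                col = [float("nan")] * 6
            else:
                col = [
                    float(v.min()),
                    float(np.quantile(v, 0.25)),
                    float(np.quantile(v, 0.5)),
                    float(v.mean()),
                    float(np.quantile(v, 0.75)),
                    float(v.max()),
                ]
            data[f"{s}_{tag}"] = col
    return pd.DataFrame(data, index=list(SUMMARY_ROWS))
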