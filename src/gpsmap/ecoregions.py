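"""Discrete ecoregions from climate normals.

Thirty-year normals for mean temperature (degC), precipitation (mm/yr) and
elevation (m) on a lat/lon grid are clustered with K-means (default K = 9)
into discrete ecoregions.  Animals are linked to a grid cell through their
zip code's coordinates rounded to 0.1 degrees; zip codes whose coordinates
fall in cells of different regions are excluded from discrete (case-control)
analyses but kept for continuous ones.

Variables are z-scored before clustering because their units differ by
orders of magnitude; assignment is nearest centroid in that standardized
space, ties broken by the lowest region index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "EcoregionModel",
    "fit_ecoregions",
    "assign_ecoregion",
    "synthetic_environment",
]

CLIMATE_VARS = ["temperature", "precipitation", "elevation"]


@dataclass
class EcoregionModel:
    """Fitted K-means climate clustering."""

    k: int
    centroids: np.ndarray          # K x 3, standardized space
    scaler_mean: np.ndarray        # per-variable mean
    scaler_sd: np.ndarray          # per-variable SD
    inertia: float
    labels: list[str]

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.scaler_mean) / self.scaler_sd

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Nearest-centroid region index; ties go to the lowest index."""
        Z = np.atleast_2d(self.standardize(values))
        d2 = ((Z[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "inertia": self.inertia,
            "labels": self.labels,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EcoregionModel":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], centroids=np.array(d["centroids"]),
                   scaler_mean=np.array(d["scaler_mean"]),
                   scaler_sd=np.array(d["scaler_sd"]),
                   inertia=d["inertia"], labels=d["labels"])


def fit_ecoregions(grid: pd.DataFrame, k: int = 9, seed: int | None = None,
                   n_init: int = 25) -> EcoregionModel:
    """K-means over standardized (temperature, precipitation, elevation).

    Uses k-means++ initialization with ``n_init`` restarts at a fixed seed so
    refits reproduce centroids bitwise.
    """
    vals = grid[CLIMATE_VARS].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("climate grid contains non-finite values")
    distinct = np.unique(vals, axis=0).shape[0]
    if k > distinct:
        raise ValueError(f"K={k} exceeds the {distinct} distinct grid points")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (vals - mean) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed)
    km.fit(Z)
    return EcoregionModel(
        k=k, centroids=km.cluster_centers_.copy(), scaler_mean=mean,
        scaler_sd=sd, inertia=float(km.inertia_),
        labels=[f"region_{i}" for i in range(k)],
    )


def _round_half_up(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    f = 10.0 ** decimals
    return np.floor(np.asarray(x, dtype=float) * f + 0.5) / f


def grid_regions(grid: pd.DataFrame, model: EcoregionModel) -> pd.DataFrame:
    """Region label per grid cell (lat/lon rounded to 0.1 degrees)."""
    out = grid.copy()
    out["lat"] = _round_half_up(out["lat"])
    out["lon"] = _round_half_up(out["lon"])
    out["ecoregion"] = model.predict(out[CLIMATE_VARS].to_numpy())
    return out


def assign_ecoregion(samples: pd.DataFrame, model: EcoregionModel,
                     grid: pd.DataFrame,
                     zip_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach climate values and an ecoregion to each sample.

    Samples need either ``lat``/``lon`` columns or a ``zip`` column plus a
    ``zip_table`` with zip -> (lat, lon) rows (a zip may map to several
    coordinates).  Coordinates are rounded half-up to 0.1 degrees and looked
    up in the grid.  A zip whose cells span more than one region keeps its
    climate values (averaged) but is flagged ``excluded_discrete`` so discrete
    analyses drop it; off-grid locations stay unassigned (NaN region, logged).
    """
    cells = grid_regions(grid, model)
    cell_key = list(zip(cells["lat"], cells["lon"]))
    cell_lookup = dict(zip(cell_key, cells.index))

    out = samples.copy()
    out["ecoregion"] = np.nan
    out["excluded_discrete"] = False
    for var in CLIMATE_VARS:
        out[var] = np.nan

    if "lat" in out.columns and "lon" in out.columns and \
            out[["lat", "lon"]].notna().all(axis=None):
        coords_per_sample = [
            [(la, lo)] for la, lo in zip(_round_half_up(out["lat"]),
                                         _round_half_up(out["lon"]))
        ]
    else:
        if zip_table is None or "zip" not in out.columns:
            raise ValueError("need lat/lon columns, or zip column + zip_table")
        zt = zip_table.copy()
        zt["lat"] = _round_half_up(zt["lat"])
        zt["lon"] = _round_half_up(zt["lon"])
        zip_coords = zt.groupby("zip").apply(
            lambda g: list(zip(g["lat"], g["lon"])), include_groups=False)
        coords_per_sample = [
            zip_coords.get(z, []) for z in out["zip"]
        ]

    n_offgrid = 0
    for i, coords in enumerate(coords_per_sample):
        idx = [cell_lookup[c] for c in coords if c in cell_lookup]
        if not idx:
            n_offgrid += 1
            continue
        sub = cells.loc[idx]
        for var in CLIMATE_VARS:
            out.iloc[i, out.columns.get_loc(var)] = float(sub[var].mean())
        regions = sub["ecoregion"].unique()
        if len(regions) == 1:
            out.iloc[i, out.columns.get_loc("ecoregion")] = float(regions[0])
        else:
            out.iloc[i, out.columns.get_loc("excluded_discrete")] = True
    if n_offgrid:
        logger.info("%d samples had off-grid locations and stay unassigned",
                    n_offgrid)
    return out


def synthetic_environment(n_regions: int = 9, cells_per_region: int = 40,
                          separation: float = 6.0, seed: int | None = None,
                          n_multi_region_zips: int = 0):
    """Gaussian-blob climate grid with known region labels.

    Region centers sit ``separation`` standard deviations apart in the
    standardized climate space; cells scatter around them with unit SD and are
    mapped to plausible climate units (degC, mm/yr, m).  Returns
    ``(grid, zip_table)`` where the grid carries a ``true_region`` column and
    the zip table maps one synthetic zip per cell -- plus, optionally, zips
    deliberately attached to two cells in different regions to exercise the
    multi-region-zip exclusion rule.
    """
    rng = np.random.default_rng(seed)
    # random center placement rescaled so the closest pair sits exactly
    # ``separation`` apart; all three variables stay informative
    base = rng.uniform(0.0, 1.0, size=(n_regions, 3))
    if n_regions > 1:
        d = np.sqrt(((base[:, None] - base[None]) ** 2).sum(axis=2))
        dmin = d[np.triu_indices(n_regions, 1)].min()
        centers = base * (separation / dmin if dmin > 0 else 0.0)
    else:
        centers = base * 0.0
    z = np.concatenate([
        centers[r] + rng.normal(0, 1.0, size=(cells_per_region, 3))
        for r in range(n_regions)
    ])
    labels = np.repeat(np.arange(n_regions), cells_per_region)

    scale = np.array([8.0, 400.0, 400.0])
    offset = np.array([12.0, 900.0, 800.0])
    climate = z * scale + offset

    n_cells = len(z)
    lat = 30.0 + 0.1 * np.arange(n_cells) % 18.0
    lon = -110.0 + 0.1 * (np.arange(n_cells) // 180)
    # keep one cell per rounded coordinate
    lat = _round_half_up(lat)
    lon = _round_half_up(lon)

    grid = pd.DataFrame({
        "lat": lat, "lon": lon,
        "temperature": climate[:, 0],
        "precipitation": climate[:, 1],
        "elevation": climate[:, 2],
        "true_region": labels,
    })
    zip_rows = [{"zip": f"Z{i:05d}", "lat": grid["lat"].iloc[i],
                 "lon": grid["lon"].iloc[i]} for i in range(n_cells)]
    for j in range(n_multi_region_zips):
        a = int(rng.integers(0, cells_per_region))               # region 0 cell
        b = int(cells_per_region + rng.integers(0, cells_per_region))  # region 1
        zip_rows.append({"zip": f"M{j:05d}", "lat": grid["lat"].iloc[a],
                         "lon": grid["lon"].iloc[a]})
        zip_rows.append({"zip": f"M{j:05d}", "lat": grid["lat"].iloc[b],
                         "lon": grid["lon"].iloc[b]})
    zip_table = pd.DataFrame(zip_rows)
    return grid, zip_table
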