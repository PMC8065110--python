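"""Aggregation of daily positions and environmental fields onto the grid.

Daily positions are binned into 10-km cells by calendar month; the study
region is restricted to continental-shelf water (depth < 200 m) between
33.5 and 41.6 degrees N; coarse SST rasters are up-sampled to the grid by
simple averaging; and everything is joined into the cell x month occurrence
table the habitat model consumes.

Absence convention: a shelf cell x month with no tracked-animal position is
an absence (y = 0). No tagging-effort correction is applied, so "absence"
means "no tagged animal was estimated there", not "no animal was there" —
a caveat inherent to presence models built from telemetry alone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo import project_coordinates
from .synthetic import EnvironmentGrid, SSTClimatology

__all__ = [
    "assign_cells",
    "apply_study_mask",
    "regrid_to_cells",
    "monthly_sst",
    "build_occurrence_table",
    "write_occurrence_csv",
    "read_occurrence_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_LAT_BAND = (33.5, 41.6)
DEFAULT_MAX_DEPTH = 200.0


def _cell_index(grid: EnvironmentGrid, x: np.ndarray, y: np.ndarray):
    """Half-open binning [edge, edge + cell_size) on both axes.

    Returns (flat row index into grid.cells, in-extent mask).
    """
    ix = np.floor((x - grid.x_edge0) / grid.cell_size).astype(int)
    iy = np.floor((y - grid.y_edge0) / grid.cell_size).astype(int)
    ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    return iy * grid.nx + ix, ok


def assign_cells(daily_positions: pd.DataFrame, grid: EnvironmentGrid):
    """Bin daily positions (columns x, y in metres, date) into cell x month
    presence indicators.

    Returns (presences, n_dropped): ``presences`` has one row per distinct
    (cell_id, month) with at least one position; positions outside the grid
    extent are dropped and counted.
    """
    x = daily_positions["x"].to_numpy(dtype=float)
    y = daily_positions["y"].to_numpy(dtype=float)
    month = pd.DatetimeIndex(daily_positions["date"]).month.to_numpy()
    idx, ok = _cell_index(grid, x, y)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("assign_cells: dropped %d positions outside grid extent", n_dropped)
    pres = (
        pd.DataFrame({"cell_id": idx[ok], "month": month[ok]})
        .drop_duplicates()
        .sort_values(["cell_id", "month"])
        .reset_index(drop=True)
    )
    return pres, n_dropped


def apply_study_mask(
    grid: EnvironmentGrid,
    lat_band: tuple[float, float] = DEFAULT_LAT_BAND,
    max_depth: float = DEFAULT_MAX_DEPTH,
) -> np.ndarray:
    """Mark shelf cells: water, depth strictly below ``max_depth``, latitude
    within ``lat_band`` (inclusive). Writes grid.cells['shelf_mask'] and
    returns the mask."""
    cells = grid.cells
    if cells["depth"].isna().any():
        raise ValueError("grid has no bathymetry; run make_bathymetry first")
    lat = cells["lat_center"].to_numpy()
    mask = (
        ~cells["land_mask"].to_numpy()
        & (cells["depth"].to_numpy() < max_depth)
        & (lat >= lat_band[0])
        & (lat <= lat_band[1])
    )
    if not mask.any():
        raise ValueError("study mask is empty")
    cells["shelf_mask"] = mask
    return mask


def regrid_to_cells(
    coarse_lon: np.ndarray,
    coarse_lat: np.ndarray,
    fields: np.ndarray,
    grid: EnvironmentGrid,
) -> np.ndarray:
    """Up-sample coarse lon/lat rasters to the analysis grid by simple
    averaging.

    ``coarse_lon``/``coarse_lat`` are 1-D pixel-centre axes and ``fields``
    has shape (..., n_lat, n_lon). Each cell receives the unweighted mean of
    the coarse pixels whose centres fall inside it; cells containing no
    pixel centre take the value of the nearest pixel (projected distance to
    the cell centre). A field that is entirely missing raises.
    """
    coarse_lon = np.asarray(coarse_lon, dtype=float)
    coarse_lat = np.asarray(coarse_lat, dtype=float)
    fields = np.asarray(fields, dtype=float)
    lead = fields.shape[:-2]
    flat = fields.reshape((-1,) + fields.shape[-2:])
    glon, glat = np.meshgrid(coarse_lon, coarse_lat)
    px, py = project_coordinates(glon.ravel(), glat.ravel())
    idx, ok = _cell_index(grid, px, py)
    n_cells = grid.n_cells
    out = np.empty((flat.shape[0], n_cells))
    cx = grid.cells["x_center"].to_numpy()
    cy = grid.cells["y_center"].to_numpy()
    for k in range(flat.shape[0]):
        vals = flat[k].ravel()
        if np.all(np.isnan(vals)):
            raise ValueError("source field is entirely missing")
        good = ok & np.isfinite(vals)
        sums = np.bincount(idx[good], weights=vals[good], minlength=n_cells)
        counts = np.bincount(idx[good], minlength=n_cells)
        with np.errstate(invalid="ignore"):
            mean = sums / counts
        empty = counts == 0
        if empty.any():
            fin = np.flatnonzero(np.isfinite(vals))
            for c in np.flatnonzero(empty):
                d2 = (px[fin] - cx[c]) ** 2 + (py[fin] - cy[c]) ** 2
                mean[c] = vals[fin[np.argmin(d2)]]
        out[k] = mean
    return out.reshape(lead + (n_cells,))


def monthly_sst(
    coarse_lon: np.ndarray,
    coarse_lat: np.ndarray,
    monthly_fields: np.ndarray,
    grid: EnvironmentGrid,
) -> SSTClimatology:
    """Align a coarse 12-month SST raster stack (12, n_lat, n_lon) with the
    analysis grid."""
    monthly_fields = np.asarray(monthly_fields, dtype=float)
    if monthly_fields.shape[0] != 12:
        raise ValueError("expected 12 monthly fields")
    return SSTClimatology(regrid_to_cells(coarse_lon, coarse_lat, monthly_fields, grid))


def build_occurrence_table(
    presences: pd.DataFrame,
    grid: EnvironmentGrid,
    climatology: SSTClimatology,
    study_months=range(1, 13),
) -> pd.DataFrame:
    """One row per shelf cell per study month with y, SST and depth.

    y = 1 where a presence was recorded in that cell x month (presences in
    non-shelf cells are excluded), else 0. Rows with missing covariates are
    dropped with a logged count. A table with no presences raises: the
    Bernoulli model would be unidentifiable.
    """
    shelf = grid.cells[grid.cells["shelf_mask"]]
    if len(shelf) == 0:
        raise ValueError("study mask is empty")
    months = [int(m) for m in study_months]
    cid = shelf["cell_id"].to_numpy()
    idx = shelf.index.to_numpy()
    depth = shelf["depth"].to_numpy()
    pres_set = set(zip(presences["cell_id"].astype(int), presences["month"].astype(int)))
    parts = []
    for m in months:
        sst = climatology.month(m)[idx]
        y = np.fromiter(((c, m) in pres_set for c in cid), dtype=int, count=len(cid))
        parts.append(
            pd.DataFrame({"cell_id": cid, "month": m, "y": y, "sst_c": sst, "depth_m": depth})
        )
    table = pd.concat(parts, ignore_index=True)
    bad = table[["sst_c", "depth_m"]].isna().any(axis=1)
    if bad.any():
        logger.info("build_occurrence_table: dropped %d rows with missing covariates", int(bad.sum()))
        table = table[~bad].reset_index(drop=True)
    if table["y"].sum() == 0:
        raise ValueError("no presences fall inside the study mask; model unidentifiable")
    return table


def write_occurrence_csv(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"month": "month"})[["cell_id", "month", "y", "sst_c", "depth_m"]]
    out.to_csv(path, index=False, float_format="%.6f")


def read_occurrence_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
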