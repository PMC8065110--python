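"""Climate-delta projection of occupancy and seasonal/decadal summaries.

The delta method adds model-projected monthly SST anomalies to the observed
monthly climatology rather than using raw climate-model output; depth is
held constant. The fitted habitat model then converts each projected SST
field into a presence-probability field, the Index-of-Union cut-point turns
probabilities into occupancy, and results are summarised by season
(Jan-Mar winter, Apr-Jun spring, Jul-Sep summer, Oct-Dec fall) and by 10-
or 20-year bins, with bin 0 denoting the observed era.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import classify_occupancy
from .habitat import HabitatFit, predict_probability
from .synthetic import DeltaSeries, EnvironmentGrid, SSTClimatology

__all__ = [
    "DEFAULT_SEASONS",
    "OccupancyProjection",
    "SeasonalSummary",
    "apply_deltas",
    "project_occupancy",
    "seasonal_decadal_summary",
    "habitat_trend_report",
]

DEFAULT_SEASONS = {
    "winter": (1, 2, 3),
    "spring": (4, 5, 6),
    "summer": (7, 8, 9),
    "fall": (10, 11, 12),
}


def apply_deltas(
    climatology: SSTClimatology, deltas: DeltaSeries, year: int, month: int
) -> np.ndarray:
    """Projected SST field for one (year, month): climatology + delta."""
    if climatology.values.shape[1] != deltas.values.shape[2]:
        raise ValueError("climatology and deltas are on different grids")
    return climatology.month(month) + deltas.field(year, month)


@dataclass
class OccupancyProjection:
    """Projected SST, probability, and occupancy over (year, month, cell).

    ``baseline_probability`` (12, n_cells) is the fitted-era field (zero
    delta). Probability and occupancy are NaN off the study mask.
    """

    sst: np.ndarray  # (H, 12, n_cells)
    probability: np.ndarray  # (H, 12, n_cells), NaN off-mask
    occupancy: np.ndarray  # (H, 12, n_cells), 1/0/NaN
    baseline_probability: np.ndarray  # (12, n_cells), NaN off-mask
    cutpoint: float
    shelf_mask: np.ndarray  # (n_cells,) bool

    @property
    def horizon(self) -> int:
        return self.sst.shape[0]


def project_occupancy(
    fit: HabitatFit,
    climatology: SSTClimatology,
    deltas: DeltaSeries,
    grid: EnvironmentGrid,
    c: float,
    horizon: int | None = None,
) -> OccupancyProjection:
    """Project presence probability and occupancy for every cell x month x
    projection year.

    A year with zero deltas reproduces the fitted-era probabilities exactly
    (the projection is the identity map at delta = 0).
    """
    if not fit.converged:
        raise ValueError("habitat fit did not converge; refusing to project")
    horizon = deltas.horizon if horizon is None else int(horizon)
    if not 1 <= horizon <= deltas.horizon:
        raise ValueError("horizon out of range of the delta series")
    if climatology.values.shape[1] != grid.n_cells:
        raise ValueError("climatology is not aligned with the grid")
    mask = grid.cells["shelf_mask"].to_numpy()
    depth = grid.cells["depth"].to_numpy()
    sst = climatology.values[None, :, :] + deltas.values[:horizon]
    prob = predict_probability(fit, sst, depth[None, None, :])
    prob = np.where(mask[None, None, :], prob, np.nan)
    occ = classify_occupancy(prob, c)
    base = predict_probability(fit, climatology.values, depth[None, :])
    base = np.where(mask[None, :], base, np.nan)
    return OccupancyProjection(sst, prob, occ, base, float(c), mask)


@dataclass
class SeasonalSummary:
    """Cellwise mean probability and occupied fraction per season x bin.

    Bin 0 is the observed era; bin k >= 1 covers projection years
    ((k-1)*width, k*width]. ``table`` has columns season, bin, occupied_
    fraction; ``mean_probability[(season, bin)]`` is the (n_cells,) field.
    """

    table: pd.DataFrame
    mean_probability: dict
    bin_width: int
    cutpoint: float
    mode: str


def seasonal_decadal_summary(
    projection: OccupancyProjection,
    season_map: dict | None = None,
    bin_width: int = 10,
    mode: str = "mean-then-classify",
) -> SeasonalSummary:
    """Summarise the projection by season and year-bin.

    mode="mean-then-classify" (default): the seasonal-bin mean probability
    field is classified at c and the occupied fraction is the share of
    shelf cells classified 1. mode="classify-then-mean": monthly occupancy
    is averaged instead, giving the mean monthly occupied fraction.
    """
    seasons = DEFAULT_SEASONS if season_map is None else season_map
    months = sorted(m for ms in seasons.values() for m in ms)
    if months != list(range(1, 13)):
        raise ValueError("seasons must partition months 1..12 exactly")
    if mode not in ("mean-then-classify", "classify-then-mean"):
        raise ValueError(f"unknown mode: {mode}")
    h = projection.horizon
    if bin_width < 1 or h < bin_width:
        raise ValueError("projection horizon shorter than one bin")
    n_bins = h // bin_width
    mask = projection.shelf_mask
    n_shelf = int(mask.sum())
    c = projection.cutpoint
    rows = []
    fields = {}
    for name, ms in seasons.items():
        midx = [m - 1 for m in ms]
        # bin 0: observed era
        base = projection.baseline_probability[midx]  # (n_months, n_cells)
        for b in range(n_bins + 1):
            if b == 0:
                prob = base[None, :, :]
            else:
                years = slice((b - 1) * bin_width, b * bin_width)
                prob = projection.probability[years][:, midx, :]
            if prob.size == 0:
                raise ValueError(f"empty bin {b} for season {name}")
            flat = prob.reshape(-1, prob.shape[-1])
            mean_field = np.full(flat.shape[-1], np.nan)
            mean_field[mask] = flat[:, mask].mean(axis=0)
            if mode == "mean-then-classify":
                occ = classify_occupancy(mean_field, c)
                frac = float(np.nansum(occ) / n_shelf)
            else:
                occ = classify_occupancy(prob, c)
                frac = float(np.nanmean(occ.reshape(-1, occ.shape[-1])[:, mask]))
            fields[(name, b)] = mean_field
            rows.append({"season": name, "bin": b, "occupied_fraction": frac})
    table = pd.DataFrame(rows).sort_values(["season", "bin"]).reset_index(drop=True)
    return SeasonalSummary(table, fields, bin_width, c, mode)


def habitat_trend_report(summary: SeasonalSummary) -> pd.DataFrame:
    """Long-format trend table: occupied fraction by season x bin and its
    change versus the observed era (bin 0)."""
    t = summary.table
    if t["bin"].nunique() < 2:
        raise ValueError("need at least two bins for a trend")
    base = t[t["bin"] == 0].set_index("season")["occupied_fraction"]
    out = t.copy()
    out["change_vs_observed"] = out.apply(
        lambda r: r["occupied_fraction"] - base[r["season"]], axis=1
    )
    return out
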