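"""Synthetic study system: grids, bathymetry, SST fields, deltas, and tracks.

Real loggerhead telemetry is proprietary and the environmental products the
pipeline was designed around (a 1/4-degree blended SST analysis, global
relief bathymetry, high-resolution climate-model SST anomalies) are large
downloads; this module emulates all of them at desk scale so every pipeline
stage can be exercised and tested against planted truth.

The emulation keeps the features the pipeline is sensitive to and nothing
else: a uniform 10-km projected lattice bounded by a parametric coastline; a
shelf that deepens offshore; a seasonally and latitudinally structured SST
climatology; warming deltas that grow over the projection horizon and can
warm the north faster (as the Gulf of Maine is expected to); CTCRW tracks
observed irregularly with Gaussian noise and planted errant fixes; and
Bernoulli occupancy drawn from a known quadratic logistic surface in
(SST, depth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo import project_coordinates, unproject_coordinates
from .tracks import CtcrwParams, RawTrack, ou_transition

__all__ = [
    "CoastlineSpec",
    "EnvironmentGrid",
    "SSTClimatology",
    "DeltaSeries",
    "TruthSurface",
    "SimulatedTrack",
    "make_grid",
    "make_bathymetry",
    "make_sst_climatology",
    "make_deltas",
    "simulate_occupancy",
    "simulate_tracks",
    "default_scenario",
    "DEFAULT_TRUTH",
]


@dataclass(frozen=True)
class CoastlineSpec:
    """Parametric coastline in projected coordinates: land where
    ``x < x0 + slope * y + amplitude * sin(2 pi y / wavelength)``."""

    x0: float = -90_000.0
    slope: float = 0.18
    amplitude: float = 15_000.0
    wavelength: float = 300_000.0

    def coast_x(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self.x0 + self.slope * y + self.amplitude * np.sin(
            2.0 * np.pi * y / self.wavelength
        )


@dataclass
class EnvironmentGrid:
    """Uniform projected lattice of analysis cells.

    ``cells`` has one row per cell with columns cell_id, lon_center,
    lat_center, x_center, y_center, depth (m, positive down, NaN until
    bathymetry is attached), land_mask, shelf_mask.
    """

    cells: pd.DataFrame
    cell_size: float
    nx: int
    ny: int
    x_edge0: float
    y_edge0: float
    coastline: CoastlineSpec | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shelf_index(self) -> np.ndarray:
        return self.cells.index[self.cells["shelf_mask"]].to_numpy()


@dataclass
class SSTClimatology:
    """Monthly mean SST per cell: array of shape (12, n_cells), degrees C."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 12:
            raise ValueError("climatology must have shape (12, n_cells)")

    def month(self, m: int) -> np.ndarray:
        if not 1 <= m <= 12:
            raise ValueError("month index must be in 1..12")
        return self.values[m - 1]


@dataclass
class DeltaSeries:
    """SST deviations per (projection year, month, cell): shape (H, 12, n)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != 12:
            raise ValueError("deltas must have shape (horizon, 12, n_cells)")

    @property
    def horizon(self) -> int:
        return self.values.shape[0]

    def field(self, year: int, month: int) -> np.ndarray:
        if not 1 <= year <= self.horizon:
            raise ValueError("projection year out of range")
        if not 1 <= month <= 12:
            raise ValueError("month index must be in 1..12")
        return self.values[year - 1, month - 1]


@dataclass(frozen=True)
class TruthSurface:
    """Known quadratic logistic presence surface used to plant occupancy.

    logit(p) = b0 + b1*SST + b2*SST^2 + b3*depth + b4*depth^2, with b2, b4
    negative so the response is concave with a single bathythermal optimum at
    (-b1/(2 b2), -b3/(2 b4)).
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float

    @classmethod
    def from_peaks(
        cls,
        peak_sst: float,
        peak_depth: float,
        sst_curvature: float,
        depth_curvature: float,
        peak_logit: float,
    ) -> "TruthSurface":
        """Build from the optimum location, curvatures (>0), and peak logit."""
        b2 = -sst_curvature
        b4 = -depth_curvature
        b1 = 2.0 * sst_curvature * peak_sst
        b3 = 2.0 * depth_curvature * peak_depth
        b0 = peak_logit - sst_curvature * peak_sst**2 - depth_curvature * peak_depth**2
        return cls(b0, b1, b2, b3, b4)

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3, self.beta4])

    @property
    def peak_sst(self) -> float:
        return -self.beta1 / (2.0 * self.beta2)

    @property
    def peak_depth(self) -> float:
        return -self.beta3 / (2.0 * self.beta4)

    def probability(self, sst, depth) -> np.ndarray:
        sst = np.asarray(sst, dtype=float)
        depth = np.asarray(depth, dtype=float)
        eta = (
            self.beta0
            + self.beta1 * sst
            + self.beta2 * sst**2
            + self.beta3 * depth
            + self.beta4 * depth**2
        )
        return expit(eta)


#: Planted truth for the default scenario: bathythermal optimum at 21.5 degC
#: and 50 m, peak presence probability expit(0.5) ~ 0.62, and curvatures that
#: give a plausible thermal envelope (p >= 0.08 between roughly 14 and 29 degC
#: and 12 and 88 m).
DEFAULT_TRUTH = TruthSurface.from_peaks(
    peak_sst=21.5, peak_depth=50.0, sst_curvature=0.05, depth_curvature=0.002, peak_logit=0.5
)


# ---------------------------------------------------------------------------
# Grid, bathymetry, climatology, deltas
# ---------------------------------------------------------------------------


def make_grid(
    lon_range: tuple[float, float],
    lat_range: tuple[float, float],
    cell_size: float = 10_000.0,
    coastline: CoastlineSpec | None = None,
) -> EnvironmentGrid:
    """Build a uniform ``cell_size``-metre lattice covering the given extent.

    The lon/lat extent corners are projected and the lattice spans their
    bounding box; cell centres are inverse-projected back to geographic
    coordinates. ``coastline`` (optional) marks cells west of the parametric
    coast as land.
    """
    if not (lon_range[1] > lon_range[0] and lat_range[1] > lat_range[0]):
        raise ValueError("degenerate lon/lat extent")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    corner_lon = [lon_range[0], lon_range[0], lon_range[1], lon_range[1]]
    corner_lat = [lat_range[0], lat_range[1], lat_range[0], lat_range[1]]
    cx, cy = project_coordinates(corner_lon, corner_lat)
    x0, x1 = float(np.min(cx)), float(np.max(cx))
    y0, y1 = float(np.min(cy)), float(np.max(cy))
    nx = max(int(np.floor((x1 - x0) / cell_size)), 1)
    ny = max(int(np.floor((y1 - y0) / cell_size)), 1)
    xc = x0 + cell_size * (np.arange(nx) + 0.5)
    yc = y0 + cell_size * (np.arange(ny) + 0.5)
    xx, yy = np.meshgrid(xc, yc)
    xx, yy = xx.ravel(), yy.ravel()
    lon, lat = unproject_coordinates(xx, yy)
    land = (
        xx < coastline.coast_x(yy) if coastline is not None else np.zeros(len(xx), dtype=bool)
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(xx)),
            "lon_center": lon,
            "lat_center": lat,
            "x_center": xx,
            "y_center": yy,
            "depth": np.where(land, 0.0, np.nan),
            "land_mask": land,
            "shelf_mask": False,
        }
    )
    return EnvironmentGrid(cells, cell_size, nx, ny, x0, y0, coastline)


def make_bathymetry(
    grid: EnvironmentGrid,
    ramp_width: float = 100_000.0,
    ramp_widening: float = 0.39,
    max_depth: float = 300.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Attach a shelf-like depth field: a linear offshore ramp plus noise.

    Depth (positive down) rises from 0 at the coast to ``max_depth`` over
    the ramp width, in expectation monotone offshore. The ramp width grows
    northward as ``ramp_width + ramp_widening * (y - y_min)``, emulating
    the real geometry of this margin: a narrow southern shelf broadening
    several-fold into the wide northern banks. Land cells stay at depth 0.
    The field is written into ``grid.cells['depth']`` and returned.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = grid.cells["x_center"].to_numpy()
    y = grid.cells["y_center"].to_numpy()
    coast = grid.coastline.coast_x(y) if grid.coastline is not None else grid.x_edge0
    offshore = np.clip(x - coast, 0.0, None)
    width = ramp_width + ramp_widening * np.clip(y - y.min(), 0.0, None)
    depth = max_depth * np.clip(offshore / width, 0.0, 1.0)
    if noise_sd > 0:
        depth = np.clip(depth + rng.normal(0.0, noise_sd, size=len(depth)), 0.0, None)
    land = grid.cells["land_mask"].to_numpy()
    depth = np.where(land, 0.0, depth)
    grid.cells["depth"] = depth
    return depth


def make_sst_climatology(
    grid: EnvironmentGrid,
    mean_at_ref: float = 19.0,
    ref_lat: float = 33.5,
    lat_gradient: float = -0.9,
    seasonal_amplitude: float = 7.0,
    warmest_month: int = 8,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SSTClimatology:
    """Monthly SST climatology: latitudinal ramp + annual harmonic + noise.

    SST(cell, m) = mean_at_ref + lat_gradient * (lat - ref_lat)
                   + seasonal_amplitude * cos(2 pi (m - warmest_month) / 12)
                   + N(0, noise_sd^2).

    Defaults emulate the US northeast shelf: ~19 degC annual mean in the
    south cooling ~0.9 degC per degree of latitude northward, and a 7 degC
    seasonal cycle peaking in August (the observed amplitude runs ~6 degC
    on the southern shelf to ~7.5 degC on the northern banks; a single
    mid-range value is used because the harmonic is not latitude-coupled).
    """
    if seasonal_amplitude < 0:
        raise ValueError("seasonal_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    lat = grid.cells["lat_center"].to_numpy()
    months = np.arange(1, 13)
    base = mean_at_ref + lat_gradient * (lat - ref_lat)
    seasonal = seasonal_amplitude * np.cos(2.0 * np.pi * (months - warmest_month) / 12.0)
    values = base[None, :] + seasonal[:, None]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return SSTClimatology(values)


def make_deltas(
    grid: EnvironmentGrid,
    horizon_years: int = 80,
    end_warming: float = 3.0,
    north_south_gradient: float = 1.0,
) -> DeltaSeries:
    """Linear-in-time warming deltas, optionally stronger at high latitude.

    The spatial pattern ``1 + g * (lat - lat_min)/(lat_max - lat_min)`` is
    normalised to mean 1 so the year-``H`` spatial-mean delta equals
    ``end_warming`` exactly. All 12 months share the same delta (seasonal
    structure in the anomaly is not emulated).
    """
    if horizon_years < 1:
        raise ValueError("horizon must be >= 1")
    lat = grid.cells["lat_center"].to_numpy()
    span = lat.max() - lat.min()
    pattern = 1.0 + north_south_gradient * (lat - lat.min()) / (span if span > 0 else 1.0)
    pattern = pattern / pattern.mean()
    years = np.arange(1, horizon_years + 1, dtype=float) / horizon_years
    values = end_warming * years[:, None, None] * pattern[None, None, :]
    values = np.broadcast_to(values, (horizon_years, 12, len(lat))).copy()
    return DeltaSeries(values)


# ---------------------------------------------------------------------------
# Occupancy and track simulation
# ---------------------------------------------------------------------------


def simulate_occupancy(
    truth: TruthSurface,
    grid: EnvironmentGrid,
    climatology: SSTClimatology,
    months=range(1, 13),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw Bernoulli presence for every shelf cell x month from the truth
    surface, returning an occurrence table (cell_id, month, y, sst_c,
    depth_m)."""
    if truth.beta2 >= 0 or truth.beta4 >= 0:
        warnings.warn("truth surface is not concave; bathythermal peak undefined")
    shelf = grid.cells[grid.cells["shelf_mask"]]
    if len(shelf) == 0:
        raise ValueError("no shelf cells in grid; apply the study mask first")
    rng = np.random.default_rng(seed)
    rows = []
    depth = shelf["depth"].to_numpy()
    cid = shelf["cell_id"].to_numpy()
    idx = shelf.index.to_numpy()
    for m in months:
        sst = climatology.month(int(m))[idx]
        p = truth.probability(sst, depth)
        y = rng.binomial(1, p)
        rows.append(
            pd.DataFrame({"cell_id": cid, "month": int(m), "y": y, "sst_c": sst, "depth_m": depth})
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class SimulatedTrack:
    """A simulated tag: observed fixes plus the true states for testing."""

    raw: RawTrack
    true_x: np.ndarray
    true_y: np.ndarray
    true_vx: np.ndarray
    true_vy: np.ndarray
    errant: np.ndarray  # bool per fix: displaced to violate the speed bound


def _simulate_ou_axis(times_h, beta, sigma, x0, rng):
    n = len(times_h)
    x = np.empty(n)
    v = np.empty(n)
    x[0] = x0
    v[0] = rng.normal(0.0, np.sqrt(sigma**2 / (2.0 * beta))) if sigma > 0 else 0.0
    for k in range(1, n):
        dt = times_h[k] - times_h[k - 1]
        phi, q = ou_transition(beta, max(sigma, 1e-300), dt)
        mean = phi @ np.array([x[k - 1], v[k - 1]])
        if sigma > 0:
            # Cholesky of the 2x2 process covariance
            l11 = np.sqrt(q[0, 0])
            l21 = q[0, 1] / l11 if l11 > 0 else 0.0
            l22 = np.sqrt(max(q[1, 1] - l21**2, 0.0))
            z = rng.standard_normal(2)
            noise = np.array([l11 * z[0], l21 * z[0] + l22 * z[1]])
        else:
            noise = np.zeros(2)
        x[k], v[k] = mean + noise
    return x, v


def simulate_tracks(
    n_animals: int = 12,
    ctcrw_params: CtcrwParams = CtcrwParams(0.3, 1500.0, 500.0),
    duration_days: float = 120.0,
    mean_gap_hours: float = 2.0,
    min_gap_hours: float = 0.5,
    noise_sd: float | None = None,
    errant_rate: float = 0.0,
    start_box=((-150_000.0, 150_000.0), (-100_000.0, 400_000.0)),
    start_time: str = "2015-06-01T00:00:00",
    vmax_kmh: float = 5.0,
    seed: int = 0,
) -> list[SimulatedTrack]:
    """Simulate tagged animals from the exact CTCRW transition.

    Observation times per animal are cumulative shifted-exponential gaps
    (mean ``mean_gap_hours``, never shorter than ``min_gap_hours`` —
    satellite tags are duty-cycled, and without a floor on the gap the
    observation noise alone would imply implausible speeds over
    back-to-back fixes); observations are the true positions plus isotropic
    Gaussian noise of sd ``noise_sd`` (defaults to ``ctcrw_params.
    obs_error_sd``). A fraction ``errant_rate`` of interior fixes is
    displaced far enough to violate the ``vmax_kmh`` speed bound against
    both neighbours. True states are retained for testing.

    The default reversion/diffusion pair (0.3 /h, 1500 m/h^1.5) gives a
    per-axis stationary velocity sd of ~1.9 km/h — a plausible sustained
    swimming scale for a foraging loggerhead — so genuine fixes essentially
    never trip the 5 km/h filter and planted errant fixes always do.
    """
    if not 0.0 <= errant_rate < 1.0:
        raise ValueError("errant_rate must be in [0, 1)")
    if mean_gap_hours <= 0 or duration_days <= 0:
        raise ValueError("schedule parameters must be positive")
    if not 0.0 <= min_gap_hours < mean_gap_hours:
        raise ValueError("min_gap_hours must be in [0, mean_gap_hours)")
    if noise_sd is None:
        noise_sd = ctcrw_params.obs_error_sd
    rng = np.random.default_rng(seed)
    t0 = np.datetime64(start_time, "ns")
    out = []
    for a in range(n_animals):
        n_max = int(duration_days * 24 / mean_gap_hours) + 1
        gaps = min_gap_hours + rng.exponential(mean_gap_hours - min_gap_hours, size=n_max)
        times_h = np.concatenate([[0.0], np.cumsum(gaps)])
        times_h = times_h[times_h <= duration_days * 24.0]
        if np.any(np.diff(times_h) <= 0):
            raise ValueError("non-increasing observation times")
        x0 = rng.uniform(*start_box[0])
        y0 = rng.uniform(*start_box[1])
        tx, tvx = _simulate_ou_axis(
            times_h, ctcrw_params.reversion_rate, ctcrw_params.diffusion, x0, rng
        )
        ty, tvy = _simulate_ou_axis(
            times_h, ctcrw_params.reversion_rate, ctcrw_params.diffusion, y0, rng
        )
        ox = tx + (rng.normal(0.0, noise_sd, len(tx)) if noise_sd > 0 else 0.0)
        oy = ty + (rng.normal(0.0, noise_sd, len(ty)) if noise_sd > 0 else 0.0)
        errant = np.zeros(len(tx), dtype=bool)
        if errant_rate > 0 and len(tx) > 2:
            interior = np.arange(1, len(tx) - 1)
            errant[interior] = rng.random(len(interior)) < errant_rate
            for i in np.flatnonzero(errant):
                gap_h = max(times_h[i] - times_h[i - 1], times_h[i + 1] - times_h[i])
                # big enough to violate vmax against both neighbours
                mag = 3.0 * vmax_kmh * 1000.0 * gap_h + 50_000.0
                ang = rng.uniform(0.0, 2.0 * np.pi)
                ox[i] += mag * np.cos(ang)
                oy[i] += mag * np.sin(ang)
        lon, lat = unproject_coordinates(ox, oy)
        times = t0 + (times_h * 3.6e12).astype("timedelta64[ns]")
        raw = RawTrack(f"turtle_{a:03d}", times, lon, lat)
        out.append(SimulatedTrack(raw, tx, ty, tvx, tvy, errant))
    return out


# ---------------------------------------------------------------------------
# Default study scenario
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    grid: EnvironmentGrid
    climatology: SSTClimatology
    deltas: DeltaSeries
    truth: TruthSurface


def default_scenario(
    seed: int = 0,
    lon_range=(-76.0, -69.5),
    lat_range=(33.0, 42.2),
    cell_size: float = 10_000.0,
    horizon_years: int = 80,
) -> Scenario:
    """The default synthetic study system: shelf grid, climatology, deltas,
    and the planted truth surface. The study mask (depth < 200 m within
    33.5-41.6 degN) is applied to the grid."""
    from .gridding import apply_study_mask

    ss = np.random.SeedSequence(seed)
    s_bathy, s_clim = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    grid = make_grid(lon_range, lat_range, cell_size, coastline=CoastlineSpec())
    make_bathymetry(grid, seed=s_bathy)
    apply_study_mask(grid)
    clim = make_sst_climatology(grid, seed=s_clim)
    deltas = make_deltas(grid, horizon_years=horizon_years)
    return Scenario(grid, clim, deltas, DEFAULT_TRUTH)
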