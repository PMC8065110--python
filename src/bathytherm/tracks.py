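"""Telemetry track cleaning, movement modelling, and daily interpolation.

The processing chain mirrors standard practice for marine-turtle satellite
tags: errant fixes are removed with a 5 km/h speed filter, a continuous-time
correlated random walk (CTCRW) is fitted to each animal's remaining fixes by
maximum likelihood, and daily positions (with uncertainty) are interpolated
from the smoothed state estimates.

The CTCRW is the integrated Ornstein–Uhlenbeck velocity model: per axis the
velocity follows ``dv = -beta * v dt + sigma dW`` and position integrates
velocity. Over an arbitrary time gap the transition is available in closed
form, so irregular sampling is handled exactly by a Kalman filter with state
(position, velocity) per axis and isotropic Gaussian observation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geo import great_circle_distance_m, project_coordinates

__all__ = [
    "RawTrack",
    "CtcrwParams",
    "CtcrwFitResult",
    "FittedTrack",
    "speed_filter",
    "ou_transition",
    "ctcrw_loglik",
    "fit_ctcrw",
    "smooth_track",
    "interpolate_daily",
    "read_tracks_csv",
    "write_tracks_csv",
]

#: Default maximum plausible sustained swimming speed for loggerheads (km/h).
DEFAULT_VMAX_KMH = 5.0

# Vague prior sd (m) on the initial position, centred on the first fix.
# Because the prior mean equals the first observation, the first innovation
# is exactly zero and this only needs to dominate the observation error;
# keeping it moderate preserves float precision in the likelihood.
_INIT_POS_SD_M = 1.0e4


@dataclass
class RawTrack:
    """One animal's transmitted fixes, in geographic coordinates.

    Times must be strictly increasing; latitudes must lie in [-90, 90].
    """

    animal_id: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.times) == len(self.lon) == len(self.lat)):
            raise ValueError("times, lon, lat must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > np.timedelta64(0, "ns")):
            raise ValueError("fix times must be strictly increasing")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def hours(self) -> np.ndarray:
        """Elapsed hours since the first fix."""
        return (self.times - self.times[0]) / np.timedelta64(1, "h")

    def subset(self, keep: np.ndarray) -> "RawTrack":
        return RawTrack(self.animal_id, self.times[keep], self.lon[keep], self.lat[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": pd.DatetimeIndex(self.times).strftime("%Y-%m-%dT%H:%M:%SZ"),
                "lon": self.lon,
                "lat": self.lat,
            }
        )


@dataclass(frozen=True)
class CtcrwParams:
    """CTCRW parameters (shared across the two planar axes).

    reversion_rate
        OU velocity autocorrelation decay rate ``beta`` (1/hour).
    diffusion
        Velocity innovation magnitude ``sigma`` (m/hour^{3/2}); the
        stationary velocity sd is ``sigma / sqrt(2 * beta)`` m/hour.
    obs_error_sd
        Isotropic Gaussian observation error sd (metres).
    """

    reversion_rate: float
    diffusion: float
    obs_error_sd: float

    def __post_init__(self) -> None:
        if self.reversion_rate <= 0:
            raise ValueError("reversion_rate must be > 0")
        # diffusion 0 is allowed as a degenerate simulation case (the animal
        # never moves); likelihood evaluation requires diffusion > 0
        if self.diffusion < 0 or self.obs_error_sd < 0:
            raise ValueError("diffusion and obs_error_sd must be >= 0")

    @property
    def stationary_velocity_var(self) -> float:
        return self.diffusion**2 / (2.0 * self.reversion_rate)


@dataclass
class CtcrwFitResult:
    params: CtcrwParams
    log_likelihood: float
    log_params: np.ndarray  # (log beta, log sigma, log tau)
    se_log_params: np.ndarray
    converged: bool
    n_restarts: int
    message: str = ""


@dataclass
class FittedTrack:
    """Daily smoothed positions for one animal, in projected metres."""

    animal_id: str
    daily_positions: pd.DataFrame  # date, x, y, sd_x, sd_y
    params: CtcrwParams
    log_likelihood: float


# ---------------------------------------------------------------------------
# Speed filter
# ---------------------------------------------------------------------------


def _implied_speeds_kmh(track: RawTrack, keep: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(keep)
    if len(idx) < 2:
        return np.empty(0)
    d_km = (
        great_circle_distance_m(
            track.lon[idx[:-1]], track.lat[idx[:-1]], track.lon[idx[1:]], track.lat[idx[1:]]
        )
        / 1000.0
    )
    dt_h = (track.times[idx[1:]] - track.times[idx[:-1]]) / np.timedelta64(1, "h")
    return d_km / dt_h


def _n_violations(track: RawTrack, keep: np.ndarray, vmax: float) -> int:
    return int(np.sum(_implied_speeds_kmh(track, keep) > vmax))


def speed_filter(track: RawTrack, vmax: float = DEFAULT_VMAX_KMH) -> RawTrack:
    """Remove errant fixes whose implied travel speed exceeds ``vmax`` km/h.

    Iterative worst-offender removal: while any consecutive pair of retained
    fixes implies a speed above ``vmax``, delete the single fix whose removal
    most reduces the number of violating pairs (ties broken by removing the
    later fix). The retained fixes are a subset of the input in original
    order and imply no speed above ``vmax``; the filter is idempotent.
    """
    if len(track) < 2:
        raise ValueError("speed filter needs at least 2 fixes")
    keep = np.ones(len(track), dtype=bool)
    while True:
        speeds = _implied_speeds_kmh(track, keep)
        if len(speeds) == 0:
            raise ValueError("speed filter removed all fixes")
        bad = speeds > vmax
        if not bad.any():
            break
        idx = np.flatnonzero(keep)
        # candidates: every fix touching a violating pair
        cand: set[int] = set()
        for j in np.flatnonzero(bad):
            cand.add(idx[j])
            cand.add(idx[j + 1])
        # remove the fix whose removal most reduces violations; ties broken
        # by the larger implied speed against current neighbours (the worse
        # offender), then by the later fix
        best = None
        for i in sorted(cand):
            trial = keep.copy()
            trial[i] = False
            n_after = _n_violations(track, trial, vmax)
            pos = int(np.searchsorted(idx, i))
            spd = 0.0
            for j in (pos - 1, pos + 1):
                if 0 <= j < len(idx):
                    a, b = (idx[j], i) if j < pos else (i, idx[j])
                    d = great_circle_distance_m(
                        track.lon[a], track.lat[a], track.lon[b], track.lat[b]
                    ) / 1000.0
                    dt = (track.times[b] - track.times[a]) / np.timedelta64(1, "h")
                    spd = max(spd, float(d / dt))
            key = (n_after, -spd, -i)
            if best is None or key < best[0]:
                best = (key, i)
        keep[best[1]] = False
        if keep.sum() < 2:
            raise ValueError("speed filter removed all fixes")
    return track.subset(keep)


# ---------------------------------------------------------------------------
# CTCRW state space
# ---------------------------------------------------------------------------


def ou_transition(beta: float, sigma: float, dt: float):
    """Exact integrated-OU transition over a gap of ``dt`` hours.

    Returns (Phi, Q): the 2x2 transition matrix and process-noise covariance
    for the per-axis state (position, velocity).
    """
    e = math.exp(-beta * dt)
    phi = np.array([[1.0, (1.0 - e) / beta], [0.0, e]])
    s2 = sigma * sigma
    q_vv = s2 * (1.0 - e * e) / (2.0 * beta)
    q_xv = s2 * (1.0 - e) ** 2 / (2.0 * beta * beta)
    q_xx = (s2 / beta**2) * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e * e) / (2.0 * beta))
    q = np.array([[q_xx, q_xv], [q_xv, q_vv]])
    return phi, q


def _kalman_loglik_1d(times_h, obs, beta, sigma, tau2) -> float:
    """Scalar-arithmetic Kalman filter log-likelihood for one axis.

    ``obs`` may contain None entries (prediction-only nodes). The prior at
    the first time is position ~ N(first observation, 1e12 m^2), velocity ~
    N(0, stationary variance).
    """
    first = next(v for v in obs if v is not None)
    mx, mv = float(first), 0.0
    pxx, pxv, pvv = _INIT_POS_SD_M**2, 0.0, sigma * sigma / (2.0 * beta)
    ll = 0.0
    t_prev = times_h[0]
    for k in range(len(times_h)):
        if k > 0:
            dt = times_h[k] - t_prev
            t_prev = times_h[k]
            e = math.exp(-beta * dt)
            a = (1.0 - e) / beta
            # mean
            mx = mx + a * mv
            mv = e * mv
            # covariance: Phi P Phi' + Q
            nxx = pxx + 2.0 * a * pxv + a * a * pvv
            nxv = e * (pxv + a * pvv)
            nvv = e * e * pvv
            s2 = sigma * sigma
            nxx += (s2 / beta**2) * (dt - 2.0 * a + (1.0 - e * e) / (2.0 * beta))
            nxv += s2 * (1.0 - e) ** 2 / (2.0 * beta * beta)
            nvv += s2 * (1.0 - e * e) / (2.0 * beta)
            pxx, pxv, pvv = nxx, nxv, nvv
        y = obs[k]
        if y is None:
            continue
        s = pxx + tau2
        if s <= 0.0 or not math.isfinite(s):
            raise FloatingPointError("singular innovation covariance in Kalman filter")
        r = y - mx
        ll += -0.5 * (math.log(2.0 * math.pi * s) + r * r / s)
        g = 1.0 / s
        kx, kv = pxx * g, pxv * g
        mx += kx * r
        mv += kv * r
        pvv = pvv - kv * pxv
        pxv = pxv - kx * pxv
        pxx = pxx - kx * pxx
    return ll


def _track_xy_hours(track: RawTrack):
    x, y = project_coordinates(track.lon, track.lat)
    return x, y, np.asarray(track.hours, dtype=float)


def ctcrw_loglik(track: RawTrack, params: CtcrwParams) -> float:
    """CTCRW log-likelihood of a track (both axes, independent filters)."""
    x, y, t = _track_xy_hours(track)
    tau2 = params.obs_error_sd**2
    return _kalman_loglik_1d(t, list(x), params.reversion_rate, params.diffusion, tau2) + (
        _kalman_loglik_1d(t, list(y), params.reversion_rate, params.diffusion, tau2)
    )


def _nll_logparams(theta, t, xs, ys) -> float:
    beta, sigma, tau = (math.exp(v) for v in theta)
    tau2 = tau * tau
    try:
        ll = _kalman_loglik_1d(t, xs, beta, sigma, tau2)
        ll += _kalman_loglik_1d(t, ys, beta, sigma, tau2)
    except (FloatingPointError, OverflowError):
        return 1e12
    if not math.isfinite(ll):
        return 1e12
    return -ll


def _fd_hessian(f, x0, h=1e-4) -> np.ndarray:
    n = len(x0)
    hess = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    # guard: if diagonal came out non-positive, fall back to |f''| estimate
    for i in range(n):
        if hess[i, i] <= 0:
            xp = x0.copy(); xp[i] += h
            xm = x0.copy(); xm[i] -= h
            hess[i, i] = abs((f(xp) - 2 * f0 + f(xm)) / (h * h)) + 1e-10
    return hess


def fit_ctcrw(
    track: RawTrack,
    init: CtcrwParams | None = None,
    bounds: tuple[float, float] = (-12.0, 12.0),
    max_restarts: int = 3,
) -> CtcrwFitResult:
    """Maximum-likelihood CTCRW fit by quasi-Newton search on log parameters.

    Deterministic multi-start: on failure the initial point is perturbed by a
    fixed schedule of offsets. Standard errors on the log scale come from a
    finite-difference Hessian of the negative log-likelihood at the optimum.
    Non-convergence after all restarts is flagged (``converged=False``) and
    the best point found is still returned.
    """
    if len(track) < 4:
        raise ValueError("CTCRW fit needs at least 4 fixes")
    x, y, t = _track_xy_hours(track)
    xs, ys = list(x), list(y)

    if init is None:
        dt = np.diff(t)
        step = np.hypot(np.diff(x), np.diff(y))
        vscale = float(np.median(step / dt)) + 1e-6
        beta0 = 0.1
        sigma0 = vscale * math.sqrt(2.0 * beta0)
        tau0 = max(float(np.median(step)) * 0.1, 10.0)
        init = CtcrwParams(beta0, sigma0, tau0)
    theta0 = np.log([init.reversion_rate, init.diffusion, max(init.obs_error_sd, 1e-3)])

    fun = lambda th: _nll_logparams(th, t, xs, ys)
    offsets = [np.zeros(3), np.array([1.5, 0.0, -1.0]), np.array([-1.5, 1.0, 1.0]),
               np.array([0.0, -1.5, 2.0])]
    best = None
    n_used = 0
    for k in range(min(max_restarts + 1, len(offsets))):
        n_used = k
        res = minimize(
            fun,
            theta0 + offsets[k],
            method="L-BFGS-B",
            bounds=[bounds] * 3,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    theta = np.asarray(best.x, dtype=float)
    hess = _fd_hessian(fun, theta)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    beta, sigma, tau = np.exp(theta)
    return CtcrwFitResult(
        params=CtcrwParams(beta, sigma, tau),
        log_likelihood=-best.fun,
        log_params=theta,
        se_log_params=se,
        converged=bool(best.success),
        n_restarts=n_used,
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# Smoothing and daily interpolation
# ---------------------------------------------------------------------------


def _kalman_smooth_1d(times_h, obs, beta, sigma, tau2):
    """RTS smoother for one axis; returns smoothed means and covariances.

    Nodes with ``obs[k] is None`` are prediction-only; the smoother spreads
    information from neighbouring observations both forward and backward, so
    uncertainty grows inside gaps and shrinks near fixes.
    """
    n = len(times_h)
    first = next(v for v in obs if v is not None)
    m = np.array([float(first), 0.0])
    p = np.diag([_INIT_POS_SD_M**2, sigma * sigma / (2.0 * beta)])
    h_obs = np.array([1.0, 0.0])

    m_pred = np.empty((n, 2)); p_pred = np.empty((n, 2, 2))
    m_filt = np.empty((n, 2)); p_filt = np.empty((n, 2, 2))
    phis = np.empty((n, 2, 2))
    for k in range(n):
        if k > 0:
            phi, q = ou_transition(beta, sigma, times_h[k] - times_h[k - 1])
            m = phi @ m
            p = phi @ p @ phi.T + q
            phis[k] = phi
        m_pred[k], p_pred[k] = m, p
        if obs[k] is not None:
            s = p[0, 0] + tau2
            if s <= 0 or not np.isfinite(s):
                raise FloatingPointError("singular innovation covariance in smoother")
            gain = p @ h_obs / s
            r = obs[k] - m[0]
            m = m + gain * r
            p = p - np.outer(gain, h_obs @ p)
        m_filt[k], p_filt[k] = m, p

    ms = np.empty((n, 2)); ps = np.empty((n, 2, 2))
    ms[-1], ps[-1] = m_filt[-1], p_filt[-1]
    for k in range(n - 2, -1, -1):
        phi = phis[k + 1]
        j = p_filt[k] @ phi.T @ np.linalg.inv(p_pred[k + 1])
        ms[k] = m_filt[k] + j @ (ms[k + 1] - m_pred[k + 1])
        ps[k] = p_filt[k] + j @ (ps[k + 1] - p_pred[k + 1]) @ j.T
    return ms, ps


def smooth_track(track: RawTrack, params: CtcrwParams, at_times: np.ndarray | None = None):
    """Smoothed positions/uncertainties at the fix times plus ``at_times``.

    Returns a DataFrame (time, x, y, sd_x, sd_y, is_observation).
    """
    x, y, _ = _track_xy_hours(track)
    times = np.asarray(track.times, dtype="datetime64[ns]")
    extra = (
        np.asarray(at_times, dtype="datetime64[ns]")
        if at_times is not None
        else np.empty(0, dtype="datetime64[ns]")
    )
    all_times = np.union1d(times, extra)
    t_h = (all_times - times[0]) / np.timedelta64(1, "h")
    pos = {t: i for i, t in enumerate(times.astype("int64"))}
    obs_x: list[float | None] = [None] * len(all_times)
    obs_y: list[float | None] = [None] * len(all_times)
    is_obs = np.zeros(len(all_times), dtype=bool)
    for k, t in enumerate(all_times.astype("int64")):
        i = pos.get(t)
        if i is not None:
            obs_x[k], obs_y[k] = float(x[i]), float(y[i])
            is_obs[k] = True
    tau2 = params.obs_error_sd**2
    mx, px = _kalman_smooth_1d(list(t_h), obs_x, params.reversion_rate, params.diffusion, tau2)
    my, py = _kalman_smooth_1d(list(t_h), obs_y, params.reversion_rate, params.diffusion, tau2)
    return pd.DataFrame(
        {
            "time": all_times,
            "x": mx[:, 0],
            "y": my[:, 0],
            "sd_x": np.sqrt(np.clip(px[:, 0, 0], 0.0, None)),
            "sd_y": np.sqrt(np.clip(py[:, 0, 0], 0.0, None)),
            "is_observation": is_obs,
        }
    )


def interpolate_daily(track: RawTrack, params: CtcrwParams) -> FittedTrack:
    """Smoothed positions at daily midnights (UTC) spanning the track."""
    t0 = pd.Timestamp(track.times[0]).ceil("D")
    t1 = pd.Timestamp(track.times[-1]).floor("D")
    if t0 > t1:
        raise ValueError("track spans less than one daily midnight; cannot interpolate")
    daily = pd.date_range(t0, t1, freq="D")
    sm = smooth_track(track, params, at_times=daily.values)
    sm = sm[np.isin(sm["time"].values, daily.values)]
    out = pd.DataFrame(
        {
            "date": pd.DatetimeIndex(sm["time"]).normalize(),
            "x": sm["x"].to_numpy(),
            "y": sm["y"].to_numpy(),
            "sd_x": sm["sd_x"].to_numpy(),
            "sd_y": sm["sd_y"].to_numpy(),
        }
    ).reset_index(drop=True)
    return FittedTrack(track.animal_id, out, params, ctcrw_loglik(track, params))


# ---------------------------------------------------------------------------
# Track I/O (CSV dialect: animal_id, timestamp ISO-8601 UTC, lon, lat)
# ---------------------------------------------------------------------------


def write_tracks_csv(tracks: list[RawTrack], path) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path) -> list[RawTrack]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp")
        times = pd.DatetimeIndex(grp["timestamp"]).tz_localize(None)
        out.append(RawTrack(str(aid), times.values, grp["lon"].to_numpy(), grp["lat"].to_numpy()))
    return out
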