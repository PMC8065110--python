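"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (dense covariance
construction, brute-force subset scans, rank statistics) so they stay
independent of the filtering/optimisation code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, rankdata

import bathytherm as bt
from bathytherm.tracks import _INIT_POS_SD_M, ou_transition


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def dense_axis_loglik(t, obs, beta, sigma, tau2) -> float:
    """Joint multivariate-normal log-density of one axis's observations.

    Builds the full observation covariance by propagating the 2x2 state
    covariance through every pairwise transition — no Kalman recursion.
    """
    n = len(t)
    cov_state = [None] * n
    cov_state[0] = np.diag([_INIT_POS_SD_M**2, sigma**2 / (2.0 * beta)])
    phis = [None] * n
    for k in range(1, n):
        phi, q = ou_transition(beta, sigma, t[k] - t[k - 1])
        phis[k] = phi
        cov_state[k] = phi @ cov_state[k - 1] @ phi.T + q
    c = np.empty((n, n))
    for i in range(n):
        m = cov_state[i]
        c[i, i] = m[0, 0]
        for j in range(i + 1, n):
            m = m @ phis[j].T
            c[i, j] = c[j, i] = m[0, 0]
    c = c + tau2 * np.eye(n)
    return float(multivariate_normal.logpdf(obs, np.full(n, obs[0]), c))


def dense_track_loglik(track: bt.RawTrack, params: bt.CtcrwParams) -> float:
    x, y = bt.project_coordinates(track.lon, track.lat)
    t = np.asarray(track.hours, dtype=float)
    tau2 = params.obs_error_sd**2
    return dense_axis_loglik(t, x, params.reversion_rate, params.diffusion, tau2) + (
        dense_axis_loglik(t, y, params.reversion_rate, params.diffusion, tau2)
    )


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the tie-corrected rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    r = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    return (r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def brute_force_iu(scores, labels):
    """IU minimiser by a plain loop over candidate thresholds."""
    roc = bt.roc_curve(scores, labels)
    best = None
    for c, se, sp in zip(roc.thresholds, roc.se, roc.sp):
        iu = abs(se - roc.auc) + abs(sp - roc.auc)
        key = (round(iu, 12), round(abs(se - sp), 12), c)
        if best is None or key < best[0]:
            best = (key, c, iu, se, sp)
    return best[1], best[2]


def brute_force_speed_subsets(track: bt.RawTrack, vmax: float):
    """All maximum-size ordered subsets of fixes with no speed violation."""
    from itertools import combinations

    n = len(track)
    for size in range(n, 1, -1):
        good = []
        for keep_idx in combinations(range(n), size):
            keep = np.zeros(n, dtype=bool)
            keep[list(keep_idx)] = True
            sub = track.subset(keep)
            lon, lat = sub.lon, sub.lat
            d = bt.great_circle_distance_m(lon[:-1], lat[:-1], lon[1:], lat[1:]) / 1000.0
            dt = np.diff(sub.times) / np.timedelta64(1, "h")
            if not np.any(d / dt > vmax):
                good.append(keep_idx)
        if good:
            return size, good
    return 0, []


def hierarchy_subsets():
    """All term subsets respecting the quadratic hierarchy (9 of them)."""
    sst_levels = [(), ("sst",), ("sst", "sst2")]
    depth_levels = [(), ("depth",), ("depth", "depth2")]
    return [s + d for s in sst_levels for d in depth_levels]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def truth() -> bt.TruthSurface:
    return bt.synthetic.DEFAULT_TRUTH


@pytest.fixture(scope="session")
def glm_fixture_200(truth) -> pd.DataFrame:
    """200-row occurrence fixture drawn from the default truth surface."""
    rng = np.random.default_rng(42)
    n = 200
    sst = rng.uniform(8.0, 30.0, n)
    depth = rng.uniform(0.0, 150.0, n)
    y = rng.binomial(1, truth.probability(sst, depth))
    return pd.DataFrame({"y": y, "sst_c": sst, "depth_m": depth})


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced study system shared by the slower integration tests."""
    return bt.default_scenario(seed=5, lon_range=(-75.0, -71.0), lat_range=(35.0, 41.0),
                               horizon_years=20)


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    occ = bt.simulate_occupancy(
        small_scenario.truth, small_scenario.grid, small_scenario.climatology, seed=8
    )
    return bt.fit_logistic(occ), occ
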