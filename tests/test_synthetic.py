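"""Synthetic-data generators: grids, fields, occupancy, and tracks."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import bathytherm as bt
from bathytherm.synthetic import CoastlineSpec, make_bathymetry, make_grid
from bathytherm.tracks import CtcrwParams


class TestMakeGrid:
    def test_uniform_10km_spacing(self):
        g = make_grid((-75.5, -74.0), (34.5, 35.5), cell_size=10_000.0)
        pts = g.cells[["x_center", "y_center"]].to_numpy()
        d, _ = cKDTree(pts).query(pts, k=2)
        assert np.allclose(d[:, 1], 10_000.0)

    def test_all_ocean_when_no_coastline(self):
        g = make_grid((-75.5, -74.5), (34.5, 35.5))
        assert not g.cells["land_mask"].any()

    def test_toy_extent_cell_count(self):
        g = make_grid((-75.3, -74.72), (34.8, 35.21), cell_size=10_000.0)
        assert (g.nx, g.ny) == (5, 4)
        assert g.n_cells == 20

    @pytest.mark.parametrize("lon_range,lat_range", [((-75.0, -75.0), (34.0, 35.0)),
                                                     ((-75.0, -74.0), (35.0, 34.0))])
    def test_degenerate_extent_rejected(self, lon_range, lat_range):
        with pytest.raises(ValueError):
            make_grid(lon_range, lat_range)


class TestBathymetry:
    def test_zero_noise_equals_deterministic_ramp(self):
        g = make_grid((-75.5, -73.0), (34.0, 36.0), coastline=CoastlineSpec())
        depth = make_bathymetry(g, ramp_width=100_000.0, ramp_widening=0.39,
                                max_depth=300.0, noise_sd=0.0, seed=1)
        x = g.cells["x_center"].to_numpy()
        y = g.cells["y_center"].to_numpy()
        coast = g.coastline.coast_x(y)
        width = 100_000.0 + 0.39 * np.clip(y - y.min(), 0.0, None)
        expect = 300.0 * np.clip(np.clip(x - coast, 0, None) / width, 0.0, 1.0)
        expect[g.cells["land_mask"].to_numpy()] = 0.0
        assert np.allclose(depth, expect)

    def test_seed_reproducibility(self):
        g1 = make_grid((-75.5, -73.0), (34.0, 36.0), coastline=CoastlineSpec())
        g2 = make_grid((-75.5, -73.0), (34.0, 36.0), coastline=CoastlineSpec())
        d1 = make_bathymetry(g1, seed=7)
        d2 = make_bathymetry(g2, seed=7)
        assert np.array_equal(d1, d2)

    def test_ramp_produces_off_shelf_depths(self):
        # with a 0-300 m ramp, the deterministic field alone must put some
        # cells at or beyond the 200 m shelf break
        g = make_grid((-76.0, -69.5), (33.0, 42.2), coastline=CoastlineSpec())
        depth = make_bathymetry(g, noise_sd=0.0, seed=0)
        x = g.cells["x_center"].to_numpy()
        y = g.cells["y_center"].to_numpy()
        width = 100_000.0 + 0.39 * np.clip(y - y.min(), 0.0, None)
        expected_deep = (
            300.0 * np.clip(np.clip(x - g.coastline.coast_x(y), 0, None) / width, 0, 1) >= 200.0
        ).sum()
        assert expected_deep > 0
        assert (depth >= 200.0).sum() == expected_deep


class TestClimatology:
    def test_zero_amplitude_all_months_identical(self):
        g = make_grid((-75.5, -74.0), (34.5, 36.0))
        clim = bt.make_sst_climatology(g, seasonal_amplitude=0.0, noise_sd=0.0)
        assert np.allclose(clim.values, clim.values[0][None, :])

    def test_latitudinal_gradient(self):
        g = make_grid((-75.2, -74.8), (34.0, 40.0))
        clim = bt.make_sst_climatology(g, lat_gradient=-0.9, noise_sd=0.0)
        lat = g.cells["lat_center"].to_numpy()
        i, j = np.argmin(lat), np.argmax(lat)
        expected = -0.9 * (lat[j] - lat[i])
        assert clim.values[:, j].mean() - clim.values[:, i].mean() == pytest.approx(expected)

    def test_august_warmer_than_february_everywhere(self):
        g = make_grid((-76.0, -70.0), (33.5, 41.6))
        clim = bt.make_sst_climatology(g, noise_sd=0.0)
        assert np.all(clim.month(8) > clim.month(2))


class TestDeltas:
    def test_zero_end_warming(self):
        g = make_grid((-75.5, -74.0), (34.5, 36.0))
        d = bt.make_deltas(g, horizon_years=10, end_warming=0.0)
        assert np.all(d.values == 0.0)

    def test_final_year_spatial_mean_is_end_warming(self):
        g = make_grid((-76.0, -70.0), (33.5, 41.6))
        d = bt.make_deltas(g, horizon_years=80, end_warming=3.0, north_south_gradient=1.0)
        assert d.field(80, 6).mean() == pytest.approx(3.0)

    def test_north_warms_faster_with_gradient(self):
        g = make_grid((-75.2, -74.8), (34.0, 41.0))
        d = bt.make_deltas(g, horizon_years=80, end_warming=3.0, north_south_gradient=1.0)
        lat = g.cells["lat_center"].to_numpy()
        assert d.field(80, 1)[np.argmax(lat)] > d.field(80, 1)[np.argmin(lat)]

    def test_deltas_increase_with_year(self):
        g = make_grid((-75.2, -74.8), (34.0, 41.0))
        d = bt.make_deltas(g, horizon_years=30, end_warming=3.0)
        assert np.all(np.diff(d.values, axis=0) > 0)


class TestOccupancy:
    def test_null_truth_gives_half_presence(self, small_scenario):
        flat = bt.TruthSurface(0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.warns(UserWarning):
            occ = bt.simulate_occupancy(flat, small_scenario.grid,
                                        small_scenario.climatology, seed=3)
        n = len(occ)
        assert abs(occ["y"].mean() - 0.5) < 4.0 * np.sqrt(0.25 / n)

    def test_presence_rate_peaks_at_planted_optimum(self, small_scenario, truth):
        parts = [
            bt.simulate_occupancy(truth, small_scenario.grid, small_scenario.climatology, seed=s)
            for s in range(12)
        ]
        occ = pd.concat(parts, ignore_index=True)
        occ = occ[(occ.depth_m > 20) & (occ.depth_m < 80)]
        occ["sbin"] = (occ.sst_c // 3) * 3
        rate = occ.groupby("sbin")["y"].agg(["mean", "size"])
        rate = rate[rate["size"] >= 300]
        best = rate["mean"].idxmax()
        assert best <= 21.5 <= best + 3.0

    def test_seed_determinism(self, small_scenario, truth):
        a = bt.simulate_occupancy(truth, small_scenario.grid, small_scenario.climatology, seed=9)
        b = bt.simulate_occupancy(truth, small_scenario.grid, small_scenario.climatology, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empirical_rate_converges_to_truth_probability(self, small_scenario, truth):
        # binomial convergence of the planted Bernoulli field, pooled over
        # replicate draws of the same cell x month design
        reps = [
            bt.simulate_occupancy(truth, small_scenario.grid, small_scenario.climatology, seed=s)
            for s in range(20)
        ]
        p = truth.probability(reps[0]["sst_c"].to_numpy(), reps[0]["depth_m"].to_numpy())
        emp = np.mean([r["y"].to_numpy() for r in reps], axis=0)
        n_eff = len(reps)
        se = np.sqrt(p.mean() * (1 - p.mean()) / (len(p) * n_eff))
        assert abs(emp.mean() - p.mean()) < 5.0 * se


class TestTracks:
    def test_noiseless_tracks_equal_truth(self):
        sims = bt.simulate_tracks(n_animals=1, noise_sd=0.0, errant_rate=0.0,
                                  duration_days=10, seed=4)
        s = sims[0]
        x, y = bt.project_coordinates(s.raw.lon, s.raw.lat)
        assert np.allclose(x, s.true_x, atol=1e-6)
        assert np.allclose(y, s.true_y, atol=1e-6)

    def test_planted_errant_fixes_violate_speed_bound(self):
        sims = bt.simulate_tracks(n_animals=1, errant_rate=0.02, duration_days=90, seed=6)
        s = sims[0]
        n = len(s.raw)
        n_err = int(s.errant.sum())
        # ~2% of interior fixes, binomial 4-sigma band
        assert abs(n_err - 0.02 * (n - 2)) < 4.0 * np.sqrt(n * 0.02 * 0.98) + 1
        lon, lat = s.raw.lon, s.raw.lat
        t_h = s.raw.hours
        for i in np.flatnonzero(s.errant):
            d_prev = bt.great_circle_distance_m(lon[i - 1], lat[i - 1], lon[i], lat[i]) / 1000.0
            d_next = bt.great_circle_distance_m(lon[i], lat[i], lon[i + 1], lat[i + 1]) / 1000.0
            assert d_prev / (t_h[i] - t_h[i - 1]) > 5.0
            assert d_next / (t_h[i + 1] - t_h[i]) > 5.0

    def test_zero_diffusion_stays_at_start(self):
        params = CtcrwParams(0.3, 0.0, 0.0)
        sims = bt.simulate_tracks(n_animals=1, ctcrw_params=params, noise_sd=0.0,
                                  errant_rate=0.0, duration_days=5, seed=2)
        s = sims[0]
        assert np.allclose(s.true_x, s.true_x[0])
        assert np.allclose(s.true_y, s.true_y[0])

    def test_seed_determinism(self):
        a = bt.simulate_tracks(n_animals=2, errant_rate=0.01, duration_days=15, seed=11)
        b = bt.simulate_tracks(n_animals=2, errant_rate=0.01, duration_days=15, seed=11)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.raw.lon, s2.raw.lon)
            assert np.array_equal(s1.raw.times, s2.raw.times)

    def test_velocity_moments_match_stationary_variance(self):
        # moment check of the generative process against sigma^2 / (2 beta)
        params = CtcrwParams(0.3, 1500.0, 0.0)
        sims = bt.simulate_tracks(n_animals=6, ctcrw_params=params, noise_sd=0.0,
                                  errant_rate=0.0, duration_days=200, seed=13)
        v = np.concatenate([np.r_[s.true_vx, s.true_vy] for s in sims])
        target = params.stationary_velocity_var
        assert np.var(v) == pytest.approx(target, rel=0.1)
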