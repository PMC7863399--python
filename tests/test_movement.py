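"""Brownian bridge machinery: variance MLE, dBBMM change points,
occurrence distributions and contour masks."""

import numpy as np
import pytest

from sympatry.grids import GridGeometry
from sympatry.movement import (MotionVarianceProfile, _loo_triples,
                               _neg_log_lik, fit_dynamic_motion_variance,
                               fit_motion_variance, fit_vhf_od, od_contour,
                               occurrence_distribution)
from sympatry.tracks import GpsTrack


def brownian_track(sigma2, n, dt_min=15.0, err=5.0, seed=0, start="2014-05-05T00:00:00"):
    """Pure Brownian walk sampled at regular fixes with observation error.

    ``sigma2`` may be a scalar or a per-segment array (two-phase tracks).
    """
    rng = np.random.default_rng(seed)
    sig = np.broadcast_to(np.asarray(sigma2, dtype=float), (n - 1,))
    steps = rng.standard_normal((n - 1, 2)) * np.sqrt(sig * dt_min)[:, None]
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    obs = pos + rng.normal(0, err, (n, 2))
    ts = (np.datetime64(start, "s")
          + (np.arange(n) * dt_min * 60).astype("timedelta64[s]"))
    return GpsTrack("sim", "wolf", ts, obs[:, 0], obs[:, 1], np.full(n, float(err)))


class TestMotionVariance:
    def test_optimizer_matches_grid_search(self):
        """Bounded MLE agrees with a dense grid search on the same likelihood."""
        track = brownian_track(2.0, 200, seed=1)
        triples = _loo_triples(track.minutes(), track.x, track.y,
                               track.error_sd, None)
        grid = np.geomspace(1e-6, 1e3, 4000)
        vals = [_neg_log_lik(s, triples) for s in grid]
        s2_grid = grid[int(np.argmin(vals))]
        s2_opt = fit_motion_variance(track)
        assert abs(s2_opt - s2_grid) / s2_grid < 0.01

    def test_simulation_recovery(self):
        """sigma_m^2 = 2.0 m^2/min with 5 m error recovered within 20%."""
        track = brownian_track(2.0, 500, err=5.0, seed=2)
        s2 = fit_motion_variance(track)
        assert abs(s2 - 2.0) / 2.0 < 0.20

    def test_stationary_noiseless_track_hits_lower_bound(self):
        """A bridge that fits exactly drives sigma_m^2 to the lower bound."""
        n = 20
        ts = (np.datetime64("2014-05-05T00:00:00", "s")
              + (np.arange(n) * 900).astype("timedelta64[s]"))
        x = np.linspace(0.0, 190.0, n)      # collinear, equally spaced
        track = GpsTrack("c", "wolf", ts, x, np.zeros(n), np.zeros(n))
        assert fit_motion_variance(track) < 1e-5

    def test_affine_equivariance(self):
        """Scaling all coordinates by c scales the fitted sigma_m^2 by c^2."""
        track = brownian_track(1.5, 300, err=3.0, seed=5)
        s2 = fit_motion_variance(track)
        c = 3.0
        scaled = GpsTrack("s", "wolf", track.timestamps, c * track.x,
                          c * track.y, c * track.error_sd)
        s2_scaled = fit_motion_variance(scaled)
        assert s2_scaled == pytest.approx(c ** 2 * s2, rel=1e-2)

    def test_max_lag_exhaustion_raises(self):
        track = brownian_track(1.0, 10, dt_min=60 * 30, seed=2)  # 30 h spacing
        with pytest.raises(ValueError, match="max_lag"):
            fit_motion_variance(track, max_lag_hours=48.0)


class TestDynamicMotionVariance:
    def test_constant_track_profile_is_flat(self):
        """No systematic dynamics on a constant-sigma track: the profile's
        mean and median stay within 10% of the static estimate."""
        track = brownian_track(2.0, 500, err=5.0, seed=1)
        s2 = fit_motion_variance(track)
        prof = fit_dynamic_motion_variance(track, 23, 5)
        assert len(prof.sigma2) == track.n_fixes - 1
        assert abs(prof.sigma2.mean() - s2) / s2 < 0.10
        assert abs(np.median(prof.sigma2) - s2) / s2 < 0.10

    def test_two_phase_breakpoint_located_within_margin(self):
        """A 0.5 -> 8.0 m^2/min change at fix 300 is found within 5 fixes."""
        sig = np.where(np.arange(599) < 299, 0.5, 8.0)
        track = brownian_track(sig, 600, err=2.0, seed=7)
        prof = fit_dynamic_motion_variance(track, 23, 5)
        crossing = int(np.argmax(prof.sigma2 > (0.5 + 8.0) / 2))
        assert abs(crossing - 300) <= 5
        assert prof.sigma2[:250].mean() == pytest.approx(0.5, rel=0.3)
        assert prof.sigma2[350:].mean() == pytest.approx(8.0, rel=0.3)

    def test_short_track_falls_back_to_static(self):
        track = brownian_track(1.0, 10, seed=3)
        with pytest.warns(UserWarning, match="static"):
            prof = fit_dynamic_motion_variance(track, 23, 5)
        np.testing.assert_allclose(prof.sigma2, fit_motion_variance(track))

    def test_window_margin_relation_enforced(self):
        track = brownian_track(1.0, 50, seed=3)
        with pytest.raises(ValueError, match="margin"):
            fit_dynamic_motion_variance(track, window=11, margin=5)


class TestOccurrenceDistribution:
    def test_heights_normalize(self):
        track = brownian_track(2.0, 60, seed=4)
        od = occurrence_distribution(track, 2.0, cell=30.0)
        assert od.height.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_bridge_matches_fine_quadrature(self):
        """Stationary unit bridge: cell density equals a 1e5-step quadrature
        of the closed-form integrand to 3 significant figures."""
        geom = GridGeometry(-15.0, -15.0, 1.0, 30, 30)
        ts = np.array(["2014-05-05T00:00:00", "2014-05-05T00:01:00"],
                      dtype="datetime64[s]")
        track = GpsTrack("o", "wolf", ts, [0.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        od = occurrence_distribution(track, np.array([1.0]), geometry=geom)

        a = (np.arange(100_000) + 0.5) / 100_000
        var = a * (1 - a)  # T = 1 min, sigma2 = 1

        def oracle_density(px, py):
            return np.mean(np.exp(-0.5 * (px * px + py * py) / var)
                           / (2 * np.pi * var))

        X, Y = geom.cell_centers()
        total = sum(oracle_density(x, y) for x, y in zip(X.ravel(), Y.ravel()))
        r, c = 14, 15  # the cell whose center is (0.5, 0.5)
        expected = oracle_density(X[r, c], Y[r, c]) / total
        assert od.height[r, c] == pytest.approx(expected, rel=5e-4)

    def test_mass_concentrates_within_five_bridge_sds(self):
        track = brownian_track(2.0, 40, err=5.0, seed=6)
        od = occurrence_distribution(track, 2.0, cell=10.0)
        dt = np.diff(track.minutes())
        sd_max = np.sqrt(dt.max() * 0.25 * 2.0 + 25.0)
        X, Y = od.geometry.cell_centers()
        # distance from each cell to the nearest fix (conservative proxy
        # for distance to the path)
        d = np.full(od.geometry.shape, np.inf)
        for px, py in zip(track.x, track.y):
            d = np.minimum(d, np.hypot(X - px, Y - py))
        far = d > 5 * sd_max
        assert od.height[far].sum() < 1e-3

    def test_state_filter_drops_mixed_segments(self):
        track = brownian_track(2.0, 30, seed=8)
        track.activity = np.array(["active", "inactive"] * 15)
        with pytest.raises(ValueError, match="no usable segments"):
            # alternating states: no segment has both endpoints active
            occurrence_distribution(track, 2.0, state="active")

    def test_profile_misalignment_rejected(self):
        track = brownian_track(2.0, 30, seed=8)
        with pytest.raises(ValueError, match="aligned"):
            occurrence_distribution(track, np.ones(5))


class TestContour:
    def test_hand_computed_cumulative(self):
        heights = np.array([[0.5, 0.3], [0.15, 0.05]])
        mask = od_contour(heights, 0.9)
        assert mask.tolist() == [[True, True], [True, False]]

    def test_level_one_includes_all_positive_cells(self):
        heights = np.array([[0.6, 0.4], [0.0, 0.0]])
        assert od_contour(heights, 1.0).tolist() == [[True, True], [False, False]]

    def test_mask_total_reaches_level(self, rng):
        h = rng.random((20, 20))
        h /= h.sum()
        for level in (0.5, 0.9, 0.99):
            assert h[od_contour(h, level)].sum() >= level - 1e-12

    def test_ties_at_threshold_all_included(self):
        heights = np.array([0.4, 0.2, 0.2, 0.2]).reshape(2, 2)
        mask = od_contour(heights, 0.5)
        assert mask.sum() == 4  # the three tied 0.2 cells all enter


class TestVhfOd:
    def test_long_segment_contributes_nothing(self):
        """A >48 h segment is excluded: appending a temporally isolated fix
        leaves the OD unchanged."""
        track = brownian_track(2.0, 30, dt_min=12 * 60.0, err=20.0, seed=9)
        n = track.n_fixes
        extra_ts = track.timestamps[-1] + np.timedelta64(49 * 3600, "s")
        longer = GpsTrack("sim", "wolf",
                          np.append(track.timestamps, extra_ts),
                          np.append(track.x, track.x[-1] + 5000.0),
                          np.append(track.y, track.y[-1]),
                          np.append(track.error_sd, 20.0))
        geom = GridGeometry(min(track.x.min(), track.y.min()) - 2000, -8000,
                            30.0, 600, 600)
        od_a = fit_vhf_od(track, 48.0, geometry=geom)
        od_b = fit_vhf_od(longer, 48.0, geometry=geom)
        np.testing.assert_allclose(od_a.height, od_b.height, atol=1e-12)
        assert od_b.height.sum() == pytest.approx(1.0, abs=1e-6)

    def test_road_attracted_deer_od_concentrates_near_roads(self, scenario, landscape):
        """OD-weighted mean distance-to-road falls below the grid mean for a
        road-seeking walk."""
        from sympatry.simulate import simulate_track

        rng = np.random.default_rng(11)
        sim = simulate_track(scenario, "d1", "deer_adult", "2014-05-01T06:00:00",
                             60, rng, origin=(720.0, 720.0),
                             fix_interval_minutes=12 * 60.0, error_sd=50.0,
                             attractor=landscape.roads, attraction=0.05,
                             step_minutes=30.0)
        od = fit_vhf_od(sim.track, 48.0, geometry=landscape.geometry)
        dist = landscape["dist_road"]
        weighted = float((od.height * dist).sum())
        assert weighted < dist.mean()
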