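"""Resource utilization functions: covariate screening, coefficient
recovery, population averaging, prediction surfaces and
leave-one-individual-out cross-validation."""

import numpy as np
import pandas as pd
import pytest

from sympatry import ruf
from sympatry.grids import GridGeometry, LandscapeStack
from sympatry.movement import OccurrenceDistribution
from sympatry.simulate import make_synthetic_od


def _flat_stack(layers: dict[str, np.ndarray], n=64) -> LandscapeStack:
    geom = GridGeometry(0, 0, 30.0, 1, n)
    return LandscapeStack(geom, None,
                          {k: np.asarray(v, float).reshape(1, n)
                           for k, v in layers.items()})


def _linear_od(stack, effects, intercept=10.0, noise_sd=0.0, rng=None,
               individual="sim"):
    """OD whose (unnormalized) height is exactly intercept + sum(b z)."""
    geom = stack.geometry
    h = np.full(geom.shape, intercept)
    for name, beta in effects.items():
        v = stack[name]
        h = h + beta * (v - v.mean()) / v.std()
    if noise_sd:
        h = h + rng.normal(0, noise_sd, geom.shape)
    mask = np.ones(geom.shape, dtype=bool)
    return OccurrenceDistribution(geom, h, mask, 0.99, individual=individual,
                                  species="wolf", period="PPP", state="active")


class TestScreening:
    def test_duplicate_dropped_by_priority(self, landscape):
        st = landscape.with_layer("dist_road_copy", landscape["dist_road"])
        kept = ruf.screen_covariates(
            st, ["dist_road", "dist_road_copy", "hare_density"], 0.7,
            ("dist_road", "dist_road_copy", "hare_density"))
        assert kept == ["dist_road", "hare_density"]

    def test_exact_cutoff_keeps_both(self):
        """|r| exactly 0.7 is not a conflict (strict inequality)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        z = rng.standard_normal(64)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)          # orthogonalize
        z /= z.std()
        y = 0.7 * x + np.sqrt(1 - 0.49) * z
        stack = _flat_stack({"a": x, "b": y})
        r = np.corrcoef(x, y)[0, 1]
        assert abs(abs(r) - 0.7) < 1e-12
        kept = ruf.screen_covariates(stack, ["a", "b"], 0.7, ("a", "b"))
        assert kept == ["a", "b"]

    def test_independent_covariates_all_kept(self, landscape):
        kept = ruf.screen_covariates(
            landscape, ["dist_road", "hare_density", "grouse_density"], 0.7,
            ("dist_road", "hare_density", "grouse_density"))
        assert kept == ["dist_road", "hare_density", "grouse_density"]

    def test_conflict_outside_priority_is_config_error(self, landscape):
        st = landscape.with_layer("dist_road_copy", landscape["dist_road"])
        with pytest.raises(ValueError, match="priority"):
            ruf.screen_covariates(st, ["dist_road", "dist_road_copy"], 0.7,
                                  ("dist_road",))


class TestIndividualFit:
    def test_noiseless_exact_recovery(self, landscape):
        """Height = 0.6 z(dist_road) - 0.4 z(hare) + c recovers the
        standardized betas to 1e-6."""
        od = _linear_od(landscape, {"dist_road": 0.6, "hare_density": -0.4})
        fit = ruf.fit_individual_ruf(od, landscape, ["dist_road", "hare_density"])
        assert fit.coef_std["dist_road"] == pytest.approx(0.6, abs=1e-6)
        assert fit.coef_std["hare_density"] == pytest.approx(-0.4, abs=1e-6)

    def test_unstandardized_coefficients_predict_raw_heights(self, landscape):
        from sympatry.grids import LAND_COVER_CLASSES

        od = _linear_od(landscape, {"dist_road": 0.6})
        fit = ruf.fit_individual_ruf(od, landscape, ["dist_road"])
        pred = (fit.coef_unstd["intercept"]
                + fit.coef_unstd["dist_road"] * landscape["dist_road"])
        for name in (c for c in fit.coef_unstd.index if c.startswith("lc_")):
            code = LAND_COVER_CLASSES.index(name[3:])
            pred = pred + fit.coef_unstd[name] * (landscape.land_cover == code)
        np.testing.assert_allclose(pred, od.height, atol=1e-6)

    def test_null_covariate_rarely_significant(self, landscape):
        """A zero-effect covariate has |beta| < 2 SE in >=90% of replicates."""
        rng = np.random.default_rng(10)
        inside = 0
        n_rep = 100
        for _ in range(n_rep):
            od = _linear_od(landscape, {"dist_road": 0.5}, noise_sd=0.3, rng=rng)
            fit = ruf.fit_individual_ruf(od, landscape,
                                         ["dist_road", "hare_density"])
            if abs(fit.coef_std["hare_density"]) < 2 * fit.se_std["hare_density"]:
                inside += 1
        assert inside >= 90

    def test_single_class_landscape_has_no_dummies(self):
        geom = GridGeometry(0, 0, 30.0, 8, 8)
        rng = np.random.default_rng(1)
        stack = LandscapeStack(geom, np.zeros((8, 8), dtype=int),
                               {"dist_road": rng.random((8, 8))})
        od = _linear_od(stack, {"dist_road": 0.3})
        fit = ruf.fit_individual_ruf(od, stack, ["dist_road"])
        assert not any(c.startswith("lc_") for c in fit.covariates)

    def test_too_few_cells_rejected(self):
        geom = GridGeometry(0, 0, 30.0, 1, 3)
        rng = np.random.default_rng(2)
        stack = LandscapeStack(geom, None,
                               {"a": rng.random((1, 3)), "b": rng.random((1, 3)),
                                "c": rng.random((1, 3))})
        od = _linear_od(stack, {"a": 0.1})
        with pytest.raises(ValueError, match="fewer cells"):
            ruf.fit_individual_ruf(od, stack, ["a", "b", "c"])


def _fit(individual, betas: dict) -> ruf.RufFit:
    s = pd.Series({"intercept": 0.0, **betas})
    return ruf.RufFit(individual, "wolf", "PPP", "active",
                      coef_std=s, se_std=s * 0 + 0.1, coef_unstd=s, n_cells=100)


class TestPopulation:
    def test_symmetric_betas_average_to_zero(self):
        pop = ruf.population_ruf([_fit("a", {"x": 0.7}), _fit("b", {"x": -0.7})])
        assert pop.table.loc["x", "mean"] == 0.0

    def test_hand_mean_and_variance(self):
        pop = ruf.population_ruf([_fit("a", {"x": 1.0}), _fit("b", {"x": 2.0}),
                                  _fit("c", {"x": 3.0})])
        assert pop.table.loc["x", "mean"] == pytest.approx(2.0)
        assert pop.table.loc["x", "var"] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            betas = rng.standard_normal(n)
            pop = ruf.population_ruf([_fit(f"i{j}", {"x": b})
                                      for j, b in enumerate(betas)])
            assert pop.table.loc["x", "mean"] == pytest.approx(betas.mean())
            assert pop.table.loc["x", "var"] == pytest.approx(
                betas.var(ddof=1), rel=1e-12)

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError, match="two individuals"):
            ruf.population_ruf([_fit("a", {"x": 1.0})])

    def test_ci_contains_mean(self, rng):
        fits = [_fit(f"i{j}", {"x": b}) for j, b in enumerate(rng.standard_normal(6))]
        row = ruf.population_ruf(fits).table.loc["x"]
        assert row["ci_lo"] <= row["mean"] <= row["ci_hi"]

    def test_ci_coverage_of_true_population_mean(self, landscape):
        """Across 200 simulated populations (n = 10 individuals, true mean
        effect 0.5, between-individual SD 0.1, cell noise), the 95% CI
        covers the truth 93-97% of the time."""
        rng = np.random.default_rng(77)
        covered = 0
        n_pop, n_ind = 200, 10
        for _ in range(n_pop):
            fits = []
            for j in range(n_ind):
                beta_j = 0.5 + 0.1 * rng.standard_normal()
                od = _linear_od(landscape, {"dist_road": beta_j},
                                noise_sd=0.3, rng=rng, individual=f"i{j}")
                fits.append(ruf.fit_individual_ruf(od, landscape, ["dist_road"]))
            row = ruf.population_ruf(fits, alpha=0.05).table.loc["dist_road"]
            if row["ci_lo"] <= 0.5 <= row["ci_hi"]:
                covered += 1
        assert 0.93 * n_pop <= covered <= 0.97 * n_pop


class TestPrediction:
    def test_intercept_only_constant(self, landscape):
        pop = ruf.population_ruf([_fit("a", {}), _fit("b", {})])
        surface = ruf.predict_surface(pop, landscape)
        assert np.ptp(surface) == 0.0

    def test_spot_check_dot_product(self, landscape):
        fits = [_fit("a", {"dist_road": 0.4, "hare_density": -0.2}),
                _fit("b", {"dist_road": 0.6, "hare_density": -0.4})]
        pop = ruf.population_ruf(fits)
        surface = ruf.predict_surface(pop, landscape)
        lp = (0.5 * landscape["dist_road"] - 0.3 * landscape["hare_density"])
        expected = (lp - lp.min()) / np.ptp(lp)
        np.testing.assert_allclose(surface, expected, atol=1e-12)
        assert surface.min() >= 0.0 and surface.max() <= 1.0

    def test_missing_layer_rejected(self, landscape):
        pop = ruf.population_ruf([_fit("a", {"nope": 1.0}), _fit("b", {"nope": 2.0})])
        with pytest.raises(ValueError, match="nope"):
            ruf.predict_surface(pop, landscape)


class TestBinning:
    def test_equal_counts_with_remainder_to_last_bin(self):
        obs = np.ones(100)
        pred = np.arange(100.0)
        sum_obs, _ = ruf.bin_sums(obs, pred, bins=8)
        assert sum_obs[:-1].tolist() == [12.0] * 7
        assert sum_obs[-1] == 16.0  # 100 = 12*7 + 16

    def test_exact_division(self):
        sum_obs, _ = ruf.bin_sums(np.ones(64), np.arange(64.0), bins=8)
        assert sum_obs.tolist() == [8.0] * 8

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            ruf.bin_sums(np.ones(5), np.ones(5), bins=8)


class TestCrossValidation:
    def _self_consistent(self, landscape, n_ind=5):
        fits, ods = [], []
        for i in range(n_ind):
            od = make_synthetic_od(landscape, {"dist_road": 0.6,
                                               "hare_density": -0.4},
                                   individual=f"w{i}")
            fits.append(ruf.fit_individual_ruf(od, landscape,
                                               ["dist_road", "hare_density"]))
            ods.append(od)
        return fits, ods

    def test_noiseless_folds_fit_perfectly(self, landscape):
        fits, ods = self._self_consistent(landscape)
        cv = ruf.loio_cv(fits, ods, landscape)
        assert (cv.folds["slope"] > 0).all()
        assert (cv.folds["r2"] > 0.99).all()
        assert len(cv.folds) == len(fits)

    def test_uninformative_covariates_give_null_slope(self, landscape):
        """Permuted covariates against structureless ODs: mean slope within
        2 SE of zero over 20 seeded replicates."""
        slopes = []
        for rep in range(20):
            perm = np.random.default_rng(500 + rep)
            st = landscape
            for name in ("dist_road", "hare_density"):
                v = landscape[name].ravel().copy()
                perm.shuffle(v)
                st = st.with_layer(name, v.reshape(landscape.geometry.shape))
            rng = np.random.default_rng(900 + rep)
            fits, ods = [], []
            for i in range(5):
                od = make_synthetic_od(st, {}, individual=f"p{i}",
                                       noise_sd=0.5, rng=rng)
                fits.append(ruf.fit_individual_ruf(
                    od, st, ["dist_road", "hare_density"]))
                ods.append(od)
            slopes.append(ruf.loio_cv(fits, ods, st).mean_slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 2 * se

    def test_requires_three_individuals(self, landscape):
        fits, ods = self._self_consistent(landscape, n_ind=2)
        with pytest.raises(ValueError, match="three"):
            ruf.loio_cv(fits, ods, landscape)

    def test_r2_bounded(self, landscape):
        fits, ods = self._self_consistent(landscape)
        cv = ruf.loio_cv(fits, ods, landscape)
        assert ((cv.folds["r2"] >= 0) & (cv.folds["r2"] <= 1)).all()
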