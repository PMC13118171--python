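import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from prevmap.aggregation import (
    PopulationRaster,
    UrbanFractions,
    UrbanPartition,
    aggregate_pixel_level,
    aggregate_stratified_area,
    read_grid,
    target_population_fractions,
    urban_threshold_partition,
    write_grid,
)
from prevmap.posterior import PosteriorFit
from prevmap.survey_data import AreaHierarchy


def single_admin1_raster(values):
    values = np.asarray(values, dtype=float)
    zeros = np.zeros(values.shape, dtype=int)
    return PopulationRaster(values, zeros, zeros)


def make_fit(alpha, u, gamma=None, level="admin2", n_admin1=1, a_of=None, beta=None):
    """Minimal PosteriorFit with S draws inferred from alpha/u shapes."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    S, M = u.shape
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(S, float(alpha))
    a_of = np.zeros(M, dtype=int) if a_of is None else np.asarray(a_of)
    return PosteriorFit(
        variant="stratified_nonnested" if gamma is not None else "unstratified",
        level=level,
        areas=tuple(range(M)),
        admin1_labels=tuple(range(n_admin1)),
        a_of=a_of,
        alpha=alpha,
        u=u,
        sigma=np.full(S, 0.3),
        gamma=None if gamma is None else np.full(S, float(gamma)),
        beta=beta,
    )


class TestGridIO:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.uniform(0, 100, (4, 5))
        vals[0, 0] = np.nan
        path = str(tmp_path / "grid.asc")
        write_grid(path, vals, origin=(1.0, 2.0), step=0.5)
        back, header = read_grid(path)
        assert header["ncols"] == 5 and header["nrows"] == 4
        assert header["cellsize"] == 0.5
        assert np.isnan(back[0, 0])
        assert np.allclose(back[~np.isnan(back)], vals[~np.isnan(vals)])


class TestUrbanThreshold:
    def test_first_crossing_exact(self):
        r = single_admin1_raster([[10, 20], [30, 40]])
        part = urban_threshold_partition(r, [0.4])
        assert part.urban.sum() == 1
        assert part.urban[1, 1]  # the 40 pixel
        assert part.achieved_fraction[0] == pytest.approx(0.4)

    def test_first_crossing_overshoot(self):
        r = single_admin1_raster([[10, 20], [30, 40]])
        part = urban_threshold_partition(r, [0.5])
        assert part.urban.sum() == 2
        assert part.urban[1, 1] and part.urban[1, 0]  # 40 and 30
        assert part.achieved_fraction[0] == pytest.approx(0.7)

    def test_ties_by_pixel_index(self):
        r = single_admin1_raster([[5, 5, 5, 5]])
        part = urban_threshold_partition(r, [0.5])
        assert part.urban.ravel().tolist() == [True, True, False, False]

    def test_target_zero(self):
        r = single_admin1_raster([[10, 20]])
        part = urban_threshold_partition(r, [0.0])
        assert part.urban.sum() == 0

    def test_target_one_clamps(self):
        r = single_admin1_raster([[10, 20]])
        part = urban_threshold_partition(r, [1.0])
        assert part.urban.all()

    def test_zero_population_error(self):
        r = single_admin1_raster([[0.0, 0.0]])
        with pytest.raises(ValueError):
            urban_threshold_partition(r, [0.3])

    def test_invalid_fraction(self):
        r = single_admin1_raster([[1.0]])
        with pytest.raises(ValueError):
            urban_threshold_partition(r, [1.2])


class TestTargetFractions:
    @pytest.fixture
    def hierarchy2(self):
        return AreaHierarchy.from_table(pd.DataFrame({"admin2": [0, 1], "admin1": [0, 0]}))

    def test_all_urban(self, hierarchy2):
        pop = np.array([[5.0, 7.0], [3.0, 2.0]])
        a2 = np.array([[0, 0], [1, 1]])
        r = PopulationRaster(pop, np.zeros_like(a2), a2)
        part = UrbanPartition(np.ones((2, 2), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        fr = target_population_fractions(part, r, hierarchy2)
        assert np.allclose(fr.q, 1.0)

    def test_uniform_half_urban(self, hierarchy2):
        pop = np.ones((2, 2))
        a2 = np.array([[0, 0], [1, 1]])
        r = PopulationRaster(pop, np.zeros_like(a2), a2)
        urban = np.array([[True, False], [False, True]])
        part = UrbanPartition(urban, pd.Series(), pd.Series(), pd.Series())
        fr = target_population_fractions(part, r, hierarchy2)
        assert np.allclose(fr.q, 0.5)

    def test_qprime_sums_to_one(self, hierarchy2, rng):
        pop = rng.uniform(1, 10, (2, 2))
        a2 = np.array([[0, 0], [1, 1]])
        r = PopulationRaster(pop, np.zeros_like(a2), a2)
        part = UrbanPartition(np.zeros((2, 2), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        fr = target_population_fractions(part, r, hierarchy2)
        for i in range(2):
            assert fr.qprime[a2 == i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_20x20(self, rng):
        n1, n2 = 4, 16
        h = AreaHierarchy.from_table(
            pd.DataFrame({"admin2": range(n2), "admin1": [i % n1 for i in range(n2)]})
        )
        pop = rng.uniform(0.5, 20, (20, 20))
        a2 = rng.integers(0, n2, (20, 20))
        a1 = np.array([i % n1 for i in range(n2)])[a2]
        r = PopulationRaster(pop, a1, a2)
        urban = rng.uniform(size=(20, 20)) < 0.3
        part = UrbanPartition(urban, pd.Series(), pd.Series(), pd.Series())
        fr = target_population_fractions(part, r, h)
        for i in range(n2):
            tot = urb = 0.0
            for rr in range(20):
                for cc in range(20):
                    if a2[rr, cc] == i:
                        tot += pop[rr, cc]
                        if urban[rr, cc]:
                            urb += pop[rr, cc]
            assert fr.q[i] == pytest.approx(urb / tot, abs=1e-12)

    def test_zero_target_population_missing(self, hierarchy2):
        pop = np.array([[1.0, 1.0], [0.0, 0.0]])
        a2 = np.array([[0, 0], [1, 1]])
        r = PopulationRaster(pop, np.zeros_like(a2), a2)
        part = UrbanPartition(np.zeros((2, 2), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        fr = target_population_fractions(part, r, hierarchy2)
        assert np.isnan(fr.q[1])


class TestAggregateStratified:
    def test_q_one_urban_expression(self, rng):
        u = rng.normal(0, 0.3, (50, 3))
        fit = make_fit(0.2, u, gamma=-0.5)
        field = aggregate_stratified_area(fit, pd.Series([1.0, 1.0, 1.0]))
        assert np.allclose(field.draws, expit(0.2 + u))

    def test_gamma_zero_collapse(self, rng):
        u = rng.normal(0, 0.3, (50, 3))
        fit_g0 = make_fit(0.2, u, gamma=0.0)
        fit_unstrat = make_fit(0.2, u, gamma=None)
        q = pd.Series([0.1, 0.5, 0.9])
        f1 = aggregate_stratified_area(fit_g0, q)
        f2 = aggregate_stratified_area(fit_unstrat, q)
        assert np.allclose(f1.draws, f2.draws)

    def test_hand_computed(self):
        fit = make_fit(0.0, np.zeros((1, 1)), gamma=-0.5)
        field = aggregate_stratified_area(fit, pd.Series([0.3]))
        expected = 0.7 * expit(-0.5) + 0.3 * 0.5
        assert field.draws[0, 0] == pytest.approx(expected, abs=1e-9)
        assert field.draws[0, 0] == pytest.approx(0.41428, abs=1e-4)

    def test_missing_q_dropped(self, rng):
        u = rng.normal(0, 0.3, (10, 3))
        fit = make_fit(0.2, u, gamma=-0.5)
        field = aggregate_stratified_area(fit, pd.Series([0.3, np.nan, 0.7]))
        assert field.areas == (0, 2)
        assert field.draws.shape == (10, 2)

    def test_convexity(self, rng):
        u = rng.normal(0, 0.5, (40, 4))
        fit = make_fit(0.1, u, gamma=-0.8)
        q = pd.Series(rng.uniform(0, 1, 4))
        field = aggregate_stratified_area(fit, q)
        urbanp = expit(0.1 + u)
        ruralp = expit(0.1 - 0.8 + u)
        lo = np.minimum(urbanp, ruralp)
        hi = np.maximum(urbanp, ruralp)
        assert np.all(field.draws >= lo - 1e-12) and np.all(field.draws <= hi + 1e-12)

    def test_draw_subset_commutes(self, rng):
        u = rng.normal(0, 0.5, (40, 4))
        fit = make_fit(0.1, u, gamma=-0.8)
        q = pd.Series(rng.uniform(0, 1, 4))
        full = aggregate_stratified_area(fit, q).subset_draws(10)
        fit10 = make_fit(0.1, u[:10], gamma=-0.8)
        sub = aggregate_stratified_area(fit10, q)
        assert np.allclose(full.draws, sub.draws)


class TestAggregatePixelLevel:
    @pytest.fixture
    def setup(self, rng):
        # 2 areas in one admin1; 2x2 raster with two pixels per area
        pop = np.array([[2.0, 3.0], [5.0, 5.0]])
        a2 = np.array([[0, 0], [1, 1]])
        a1 = np.zeros((2, 2), dtype=int)
        raster = PopulationRaster(pop, a1, a2, epoch="T")
        return raster

    def test_consistency_with_stratified(self, setup, rng):
        u = rng.normal(0, 0.3, (30, 2))
        fit = make_fit(0.2, u, gamma=-0.5)
        part = UrbanPartition(np.ones((2, 2), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        f_pix = aggregate_pixel_level(fit, part, None, setup)
        f_area = aggregate_stratified_area(fit, pd.Series([1.0, 1.0]))
        assert np.allclose(f_pix.draws, f_area.draws, atol=1e-12)

    def test_single_pixel_area(self, rng):
        pop = np.array([[4.0]])
        r = PopulationRaster(pop, np.zeros((1, 1), dtype=int), np.zeros((1, 1), dtype=int))
        u = rng.normal(0, 0.3, (20, 1))
        fit = make_fit(0.2, u, gamma=-0.5)
        part = UrbanPartition(np.zeros((1, 1), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        field = aggregate_pixel_level(fit, part, None, r)
        assert np.allclose(field.draws[:, 0], expit(0.2 - 0.5 + u[:, 0]))

    def test_three_pixel_hand_oracle(self):
        pop = np.array([[2.0, 3.0, 5.0]])  # weights 0.2, 0.3, 0.5
        r = PopulationRaster(pop, np.zeros((1, 3), dtype=int), np.zeros((1, 3), dtype=int))
        urban = np.array([[True, False, True]])
        part = UrbanPartition(urban, pd.Series(), pd.Series(), pd.Series())
        fit = make_fit(0.1, np.full((1, 1), 0.05), gamma=-0.4)
        field = aggregate_pixel_level(fit, part, None, r)
        eta = 0.1 + 0.05
        expected = 0.2 * expit(eta) + 0.3 * expit(eta - 0.4) + 0.5 * expit(eta)
        assert field.draws[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_covariate_nodata_error(self, setup, rng):
        u = rng.normal(0, 0.3, (5, 2))
        fit = make_fit(0.2, u, gamma=-0.5, beta=np.full((5, 1), 0.3))
        part = UrbanPartition(np.zeros((2, 2), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        cov = np.array([[0.5, np.nan], [0.2, 0.1]])
        with pytest.raises(ValueError, match="nodata"):
            aggregate_pixel_level(fit, part, [cov], setup)

    def test_constant_predictor_returns_constant(self, setup):
        fit = make_fit(0.3, np.zeros((4, 2)), gamma=None)
        part = UrbanPartition(np.zeros((2, 2), dtype=bool), pd.Series(), pd.Series(), pd.Series())
        field = aggregate_pixel_level(fit, part, None, setup)
        assert np.allclose(field.draws, expit(0.3))
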