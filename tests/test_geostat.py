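"""Variography, kriging, and SSPE validation."""

import numpy as np
import pytest
from scipy import stats

from soilrich.geostat import (
    REFERENCE_MAP_MODEL,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    kfold_validate,
    krige_map,
    loo_validate,
    ordinary_krige,
    simulate_gaussian_field,
    sspe_reference,
)


class TestVariogramModel:
    @pytest.mark.parametrize(
        "family", ["matern", "exponential", "gaussian", "spherical"]
    )
    def test_limits_at_origin_and_infinity(self, family):
        m = VariogramModel(family, nugget=0.3, psill=1.2, range_=50.0, kappa=1.5)
        assert m.semivariance(1e-9) == pytest.approx(0.3, abs=1e-6)
        assert m.semivariance(1e6) == pytest.approx(1.5, rel=1e-6)

    def test_matern_half_equals_exponential(self):
        m = VariogramModel("matern", nugget=0.0, psill=1.0, range_=30.0, kappa=0.5)
        e = VariogramModel("exponential", nugget=0.0, psill=1.0, range_=30.0)
        h = np.linspace(0.1, 200, 50)
        np.testing.assert_allclose(m.correlation(h), e.correlation(h), rtol=1e-8)

    def test_effective_range_exponential_closed_form(self):
        # correlation 0.05 at h = -phi ln 0.05 = 2.9957 phi
        m = VariogramModel("matern", nugget=0.1, psill=1.0, range_=40.0, kappa=0.5)
        assert m.effective_range == pytest.approx(-40.0 * np.log(0.05), rel=1e-6)

    def test_reference_map_model_constants(self):
        assert REFERENCE_MAP_MODEL.effective_range == pytest.approx(111.6, rel=1e-9)
        assert REFERENCE_MAP_MODEL.nugget_ratio == pytest.approx(0.73, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("matern", nugget=-1.0, psill=1.0)
        with pytest.raises(ValueError):
            VariogramModel("banana", nugget=0.0, psill=1.0)


class TestEmpiricalVariogram:
    def test_constant_field_zero_semivariance(self, rng):
        coords = rng.uniform(0, 100, (30, 2))
        emp = empirical_variogram(coords, np.full(30, 7.0))
        assert np.nanmax(emp.gamma) == 0.0

    def test_two_point_hand_computation(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        emp = empirical_variogram(coords, np.array([0.0, 2.0]), cutoff=10.0, n_bins=1)
        assert emp.gamma[0] == pytest.approx(2.0)       # (1/2) * 2^2
        assert emp.counts[0] == 1

    def test_matches_bruteforce_pair_enumeration(self, rng):
        # oracle: unbinned double loop over all pairs
        coords = rng.uniform(0, 50, (50, 2))
        z = rng.normal(size=50)
        cutoff, n_bins = 30.0, 6
        emp = empirical_variogram(coords, z, cutoff=cutoff, n_bins=n_bins)
        edges = np.linspace(0, cutoff, n_bins + 1)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for i in range(50):
            for j in range(i + 1, 50):
                h = np.hypot(*(coords[i] - coords[j]))
                if h > cutoff:
                    continue
                b = min(np.searchsorted(edges, h, side="right") - 1, n_bins - 1)
                sums[b] += 0.5 * (z[i] - z[j]) ** 2
                counts[b] += 1
        np.testing.assert_array_equal(emp.counts, counts)
        mask = counts > 0
        np.testing.assert_allclose(emp.gamma[mask], sums[mask] / counts[mask])

    def test_all_pairs_beyond_cutoff_rejected(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        with pytest.raises(ValueError, match="cutoff"):
            empirical_variogram(coords, np.array([0.0, 1.0]), cutoff=5.0)


class TestFitVariogram:
    def test_pure_nugget_data_yields_nugget_ratio_one(self, rng):
        coords = rng.uniform(0, 500, (300, 2))
        z = rng.normal(0, 2.0, 300)
        emp = empirical_variogram(coords, z)
        model, _ = fit_variogram(emp, families=("matern",))
        assert model.nugget_ratio > 0.9

    def test_wls_recovers_simulated_model(self, rng):
        truth = VariogramModel("matern", nugget=2.0, psill=8.0, range_=25.0, kappa=0.5)
        coords = rng.uniform(0, 400, (500, 2))
        z = simulate_gaussian_field(coords, truth, rng=rng)
        emp = empirical_variogram(coords, z, cutoff=150.0, n_bins=20)
        model, _ = fit_variogram(emp, families=("matern",))
        assert model.effective_range == pytest.approx(truth.effective_range, rel=0.5)
        assert model.nugget_ratio == pytest.approx(truth.nugget_ratio, abs=0.25)

    def test_ml_and_wls_agree_on_family_ranking(self, rng):
        # gaussian-shaped truth: both fitting routes prefer gaussian over
        # the much rougher exponential on the same realization
        truth = VariogramModel("gaussian", nugget=0.5, psill=4.0, range_=60.0)
        coords = rng.uniform(0, 300, (160, 2))
        z = simulate_gaussian_field(coords, truth, rng=rng)
        emp = empirical_variogram(coords, z, cutoff=150.0, n_bins=15)
        wls_model, _ = fit_variogram(
            emp, families=("gaussian", "exponential"), method="wls"
        )
        ml_model, _ = fit_variogram(
            families=("gaussian", "exponential"), method="ml",
            coords=coords, values=z,
        )
        assert wls_model.family == ml_model.family == "gaussian"


class TestOrdinaryKriging:
    def test_exact_interpolation_at_datum_without_nugget(self):
        model = VariogramModel("exponential", nugget=0.0, psill=2.0, range_=30.0)
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        z = np.array([1.0, 3.0, -2.0])
        res = ordinary_krige(coords, z, model, coords)
        np.testing.assert_allclose(res.predictions, z, atol=1e-8)
        np.testing.assert_allclose(res.variances, 0.0, atol=1e-8)

    def test_weights_sum_to_one(self, rng):
        model = VariogramModel("matern", nugget=0.5, psill=2.0, range_=40.0)
        coords = rng.uniform(0, 100, (25, 2))
        z = rng.normal(size=25)
        targets = rng.uniform(0, 100, (10, 2))
        res = ordinary_krige(coords, z, model, targets, return_weights=True)
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-10)

    def test_two_point_system_hand_solved(self):
        # oracle: symbolic 3x3 ordinary-kriging system solved directly
        model = VariogramModel("exponential", nugget=0.4, psill=1.6, range_=20.0)
        coords = np.array([[0.0, 0.0], [30.0, 0.0]])
        z = np.array([5.0, 9.0])
        target = np.array([[10.0, 0.0]])

        c = lambda h: 1.6 * np.exp(-h / 20.0) + (0.4 if h == 0 else 0.0)
        A = np.array(
            [[c(0.0), c(30.0), 1.0], [c(30.0), c(0.0), 1.0], [1.0, 1.0, 0.0]]
        )
        b = np.array([c(10.0), c(20.0), 1.0])
        lam1, lam2, mu = np.linalg.solve(A, b)
        expected_pred = lam1 * 5.0 + lam2 * 9.0
        expected_var = c(0.0) - lam1 * c(10.0) - lam2 * c(20.0) - mu

        res = ordinary_krige(coords, z, model, target)
        assert res.predictions[0] == pytest.approx(expected_pred, abs=1e-8)
        assert res.variances[0] == pytest.approx(expected_var, abs=1e-8)

    def test_variance_grows_away_from_data(self):
        model = VariogramModel("exponential", nugget=0.1, psill=1.0, range_=20.0)
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        z = np.array([1.0, 2.0])
        transect = np.column_stack([np.linspace(5, 200, 40), np.zeros(40)])
        res = ordinary_krige(coords, z, model, transect)
        assert res.variances[-1] > res.variances[0]


class TestSSPEValidation:
    def test_reference_distribution_is_chi2_one(self):
        ref = sspe_reference()
        assert ref["mean"] == 1.0
        assert ref["median"] == pytest.approx(stats.chi2(1).median(), abs=1e-12)
        assert round(ref["median"], 3) == 0.455

    def test_loo_matches_refitted_deleted_systems(self, rng):
        # oracle: per-site ordinary kriging with the site removed
        model = VariogramModel("exponential", nugget=0.5, psill=1.5, range_=30.0)
        coords = rng.uniform(0, 150, (25, 2))
        z = simulate_gaussian_field(coords, model, rng=rng)
        summary = loo_validate(coords, z, model, n_sim=0)
        for i in range(25):
            others = np.delete(np.arange(25), i)
            res = ordinary_krige(coords[others], z[others], model, coords[i][None])
            assert summary.predictions[i] == pytest.approx(
                res.predictions[0], abs=1e-8
            )
            assert summary.variances[i] == pytest.approx(res.variances[0], abs=1e-8)

    def test_correct_model_gives_sspe_near_one(self, rng):
        model = VariogramModel("matern", nugget=1.0, psill=2.0, range_=30.0)
        coords = rng.uniform(0, 400, (200, 2))
        z = simulate_gaussian_field(coords, model, rng=rng)
        s = loo_validate(coords, z, model, n_sim=300, seed=1)
        assert s.mean_inside
        assert s.median_inside

    def test_inflated_variance_scales_sspe_down(self, rng):
        # oracle: theta scales as 1/sigma^2 — x4 variance quarters the mean
        model = VariogramModel("exponential", nugget=1.0, psill=2.0, range_=30.0)
        coords = rng.uniform(0, 300, (80, 2))
        z = simulate_gaussian_field(coords, model, rng=rng)
        base = loo_validate(coords, z, model, n_sim=0)
        inflated = VariogramModel(
            "exponential", nugget=4.0, psill=8.0, range_=30.0
        )
        infl = loo_validate(coords, z, inflated, n_sim=0)
        assert infl.mean == pytest.approx(base.mean / 4.0, rel=1e-6)

    def test_constant_field_nugget_model_zero_sspe(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10)])
        z = np.full(10, 3.0)
        model = VariogramModel("nugget", nugget=1.0, psill=0.0)
        s = loo_validate(coords, z, model, n_sim=0)
        np.testing.assert_allclose(s.predictions, 3.0, atol=1e-10)
        np.testing.assert_allclose(s.sspe, 0.0, atol=1e-16)

    def test_kfold_validation_runs(self, rng):
        model = VariogramModel("exponential", nugget=1.0, psill=2.0, range_=30.0)
        coords = rng.uniform(0, 300, (60, 2))
        z = simulate_gaussian_field(coords, model, rng=rng)
        s = kfold_validate(coords, z, model, k=10, seed=0)
        assert 0.3 < s.mean < 3.0

    def test_zero_sill_model_rejected(self, rng):
        coords = rng.uniform(0, 100, (12, 2))
        with pytest.raises(ValueError, match="sill"):
            loo_validate(
                coords, np.ones(12), VariogramModel("nugget", nugget=0.0, psill=0.0)
            )


class TestKrigeMap:
    def test_single_cell_at_datum_returns_datum(self):
        model = VariogramModel("exponential", nugget=0.0, psill=1.0, range_=20.0)
        coords = np.array([[5.0, 5.0], [50.0, 50.0]])
        z = np.array([2.0, -1.0])
        grid = krige_map(coords, z, model, bounds=(0, 10, 0, 10), cell_km=10.0)
        assert grid.predictions.shape == (1, 1)
        assert grid.predictions[0, 0] == pytest.approx(2.0, abs=1e-8)

    def test_coarse_grid_consistent_with_fine_grid(self, rng):
        model = VariogramModel("exponential", nugget=0.2, psill=1.0, range_=30.0)
        coords = rng.uniform(0, 80, (30, 2))
        z = rng.normal(size=30)
        fine = krige_map(coords, z, model, bounds=(0, 80, 0, 80), cell_km=10.0)
        coarse = krige_map(coords, z, model, bounds=(0, 80, 0, 80), cell_km=20.0)
        # shared cell centers: fine (10-km) grid covers coarse centers at odd indices
        for iy, y in enumerate(coarse.y):
            for ix, x in enumerate(coarse.x):
                jy = np.argmin(np.abs(fine.y - y))
                jx = np.argmin(np.abs(fine.x - x))
                if np.isclose(fine.y[jy], y) and np.isclose(fine.x[jx], x):
                    assert coarse.predictions[iy, ix] == pytest.approx(
                        fine.predictions[jy, jx], abs=1e-9, nan_ok=True
                    )

    def test_distant_cells_masked(self):
        model = VariogramModel("exponential", nugget=0.1, psill=1.0, range_=5.0)
        coords = np.array([[0.0, 0.0], [1.0, 1.0]])
        z = np.array([1.0, 2.0])
        grid = krige_map(
            coords, z, model, bounds=(0, 200, 0, 200), cell_km=20.0, max_dist_km=30.0
        )
        assert np.isnan(grid.predictions[-1, -1])
        assert np.isfinite(grid.predictions[0, 0])

    def test_zero_cell_grid_rejected(self):
        model = VariogramModel("exponential", nugget=0.1, psill=1.0, range_=5.0)
        with pytest.raises(ValueError, match="zero cells"):
            krige_map(
                np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([1.0, 2.0]),
                model, bounds=(0, 0.5, 0, 0.5), cell_km=10.0,
            )

    def test_ascii_grid_roundtrip(self, tmp_path, rng):
        model = VariogramModel("exponential", nugget=0.2, psill=1.0, range_=30.0)
        coords = rng.uniform(0, 60, (20, 2))
        z = rng.normal(size=20)
        grid = krige_map(coords, z, model, bounds=(0, 60, 0, 60), cell_km=15.0)
        path = tmp_path / "map.asc"
        grid.to_ascii_grid(path)
        lines = path.read_text().splitlines()
        assert lines[0].split() == ["ncols", "4"]
        assert len(lines) == 6 + 4
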