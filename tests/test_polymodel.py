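"""Collinearity filter, Kennard–Stone split, subset search, polynomial fit,
SRC sensitivity, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from soilrich.polymodel import (
    REFERENCE_RICHNESS_MODEL_TERMS,
    collinearity_filter,
    fit_polynomial,
    kennard_stone_split,
    polynomial_degree_ladder,
    predict_richness,
    random_split,
    reference_richness_model,
    search_models,
    src_sensitivity,
)
from soilrich.synthetic import (
    DEFAULT_RICHNESS_COEFFICIENTS,
    FieldParams,
    generate_survey,
    simulate_richness,
)
from soilrich.terms import parse_term


class TestCollinearityFilter:
    def test_perfect_duplicate_dropped_with_infinite_vif(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100)})
        X["b"] = X["a"]
        X["c"] = rng.normal(size=100)
        report, reduced = collinearity_filter(X)
        assert len(report.dropped) == 1
        assert report.dropped[0][0] in ("a", "b")
        assert "inf" in report.dropped[0][1] or "VIF" in report.dropped[0][1]

    def test_constructed_vif_five_dropped_at_four(self):
        # oracle: X3 = X1 + X2 + eps with Var(eps) = 0.5 gives R²3 = 0.8,
        # hence VIF3 = 1/(1-0.8) = 5 > 4
        rng = np.random.default_rng(0)
        n = 4000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        x3 = x1 + x2 + rng.normal(scale=np.sqrt(0.5), size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        report, reduced = collinearity_filter(X, vif_max=4.0)
        assert "x3" not in report.kept

    def test_independent_predictors_all_kept(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        report, reduced = collinearity_filter(X)
        assert report.kept == list("abcd")
        assert (report.vif < 1.2).all()

    def test_high_correlation_pair_resolved(self, rng):
        a = rng.normal(size=500)
        X = pd.DataFrame(
            {"a": a, "b": 0.95 * a + 0.1 * rng.normal(size=500),
             "c": rng.normal(size=500)}
        )
        report, reduced = collinearity_filter(X, r_max=0.7, vif_max=100.0)
        assert len(report.kept) == 2
        assert "c" in report.kept


class TestKennardStone:
    def test_survey_split_sizes(self):
        # 90% of 1,798 sites -> 1,618 modeling, 180 validation
        sites = generate_survey(n_sites=1798, seed=0)
        spec = kennard_stone_split(sites[["x_km", "y_km", "pH", "clay"]])
        assert len(spec.modeling) == 1618
        assert len(spec.validation) == 180
        assert len(np.intersect1d(spec.modeling, spec.validation)) == 0

    def test_two_points_half_fraction(self):
        X = pd.DataFrame({"x": [0.0, 10.0]})
        spec = kennard_stone_split(X, fraction=0.5)
        assert len(spec.modeling) == 1
        assert len(spec.validation) == 1

    def test_matches_bruteforce_maxmin_replay(self):
        # oracle: exhaustive max–min selection replay on 6 planar points
        X = pd.DataFrame(
            {"x": [0.0, 1.0, 5.0, 9.0, 10.0, 4.0],
             "y": [0.0, 8.0, 5.0, 1.0, 9.0, 2.0]}
        )
        sd = X.std(ddof=1)
        Z = ((X - X.mean()) / sd).to_numpy()
        D = np.sqrt(((Z[:, None] - Z[None]) ** 2).sum(-1))
        i, j = np.unravel_index(np.argmax(D), D.shape)
        sel = [min(i, j), max(i, j)]
        while len(sel) < 5:
            cand, best = None, -1.0
            for k in range(6):
                if k in sel:
                    continue
                d = min(D[k, s] for s in sel)
                if d > best:
                    cand, best = k, d
            sel.append(cand)
        spec = kennard_stone_split(X, fraction=5 / 6)
        assert sorted(sel) == list(spec.modeling)

    def test_modeling_set_contains_two_farthest_points(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        sd = X.std(ddof=1)
        Z = ((X - X.mean()) / sd).to_numpy()
        D = np.sqrt(((Z[:, None] - Z[None]) ** 2).sum(-1))
        i, j = np.unravel_index(np.argmax(D), D.shape)
        spec = kennard_stone_split(X, fraction=0.5)
        assert i in spec.modeling and j in spec.modeling

    def test_random_split_shape(self):
        spec = random_split(100, fraction=0.9, seed=0)
        assert len(spec.modeling) == 90
        assert spec.algorithm == "random"


class TestSearchModels:
    def test_planted_triple_recovered_by_bic(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(size=(1000, 10)), columns=[f"v{i}" for i in range(10)]
            )
            y = (
                X["v0"] - 0.8 * X["v3"] + 0.6 * X["v7"]
            ).to_numpy() + rng.normal(size=1000)
            _, best = search_models(X, y)
            hits += set(best["bic"]) == {"v0", "v3", "v7"}
        assert hits / n_seeds >= 0.9

    def test_noise_column_monotonicity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=200)
        X["noise"] = rng.normal(size=200)
        table, _ = search_models(X, y)
        best_r2_by_size = table[table.criterion == "r2adj"].set_index("size")["r2"]
        assert (np.diff(best_r2_by_size.to_numpy()) > -1e-12).all()

    def test_membership_matrix_columns_present(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        table, _ = search_models(X, y)
        assert {"in:a", "in:b", "in:c"} <= set(table.columns)


class TestFitPolynomial:
    def test_noiseless_degree4_recovery(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"pH": rng.uniform(4, 9, 200)})
        coefs = {"1": 100.0, "pH": -3.0, "pH^2": 2.0, "pH^3": -0.5, "pH^4": 0.05}
        y = sum(
            c * df["pH"] ** (0 if t == "1" else parse_term(t)[0][1])
            for t, c in coefs.items()
        ).to_numpy()
        m = fit_polynomial(df, y, ["pH", "pH^2", "pH^3", "pH^4"])
        assert m.r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            m.coefficients, [100.0, -3.0, 2.0, -0.5, 0.05], rtol=1e-6
        )

    def test_ph_ladder_r2_nondecreasing(self, small_survey):
        sites, _ = small_survey
        ladder = polynomial_degree_ladder(sites, sites["richness"].to_numpy())
        assert list(ladder["degree"]) == [1, 2, 3, 4, 5]
        assert (np.diff(ladder["r2"].to_numpy()) > -1e-12).all()

    def test_bic_matches_closed_form_recomputation(self, small_survey):
        # oracle: recompute the stored convention from RSS, n, k
        sites, _ = small_survey
        y = sites["richness"].to_numpy()
        m = fit_polynomial(sites, y, ["pH", "pH^2"])
        M = m.design(sites)
        resid = y - M @ m.coefficients
        rss = float(resid @ resid)
        n, k = len(y), M.shape[1] + 1
        assert m.bic == pytest.approx(n * np.log(rss / n) + k * np.log(n), rel=1e-12)

    def test_aliased_terms_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = 2.0 * df["a"]
        y = df["a"].to_numpy() + rng.normal(size=50)
        m = fit_polynomial(df, y, ["a", "b"])
        assert m.dropped_terms == ["b"]

    def test_degree_cap_enforced(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30)})
        with pytest.raises(ValueError, match="degree"):
            fit_polynomial(df, rng.normal(size=30), ["a^6"])

    def test_diagnostics_calibrated_under_gaussian_truth(self):
        # Shapiro–Wilk and Breusch–Pagan p-values ~ U(0,1) when the model is
        # correctly specified, Gaussian and homoskedastic
        from scipy import stats

        sw, bp = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.uniform(-2, 2, 80)})
            y = 1.0 + 0.5 * df["x"].to_numpy() + rng.normal(size=80)
            m = fit_polynomial(df, y, ["x"])
            sw.append(m.shapiro_p)
            bp.append(m.breusch_pagan_p)
        assert stats.kstest(sw, "uniform").pvalue > 0.01
        assert stats.kstest(bp, "uniform").pvalue > 0.01

    def test_reference_form_coefficient_recovery(self):
        # surveys generated from known coefficients + white noise: fitting
        # the generating functional form recovers every coefficient within
        # 3 SE in >= 95% of seeds
        from soilrich.geostat import VariogramModel

        n_seeds, ok = 50, 0
        terms = list(REFERENCE_RICHNESS_MODEL_TERMS[1:])
        noise_only = FieldParams(
            model=VariogramModel("nugget", nugget=0.0, psill=0.0),
            noise_sd=102.0, seed=0,
        )
        for seed in range(n_seeds):
            sites = generate_survey(n_sites=600, seed=100 + seed)
            fp = FieldParams(model=noise_only.model, noise_sd=102.0,
                             seed=100 + seed)
            truth = simulate_richness(sites, field=fp)
            m = fit_polynomial(sites, truth.richness, terms)
            true = {
                parse_term(t): c for t, c in DEFAULT_RICHNESS_COEFFICIENTS.items()
            }
            good = all(
                abs(c - true[parse_term(t)]) <= 3 * se
                for t, c, se in zip(m.terms, m.coefficients, m.std_errors)
            )
            ok += good
        assert ok / n_seeds >= 0.95


class TestSRC:
    def test_standardized_data_src_equals_beta(self, rng):
        n = 400
        df = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        df = (df - df.mean()) / df.std(ddof=1)
        y = 0.6 * df["x"].to_numpy() - 0.3 * df["z"].to_numpy() + rng.normal(
            scale=0.69, size=n
        )
        y = (y - y.mean()) / y.std(ddof=1)
        m = fit_polynomial(df, y, ["x", "z"])
        src = m.src.set_index("term")["src"]
        coef = {t: c for t, c in zip(m.terms, m.coefficients)}
        assert src["x"] == pytest.approx(coef["x"], rel=1e-9)
        assert src["z"] == pytest.approx(coef["z"], rel=1e-9)

    def test_orthogonal_predictors_src_squares_sum_to_r2(self):
        # oracle: variance decomposition identity for orthogonal designs
        rng = np.random.default_rng(4)
        n = 5000
        # QR against a leading constant column: the remaining columns are
        # exactly centered and mutually orthogonal
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        )
        X = pd.DataFrame(q[:, 1:] * np.sqrt(n), columns=list("abc"))
        y = (
            0.5 * X["a"] - 0.4 * X["b"] + 0.2 * X["c"]
        ).to_numpy() + rng.normal(size=n)
        m = fit_polynomial(X, y, ["a", "b", "c"])
        src2 = (m.src["src"] ** 2).sum()
        assert src2 == pytest.approx(m.r2, abs=1e-8)

    def test_scale_invariance(self, rng):
        n = 300
        df = pd.DataFrame({"x": rng.normal(size=n)})
        y = 2.0 * df["x"].to_numpy() + rng.normal(size=n)
        m1 = fit_polynomial(df, y, ["x"])
        df2 = pd.DataFrame({"x": 2.0 * df["x"]})
        m2 = fit_polynomial(df2, y, ["x"])
        assert m2.coefficients[1] == pytest.approx(m1.coefficients[1] / 2, rel=1e-9)
        assert m2.src["src"].iloc[0] == pytest.approx(
            m1.src["src"].iloc[0], rel=1e-9
        )

    def test_sorted_by_absolute_src(self, small_survey):
        sites, _ = small_survey
        m = fit_polynomial(
            sites, sites["richness"].to_numpy(),
            list(REFERENCE_RICHNESS_MODEL_TERMS[1:]),
        )
        table = src_sensitivity(m, sites)
        vals = table["src"].abs().to_numpy()
        assert (np.diff(vals) <= 1e-12).all()


class TestPredict:
    def test_zero_covariates_give_intercept(self):
        model = reference_richness_model()
        df = pd.DataFrame(
            {"pH": [0.0], "clay": [0.0], "CN_ratio": [0.0], "x_km": [0.0]}
        )
        pred, flags = predict_richness(model, df)
        assert pred[0] == pytest.approx(model.coefficients[0])
        assert flags[0]  # origin is far outside the national envelope

    def test_reference_form_term_set(self):
        model = reference_richness_model()
        got = {parse_term(t) for t in model.terms}
        expected = {
            parse_term(t)
            for t in (
                "1", "pH^4", "clay^2", "clay^2*CN_ratio", "clay^3*CN_ratio",
                "CN_ratio^2*x_km",
            )
        }
        assert got == expected
        assert model.provisional

    def test_refit_on_synthetic_truth_approaches_noise_floor(self):
        # RMSE of the refitted generator model tends to the white-noise sd
        # as n grows (field excluded: it is spatial signal, not model error)
        sites = generate_survey(n_sites=1500, seed=42)
        null_field = FieldParams(
            model=FieldParams().model.__class__(
                "nugget", nugget=0.0, psill=0.0
            ),
            noise_sd=80.0,
            seed=42,
        )
        truth = simulate_richness(sites, field=null_field)
        m = fit_polynomial(
            sites, truth.richness, list(REFERENCE_RICHNESS_MODEL_TERMS[1:])
        )
        pred = m.predict(sites)
        rmse = np.sqrt(np.mean((pred - truth.richness) ** 2))
        assert rmse == pytest.approx(80.0, rel=0.1)
        rmse_vs_det = np.sqrt(np.mean((pred - truth.deterministic) ** 2))
        assert rmse_vs_det < 20.0

    def test_out_of_envelope_flagging(self, small_survey):
        sites, _ = small_survey
        m = fit_polynomial(
            sites, sites["richness"].to_numpy(),
            list(REFERENCE_RICHNESS_MODEL_TERMS[1:]),
        )
        inside = sites.iloc[:5]
        pred, flags = m.predict(inside, with_flags=True)
        assert not flags.any()
        outside = inside.copy()
        outside.loc[:, "pH"] = 12.0
        _, flags2 = m.predict(outside, with_flags=True)
        assert flags2.all()

    def test_missing_covariate_raises(self):
        model = reference_richness_model()
        with pytest.raises(KeyError):
            model.predict(pd.DataFrame({"pH": [7.0]}))
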