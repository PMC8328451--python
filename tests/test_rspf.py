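import numpy as np
import pandas as pd
import pytest

from snowsel.grid import Grid
from snowsel.rspf import (
    build_design,
    fit_rspf,
    hosmer_lemeshow,
    parse_terms,
    rank_models,
    snap_position,
    standardize,
    vif,
)


def cloglog_p(eta):
    return 1.0 - np.exp(-np.exp(eta))


def simulate_design(n, beta0, beta1, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.uniform(size=n) < cloglog_p(beta0 + beta1 * x)
    return pd.DataFrame({"used": y.astype(float), "SNOW": x})


class TestSnapPosition:
    def depth_grid(self, vals, cell=1.0):
        vals = np.asarray(vals, dtype=float)
        return Grid(vals, origin_x=0.0, origin_y=vals.shape[0] * cell, cell=cell)

    def test_zero_buffer_returns_containing_cell(self):
        g = self.depth_grid(np.arange(9).reshape(3, 3))
        assert snap_position(1.5, 1.5, g, buffer=0.0) == (1, 1)

    def test_unique_minimum_in_buffer_wins(self):
        vals = np.full((3, 3), 50.0)
        vals[0, 2] = 1.0  # NE corner
        g = self.depth_grid(vals)
        assert snap_position(1.5, 1.5, g, buffer=5.0) == (0, 2)

    def test_tie_broken_by_distance_to_fix(self):
        vals = np.full((3, 3), 50.0)
        vals[1, 0] = 1.0
        vals[1, 2] = 1.0
        g = self.depth_grid(vals)
        # fix slightly west of center: the western minimum is nearer
        assert snap_position(1.3, 1.5, g, buffer=5.0) == (1, 0)

    def test_negative_buffer_rejected(self):
        g = self.depth_grid(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            snap_position(0.5, 0.5, g, buffer=-1.0)

    def test_snapping_lowers_depth_on_average(self, bundle):
        rng = np.random.default_rng(2)
        xs = rng.uniform(10, 290, size=200)
        ys = rng.uniform(10, 290, size=200)
        raw = bundle.snow_depth.sample(xs, ys)
        snapped = np.array(
            [
                bundle.snow_depth.values[snap_position(x, y, bundle.snow_depth, 5.0)]
                for x, y in zip(xs, ys)
            ]
        )
        assert snapped.mean() < raw.mean()
        assert np.all(snapped <= raw + 1e-12)


class TestStandardize:
    def test_basic_columns(self):
        df = pd.DataFrame({"used": [0, 1, 0], "SNOW": [1.0, 2.0, 3.0]})
        out, means, sds = standardize(df)
        assert list(out["SNOW"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert means["SNOW"] == 2.0 and sds["SNOW"] == 1.0  # sample sd, n-1

    def test_idempotent_on_standardized_column(self):
        z = pd.DataFrame({"used": [0, 1, 0, 1], "SNOW": [-1.0, 1.0, -1.0, 1.0]})
        z["SNOW"] = (z["SNOW"] - z["SNOW"].mean()) / z["SNOW"].std(ddof=1)
        out, _, _ = standardize(z)
        assert np.allclose(out["SNOW"], z["SNOW"], atol=1e-12)

    def test_roundtrip_via_returned_moments(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"used": rng.integers(0, 2, 50), "SNOW": rng.normal(5, 3, 50)})
        out, means, sds = standardize(df)
        back = out["SNOW"] * sds["SNOW"] + means["SNOW"]
        assert np.allclose(back, df["SNOW"], atol=1e-12)

    def test_constant_column_error_names_column(self):
        df = pd.DataFrame({"used": [0, 1], "LICHEN": [5.0, 5.0]})
        with pytest.raises(ValueError, match="LICHEN"):
            standardize(df)


class TestFitRSPF:
    def test_cloglog_response_closed_form(self):
        assert cloglog_p(0.0) == pytest.approx(0.63212, abs=1e-5)

    def test_intercept_only_matches_binomial_closed_form(self):
        df = simulate_design(2000, -1.0, 0.0, seed=1)
        df["ONES"] = np.linspace(-1, 1, len(df))  # unused spare column
        fit = fit_rspf(df, [])
        phat = df["used"].mean()
        n1 = df["used"].sum()
        n = len(df)
        ll = n1 * np.log(phat) + (n - n1) * np.log(1 - phat)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6)
        fitted_p = cloglog_p(fit.coefficients["(Intercept)"])
        assert fitted_p == pytest.approx(phat, abs=1e-8)

    def test_parameter_recovery_within_3se(self):
        df = simulate_design(5000, -1.0, 0.7, seed=42)
        fit = fit_rspf(df, ["SNOW"])
        est, se = fit.coefficients["SNOW"], fit.std_errors["SNOW"]
        assert abs(est - 0.7) < 3 * se

    def test_aic_identity(self):
        df = simulate_design(1000, -0.5, 0.5, seed=3)
        fit = fit_rspf(df, ["SNOW"])
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        df = simulate_design(200, -0.5, 0.5, seed=4)
        df["SNOW2"] = df["SNOW"] * 2.0
        with pytest.raises(ValueError, match="rank"):
            fit_rspf(df, ["SNOW", "SNOW2"])

    def test_single_class_rejected(self):
        df = pd.DataFrame({"used": np.ones(50), "SNOW": np.arange(50.0)})
        with pytest.raises(ValueError):
            fit_rspf(df, ["SNOW"])

    def test_interaction_term_built_as_product(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "used": rng.integers(0, 2, 500).astype(float),
                "SNOW": rng.normal(size=500),
                "LICHEN": rng.normal(size=500),
            }
        )
        fit = fit_rspf(df, parse_terms("SNOW + LICHEN + SNOW:LICHEN"))
        assert "SNOW:LICHEN" in fit.coefficients


class TestRankModels:
    def test_single_model_delta_zero(self):
        df = rank_models([("m1", 100.0)])
        assert df["delta_aic"].iloc[0] == 0.0

    def test_printed_aic_table_deltas(self):
        # AICs of the full model and the internally consistent reduced models
        aics = [("full", 72103.0), ("-SNOW", 72249.2), ("-DIST", 72420.6),
                ("-DEM", 72464.5), ("-XCOORD", 73274.1)]
        df = rank_models(aics)
        assert list(df["delta_aic"].round(1)) == [0.0, 146.2, 317.6, 361.5, 1171.1]

    def test_order_invariance(self):
        aics = [("a", 105.0), ("b", 100.0), ("c", 102.5)]
        d1 = rank_models(aics)
        d2 = rank_models(aics[::-1])
        assert list(d1["model"]) == list(d2["model"]) == ["b", "c", "a"]

    def test_within_two_units_flagged(self):
        df = rank_models([("a", 100.0), ("b", 101.9), ("c", 102.1)])
        assert list(df["within_2_aic"]) == [True, True, False]


class TestHosmerLemeshow:
    def test_ten_groups_gives_df_8(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.05, 0.95, size=2000)
        y = (rng.uniform(size=2000) < p).astype(float)
        x2, dof, pval = hosmer_lemeshow(p, y, groups=10)
        assert dof == 8
        assert x2 >= 0 and 0 <= pval <= 1

    def test_calibrated_fitted_model_statistic_near_df(self):
        # HL on the fitted probabilities of a correctly specified model:
        # the df = groups - 2 correction presumes estimated parameters
        stats = []
        for rep in range(20):
            rng = np.random.default_rng([7, rep])
            x = rng.standard_normal(1500)
            p = 1.0 - np.exp(-np.exp(-1.0 + 0.8 * x))
            y = (rng.uniform(size=1500) < p).astype(float)
            fit = fit_rspf(pd.DataFrame({"used": y, "SNOW": x}), ["SNOW"])
            x2, dof, _ = hosmer_lemeshow(fit.fitted, y, groups=10)
            assert dof == 8
            stats.append(x2)
        assert abs(np.mean(stats) - 8.0) < 2.5

    def test_identical_fitted_probabilities_rejected(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            hosmer_lemeshow(np.full(100, 0.3), np.zeros(100))


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        n = 400
        rng = np.random.default_rng(8)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # zero correlation after centering
        df = pd.DataFrame({"A": a, "B": b})
        v = vif(df, ["A", "B"])
        assert v["A"] == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_column_infinite(self):
        df = pd.DataFrame({"A": np.arange(10.0), "B": np.arange(10.0) * 2})
        v = vif(df, ["A", "B"])
        assert np.isinf(v["A"]) and np.isinf(v["B"])

    def test_known_correlation_closed_form(self):
        # two standardized columns with exact correlation 0.6: VIF = 1/(1-0.36)
        n = 500
        rng = np.random.default_rng(9)
        a = rng.standard_normal(n)
        e = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        e -= a * (a @ e) / (a @ a)
        e = (e - e.mean()) / e.std()
        b = 0.6 * a + np.sqrt(1 - 0.36) * e
        v = vif(pd.DataFrame({"A": a, "B": b}), ["A", "B"])
        assert v["A"] == pytest.approx(1.5625, abs=1e-6)

    def test_fewer_than_two_terms_rejected(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"A": np.arange(5.0)}), ["A"])


def test_build_design_from_bundle_layers(bundle, small_cfg):
    from snowsel.patches import distance_to_snowfree

    dist = distance_to_snowfree(bundle.snow_free_fine, min_patch_area=1800.0)
    layers = {
        "SNOW": bundle.snow_depth,
        "DIST": dist,
        "DEM": bundle.dem,
        "TPI": bundle.tpi,
        "LICHEN": bundle.lichen,
    }
    used_xy = np.concatenate([np.column_stack([t.x, t.y]) for t in bundle.tracks])
    design = build_design(used_xy, layers, n_available=2000, seed=1)
    assert set(design.columns) >= {"used", "SNOW", "DIST", "DEM", "DEM2", "TPI",
                                   "LICHEN", "XCOORD"}
    assert design["used"].sum() == len(used_xy)
    assert (design["DEM2"] == design["DEM"] ** 2).all()
    assert not design.isna().any().any()
    # used cells should be shallower than availability on average (preference)
    assert design.loc[design.used == 1, "SNOW"].mean() < design.loc[
        design.used == 0, "SNOW"
    ].mean()
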