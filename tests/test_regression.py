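"""Hedonic regressions, published presets, null crossings and optima."""

import numpy as np
import pandas as pd
import pytest

import odorhedonics as oh
from odorhedonics.errors import CollinearityError, UndeterminedFeatureError
from odorhedonics.presets import PRESETS
from odorhedonics.regression import NAT_FITTED_MAX


def features_table(rows):
    """rows: list of dicts with n_at and indicator values."""
    base = {"i_ox": 0, "i_sul": 0, "i_acid": 0, "i_amine": 0}
    return pd.DataFrame(
        [{**base, **r} for r in rows],
        index=[f"m{i}" for i in range(len(rows))],
    )


def random_features(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "n_at": rng.integers(2, 23, n),
            "i_ox": rng.integers(0, 2, n),
            "i_sul": rng.integers(0, 2, n),
            "i_acid": rng.integers(0, 2, n),
            "i_amine": rng.integers(0, 2, n),
        },
        index=[f"m{i}" for i in range(n)],
    )


def scan_roots(coeffs, fixed, lo=1e-9, hi=100.0, n=2_000_001):
    """Numeric root-scan oracle: sign changes of the prediction on a dense
    N_at grid, refined by bisection."""
    from odorhedonics.regression import _polynomial_in_nat

    c0, c1, c2 = _polynomial_in_nat(coeffs, fixed)

    def f(x):
        return c0 + c1 * x + c2 * x * x

    grid = np.linspace(lo, hi, n)
    vals = f(grid)
    roots = []
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    for i in idx:
        a, b = grid[i], grid[i + 1]
        for _ in range(100):
            mid = 0.5 * (a + b)
            if f(a) * f(mid) <= 0:
                b = mid
            else:
                a = mid
        roots.append(0.5 * (a + b))
    return roots


class TestPresets:
    def test_registry_immutable(self):
        with pytest.raises(TypeError):
            PRESETS["eq7"].coefficients["n_at"] = 0.0
        with pytest.raises(TypeError):
            PRESETS["eq13"] = None

    def test_eq10_carries_advisory(self):
        assert "not recommended" in PRESETS["eq10"].advisory

    @pytest.mark.parametrize(
        "preset,feat,expected",
        [
            ("eq7", {"n_at": 10, "i_ox": 1}, -2.56 + 2.30 + 1.26),
            ("eq9", {"n_at": 4, "i_ox": 1, "i_acid": 1}, -2.62 + 0.92 + 1.58 - 2.58),
            ("eq12", {"n_at": 0}, -1.85),
        ],
    )
    def test_predict_arithmetic(self, preset, feat, expected):
        f = features_table([feat])
        out = oh.predict(preset, f)
        assert out["hedonic_score"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_eq8_round_trips_to_eq9_via_ranking_conversion(self):
        """The preference-scale equation converted through the ranking
        calibration reproduces the hedonic-scale equation closely."""
        f = random_features(50, seed=0)
        pr = oh.PRESETS["eq8"].predict(f)
        h_via = 7.11 - 0.091 * pr
        h_direct = oh.PRESETS["eq9"].predict(f)
        assert np.corrcoef(h_via, h_direct)[0, 1] > 0.99
        assert np.abs(h_via - h_direct).max() < 0.7

    @pytest.mark.parametrize("preset", ["eq7", "eq9", "eq10"])
    def test_affine_presets_strictly_increasing_in_nat(self, preset):
        f = features_table([{"n_at": n, "i_ox": 1} for n in range(1, 41)])
        p = oh.predict(preset, f)["hedonic_score"].to_numpy()
        assert (np.diff(p) > 0).all()

    @pytest.mark.parametrize("preset", ["eq11", "eq12"])
    def test_quadratic_presets_rise_then_fall(self, preset):
        f = features_table([{"n_at": n, "i_ox": 1} for n in range(1, 41)])
        p = oh.predict(preset, f)["hedonic_score"].to_numpy()
        vertex = oh.optimum_nat(preset).n_at
        d = np.diff(p)
        n_grid = np.arange(1, 40)
        assert (d[n_grid < np.floor(vertex)] > 0).all()
        assert (d[n_grid > np.ceil(vertex)] < 0).all()

    @pytest.mark.parametrize("preset", ["eq7", "eq9", "eq10", "eq11", "eq12"])
    def test_group_monotonicity(self, preset):
        """Sulfur or acid never increases, oxygen never decreases, the
        predicted pleasantness."""
        terms = set(PRESETS[preset].terms)
        for n_at in (4, 10, 20):
            base = features_table([{"n_at": n_at}])
            p0 = oh.predict(preset, base)["hedonic_score"].iloc[0]
            p_ox = oh.predict(preset, features_table([{"n_at": n_at, "i_ox": 1}]))[
                "hedonic_score"
            ].iloc[0]
            assert p_ox >= p0
            if "i_sul" in terms:
                p_s = oh.predict(preset, features_table([{"n_at": n_at, "i_sul": 1}]))[
                    "hedonic_score"
                ].iloc[0]
                assert p_s <= p0
            if "i_acid" in terms:
                p_a = oh.predict(
                    preset, features_table([{"n_at": n_at, "i_ox": 1, "i_acid": 1}])
                )["hedonic_score"].iloc[0]
                assert p_a <= p_ox


class TestFit:
    def test_noiseless_recovery_of_eq7(self):
        f = random_features(60, seed=1)
        y = PRESETS["eq7"].predict(f)
        res = oh.fit_hedonic_model(f, y, list(PRESETS["eq7"].terms))
        for t, c in PRESETS["eq7"].coefficients.items():
            assert res.params[t] == pytest.approx(c, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(12)
        f = random_features(200, seed=12)
        y = PRESETS["eq7"].predict(f) + rng.normal(0, 0.8, 200)
        res = oh.fit_hedonic_model(f, y, list(PRESETS["eq7"].terms))
        for t, c in PRESETS["eq7"].coefficients.items():
            assert abs(res.params[t] - c) < 3 * res.bse[t]

    def test_duplicate_columns_collinear(self):
        f = random_features(30, seed=2)
        f["i_acid"] = f["i_ox"]
        with pytest.raises(CollinearityError):
            oh.fit_hedonic_model(f, f["n_at"].astype(float), ["const", "i_ox", "i_acid"])

    def test_undetermined_indicator_rejected(self):
        f = random_features(30, seed=3).astype(float)
        f.loc["m5", "i_acid"] = np.nan
        with pytest.raises(UndeterminedFeatureError, match="m5"):
            oh.fit_hedonic_model(f, f["n_at"], ["const", "n_at", "i_acid"])

    def test_influence_report_and_refit(self):
        rng = np.random.default_rng(13)
        f = random_features(80, seed=13)
        y = PRESETS["eq7"].predict(f) + rng.normal(0, 0.3, 80)
        res = oh.fit_hedonic_model(f, y, ["const", "n_at", "i_ox"])
        # refit with no flagged points is a no-op
        if not res.influential["influential"].any():
            assert res.refit_without_influential() is res
        # an extreme outlier in n_at must be flagged and excludable
        f2 = pd.concat([f, features_table([{"n_at": 200, "i_ox": 1}]).set_index(
            pd.Index(["big"]))])
        y2 = pd.concat([pd.Series(y, index=f.index), pd.Series([5.0], index=["big"])])
        res2 = oh.fit_hedonic_model(f2, y2, ["const", "n_at", "i_ox"])
        assert res2.influential.loc["big", "influential"]
        res3 = res2.refit_without_influential()
        assert res3.nobs < res2.nobs

    def test_normality_diagnostic_reported(self):
        rng = np.random.default_rng(14)
        f = random_features(150, seed=14)
        y = PRESETS["eq7"].predict(f) + rng.normal(0, 0.5, 150)
        res = oh.fit_hedonic_model(f, y, list(PRESETS["eq7"].terms))
        assert 0 <= res.residual_normality["pvalue"] <= 1
        assert "residual normality" in res.summary()


class TestNullCrossing:
    @pytest.mark.parametrize(
        "preset,printed",
        [("eq7", 5.7), ("eq9", 4.5), ("eq11", 7.5), ("eq12", 5.9)],
    )
    def test_crossings_near_printed_values(self, preset, printed):
        res = oh.null_crossing(preset, {"i_ox": 1})
        assert res.threshold == pytest.approx(printed, abs=0.15)

    @pytest.mark.parametrize("preset", ["eq7", "eq8", "eq9", "eq10", "eq11", "eq12"])
    @pytest.mark.parametrize(
        "fixed",
        [{"i_ox": 1}, {"i_ox": 0}, {"i_ox": 1, "i_sul": 1}, {"i_ox": 1, "i_acid": 1}],
    )
    def test_closed_form_agrees_with_scan_oracle(self, preset, fixed):
        res = oh.null_crossing(preset, fixed)
        oracle = scan_roots(dict(PRESETS[preset].coefficients), fixed)
        assert len(res.roots) == len(oracle)
        for a, b in zip(res.roots, oracle):
            assert a == pytest.approx(b, abs=1e-6)

    def test_larger_eq11_root_flagged_extrapolation(self):
        res = oh.null_crossing("eq11", {"i_ox": 1})
        assert len(res.roots) == 2
        assert res.roots[1] == pytest.approx(29.66, abs=0.05)
        assert res.roots[1] in res.extrapolated
        assert res.roots[1] > NAT_FITTED_MAX

    def test_zero_nat_coefficient_means_no_crossing(self):
        class Flat:
            params = pd.Series({"const": 1.0, "i_ox": 0.5})

        res = oh.null_crossing(Flat(), {"i_ox": 1})
        assert not res.has_crossing and res.kind == "none"


class TestOptimum:
    def test_eq12_vertex_about_fourteen(self):
        opt = oh.optimum_nat("eq12", {"i_ox": 1})
        assert opt.kind == "maximum"
        assert opt.n_at == pytest.approx((0.35 + 0.041) / (2 * 0.014), abs=1e-12)
        assert round(opt.n_at) == 14

    def test_eq11_vertex_about_nineteen(self):
        opt = oh.optimum_nat("eq11", {"i_ox": 1})
        assert opt.n_at == pytest.approx((0.33 + 0.057) / (2 * 0.0104), abs=1e-12)
        assert round(opt.n_at) == 19

    def test_linear_model_is_monotone(self):
        assert oh.optimum_nat("eq7").kind == "monotone"

    def test_positive_quadratic_unbounded(self):
        class Convex:
            params = pd.Series({"const": 0.0, "n_at": -1.0, "n_at2": 0.1})

        assert oh.optimum_nat(Convex()).kind == "unbounded"


class TestClassifyAndCompare:
    def test_fraction_and_strict_zero_rule(self):
        out = oh.classify_pleasant(pd.Series([1.0, -0.5, 0.2]))
        assert out.attrs["fraction_pleasant"] == pytest.approx(2 / 3)
        zero = oh.classify_pleasant(pd.Series([0.0]))
        assert not zero["pleasant"].iloc[0]

    def test_perfumery_biased_set_mostly_pleasant(self):
        """Large oxygenated molecules score pleasant under the quadratic
        atlas equation, mirroring the perfumery-bias mechanism."""
        rng = np.random.default_rng(21)
        n = 300
        f = pd.DataFrame(
            {
                "n_at": rng.integers(8, 23, n),
                "i_ox": np.ones(n, dtype=int),
                "i_sul": np.zeros(n, dtype=int),
                "i_acid": (rng.random(n) < 0.015).astype(int),
                "i_amine": np.zeros(n, dtype=int),
            }
        )
        preds = oh.predict("eq11", f)
        out = oh.classify_pleasant(preds)
        assert out.attrs["fraction_pleasant"] > 0.9

    def test_compare_identical_and_anticorrelated(self):
        x = np.linspace(-2, 2, 20)
        same = oh.compare_scores(x, x)
        assert same.r == pytest.approx(1.0)
        assert same.slope == pytest.approx(1.0)
        assert same.intercept == pytest.approx(0.0, abs=1e-12)
        anti = oh.compare_scores(x, -x)
        assert anti.r == pytest.approx(-1.0)

    def test_slope_ci_covers_simulated_truth(self):
        rng = np.random.default_rng(22)
        x = rng.uniform(-3, 3, 150)
        y = 0.26 + 1.03 * x + rng.normal(0, 0.5, 150)
        cmp = oh.compare_scores(x, y)
        lo, hi = cmp.slope_ci
        assert lo < 1.03 < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            oh.compare_scores(np.ones(10), np.arange(10.0))
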