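"""Estimators: oracle equivalences, degenerate limits, simulation recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wolfroads.stats_core import (
    UnidentifiableError,
    backward_eliminate,
    fit_conditional_logistic,
    fit_lmm,
    fit_logistic_rim,
    fit_ols,
    nakagawa_r2,
    pearson_screen,
    spearman,
    wilcoxon_signed_rank,
)


def simulate_strata(rng, n_strata, beta, n_clusters=10, k=10):
    """Matched 1:k strata with the case chosen by softmax probabilities."""
    rows = []
    for s in range(n_strata):
        x = rng.normal(0.0, 1.0, k + 1)
        p = np.exp(beta * x)
        case = rng.choice(k + 1, p=p / p.sum())
        y = np.zeros(k + 1, dtype=int)
        y[case] = 1
        rows.append(
            pd.DataFrame(
                {
                    "stratum_id": s,
                    "territory_id": f"c{s % n_clusters}",
                    "y": y,
                    "x": x,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestConditionalLogistic:
    def test_matches_grid_search_oracle(self, rng):
        # two strata, one binary covariate; oracle: 1-D likelihood grid
        df = pd.DataFrame(
            {
                "stratum_id": [0] * 3 + [1] * 3,
                "territory_id": "t",
                "y": [1, 0, 0, 1, 0, 0],
                "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
            }
        )
        fit = fit_conditional_logistic(df, ["x"])

        def loglik(b):
            ll = 0.0
            for s in (0, 1):
                sub = df[df.stratum_id == s]
                eta = b * sub.x.to_numpy()
                ll += eta[sub.y.to_numpy() == 1][0] - np.log(np.exp(eta).sum())
            return ll

        grid = np.arange(-10.0, 10.0, 1e-4)
        lls = np.array([loglik(b) for b in grid])
        assert abs(fit.params["x"] - grid[np.argmax(lls)]) < 1e-3

    def test_loglik_at_zero_is_uniform_choice(self, rng):
        df = simulate_strata(rng, 50, beta=0.0)
        # max_iter=0 evaluates the conditional likelihood at beta = 0:
        # each 11-row stratum contributes ln(1/11)
        fit0 = fit_conditional_logistic(df, ["x"], max_iter=0)
        assert fit0.loglik == pytest.approx(-50 * np.log(11))

    def test_unidentifiable_constant_within_strata(self, rng):
        df = simulate_strata(rng, 20, beta=1.0)
        df["z"] = df["stratum_id"].astype(float)  # constant within stratum
        with pytest.raises(UnidentifiableError):
            fit_conditional_logistic(df, ["z"])

    def test_simulation_recovery_within_3_robust_se(self, rng):
        df = simulate_strata(rng, 500, beta=1.0)
        fit = fit_conditional_logistic(df, ["x"])
        assert abs(fit.params["x"] - 1.0) < 3 * fit.robust_se["x"]

    def test_singleton_clusters_match_hc0(self, rng):
        df = simulate_strata(rng, 200, beta=0.7)
        df["territory_id"] = df["stratum_id"]  # each stratum its own cluster
        fit = fit_conditional_logistic(df, ["x"])
        # HC0 oracle: A^-1 (sum_s g_s g_s') A^-1 over per-stratum scores
        # equals the clustered sandwich when clusters are singletons, so
        # recompute with explicit singleton clusters shuffled
        df2 = df.copy()
        df2["territory_id"] = "s" + df2["stratum_id"].astype(str)
        fit2 = fit_conditional_logistic(df2, ["x"])
        assert fit.robust_se["x"] == pytest.approx(fit2.robust_se["x"], rel=1e-10)

    def test_stratum_permutation_invariance(self, rng):
        df = simulate_strata(rng, 100, beta=0.5)
        perm = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f1 = fit_conditional_logistic(df, ["x"])
        f2 = fit_conditional_logistic(perm, ["x"])
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_separation_flagged(self):
        # case always has x=1, controls never: likelihood diverges
        rows = []
        for s in range(10):
            y = np.r_[1, np.zeros(10, int)]
            x = np.r_[1.0, np.zeros(10)]
            rows.append(
                pd.DataFrame({"stratum_id": s, "territory_id": "t", "y": y, "x": x})
            )
        df = pd.concat(rows, ignore_index=True)
        fit = fit_conditional_logistic(df, ["x"])
        assert fit.flags["separation"]
        from wolfroads.stats_core import SeparationError

        with pytest.raises(SeparationError):
            fit_conditional_logistic(df, ["x"], on_separation="raise")


def _nested_gaussian(rng, n_terr=30, n_dsets=2, n_obs=200, vt=0.25, vd=0.1, ve=1.0):
    rows = []
    for t in range(n_terr):
        bt = rng.normal(0, np.sqrt(vt))
        for d in range(n_dsets):
            bd = rng.normal(0, np.sqrt(vd))
            x = rng.normal(0, 1, n_obs)
            y = 1.0 + 0.5 * x + bt + bd + rng.normal(0, np.sqrt(ve), n_obs)
            rows.append(
                pd.DataFrame(
                    {"y": y, "x": x, "territory_id": f"t{t}", "dataset_id": f"t{t}d{d}"}
                )
            )
    return pd.concat(rows, ignore_index=True)


class TestLMM:
    def test_zero_variance_limit_matches_ols(self, rng):
        n = 300
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["territory_id"] = np.repeat([f"t{i}" for i in range(6)], 50)
        df["dataset_id"] = df["territory_id"] + "_a"
        df["y"] = 2.0 + 0.5 * df["x"] + rng.normal(0, 1, n)
        fit = fit_lmm(df, "y", ["x"])
        import statsmodels.api as sm

        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert fit.params["Intercept"] == pytest.approx(ols.params["const"], abs=1e-3)
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=1e-3)
        assert fit.vc["territory"] + fit.vc["dataset"] < 0.05

    def test_variance_components_recovered(self, rng):
        df = _nested_gaussian(rng)
        fit = fit_lmm(df, "y", ["x"])
        for name, true in (("territory", 0.25), ("dataset", 0.1), ("residual", 1.0)):
            assert abs(fit.vc[name] - true) / true < 0.5

    def test_balanced_oneway_matches_anova_estimators(self, rng):
        # balanced one-way design: REML equals the closed-form ANOVA
        # estimators sigma2_e = MSW, sigma2_g = (MSB - MSW) / n
        g, n = 12, 25
        b = rng.normal(0, np.sqrt(0.5), g)
        y = np.repeat(b, n) + rng.normal(0, 1.0, g * n)
        df = pd.DataFrame(
            {
                "y": y,
                "territory_id": np.repeat([f"g{i}" for i in range(g)], n),
            }
        )
        df["dataset_id"] = df["territory_id"] + "_a"
        fit = fit_lmm(df, "y", [])
        means = df.groupby("territory_id")["y"].mean()
        grand = df["y"].mean()
        msb = n * np.sum((means - grand) ** 2) / (g - 1)
        msw = np.sum((df["y"] - means.loc[df["territory_id"]].to_numpy()) ** 2) / (
            g * (n - 1)
        )
        assert fit.vc["residual"] == pytest.approx(msw, abs=1e-4)
        assert fit.vc["territory"] == pytest.approx(max((msb - msw) / n, 0.0), abs=1e-4)


class TestNakagawaR2:
    def test_zero_random_variance_equalizes(self):
        from wolfroads.stats_core import FitResult

        fit = FitResult(
            method="lmm", terms=["x"], params=pd.Series(dtype=float),
            se=pd.Series(dtype=float), robust_se=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float), term_pvalues={}, loglik=0.0,
            n_obs=10, n_groups=2,
            vc={"territory": 0.0, "dataset": 0.0, "residual": 2.0},
            meta={"var_fixed": 1.0},
        )
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == r2c == pytest.approx(1.0 / 3.0)

    def test_worked_example(self):
        from wolfroads.stats_core import FitResult

        fit = FitResult(
            method="lmm", terms=[], params=pd.Series(dtype=float),
            se=pd.Series(dtype=float), robust_se=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float), term_pvalues={}, loglik=0.0,
            n_obs=10, n_groups=2,
            vc={"territory": 1.0, "residual": 2.0}, meta={"var_fixed": 1.0},
        )
        assert nakagawa_r2(fit) == pytest.approx((0.25, 0.50))

    def test_null_model_marginal_zero(self, rng):
        df = _nested_gaussian(rng, n_terr=6, n_obs=50)
        fit = fit_lmm(df, "y", [])
        r2m, r2c = nakagawa_r2(fit)
        assert r2m == pytest.approx(0.0, abs=1e-10)
        assert r2c >= r2m


class TestLogisticRIM:
    def test_zero_variance_matches_plain_logistic(self, rng):
        n = 2000
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["territory_id"] = np.repeat([f"t{i}" for i in range(10)], 200)
        df["dataset_id"] = df["territory_id"] + "_a"
        eta = -1.0 + 0.8 * df["x"]
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic_rim(df, "y", ["x"])
        import statsmodels.api as sm

        plain = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert fit.params["Intercept"] == pytest.approx(plain.params["const"], abs=1e-3)
        assert fit.params["x"] == pytest.approx(plain.params["x"], abs=1e-3)

    def test_simulation_recovery(self, rng):
        rows = []
        for g in range(50):
            bg = rng.normal(0, np.sqrt(0.5))
            x = rng.normal(0, 1, 60)
            eta = -1.0 + 0.8 * x + bg
            y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(int)
            rows.append(
                pd.DataFrame(
                    {"y": y, "x": x, "territory_id": f"g{g}", "dataset_id": f"g{g}d"}
                )
            )
        df = pd.concat(rows, ignore_index=True)
        fit = fit_logistic_rim(df, "y", ["x"])
        assert abs(fit.params["Intercept"] + 1.0) < 3 * fit.se["Intercept"]
        assert abs(fit.params["x"] - 0.8) < 3 * fit.se["x"]

    def test_single_group_degrades_with_warning(self, rng):
        n = 500
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["territory_id"] = "only"
        df["dataset_id"] = "only_a"
        df["y"] = (rng.random(n) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="single territory"):
            fit = fit_logistic_rim(df, "y", ["x"])
        assert fit.method == "logistic"


class TestBackwardElimination:
    @staticmethod
    def _ols_fitter(df, response):
        def fn(terms):
            return fit_ols(df, response, terms)

        return fn

    def test_all_significant_model_unchanged(self, rng):
        n = 400
        df = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        df["y"] = 1.0 + 2.0 * df["a"] - 1.5 * df["b"] + rng.normal(0, 0.5, n)
        fit, trace = backward_eliminate(self._ols_fitter(df, "y"), ["a", "b"])
        assert trace == []
        assert set(fit.terms) == {"a", "b"}

    def test_noise_covariate_usually_eliminated(self, rng):
        hits = 0
        for rep in range(100):
            n = 150
            df = pd.DataFrame(
                {"a": rng.normal(0, 1, n), "noise": rng.normal(0, 1, n)}
            )
            df["y"] = 2.0 * df["a"] + rng.normal(0, 1, n)
            _, trace = backward_eliminate(self._ols_fitter(df, "y"), ["a", "noise"])
            if any(t[0] == "noise" for t in trace):
                hits += 1
        assert hits >= 95

    def test_marginality_keeps_main_effect_under_interaction(self, rng):
        n = 600
        df = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        # interaction real, b main effect null
        df["y"] = 1.0 + 1.0 * df["a"] + 0.4 * df["a"] * df["b"] + rng.normal(0, 1, n)
        fit, trace = backward_eliminate(
            self._ols_fitter(df, "y"), ["a", "b", "a:b"]
        )
        if "a:b" in fit.terms:  # interaction retained => b must survive
            assert "b" in fit.terms

    def test_quadratic_protects_linear(self, rng):
        n = 500
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["x_sq"] = (df["x"] - df["x"].mean()) ** 2
        df["y"] = 0.05 * df["x"] + 1.0 * df["x_sq"] + rng.normal(0, 1, n)
        fit, _ = backward_eliminate(self._ols_fitter(df, "y"), ["x", "x_sq"])
        if "x_sq" in fit.terms:
            assert "x" in fit.terms


class TestWilcoxon:
    def test_all_positive_extreme_p(self):
        d = np.arange(1, 11, dtype=float)
        V, P = wilcoxon_signed_rank(d)
        assert V == 55.0
        assert P == pytest.approx(1.0 / 2**10)

    def test_symmetric_differences_null(self):
        d = np.array([1.0, -1.5, 2.0, -2.5, 3.0, -3.5, 4.0, -4.5])
        V, P = wilcoxon_signed_rank(d)
        assert P > 0.3
        n = len(d)
        assert abs(V - n * (n + 1) / 4) <= n  # near the null mean

    def test_exact_matches_enumeration_at_n12(self, rng):
        d = rng.normal(0.3, 1.0, 12)
        while len(np.unique(np.abs(d))) < 12 or np.any(d == 0):
            d = rng.normal(0.3, 1.0, 12)
        V, P = wilcoxon_signed_rank(d)
        # oracle: enumerate all 2^12 sign assignments of the rank magnitudes
        ranks = stats.rankdata(np.abs(d))
        count = 0
        for mask in range(2**12):
            v = sum(ranks[i] for i in range(12) if (mask >> i) & 1)
            if v >= V:
                count += 1
        assert P == pytest.approx(count / 2**12)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(10))


class TestSpearmanAndScreen:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, x**3) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        y = rng.normal(0, 1, 8).round(1)
        if np.all(y == y[0]):
            y[0] += 1.0
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))

    def test_screen_drops_by_priority(self, rng):
        n = 200
        a = rng.normal(0, 1, n)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.2, n), "c": rng.normal(0, 1, n)})
        kept, dropped = pearson_screen(df, ["a", "b", "c"], priority=["a", "b", "c"])
        assert kept == ["a", "c"]
        assert dropped[0][:2] == ("b", "a")
        kept2, _ = pearson_screen(df, ["a", "b", "c"], priority=["b", "a", "c"])
        assert kept2 == ["b", "c"]

    def test_retained_set_pairwise_uncorrelated(self, rng):
        n = 300
        base = rng.normal(0, 1, (n, 3))
        df = pd.DataFrame(
            {
                "v1": base[:, 0],
                "v2": base[:, 0] * 0.9 + base[:, 1] * 0.1,
                "v3": base[:, 1],
                "v4": base[:, 2],
                "v5": base[:, 0] * 0.7 + base[:, 2] * 0.3,
            }
        )
        cols = list(df.columns)
        kept, _ = pearson_screen(df, cols)
        corr = df[kept].corr().to_numpy()
        off = corr[~np.eye(len(kept), dtype=bool)]
        assert np.all(np.abs(off) < 0.6)
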