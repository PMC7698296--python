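"""The mixed-model engine and multimodel-inference machinery."""

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from farmvisits import glmm
from farmvisits.glmm import (
    FitResult,
    ModelSpec,
    aicc,
    akaike_weights,
    enumerate_candidates,
    fit_binomial_glmm,
    mann_whitney_u,
    model_average,
    morans_i,
    overdispersion_ratio,
    prune_uninformative,
    pseudo_r2,
    spearman_rho,
    vif,
)

DATA = Path(__file__).parent / "data"


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_k_zero_equals_minus_2ll(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    @given(st.integers(10, 10**6))
    @settings(deadline=None, max_examples=30)
    def test_approaches_aic_for_large_n(self, n):
        k = 3
        gap = aicc(-100.0, k, n) - (-2 * -100.0 + 2 * k)
        assert gap == pytest.approx(2 * k * (k + 1) / (n - k - 1))


class TestAkaikeWeights:
    def test_symmetry(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([1 / (1 + np.exp(-1)), 1 - 1 / (1 + np.exp(-1))], abs=1e-4)
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    @given(st.lists(st.floats(0, 500), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_normalized_and_shift_invariant(self, values):
        w = akaike_weights(values)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        w2 = akaike_weights(np.asarray(values) + 37.5)
        assert w2 == pytest.approx(w, abs=1e-9)


def _toy_rows(rng, n=40):
    return pd.DataFrame(
        {
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "c": rng.normal(size=n),
            "numerator": rng.integers(0, 5, n),
            "denominator": 10,
            "g": rng.integers(0, 5, n),
        }
    )


class TestEnumerateCandidates:
    def test_power_set_size(self, rng):
        rows = _toy_rows(rng)
        specs = enumerate_candidates(("a", "b", "c"), rows)
        assert len(specs) == 8

    def test_collinear_pair_excluded(self, rng):
        rows = _toy_rows(rng)
        rows["b"] = rows["a"] * 2 + rng.normal(0, 0.1, len(rows))  # rho > 0.5
        specs = enumerate_candidates(("a", "b"), rows)
        assert {s.fixed_terms for s in specs} == {(), ("a",), ("b",)}

    def test_interaction_adds_one_candidate(self, rng):
        rows = _toy_rows(rng)
        specs = enumerate_candidates(("a", "b"), rows, interactions=(("a", "b"),))
        names = {s.describe() for s in specs}
        assert names == {"1", "a", "b", "a + b", "a + b + a:b"}

    def test_matches_bruteforce_filterset_oracle(self, rng):
        rows = _toy_rows(rng, n=60)
        rows["b"] = rows["a"] + rng.normal(0, 0.05, len(rows))
        terms = ("a", "b", "c")
        specs = enumerate_candidates(terms, rows, interactions=(("a", "c"),))
        # independent oracle: filter the raw powerset by the constraint
        from scipy.stats import spearmanr

        bad = {
            frozenset(p)
            for p in itertools.combinations(terms, 2)
            if abs(spearmanr(rows[p[0]], rows[p[1]]).statistic) > 0.5
        }
        expected = set()
        for r in range(4):
            for sub in itertools.combinations(terms, r):
                if any(pair <= set(sub) for pair in bad):
                    continue
                expected.add((sub, None))
                if "a" in sub and "c" in sub:
                    expected.add((sub, ("a", "c")))
        assert {(s.fixed_terms, s.interaction) for s in specs} == expected

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec(("a",), ("a", "b"))


def _fake_fit(terms, a):
    return FitResult(
        spec=ModelSpec(tuple(terms)),
        coefficients=pd.Series(1.0, index=["(Intercept)", *terms]),
        std_errors=pd.Series(0.1, index=["(Intercept)", *terms]),
        random_sd={},
        loglik=0.0,
        k=len(terms) + 1,
        n=100,
        aicc=a,
    )


class TestPruneUninformative:
    def test_nested_within_two_units_discarded(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["a", "b"], 101.5)
        assert prune_uninformative([fa, fb]) == [fa]

    def test_net_reduction_retained(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["a", "b"], 99.5)
        assert set(map(id, prune_uninformative([fa, fb]))) == {id(fa), id(fb)}

    def test_non_nested_pair_both_retained(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["b"], 101.0)
        assert len(prune_uninformative([fa, fb])) == 2


class TestModelAverage:
    def test_single_dominant_model_returned_alone(self):
        # AICc gap of 6 gives the top model weight ~0.953
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["b"], 106.0)
        avg = model_average([fa, fb])
        assert avg.single_best
        assert avg.table.loc["a", "estimate"] == 1.0

    def test_equal_weights_average(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["a"], 100.0)
        fb.coefficients["a"] = 3.0
        avg = model_average([fa, fb])
        assert avg.table.loc["a", "estimate"] == pytest.approx(2.0)

    def test_zero_substitution_and_ri(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit([], 100.0)
        avg = model_average([fa, fb])
        assert avg.table.loc["a", "estimate"] == pytest.approx(0.5)
        assert avg.table.loc["a", "ri"] == pytest.approx(0.5)
        assert avg.table.loc["(Intercept)", "ri"] == 1.0

    def test_average_within_convex_hull(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["a"], 100.7)
        fb.coefficients["a"] = -2.0
        avg = model_average([fa, fb])
        assert -2.0 <= avg.table.loc["a", "estimate"] <= 1.0
        assert avg.table.loc["a", "ri"] == pytest.approx(1.0)

    def test_ci_uses_85_percent_quantile(self):
        fa = _fake_fit(["a"], 100.0)
        fb = _fake_fit(["a"], 100.5)
        avg = model_average([fa, fb])
        row = avg.table.loc["a"]
        assert row["ci_hi"] - row["estimate"] == pytest.approx(1.4395 * row["se"], rel=1e-3)


class TestVif:
    def test_orthogonal_columns(self, rng):
        n = 200
        x = rng.normal(size=(n, 2))
        x -= x.mean(axis=0)  # VIF regressions run on centred columns
        x[:, 1] -= x[:, 0] * (x[:, 0] @ x[:, 1]) / (x[:, 0] @ x[:, 0])
        out = vif(pd.DataFrame(x, columns=["u", "v"]))
        assert out.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_exact_correlation_closed_form(self, rng):
        # construct columns with sample correlation exactly 0.6
        n = 100
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        a = (z1 - z1.mean()) / z1.std()
        b = z2 - z2.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        x2 = 0.6 * a + np.sqrt(1 - 0.36) * b
        out = vif(pd.DataFrame({"a": a, "x2": x2}))
        assert out.to_numpy() == pytest.approx([1.5625, 1.5625], rel=1e-9)

    def test_duplicated_column_errors(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="rank deficient"):
            vif(pd.DataFrame({"a": x, "b": x}))


def _glmm_rows(rng, nf=60, ns=4, den=20, sd_f=0.6, sd_s=0.3, beta=(-1.5, 0.7, -0.5)):
    farms = np.repeat(np.arange(nf), ns)
    sems = np.tile(np.arange(ns), nf)
    x1 = rng.normal(size=nf)[farms]
    x2 = rng.normal(size=nf * ns)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2
    eta += rng.normal(0, sd_f, nf)[farms] + rng.normal(0, sd_s, ns)[sems]
    y = rng.binomial(den, expit(eta))
    return pd.DataFrame(
        {
            "numerator": y,
            "denominator": den,
            "x1": x1,
            "x2": x2,
            "farm": farms,
            "semester": sems,
        }
    )


class TestBinomialGlmm:
    def test_degenerates_to_glm_without_group_variance(self, rng):
        import statsmodels.api as sm

        rows = _glmm_rows(rng, sd_f=0.0, sd_s=0.0)
        # pin both variance components at zero: the mixed model must then
        # coincide with the plain logistic GLM
        fit = fit_binomial_glmm(
            rows, ModelSpec(("x1", "x2"), None, ("farm", "semester")), max_sigma=0.0
        )
        X = np.column_stack([np.ones(len(rows)), rows["x1"], rows["x2"]])
        ref = sm.GLM(
            np.c_[rows["numerator"], rows["denominator"] - rows["numerator"]],
            X,
            family=sm.families.Binomial(),
        ).fit()
        assert fit.singular
        assert np.abs(fit.coefficients.to_numpy() - ref.params).max() < 1e-4

    def test_matches_reference_mixed_model_fixture(self):
        """Agreement with an independent mixed-model implementation (an
        lme4::glmer Laplace fit frozen alongside the synthetic fixture)."""
        ref = json.loads((DATA / "glmm_fixture_lme4.json").read_text())
        rows = pd.read_csv(DATA / "glmm_fixture.csv")
        fit = fit_binomial_glmm(rows, ModelSpec(("x1", "x2"), None, ("farm", "semester")))
        for term, value in ref["coefficients"].items():
            assert fit.coefficients[term] == pytest.approx(value, abs=1e-3)
        for factor, value in ref["random_sd"].items():
            assert fit.random_sd[factor] == pytest.approx(value, abs=1e-3)
        assert fit.loglik == pytest.approx(ref["loglik"], abs=1e-3)
        for term, value in ref["se"].items():
            assert fit.std_errors[term] == pytest.approx(value, abs=1e-3)

    def test_recovers_parameters_within_3se(self, rng):
        rows = _glmm_rows(rng, nf=150, ns=6, den=30)
        fit = fit_binomial_glmm(rows, ModelSpec(("x1", "x2"), None, ("farm", "semester")))
        truth = {"(Intercept)": -1.5, "x1": 0.7, "x2": -0.5}
        for term, value in truth.items():
            assert abs(fit.coefficients[term] - value) < 3 * fit.std_errors[term]

    def test_deterministic(self, rng):
        rows = _glmm_rows(rng)
        spec = ModelSpec(("x1",), None, ("farm", "semester"))
        f1 = fit_binomial_glmm(rows, spec)
        f2 = fit_binomial_glmm(rows, spec)
        assert f1.coefficients.equals(f2.coefficients)
        assert f1.loglik == f2.loglik

    def test_aicc_counts_variance_components(self, rng):
        rows = _glmm_rows(rng)
        fit = fit_binomial_glmm(rows, ModelSpec(("x1",), None, ("farm", "semester")))
        assert fit.k == 2 + 2  # intercept + slope + two variance components
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n))

    def test_invalid_rows_rejected(self, rng):
        rows = _glmm_rows(rng)
        rows.loc[0, "numerator"] = rows.loc[0, "denominator"] + 1
        with pytest.raises(ValueError):
            fit_binomial_glmm(rows, ModelSpec(("x1",), None, ("farm",)))

    def test_single_level_factor_rejected(self, rng):
        rows = _glmm_rows(rng)
        rows["one"] = "only"
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_binomial_glmm(rows, ModelSpec(("x1",), None, ("one",)))


class TestDiagnostics:
    def test_overdispersion_near_one_when_well_specified(self, rng):
        rows = _glmm_rows(rng, nf=200, ns=5, den=30)
        fit = fit_binomial_glmm(rows, ModelSpec(("x1", "x2"), None, ("farm", "semester")))
        assert 0.7 < overdispersion_ratio(fit) < 1.3

    def test_overdispersion_detects_betabinomial_noise(self, rng):
        rows = _glmm_rows(rng, nf=200, ns=5, den=30)
        # re-draw numerators with beta-binomial extra variance
        p = expit(-1.0 + 0.7 * rows["x1"].to_numpy())
        rho = 0.1
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        rows["numerator"] = rng.binomial(30, rng.beta(a, b))
        fit = fit_binomial_glmm(rows, ModelSpec(("x1",), None, ("farm", "semester")))
        assert overdispersion_ratio(fit) > 1.5

    def test_pseudo_r2_zero_fixed_effects(self, rng):
        rows = _glmm_rows(rng, beta=(-1.0, 0.0, 0.0))
        fit = fit_binomial_glmm(rows, ModelSpec((), None, ("farm", "semester")))
        marg, cond = pseudo_r2(fit)
        assert marg == 0.0
        assert cond > marg

    def test_pseudo_r2_no_random_variance(self, rng):
        rows = _glmm_rows(rng, sd_f=0.0, sd_s=0.0)
        fit = fit_binomial_glmm(
            rows, ModelSpec(("x1", "x2"), None, ("farm", "semester")), max_sigma=0.0
        )
        marg, cond = pseudo_r2(fit)
        assert cond == pytest.approx(marg, abs=1e-4)

    def test_pseudo_r2_matches_plugin_truth(self, rng):
        beta = (-1.5, 0.9, -0.6)
        rows = _glmm_rows(rng, nf=300, ns=6, den=40, beta=beta)
        fit = fit_binomial_glmm(rows, ModelSpec(("x1", "x2"), None, ("farm", "semester")))
        marg, cond = pseudo_r2(fit)
        var_f = 0.9**2 * np.var(rows["x1"]) + 0.6**2 * np.var(rows["x2"])
        var_r = 0.6**2 + 0.3**2
        denom = var_f + var_r + np.pi**2 / 3
        assert marg == pytest.approx(var_f / denom, abs=0.05)
        assert cond == pytest.approx((var_f + var_r) / denom, abs=0.05)


class TestMoransI:
    def test_null_expectation_under_permutation(self, rng):
        n = 120
        xy = rng.uniform(0, 1000, (n, 2))
        z = rng.normal(size=n)
        stats_ = [
            morans_i(rng.permutation(z), xy, k_neighbors=10, n_permutations=49, seed=s)[0]
            for s in range(60)
        ]
        assert np.mean(stats_) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_smooth_gradient_detected(self, rng):
        xy = rng.uniform(0, 1000, (150, 2))
        z = xy[:, 0] + rng.normal(0, 5, 150)
        i_stat, p = morans_i(z, xy, k_neighbors=15, n_permutations=999, seed=0)
        assert i_stat > 0.5
        assert p <= 0.001

    def test_deterministic_given_seed(self, rng):
        xy = rng.uniform(0, 100, (60, 2))
        z = rng.normal(size=60)
        r1 = morans_i(z, xy, seed=5)
        r2 = morans_i(z, xy, seed=5)
        assert r1 == r2

    def test_constant_residuals_error(self, rng):
        xy = rng.uniform(0, 100, (30, 2))
        with pytest.raises(ValueError):
            morans_i(np.ones(30), xy, k_neighbors=5)


class TestRankStatistics:
    def test_mann_whitney_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_mann_whitney_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=7)
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_spearman_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_spearman_midrank_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rx = pd.Series(x).rank().to_numpy()
            ry = pd.Series(y).rank().to_numpy()
            want = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(want, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])
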