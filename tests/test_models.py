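"""Tests for the homogeneous / stratified fits, Wald test, rank
normalization and per-group meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from varstrat.models import (
    CohortTable,
    Design,
    empirical_group_variances,
    fit_homogeneous,
    fit_stratified,
    per_group_meta,
    rank_normalize,
    two_stage_rank_normalize,
    wald_test,
)

DESIGN = Design(covariates=("pc",))


def _cohort(y, group, pc=None, g=None):
    n = len(y)
    cols = {
        "sample_id": [f"s{i}" for i in range(n)],
        "group_id": group,
        "y": np.asarray(y, dtype=float),
    }
    if pc is not None:
        cols["pc"] = np.asarray(pc, dtype=float)
    if g is not None:
        cols["g"] = np.asarray(g, dtype=float)
    return CohortTable(pd.DataFrame(cols), dosage_cols=("g",) if g is not None else ())


class TestFitHomogeneous:
    def test_noiseless_recovery(self, rng):
        n = 60
        pc = rng.normal(size=n)
        group = ["a"] * 30 + ["b"] * 30
        y = np.where(np.array(group) == "a", 1.0, 2.0) + 3.0 * pc
        fit = fit_homogeneous(_cohort(y, group, pc), DESIGN)
        assert fit.coefficients["intercept[a]"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["intercept[b]"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["pc"] == pytest.approx(3.0, abs=1e-10)

    def test_equal_true_variances_give_similar_group_variances(self, rng):
        n = 4000
        group = ["a"] * (n // 2) + ["b"] * (n // 2)
        y = rng.normal(size=n)
        fit = fit_homogeneous(_cohort(y, group), Design())
        v = empirical_group_variances(fit, _cohort(y, group))
        assert v["a"] == pytest.approx(v["b"], rel=0.15)

    def test_collinear_design_names_columns(self, rng):
        n = 20
        pc = rng.normal(size=n)
        tab = _cohort(rng.normal(size=n), ["a"] * n, pc)
        tab.data["pc2"] = 2.0 * pc
        with pytest.raises(ValueError, match="collinear.*pc2"):
            fit_homogeneous(tab, Design(covariates=("pc", "pc2")))


class TestEmpiricalGroupVariances:
    def test_mean_of_squares_without_df_correction(self):
        tab = _cohort([0.0, 0.0, 0.0, 0.0], ["a", "a", "b", "b"])
        fit = fit_homogeneous(tab, Design())
        fit.residuals = pd.Series([1.0, -1.0, 2.0, -2.0], index=tab.data.index)
        v = empirical_group_variances(fit, tab)
        assert v["a"] == pytest.approx(1.0)
        assert v["b"] == pytest.approx(4.0)

    def test_zero_residuals_warn_degenerate(self):
        tab = _cohort([0.0, 0.0, 1.0, -1.0], ["a", "a", "b", "b"])
        fit = fit_homogeneous(tab, Design())
        fit.residuals = pd.Series([0.0, 0.0, 1.0, -1.0], index=tab.data.index)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            v = empirical_group_variances(fit, tab)
        assert v["a"] == 0.0


class TestFitStratified:
    def test_reduces_to_ols_under_equal_variances(self, rng):
        n = 1000
        group = ["a"] * (n // 2) + ["b"] * (n // 2)
        pc = rng.normal(size=n)
        y = 1.0 + 0.5 * pc + rng.normal(size=n)
        tab = _cohort(y, group, pc)
        hom = fit_homogeneous(tab, DESIGN)
        strat = fit_stratified(tab, DESIGN)
        assert strat.converged
        assert np.allclose(strat.coefficients, hom.coefficients, rtol=5e-3, atol=5e-3)

    def test_recovers_generating_variances(self, rng):
        n1 = n2 = 5000
        group = ["a"] * n1 + ["b"] * n2
        pc = np.concatenate([rng.normal(2, 1, n1), rng.normal(-2, 1, n2)])
        # total error variance sigma_m^2 + sigma_g^2 = 2 and 3
        eps = np.concatenate(
            [rng.normal(0, np.sqrt(2.0), n1), rng.normal(0, np.sqrt(3.0), n2)]
        )
        y = np.r_[np.ones(n1), 2 * np.ones(n2)] + pc + eps
        tab = _cohort(y, group, pc)
        fit = fit_stratified(tab, DESIGN)
        assert fit.converged
        # ~4 Monte-Carlo SDs of a variance estimate at n=5000
        assert fit.group_variances["a"] == pytest.approx(2.0, abs=0.16)
        assert fit.group_variances["b"] == pytest.approx(3.0, abs=0.24)
        assert fit.coefficients["intercept[a]"] == pytest.approx(1.0, abs=0.1)
        assert fit.coefficients["intercept[b]"] == pytest.approx(2.0, abs=0.1)
        assert fit.coefficients["pc"] == pytest.approx(1.0, abs=0.05)

    def test_profiled_objective_nonincreasing(self, two_group_cohort):
        fit = fit_stratified(two_group_cohort, DESIGN, tol=1e-12)
        sizes = two_group_cohort.group_sizes()
        # profiled Gaussian -2 log likelihood (up to constants)
        objective = [
            float(sum(sizes[g] * np.log(v[g]) for g in sizes.index))
            for v in fit.variance_trace
        ]
        assert all(a >= b - 1e-9 for a, b in zip(objective, objective[1:]))

    def test_requires_two_samples_per_group(self):
        tab = _cohort([1.0, 2.0, 3.0, 1.0, 2.0], ["a"] * 4 + ["b"])
        with pytest.raises(ValueError, match="2 samples per group"):
            fit_stratified(tab, Design())


class TestWaldTest:
    def test_strong_signal_recovered(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.5 * g + rng.normal(0, 1e-6, n)
        tab = _cohort(y, ["a"] * n, g=g)
        res = wald_test(fit_homogeneous(tab, Design()), tab, "g")
        assert res.beta == pytest.approx(0.5, abs=1e-6)
        assert res.p < 1e-100

    def test_monomorphic_variant_rejected(self, rng):
        n = 50
        tab = _cohort(rng.normal(size=n), ["a"] * n, g=np.ones(n))
        with pytest.raises(ValueError, match="monomorphic"):
            wald_test(fit_homogeneous(tab, Design()), tab, "g")

    def test_variant_identical_to_covariate_is_singular(self, rng):
        n = 50
        g = rng.binomial(2, 0.5, n).astype(float)
        tab = _cohort(rng.normal(size=n), ["a"] * n, pc=g, g=g)
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            wald_test(fit_homogeneous(tab, DESIGN), tab, "g")

    def test_chi2_is_squared_z(self, two_group_cohort):
        res = wald_test(fit_homogeneous(two_group_cohort, DESIGN), two_group_cohort, "g")
        assert res.chi2 == pytest.approx((res.beta / res.se) ** 2)
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, 1))

    def test_stratified_and_homogeneous_agree_under_equal_variances(self, rng):
        n = 2000
        group = ["a"] * (n // 2) + ["b"] * (n // 2)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(size=n)
        tab = _cohort(y, group, g=g)
        hom = wald_test(fit_homogeneous(tab, Design()), tab, "g")
        strat = wald_test(fit_stratified(tab, Design()), tab, "g")
        assert np.sqrt(strat.chi2) == pytest.approx(np.sqrt(hom.chi2), abs=0.05)
        assert strat.beta == pytest.approx(hom.beta, abs=0.05 * hom.se)


class TestRankNormalize:
    def test_output_matches_normal_quantiles(self, rng):
        x = rng.exponential(size=501)  # heavily skewed input
        z = rank_normalize(x)
        # monotone in the ranks
        assert np.all(np.argsort(z) == np.argsort(x))
        k = np.arange(1, 502)
        expected = stats.norm.ppf((k - 0.375) / (501 + 0.25))
        assert np.allclose(np.sort(z), expected)
        assert abs(stats.skew(z)) < 0.01

    def test_idempotent_up_to_ties(self, rng):
        x = rng.normal(size=400)
        once = rank_normalize(x)
        twice = rank_normalize(once)
        assert np.allclose(once, twice)

    def test_two_stage_removes_covariate_skew(self, rng):
        n = 1000
        pc = rng.normal(size=n)
        y = 2.0 + pc + rng.gamma(1.0, 2.0, n)  # skewed residuals
        tab = _cohort(y, ["a"] * n, pc)
        out = two_stage_rank_normalize(tab, DESIGN)
        assert abs(stats.skew(out.data["y"])) < 0.01
        with pytest.raises(ValueError, match="at least 3"):
            two_stage_rank_normalize(_cohort([1.0, 2.0], ["a", "a"]), Design())


class TestPerGroupMeta:
    def test_single_informative_group_matches_its_own_fit(self, rng):
        n = 300
        g = np.concatenate([rng.binomial(2, 0.3, n), np.zeros(n)]).astype(float)
        y = rng.normal(size=2 * n) + 0.1 * g
        tab = _cohort(y, ["a"] * n + ["b"] * n, g=g)
        meta, skipped = per_group_meta(tab, Design(), "g")
        assert skipped == ["b"]
        sub = CohortTable(tab.data[tab.data["group_id"] == "a"], dosage_cols=("g",))
        own = wald_test(fit_homogeneous(sub, Design(group_intercepts=False)), sub, "g")
        assert meta.beta == pytest.approx(own.beta)
        assert meta.se == pytest.approx(own.se)

    def test_inverse_variance_identity_and_pooled_agreement(self, rng):
        n = 3000
        group = ["a"] * (n // 2) + ["b"] * (n // 2)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.05 * g + rng.normal(size=n)
        tab = _cohort(y, group, g=g)
        meta, skipped = per_group_meta(tab, Design(), "g")
        assert not skipped
        # fixed-effects identity: meta precision is the sum of group precisions
        per_group = []
        for gid in ("a", "b"):
            sub = CohortTable(tab.data[tab.data["group_id"] == gid], dosage_cols=("g",))
            per_group.append(
                wald_test(fit_homogeneous(sub, Design(group_intercepts=False)), sub, "g")
            )
        assert meta.se**-2 == pytest.approx(sum(r.se**-2 for r in per_group))
        pooled = wald_test(fit_homogeneous(tab, Design()), tab, "g")
        assert meta.beta == pytest.approx(pooled.beta, abs=3 * pooled.se)

    def test_all_monomorphic_rejected(self, rng):
        n = 40
        tab = _cohort(rng.normal(size=n), ["a"] * n, g=np.full(n, 2.0))
        with pytest.raises(ValueError, match="every group"):
            per_group_meta(tab, Design(), "g")


def test_cohort_table_validation():
    df = pd.DataFrame(
        {"sample_id": ["s1"], "group_id": ["a"], "y": [1.0], "g": [2.5]}
    )
    with pytest.raises(ValueError, match="outside"):
        CohortTable(df, dosage_cols=("g",))
    with pytest.raises(ValueError, match="missing required"):
        CohortTable(df.drop(columns=["y"]))
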