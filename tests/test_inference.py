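"""Group inference: ANCOVA, FDR, post hoc contrasts, partial correlation,
summary-table statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connctl.inference import (
    ancova_f,
    ancova_per_node,
    anova_from_summary,
    chi_square_independence,
    fdr_bh,
    partial_correlation,
    posthoc_pairwise,
)


def _toy_data(rng, n_per=20, shift=None):
    groups = np.repeat(["SZ", "BD", "MDD", "HC"], n_per)
    y = rng.normal(size=len(groups))
    if shift:
        for g, s in shift.items():
            y[groups == g] += s
    cov = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, len(groups)),
            "age": rng.normal(25, 5, len(groups)),
            "education": rng.normal(12, 3, len(groups)),
            "head_motion": rng.uniform(0.05, 0.3, len(groups)),
        }
    )
    return y, groups, cov


class TestAncova:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y, groups, cov = _toy_data(rng, shift={"SZ": 0.8})
        f, p = ancova_per_node(y, groups, cov)
        df = cov.copy()
        df["y"] = y
        df["diagnosis"] = groups
        model = smf.ols("y ~ sex + age + education + head_motion + C(diagnosis)", df).fit()
        table = anova_lm(model, typ=2)
        assert f == pytest.approx(table.loc["C(diagnosis)", "F"], rel=1e-10)
        assert p == pytest.approx(table.loc["C(diagnosis)", "PR(>F)"], rel=1e-8)

    def test_constant_covariates_reduce_to_anova(self, rng):
        y, groups, _ = _toy_data(rng, shift={"HC": 0.5})
        cov0 = np.zeros((len(y), 2))
        f, p = ancova_per_node(y, groups, cov0)
        f_ref, p_ref = stats.f_oneway(*[y[groups == g] for g in ("SZ", "BD", "MDD", "HC")])
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-8)

    def test_null_pvalues_uniform(self, rng):
        """Vectorized null simulation: 500 independent outcome columns."""
        groups = np.repeat(["SZ", "BD", "MDD", "HC"], 15)
        cov = rng.normal(size=(60, 3))
        y = rng.normal(size=(60, 500))
        _, p = ancova_f(y, groups, cov)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_injected_shift_dominates(self, rng):
        groups = np.repeat(["SZ", "BD", "MDD", "HC"], 25)
        y = rng.normal(size=(100, 50))
        y[groups == "SZ", 7] += 1.0
        cov = rng.normal(size=(100, 2))
        f, _ = ancova_f(y, groups, cov)
        assert f[7] > np.median(np.delete(f, 7))

    def test_rank_deficient_design_rejected(self, rng):
        y, groups, cov = _toy_data(rng)
        cov["dup"] = cov["age"] * 2.0
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            ancova_per_node(y, groups, cov)

    def test_too_small_group_rejected(self, rng):
        y = rng.normal(size=5)
        groups = np.array(["SZ", "SZ", "HC", "HC", "BD"])
        with pytest.raises(ValueError, match="too few"):
            ancova_per_node(y, groups, np.zeros((5, 0)))


class TestFdrBH:
    def test_worked_step_up_example(self):
        q = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2], atol=1e-12)

    def test_single_pvalue_identity(self):
        assert fdr_bh([0.031])[0] == pytest.approx(0.031)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_never_decreases_and_permutation_equivariant(self, pvals):
        p = np.array(pvals)
        q = fdr_bh(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(fdr_bh(p[perm]), q[perm], atol=1e-12)


class TestPosthoc:
    def test_identical_groups_null_contrast(self, rng):
        base = rng.normal(size=30)
        y = np.concatenate([base, base, rng.normal(size=30) + 5])
        groups = np.repeat(["SZ", "BD", "HC"], 30)
        cov = np.zeros((90, 0))
        out = posthoc_pairwise(y, groups, cov, [0])
        row = out[(out.group1 == "SZ") & (out.group2 == "BD")].iloc[0]
        assert row.estimate == pytest.approx(0.0, abs=1e-10)
        assert row.p > 0.99

    def test_antisymmetry_under_relabeling(self, rng):
        y, groups, cov = _toy_data(rng, shift={"SZ": -1.0})
        out = posthoc_pairwise(y, groups, cov, [0])
        swapped = np.where(groups == "SZ", "HC", np.where(groups == "HC", "SZ", groups))
        out2 = posthoc_pairwise(y, swapped, cov, [0])
        e1 = out[(out.group1 == "SZ") & (out.group2 == "HC")].iloc[0].estimate
        e2 = out2[(out2.group1 == "SZ") & (out2.group2 == "HC")].iloc[0].estimate
        assert e1 == pytest.approx(-e2, rel=1e-10)

    def test_matches_statsmodels_contrast(self, rng):
        import statsmodels.formula.api as smf

        y, groups, cov = _toy_data(rng, shift={"SZ": -0.7})
        out = posthoc_pairwise(y, groups, cov, [0])
        df = cov.copy()
        df["y"] = y
        df["diagnosis"] = pd.Categorical(groups, categories=["SZ", "BD", "MDD", "HC"])
        fit = smf.ols("y ~ sex + age + education + head_motion + C(diagnosis)", df).fit()
        tt = fit.t_test("C(diagnosis)[T.HC] = 0")  # HC - SZ (reference)
        row = out[(out.group1 == "SZ") & (out.group2 == "HC")].iloc[0]
        assert row.estimate == pytest.approx(-float(tt.effect[0]), rel=1e-8)
        assert row.p == pytest.approx(float(tt.pvalue), rel=1e-6)

    def test_empty_detected_set(self, rng):
        y, groups, cov = _toy_data(rng)
        out = posthoc_pairwise(y, groups, cov, [])
        assert len(out) == 0

    def test_recovery_of_single_group_deficit(self, rng):
        """SZ-only deficit: SZ-HC contrast significant, BD-MDD not."""
        hits_sz, hits_bdmdd = 0, 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y, groups, cov = _toy_data(r, n_per=30, shift={"SZ": -1.0})
            out = posthoc_pairwise(y, groups, cov, [0])
            sz_hc = out[(out.group1 == "SZ") & (out.group2 == "HC")].iloc[0]
            bd_mdd = out[(out.group1 == "BD") & (out.group2 == "MDD")].iloc[0]
            hits_sz += sz_hc.q < 0.05
            hits_bdmdd += bd_mdd.q < 0.05
        assert hits_sz >= 9
        assert hits_bdmdd <= 1


class TestPartialCorrelation:
    def test_self_correlation(self, rng):
        x = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        r, p = partial_correlation(x, x, cov)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_orthogonal_covariates_equal_plain_pearson(self, rng):
        x, y = rng.normal(size=(2, 50))
        cov = rng.normal(size=(50, 2))
        # orthogonalize the covariates against [1, x, y]
        basis = np.column_stack([np.ones(50), x, y])
        cov = cov - basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
        r, _ = partial_correlation(x, y, cov)
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-10)

    def test_matches_double_residualization_oracle(self, rng):
        x, y = rng.normal(size=(2, 40))
        cov = rng.normal(size=(40, 3))
        r, p = partial_correlation(x, y, cov)
        # brute-force oracle: residualize each variable by explicit normal
        # equations, then plain Pearson
        d = np.column_stack([np.ones(40), cov])
        bx = np.linalg.solve(d.T @ d, d.T @ x)
        by = np.linalg.solve(d.T @ d, d.T @ y)
        r_ref = stats.pearsonr(x - d @ bx, y - d @ by).statistic
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(size=(2, 45))
        cov = rng.normal(size=(45, 2))
        r, p = partial_correlation(x, y, cov)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_insufficient_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            partial_correlation(np.ones(4), np.ones(4), rng.normal(size=(4, 2)))


class TestSummaryStatistics:
    def test_two_groups_equal_t_squared(self, rng):
        a, b = rng.normal(size=(2, 25))
        f, df1, df2 = anova_from_summary(
            [a.mean(), b.mean()], [a.std(ddof=1), b.std(ddof=1)], [25, 25]
        )
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert (df1, df2) == (1, 48)

    def test_equal_means_zero_f(self):
        f, _, _ = anova_from_summary([5.0, 5.0, 5.0], [1.0, 2.0, 1.5], [10, 12, 14])
        assert f == 0.0

    def test_degenerate_within_variance(self):
        f, _, _ = anova_from_summary([1.0, 2.0], [0.0, 0.0], [5, 5])
        assert np.isinf(f)

    def test_chi_square_brute_force_oracle(self):
        table = np.array([[10, 20], [20, 10]])
        chi2, df, p = chi_square_independence(table)
        # explicit expected-count oracle
        rows, cols, total = table.sum(1), table.sum(0), table.sum()
        expected = np.outer(rows, cols) / total
        chi2_ref = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(chi2_ref, rel=1e-12)
        assert df == 1

    def test_identical_row_proportions_zero(self):
        chi2, _, p = chi_square_independence([[10, 30], [20, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chi_square_independence([[0, 0], [5, 3]])
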