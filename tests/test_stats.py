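"""Factorial ANOVA, outlier screening and stomatal-conductance regressions."""

import numpy as np
import pandas as pd
import pytest

import tundraphys as tp
from tundraphys.stats import DegenerateDesignError


def balanced_2x2(values):
    """2x2 design with n=3 per cell; values is a flat list of 12."""
    rows = []
    it = iter(values)
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            for _ in range(3):
                rows.append({"fa": a, "fb": b, "y": next(it)})
    return pd.DataFrame(rows)


class TestFactorialAnova:
    def test_equal_cell_means_give_zero_f(self):
        # within-cell variance > 0, all four cell means exactly 10
        df = balanced_2x2([9, 10, 11, 9.5, 10, 10.5, 8, 10, 12, 9, 10, 11])
        t = tp.factorial_anova(df, "y", ["fa", "fb"])
        effects = t.table.drop(index="Residual")
        assert effects["F"].max() == pytest.approx(0.0, abs=1e-20)
        assert (effects["p"] > 0.999).all()

    def test_balanced_design_matches_direct_ss_formulas(self):
        vals = [12.1, 11.8, 12.5, 14.2, 13.9, 14.4,
                10.9, 11.2, 10.7, 15.8, 16.1, 15.5]
        df = balanced_2x2(vals)
        t = tp.factorial_anova(df, "y", ["fa", "fb"])
        y = df["y"].to_numpy()
        grand = y.mean()
        ma = df.groupby("fa")["y"].mean()
        mb = df.groupby("fb")["y"].mean()
        mab = df.groupby(["fa", "fb"])["y"].mean()
        ss_a = 6 * float(((ma - grand) ** 2).sum())
        ss_b = 6 * float(((mb - grand) ** 2).sum())
        ss_cells = 3 * float(((mab - grand) ** 2).sum())
        ss_ab = ss_cells - ss_a - ss_b
        ss_res = float(sum(
            ((g["y"] - g["y"].mean()) ** 2).sum()
            for _, g in df.groupby(["fa", "fb"])))
        assert t.table.loc["fa", "sum_sq"] == pytest.approx(ss_a)
        assert t.table.loc["fb", "sum_sq"] == pytest.approx(ss_b)
        assert t.table.loc["fa x fb", "sum_sq"] == pytest.approx(ss_ab)
        assert t.table.loc["Residual", "sum_sq"] == pytest.approx(ss_res)
        f_a = (ss_a / 1) / (ss_res / 8)
        assert t.table.loc["fa", "F"] == pytest.approx(f_a)

    def test_balanced_design_ss_type_invariance(self):
        df = balanced_2x2(list(np.random.default_rng(2).normal(10, 2, 12)))
        t2 = tp.factorial_anova(df, "y", ["fa", "fb"], ss_type=2)
        t1 = tp.factorial_anova(df, "y", ["fa", "fb"], ss_type=1)
        for term in ("fa", "fb", "fa x fb"):
            assert t2.table.loc[term, "sum_sq"] == pytest.approx(
                t1.table.loc[term, "sum_sq"])

    def test_unbalanced_matches_model_comparison_oracle(self):
        import statsmodels.formula.api as smf
        df = balanced_2x2(list(np.random.default_rng(4).normal(8, 1.5, 12)))
        df = df.iloc[:-1]  # one cell n=2
        t = tp.factorial_anova(df, "y", ["fa", "fb"])
        # Type II: each main effect vs the model with the other main effect
        full_main = smf.ols("y ~ C(fa) + C(fb)", df).fit()
        no_a = smf.ols("y ~ C(fb)", df).fit()
        assert t.table.loc["fa", "sum_sq"] == pytest.approx(
            no_a.ssr - full_main.ssr)

    def test_f_invariant_under_affine_rescaling(self):
        df = balanced_2x2(list(np.random.default_rng(6).normal(5, 1, 12)))
        t0 = tp.factorial_anova(df, "y", ["fa", "fb"])
        df2 = df.assign(y=3.7 * df["y"] - 11.0)
        t1 = tp.factorial_anova(df2, "y", ["fa", "fb"])
        for term in ("fa", "fb", "fa x fb"):
            assert t1.table.loc[term, "F"] == pytest.approx(
                t0.table.loc[term, "F"], rel=1e-9)

    def test_transform_applied_and_recorded(self):
        df = balanced_2x2(list(np.random.default_rng(8).uniform(80, 120, 12)))
        t = tp.factorial_anova(df, "y", ["fa", "fb"], transform="inv")
        t_manual = tp.factorial_anova(df.assign(y=1 / df["y"]), "y",
                                      ["fa", "fb"])
        assert t.transform == "inv"
        assert t.table.loc["fa", "F"] == pytest.approx(
            t_manual.table.loc["fa", "F"])

    def test_empty_cell_named_in_error(self):
        df = balanced_2x2(list(range(12)))
        df = df[~((df["fa"] == "a2") & (df["fb"] == "b2"))]
        with pytest.raises(DegenerateDesignError, match="a2"):
            tp.factorial_anova(df, "y", ["fa", "fb"])


class TestRemoveOutliers:
    def test_tight_cluster_unchanged(self):
        vals = [1.6, 1.7, 1.8, 1.7, 1.65]
        kept, removed = tp.remove_outliers(vals)
        assert kept == pytest.approx(vals)
        assert removed == []

    def test_single_extreme_value_removed(self):
        kept, removed = tp.remove_outliers([1.6, 1.7, 1.8, 1.7, 1.6, 9.9])
        assert removed == [9.9]
        assert len(kept) == 5

    def test_empty_input(self):
        assert tp.remove_outliers([]) == ([], [])

    def test_single_pass_no_rescreening(self):
        # after removing the extreme point, 3.0 would fall outside the
        # survivors' own 2 SD band; a single-pass screen keeps it
        vals = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 3.0, 50.0]
        kept, removed = tp.remove_outliers(vals)
        assert removed == [50.0]
        assert 3.0 in kept
        arr = np.asarray(kept)
        resid = np.abs(arr - arr.mean())
        assert (resid > 2 * arr.std(ddof=1)).any()  # would be re-flagged


class TestGsVpdRegression:
    def test_noiseless_line_recovered_exactly(self):
        d = np.linspace(0.8, 2.2, 12)
        gs = -60.67 * d + 232.0
        r = tp.gs_vpd_regression(list(zip(gs, d)))
        assert r.slope == pytest.approx(-60.67, abs=1e-10)
        assert r.intercept == pytest.approx(232.0, abs=1e-9)
        assert r.r2_adj == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0.8, 2.2, 40)
        gs = -60.67 * d + 232.0 + rng.normal(0, 55.0, 40)
        r = tp.gs_vpd_regression(list(zip(gs, d)))
        X = np.column_stack([np.ones_like(d), d])
        beta = np.linalg.solve(X.T @ X, X.T @ gs)
        assert r.intercept == pytest.approx(beta[0], rel=1e-10)
        assert r.slope == pytest.approx(beta[1], rel=1e-10)

    def test_noisy_slope_within_two_se_of_truth(self):
        rng = np.random.default_rng(10)
        d = rng.uniform(0.8, 2.2, 60)
        gs = -60.67 * d + 232.0 + rng.normal(0, 55.0, 60)
        r = tp.gs_vpd_regression(list(zip(gs, d)))
        assert abs(r.slope - (-60.67)) <= 2 * r.slope_se
        assert 0.0 < r.r2_adj < 0.5  # weak relationship by design

    def test_constant_d_is_singular(self):
        with pytest.raises(DegenerateDesignError):
            tp.gs_vpd_regression([(100.0, 1.5), (120.0, 1.5), (90.0, 1.5)])


class TestLeafTraits:
    def test_narea_from_sla_and_percent_n(self):
        # SLA 100 cm2/g = 0.01 m2/g; 1.8% N -> 0.018 g N per g / 0.01 m2/g
        assert tp.narea_from_traits(100.0, 1.8) == pytest.approx(1.8)
        lt = tp.LeafTraits("t1", "CF", "TL", "ambient", SLA=95.74,
                           percentN=1.8)
        assert lt.Narea == pytest.approx(0.018 / (95.74 / 1e4))

    def test_invalid_traits_rejected(self):
        with pytest.raises(ValueError):
            tp.LeafTraits("t1", "CF", "TL", "ambient", SLA=-5.0, percentN=2.0)
        with pytest.raises(ValueError):
            tp.LeafTraits("t1", "CF", "TL", "ambient", SLA=90.0,
                          percentN=150.0)
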