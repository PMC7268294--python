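"""Closed-form statistics: t-tests, RM/split-plot ANOVA, Lilliefors,
through-origin regression.

The ANOVA is validated against an independent orthogonal-projection oracle
(explicit contrast design matrices per stratum) and against third-party
implementations where they cover the design.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from splitbelt.stats import (StatError, lilliefors, lilliefors_null_distribution,
                             _lilliefors_D, one_sample_t, one_sample_t_bonferroni,
                             paired_t, regress_origin, rm_anova)


class TestPairedT:
    def test_null_case(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x[::-1])   # differences [-3,-1,1,3]: mean 0
        assert res.p == pytest.approx(1.0)
        assert res.t == 0.0
        assert res.cohens_d == 0.0

    def test_zero_variance_differences_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(StatError):
            paired_t(x, x)

    def test_hand_computed_example(self):
        """differences [2,-1,3,0,1]: t = 1/(sqrt(2.5)/sqrt(5)), d_z = 1/sqrt(2.5)."""
        y = np.zeros(5)
        x = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
        res = paired_t(x, y)
        assert res.t == pytest.approx(np.sqrt(2.0), abs=1e-10)
        assert res.df == 4
        assert res.cohens_d == pytest.approx(1 / np.sqrt(2.5), abs=1e-10)
        assert res.mean_diff == pytest.approx(1.0)

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t == pytest.approx(-b.t, abs=1e-12)
        assert a.cohens_d == pytest.approx(-b.cohens_d, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_n_one_rejected(self):
        with pytest.raises(StatError):
            paired_t([1.0], [2.0])


class TestOneSampleBonferroni:
    def test_centered_sample(self):
        res = one_sample_t_bonferroni([[-1.0, 1.0, -1.0, 1.0]], mu0=0.0)
        assert res[0].t == 0.0
        assert res[0].p_corrected == 1.0

    def test_m_equal_one_keeps_raw_p(self):
        rng = np.random.default_rng(2)
        sample = rng.normal(0.5, 1, 10)
        res = one_sample_t_bonferroni([sample], m=1)[0]
        assert res.p_corrected == pytest.approx(res.p)

    def test_multiplication_rule(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(0.8, 1, 10)
        raw = one_sample_t(sample).p
        res = one_sample_t_bonferroni([sample], m=4)[0]
        assert res.p_corrected == pytest.approx(min(1.0, 4 * raw))


# -- ANOVA oracle ------------------------------------------------------------

def orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels, levels-1) orthonormal columns spanning the space orthogonal
    to the constant vector (Helmert contrasts, normalized)."""
    c = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def projection_ss(y, factor_levels, effect):
    """SS of one effect via explicit orthonormal design-matrix projection.

    ``y`` is arranged with axes in factor order; ``effect`` is the set of
    factors participating (others contribute their normalized constant)."""
    mats = []
    for name, levels in factor_levels:
        if name in effect:
            mats.append(orthonormal_contrasts(levels))
        else:
            mats.append(np.full((levels, 1), 1.0 / np.sqrt(levels)))
    design = mats[0]
    for m in mats[1:]:
        design = np.kron(design, m)
    coeffs = design.T @ y.ravel()
    return float(np.sum(coeffs ** 2))


class TestRmAnova:
    def long_within(self, y, subjects, a_levels, b_levels=None):
        rows = []
        it = itertools.product(range(subjects), range(a_levels),
                               range(b_levels) if b_levels else [0])
        for (s, i, j), v in zip(it, y.ravel()):
            rows.append({"subject": f"S{s}", "A": f"a{i}", "B": f"b{j}", "value": v})
        return pd.DataFrame(rows)

    def test_identical_responses_give_zero_f(self):
        y = np.full((6, 2, 2), 3.14)
        df = self.long_within(y, 6, 2, 2)
        res = rm_anova(df, "value", "subject", within=["A", "B"])
        assert (res.effects["F"] == 0.0).all()

    def test_two_level_single_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        df = self.long_within(np.column_stack([x, y]), 12, 2)
        res = rm_anova(df, "value", "subject", within=["A"])
        t = paired_t(x, y)
        eff = res.effect("A")
        assert eff["F"] == pytest.approx(t.t ** 2, abs=1e-10)
        assert eff["p"] == pytest.approx(t.p, abs=1e-12)
        assert (eff["df_num"], eff["df_den"]) == (1, 11)

    def test_ss_decomposition_matches_projection_oracle(self):
        """Random balanced 12-subject 2x2 within design vs. the projection
        oracle, effect by effect, to 1e-8."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=(12, 2, 2))
        df = self.long_within(y, 12, 2, 2)
        res = rm_anova(df, "value", "subject", within=["A", "B"])
        factor_levels = [("subject", 12), ("A", 2), ("B", 2)]
        want = {
            "A": {"A"}, "B": {"B"}, "A*B": {"A", "B"}, "subject": {"subject"},
            "subject*A": {"subject", "A"}, "subject*B": {"subject", "B"},
            "subject*A*B": {"subject", "A", "B"},
        }
        strata = dict(zip(res.strata["stratum"], res.strata["ss"]))
        for name, effect in want.items():
            oracle = projection_ss(y, factor_levels, effect)
            assert strata[name] == pytest.approx(oracle, abs=1e-8), name
        assert res.strata["ss"].sum() == pytest.approx(res.ss_total, abs=1e-8)

    def test_three_level_factor_against_projection_oracle(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(8, 3, 2))
        df = self.long_within(y, 8, 3, 2)
        res = rm_anova(df, "value", "subject", within=["A", "B"])
        strata = dict(zip(res.strata["stratum"], res.strata["ss"]))
        fl = [("subject", 8), ("A", 3), ("B", 2)]
        assert strata["A"] == pytest.approx(projection_ss(y, fl, {"A"}), abs=1e-8)
        assert strata["subject*A"] == pytest.approx(
            projection_ss(y, fl, {"subject", "A"}), abs=1e-8)
        eff = res.effect("A")
        assert (eff["df_num"], eff["df_den"]) == (2, 14)

    def test_matches_pingouin_two_way_rm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        df = self.long_within(rng.normal(size=(10, 2, 2)), 10, 2, 2)
        res = rm_anova(df, "value", "subject", within=["A", "B"])
        ref = pg.rm_anova(data=df, dv="value", within=["A", "B"],
                          subject="subject", detailed=True)
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        for ours, theirs in (("A", "A"), ("B", "B"), ("A*B", "A * B")):
            eff = res.effect(ours)
            row = ref[ref["Source"] == theirs].iloc[0]
            assert eff["F"] == pytest.approx(row["F"], rel=1e-8)
            assert eff["p"] == pytest.approx(row[pcol], rel=1e-8)

    def test_mixed_design_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for g, group in enumerate(["g0", "g1"]):
            for s in range(8):
                for i, a in enumerate(["a0", "a1"]):
                    rows.append({"subject": f"{group}S{s}", "grp": group, "A": a,
                                 "value": rng.normal() + 0.5 * g + 0.3 * i})
        df = pd.DataFrame(rows)
        res = rm_anova(df, "value", "subject", within=["A"], between="grp")
        ref = pg.mixed_anova(data=df, dv="value", within="A", subject="subject",
                             between="grp")
        for ours, theirs in (("grp", "grp"), ("A", "A"), ("A*grp", "Interaction")):
            eff = res.effect(ours)
            row = ref[ref["Source"] == theirs].iloc[0]
            assert eff["F"] == pytest.approx(row["F"], rel=1e-8)
            assert (eff["df_num"], eff["df_den"]) == (row["DF1"], row["DF2"])

    def test_mixed_design_error_dfs(self):
        """Split-plot with 24 subject-units in 2 groups: between error df 22,
        each within effect tested on 22 df (the study's design)."""
        rng = np.random.default_rng(9)
        rows = []
        for group in ("dAdapt", "dPost"):
            for s in range(12):
                for slope in ("flat", "incline"):
                    for leg in ("paretic", "nonparetic"):
                        rows.append({"subject": f"{group}:{s}", "epoch": group,
                                     "slope": slope, "leg": leg,
                                     "value": rng.normal()})
        res = rm_anova(pd.DataFrame(rows), "value", "subject",
                       within=["slope", "leg"], between="epoch")
        for name in ("epoch", "slope", "leg", "slope*leg",
                     "slope*epoch", "leg*epoch", "slope*leg*epoch"):
            eff = res.effect(name)
            assert (eff["df_num"], eff["df_den"]) == (1, 22), name
        assert res.strata["ss"].sum() == pytest.approx(res.ss_total, rel=1e-10)

    def test_eta_squared_sums_below_one(self):
        rng = np.random.default_rng(10)
        df = self.long_within(rng.normal(size=(6, 2, 2)), 6, 2, 2)
        res = rm_anova(df, "value", "subject", within=["A", "B"])
        assert ((res.effects["eta_sq"] >= 0) & (res.effects["eta_sq"] <= 1)).all()

    def test_incomplete_subject_dropped(self):
        rng = np.random.default_rng(11)
        df = self.long_within(rng.normal(size=(8, 2, 2)), 8, 2, 2)
        df = df.drop(df.index[df["subject"] == "S0"][:1])
        res = rm_anova(df, "value", "subject", within=["A", "B"])
        # S0 dropped listwise -> 7 complete subjects
        assert res.effect("A")["df_den"] == 6


class TestLilliefors:
    def test_normal_quantile_sample_not_rejected(self):
        """Exact normal quantiles at (i-0.5)/n are as normal as possible."""
        from scipy import stats as sps
        n = 50
        sample = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        res = lilliefors(sample, n_replicates=2000, seed=0)
        assert res.p > 0.5

    def test_uniform_sample_rejected(self):
        """Power: a uniform sample of n=250 is rejected in > 90% of seeded
        runs (at n=100 the best-fit normal sits only ~0.04 away in sup norm,
        so power there is ~60%)."""
        rng = np.random.default_rng(12)
        rejected = 0
        for k in range(20):
            sample = rng.uniform(0, 1, 250)
            res = lilliefors(sample, n_replicates=500, seed=k)
            rejected += res.p <= 0.05
        assert rejected >= 18

    def test_constant_sample_rejected(self):
        with pytest.raises(StatError):
            lilliefors(np.ones(10))

    def test_statistic_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.diagnostic")
        rng = np.random.default_rng(13)
        sample = rng.normal(size=30)
        ours = lilliefors(sample, n_replicates=100, seed=0)
        d_ref, _ = sm.lilliefors(sample, dist="norm", pvalmethod="table")
        assert ours.D == pytest.approx(d_ref, abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 within [0.03, 0.07] under the null
        (2000 replicates of n = 24)."""
        rng = np.random.default_rng(14)
        null = lilliefors_null_distribution(24, 4999, rng)
        samples = rng.standard_normal((2000, 24))
        d = _lilliefors_D(samples)
        p = (1 + (null[None, :] >= d[:, None]).sum(axis=1)) / (len(null) + 1)
        rate = float(np.mean(p <= 0.05))
        assert 0.03 <= rate <= 0.07

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(15)
        sample = rng.normal(size=24)
        a = lilliefors(sample, n_replicates=500, seed=42)
        b = lilliefors(sample, n_replicates=500, seed=42)
        assert a.p == b.p and a.D == b.D


class TestRegressOrigin:
    def test_exact_fit(self):
        fit = regress_origin([1, 2, 3], [1, 2, 3])
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_hand_computed_slope(self):
        """points (1,2), (2,3), (3,4): a = (2 + 6 + 12)/(1 + 4 + 9) = 10/7."""
        fit = regress_origin([1, 2, 3], [2, 3, 4])
        assert fit.slope == pytest.approx(10 / 7, abs=1e-12)

    def test_se_ci_and_t_closed_form(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.3, 2.8, 4.2])
        fit = regress_origin(z, y)
        a = float(np.sum(z * y) / np.sum(z * z))
        sse = float(np.sum((y - a * z) ** 2))
        se = np.sqrt(sse / 3 / np.sum(z * z))
        from scipy import stats as sps
        tcrit = sps.t.ppf(0.975, 3)
        assert fit.slope == pytest.approx(a, abs=1e-12)
        assert fit.se == pytest.approx(se, abs=1e-12)
        assert fit.ci95[0] == pytest.approx(a - tcrit * se, abs=1e-10)
        assert fit.ci95[1] == pytest.approx(a + tcrit * se, abs=1e-10)
        assert fit.df == 3
        assert fit.ci95[0] < fit.slope < fit.ci95[1]

    def test_uncentered_r_squared(self):
        z = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 4.0])
        fit = regress_origin(z, y)
        a = 10 / 7
        r2 = 1 - np.sum((y - a * z) ** 2) / np.sum(y ** 2)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert 0 <= fit.r_squared <= 1

    def test_absolute_values_erase_sign(self):
        z = np.array([1.0, 2.0, 3.0])
        fit = regress_origin(z, -z, use_abs=True)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(16)
        z = rng.uniform(1, 10, 20)
        y = 2 * z + rng.normal(0, 0.5, 20)
        base = regress_origin(z, y).slope
        assert regress_origin(z, 3 * y).slope == pytest.approx(3 * base, rel=1e-10)
        assert regress_origin(5 * z, y).slope == pytest.approx(base / 5, rel=1e-10)

    def test_pearson_r_is_centered_correlation(self):
        rng = np.random.default_rng(17)
        z = rng.uniform(1, 10, 30)
        y = 1.2 * z + rng.normal(0, 1, 30)
        fit = regress_origin(z, y)
        # r is computed on the transformed (|z|, |y|) values
        assert fit.pearson_r == pytest.approx(
            np.corrcoef(np.abs(z), np.abs(y))[0, 1], abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(StatError):
            regress_origin([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        with pytest.raises(StatError):
            regress_origin([1.0, 2.0], [1.0, 2.0])
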