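"""Cohort statistics: outlier removal, ANOVA variants, and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from admodal.stats import (
    anova_twoway,
    perm_mixed_anova,
    rout_outliers,
    simple_main_effects,
    t_tests,
    tukey_hsd,
)
from admodal.synthdata import CohortSpec, gen_cohort

EFFECTS = ["genotype", "age", "genotype:age", "roi", "genotype:roi",
           "age:roi", "genotype:age:roi"]


class TestRout:
    def test_identical_values_yield_no_flags(self):
        assert not rout_outliers(np.array([5.0, 5.0, 5.0])).any()

    def test_extreme_contaminant_flagged(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10), [50.0]])
        flags = rout_outliers(x, q=0.01)
        assert flags[-1]
        assert flags.sum() == 1

    def test_false_flag_rate_controlled(self, rng):
        hits = sum(rout_outliers(rng.normal(0, 1, 12), 0.01).any()
                   for _ in range(300))
        assert hits / 300 <= 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rout_outliers(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            rout_outliers(np.ones(5), q=0.7)


class TestTTests:
    def test_identical_paired_sample_is_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = t_tests(a, a.copy(), paired=True)
        assert (r.t, r.p) == (0.0, 1.0)

    def test_constant_shift_paired_flagged_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = t_tests(a, a + 1.0, paired=True)
        assert r.note == "constant nonzero differences"
        assert np.isinf(r.t) and r.p == 0.0

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.3, 1.2, rng.integers(3, 12))
            r = t_tests(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            assert r.t == pytest.approx(t, abs=1e-12)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_paired_matches_scipy(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        r = t_tests(a, b, paired=True)
        ref = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestAnovaTwoway:
    @staticmethod
    def _table(rng, effect_a=0.0, n=6):
        rows = []
        for a in ("x", "y"):
            for b in ("u", "v"):
                for _ in range(n):
                    rows.append(dict(genotype=a, age=b,
                                     value=rng.normal((effect_a if a == "y" else 0), 1)))
        return pd.DataFrame(rows)

    def test_type_one_error_near_nominal(self):
        rejections = 0
        nsim = 300
        for s in range(nsim):
            df = self._table(np.random.default_rng(s))
            res = anova_twoway(df)
            rejections += res.p("genotype:age") < 0.05
        # binomial 95% band around 0.05 for 300 sims
        assert 0.02 <= rejections / nsim <= 0.09

    def test_pure_main_effect_leaves_interaction_null(self):
        fs = []
        for s in range(100):
            df = self._table(np.random.default_rng(1000 + s), effect_a=2.0)
            fs.append(anova_twoway(df).F("genotype:age"))
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_constant_factor_collapses_to_one_way(self, rng):
        df = self._table(rng, effect_a=1.0)
        df["age"] = "u"
        res = anova_twoway(df)
        groups = [g.value.to_numpy() for _, g in df.groupby("genotype")]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.F("genotype") == pytest.approx(f_ref, abs=1e-9)
        assert res.p("genotype") == pytest.approx(p_ref, abs=1e-9)

    def test_empty_cell_error_names_cell(self, rng):
        df = self._table(rng)
        df = df[~((df.genotype == "y") & (df.age == "v"))]
        with pytest.raises(ValueError, match="empty design cell"):
            anova_twoway(df)


class TestTukey:
    def test_two_groups_reduce_to_t_test(self, rng):
        df = pd.DataFrame({
            "group": ["a"] * 6 + ["b"] * 8,
            "value": np.concatenate([rng.normal(0, 1, 6), rng.normal(1, 1, 8)]),
        })
        res = tukey_hsd(df).table.iloc[0]
        t = t_tests(df[df.group == "a"].value.to_numpy(),
                    df[df.group == "b"].value.to_numpy())
        assert res["q"] == pytest.approx(abs(t.t) * np.sqrt(2), abs=1e-9)
        assert res["p_adj"] == pytest.approx(t.p, abs=1e-6)

    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"group": list("aabbcc") * 3,
                           "value": [1.0, 1.001] * 9})
        out = tukey_hsd(df).table
        assert (out.p_adj > 0.9).all()

    def test_adjusted_p_not_smaller_than_raw(self, rng):
        df = pd.DataFrame({
            "group": np.repeat(list("abcd"), 7),
            "value": rng.normal(0, 1, 28) + np.repeat([0, 0.5, 1, 0], 7),
        })
        out = tukey_hsd(df).table
        for _, row in out.iterrows():
            a = df[df.group == row.group1].value.to_numpy()
            b = df[df.group == row.group2].value.to_numpy()
            assert row.p_adj >= t_tests(a, b).p - 1e-9

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = pd.DataFrame({
            "group": np.repeat(list("abc"), 8),
            "value": rng.normal(0, 1, 24) + np.repeat([0, 0.8, 0.2], 8),
        })
        ours = tukey_hsd(df).table
        ref = pairwise_tukeyhsd(df.value, df.group)
        assert np.allclose(sorted(ours.p_adj), sorted(ref.pvalues), atol=1e-6)


class TestPermMixedAnova:
    def test_effect_detection_and_df(self):
        df = gen_cohort(CohortSpec(genotype_effect=0.4, seed=1))
        res = perm_mixed_anova(df, n_perm=500, seed=0)
        tab = res.table.set_index("effect")
        n_subj = df.subject_id.nunique()
        n_roi = df.roi.nunique()
        assert tab.loc["genotype", "df2"] == n_subj - 4
        assert tab.loc["roi", "df2"] == (n_roi - 1) * (n_subj - 4)
        assert res.p("genotype") < 0.05
        assert res.p("age") > 0.05

    def test_p_resolution_and_strict_definition(self):
        df = gen_cohort(CohortSpec(seed=2))
        res = perm_mixed_anova(df, n_perm=200, seed=3)
        for p in res.table.p:
            assert (round(p * 200) - p * 200) == pytest.approx(0.0, abs=1e-9)

    def test_shift_and_relabel_invariance(self):
        df = gen_cohort(CohortSpec(genotype_effect=0.15, seed=4))
        r1 = perm_mixed_anova(df, n_perm=300, seed=5)
        shifted = df.assign(value=df.value + 100.0)
        r2 = perm_mixed_anova(shifted, n_perm=300, seed=5)
        assert np.allclose(r1.table.p, r2.table.p)
        relabeled = df.assign(subject_id="subj_" + df.subject_id.str[1:])
        r3 = perm_mixed_anova(relabeled, n_perm=300, seed=5)
        assert np.allclose(r1.table.p, r3.table.p)

    def test_parametric_agreement_on_gaussian_data(self):
        pp, pq = [], []
        for s in range(40):
            eff = 0.05 * (s % 5)
            df = gen_cohort(CohortSpec(genotype_effect=eff, age_effect=eff / 2,
                                       seed=600 + s))
            res = perm_mixed_anova(df, n_perm=400, seed=s)
            pp.extend(res.table.p)
            pq.extend(res.table.p_parametric)
        rho = sps.spearmanr(pp, pq).statistic
        assert rho > 0.95

    def test_freedman_lane_scheme_runs_and_detects(self):
        df = gen_cohort(CohortSpec(genotype_effect=0.4, seed=6))
        res = perm_mixed_anova(df, n_perm=300, seed=7, scheme="freedman_lane")
        assert res.p("genotype") < 0.05
        assert res.p("genotype:age:roi") > 0.05

    def test_incomplete_within_design_rejected(self):
        df = gen_cohort(CohortSpec(seed=8))
        broken = df.drop(df[(df.subject_id == "s001") & (df.roi == "subiculum")].index)
        with pytest.raises(ValueError, match="complete"):
            perm_mixed_anova(broken, n_perm=100, seed=0)

    def test_minimum_permutations_enforced(self):
        df = gen_cohort(CohortSpec(seed=9))
        with pytest.raises(ValueError, match="n_perm"):
            perm_mixed_anova(df, n_perm=50, seed=0)

    def test_plus_one_estimator_option(self):
        df = gen_cohort(CohortSpec(seed=10))
        r = perm_mixed_anova(df, n_perm=200, seed=1, plus_one=True)
        assert (r.table.p > 0).all()


class TestSimpleMainEffects:
    def test_effect_localized_to_one_stratum(self):
        # age effect only in the first ROI
        spec = CohortSpec(n_per_group=8, seed=20,
                          roi_labels=("r1", "r2"), roi_effects=(0.0, 0.0))
        df = gen_cohort(spec)
        df.loc[(df.roi == "r1") & (df.age == "6M"), "value"] += 0.5
        out = simple_main_effects(df, factor="age", by="roi", n_perm=400,
                                  seed=2)
        assert out["r1"].p("age") < 0.05
        assert out["r2"].p("age") > 0.05

    def test_single_stratum_matches_restricted_anova(self):
        df = gen_cohort(CohortSpec(n_per_group=6, seed=21,
                                   genotype_effect=0.3))
        sub = df[df.roi == "subiculum"].copy()
        out = simple_main_effects(sub, factor="genotype", by="roi",
                                  n_perm=300, seed=4)
        collapsed = sub.groupby(["subject_id", "genotype"], observed=True) \
                       .value.mean().reset_index()
        direct = perm_mixed_anova(collapsed, n_perm=300, seed=4,
                                  between=("genotype",), within=None)
        assert out["subiculum"].F("genotype") == pytest.approx(
            direct.F("genotype"))

    def test_single_level_stratum_skipped_with_note(self):
        df = gen_cohort(CohortSpec(n_per_group=4, seed=22))
        df = df[df.genotype == "WT"]
        out = simple_main_effects(df, factor="genotype", by="roi",
                                  n_perm=200, seed=0)
        assert all(isinstance(v, str) and "skipped" in v for v in out.values())
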