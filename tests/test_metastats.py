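import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methtriage.metastats import (
    attenuation_summary,
    bh_fdr,
    bonferroni_threshold,
    filter_probes,
    fixed_effects_meta,
    genomic_lambda,
    heterogeneity,
    ks_uniformity,
    leave_one_out,
    meta_analyse,
    random_effects_meta,
)

estimate_lists = st.lists(
    st.tuples(
        st.floats(-5e-3, 5e-3, allow_nan=False),
        st.floats(1e-5, 1e-2, allow_nan=False, exclude_min=True),
    ),
    min_size=2,
    max_size=8,
)


class TestFilterProbes:
    def _annotation(self):
        rows = (
            [(f"ctrl{i}", "1", i, "control") for i in range(3)]
            + [(f"x{i}", "X", i, "cpg") for i in range(2)]
            + [(f"auto{i}", str(1 + i % 22), i, "cpg") for i in range(5)]
        )
        return pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "probe_class"])

    def test_controls_and_sex_chromosomes_removed(self):
        ann = self._annotation()
        tab = pd.DataFrame(
            {"probe_id": ann["probe_id"], "beta": 0.0, "se": 1.0, "pval": 0.5, "n": 100}
        )
        filtered, counts, coverage = filter_probes([tab], ann)
        assert counts == {"control": 3, "X": 2, "Y": 0}
        assert sorted(filtered[0]["probe_id"]) == [f"auto{i}" for i in range(5)]
        assert coverage.to_dict() == {1: 5}

    def test_probe_in_one_cohort_retained(self):
        ann = self._annotation()
        t1 = pd.DataFrame({"probe_id": ["auto0", "auto1"], "beta": 0.0, "se": 1.0,
                           "pval": 0.5, "n": 10})
        t2 = pd.DataFrame({"probe_id": ["auto0"], "beta": 0.0, "se": 1.0,
                           "pval": 0.5, "n": 10})
        filtered, _, coverage = filter_probes([t1, t2], ann)
        assert "auto1" in set(filtered[0]["probe_id"])
        assert coverage.to_dict() == {1: 1, 2: 1}

    def test_all_autosomal_identity(self):
        ann = self._annotation()
        tab = pd.DataFrame({"probe_id": [f"auto{i}" for i in range(5)], "beta": 0.0,
                            "se": 1.0, "pval": 0.5, "n": 10})
        filtered, counts, _ = filter_probes([tab], ann)
        assert len(filtered[0]) == 5 and sum(counts.values()) == 0

    def test_unannotated_probe_errors(self):
        ann = self._annotation()
        tab = pd.DataFrame({"probe_id": ["mystery"], "beta": 0.0, "se": 1.0,
                            "pval": 0.5, "n": 10})
        with pytest.raises(ValueError, match="unannotated"):
            filter_probes([tab], ann)


class TestFixedEffects:
    def test_single_study_identity(self):
        b, se, _ = fixed_effects_meta([(-7e-4, 1e-4)])
        assert b == -7e-4 and se == 1e-4

    def test_symmetric_pair_cancels(self):
        b, se, _ = fixed_effects_meta([(1e-3, 2e-4), (-1e-3, 2e-4)])
        assert b == pytest.approx(0.0, abs=1e-18)
        assert se == pytest.approx(2e-4 / np.sqrt(2), rel=1e-12)

    def test_hand_computed_three_study(self):
        # weights 4, 1, 16 -> pooled (4*1 + 1*2 + 0)/21 = 6/21
        b, se, p = fixed_effects_meta([(1.0, 0.5), (2.0, 1.0), (0.0, 0.25)])
        assert b == pytest.approx(6 / 21, abs=1e-12)
        assert se == pytest.approx(21**-0.5, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf((6 / 21) * np.sqrt(21)), rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(estimate_lists)
    def test_pooled_estimate_in_convex_hull_and_smallest_se(self, ests):
        b, se, _ = fixed_effects_meta(ests)
        betas = [e[0] for e in ests]
        assert min(betas) - 1e-12 <= b <= max(betas) + 1e-12
        assert se <= min(e[1] for e in ests) + 1e-15


class TestHeterogeneityAndRandomEffects:
    def test_identical_estimates(self):
        q, p, i2 = heterogeneity([(1e-3, 1e-4)] * 4)
        assert q == 0 and i2 == 0 and p == pytest.approx(1.0)

    def test_i2_floored_at_zero(self):
        # tiny spread: Q < k-1
        q, _, i2 = heterogeneity([(1.0, 1.0), (1.001, 1.0)])
        assert q < 1 and i2 == 0.0

    def test_hand_computed_two_study_q(self):
        ests = [(2.0, 1.0), (0.0, 1.0)]
        q, p, i2 = heterogeneity(ests)
        # w=1 each, pooled=1, Q = 1 + 1 = 2
        assert q == pytest.approx(2.0, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-12)
        assert i2 == pytest.approx(50.0, abs=1e-9)

    def test_homogeneous_re_equals_fe(self):
        ests = [(5e-4, 1e-4)] * 3
        tau2, b_re, se_re, _ = random_effects_meta(ests)
        b_fe, se_fe, _ = fixed_effects_meta(ests)
        assert tau2 == 0.0 and b_re == b_fe and se_re == se_fe

    def test_hand_computed_dersimonian_laird(self):
        ests = [(1.0, 0.5), (2.0, 1.0), (0.0, 0.25)]
        w = np.array([4.0, 1.0, 16.0])
        b = np.array([1.0, 2.0, 0.0])
        bfe = (w * b).sum() / w.sum()
        q = (w * (b - bfe) ** 2).sum()
        tau2_hand = max(0.0, (q - 2) / (w.sum() - (w**2).sum() / w.sum()))
        tau2, b_re, se_re, _ = random_effects_meta(ests)
        assert tau2 == pytest.approx(tau2_hand, abs=1e-12)
        ws = 1.0 / (np.array([0.5, 1.0, 0.25]) ** 2 + tau2_hand)
        assert b_re == pytest.approx((ws * b).sum() / ws.sum(), abs=1e-12)
        assert se_re == pytest.approx(ws.sum() ** -0.5, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(estimate_lists)
    def test_se_re_never_below_se_fe(self, ests):
        _, _, se_re, _ = random_effects_meta(ests)
        _, se_fe, _ = fixed_effects_meta(ests)
        assert se_re >= se_fe - 1e-15

    def test_matches_statsmodels_combine_effects(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        for _ in range(20):
            k = rng.integers(2, 8)
            b = rng.normal(0, 1e-3, k)
            se = rng.uniform(5e-5, 5e-4, k)
            ests = list(zip(b, se))
            res = combine_effects(b, se**2, method_re="dl")
            b_fe, se_fe, _ = fixed_effects_meta(ests)
            tau2, b_re, se_re, _ = random_effects_meta(ests)
            q, _, i2 = heterogeneity(ests)
            assert b_fe == pytest.approx(res.mean_effect_fe, rel=1e-10)
            assert se_fe == pytest.approx(res.sd_eff_w_fe, rel=1e-10)
            assert tau2 == pytest.approx(res.tau2, abs=1e-15)
            assert b_re == pytest.approx(res.mean_effect_re, rel=1e-10)
            assert q == pytest.approx(res.q, rel=1e-10)


class TestLeaveOneOut:
    def test_identical_pair_no_change(self):
        loo = leave_one_out([(1e-3, 1e-4), (1e-3, 1e-4)])
        np.testing.assert_allclose(loo["pct_change"], [0.0, 0.0], atol=1e-12)

    def test_two_studies_each_omission_gives_the_other(self):
        loo = leave_one_out([(1.0, 0.5), (3.0, 1.0)])
        np.testing.assert_allclose(loo["beta_fe_without"], [3.0, 1.0], atol=1e-12)

    def test_dominant_weight_study_has_largest_influence(self, rng):
        # brute-force over omissions: dropping the heaviest study moves most
        ests = [(1.0, 1.0), (1.5, 0.8), (-2.0, 0.05), (0.5, 1.2)]
        loo = leave_one_out(ests)
        brute = []
        for i in range(4):
            rest = [e for j, e in enumerate(ests) if j != i]
            b_wo, _, _ = fixed_effects_meta(rest)
            brute.append(b_wo)
        np.testing.assert_allclose(loo["beta_fe_without"], brute, atol=1e-12)
        assert loo["pct_change"].idxmax() == 2


class TestLambda:
    def test_chi_square_one_each(self):
        p1 = stats.chi2.sf(1.0, 1)
        lam = genomic_lambda([p1] * 10)
        assert lam == pytest.approx(1.0 / stats.chi2.ppf(0.5, 1), rel=1e-12)

    def test_uniform_null_near_one(self):
        lam = genomic_lambda(np.random.default_rng(1).random(100_000))
        assert 0.99 <= lam <= 1.01

    def test_exact_uniform_grid(self):
        p = (np.arange(1, 10_001) - 0.5) / 10_000
        assert genomic_lambda(p) == pytest.approx(1.0, abs=1e-3)


class TestMultiplicity:
    def test_bonferroni_examples(self):
        assert f"{bonferroni_threshold(473_864, 0.05):.3g}" == "1.06e-07"
        assert bonferroni_threshold(1, 0.05) == 0.05
        assert bonferroni_threshold(100, 0.05) == pytest.approx(5e-4)

    def test_bh_equal_pvalues(self):
        np.testing.assert_allclose(bh_fdr([0.02] * 5), [0.02] * 5)

    def test_bh_hand_step_up(self):
        # sorted ranked values 0.03, 0.045, 0.04; the step-up minimum from
        # the largest p enforces monotonicity, giving 0.03, 0.04, 0.04
        np.testing.assert_allclose(bh_fdr([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=40))
    def test_bh_monotone_in_sorted_p(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-15)
        # independent hand-coded step-up oracle
        p = np.asarray(ps)
        n = len(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.minimum(oracle, 1.0)
        np.testing.assert_allclose(q[order], oracle, atol=1e-12)


class TestAttenuation:
    def _table(self, betas, ses):
        return pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(betas))],
            "beta": betas, "se": ses,
        })

    def test_fifty_percent_attenuation(self):
        s, per = attenuation_summary(self._table([-1e-3], [1e-4]),
                                     self._table([-5e-4], [9e-5]))
        assert s["median_pct_change"] == pytest.approx(50.0)
        assert per["toward_null"].all() and s["n_precision_increased"] == 1

    def test_identical_tables(self):
        t = self._table([-1e-3, 2e-4], [1e-4, 2e-5])
        s, per = attenuation_summary(t, t)
        assert s["median_pct_change"] == 0.0
        assert s["n_toward_null"] == 0 and s["n_attenuated_10pct"] == 0


class TestKsUniformity:
    def test_exact_grid(self):
        n = 1000
        p = (np.arange(1, n + 1) - 0.5) / n
        d, pval = ks_uniformity(p)
        assert d == pytest.approx(1 / (2 * n), abs=1e-12)
        assert pval > 0.999

    def test_all_small_pvalues(self, rng):
        d, pval = ks_uniformity(rng.uniform(0, 0.05, 72))
        assert pval < 1e-10

    def test_matches_brute_force_ecdf_gap(self, rng):
        p = np.sort(rng.random(200))
        d, _ = ks_uniformity(p)
        n = len(p)
        gaps = np.maximum(np.arange(1, n + 1) / n - p, p - np.arange(0, n) / n)
        assert d == pytest.approx(gaps.max(), abs=1e-12)


class TestMetaAnalyse:
    def _tables(self, rng, k=4, m=30, missing=False):
        tabs = []
        for i in range(k):
            probes = [f"p{j}" for j in range(m)]
            t = pd.DataFrame({
                "probe_id": probes,
                "beta": rng.normal(0, 1e-3, m),
                "se": rng.uniform(5e-5, 5e-4, m),
                "pval": 0.5, "n": 100,
            })
            if missing and i == 0:
                t = t.iloc[: m // 2]
            tabs.append(t)
        return tabs

    def test_invariant_to_cohort_order(self, rng):
        tabs = self._tables(rng)
        a = meta_analyse(tabs, list("abcd"))
        b = meta_analyse(tabs[::-1], list("dcba"))
        pd.testing.assert_frame_equal(a, b)

    def test_rowwise_matches_scalar_ops(self, rng):
        tabs = self._tables(rng, k=3, m=10)
        res = meta_analyse(tabs).set_index("probe_id")
        for j in (0, 5, 9):
            ests = [(t.loc[j, "beta"], t.loc[j, "se"]) for t in tabs]
            b_fe, se_fe, p_fe = fixed_effects_meta(ests)
            q, p_het, i2 = heterogeneity(ests)
            tau2, b_re, se_re, _ = random_effects_meta(ests)
            row = res.loc[f"p{j}"]
            assert row["beta_fe"] == pytest.approx(b_fe, rel=1e-12)
            assert row["Q"] == pytest.approx(q, abs=1e-12)
            assert row["I2"] == pytest.approx(i2, abs=1e-9)
            assert row["tau2"] == pytest.approx(tau2, abs=1e-15)
            assert row["beta_re"] == pytest.approx(b_re, rel=1e-12)
            assert row["max_loo_pct_change"] == pytest.approx(
                leave_one_out(ests)["pct_change"].max(), rel=1e-9
            )

    def test_missing_probes_recorded_with_k(self, rng):
        tabs = self._tables(rng, k=3, m=20, missing=True)
        res = meta_analyse(tabs).set_index("probe_id")
        assert (res.loc["p15", "k"]) == 2
        assert (res.loc["p0", "k"]) == 3
        assert res["k"].between(1, 3).all()

    def test_k1_heterogeneity_missing(self, rng):
        t1 = pd.DataFrame({"probe_id": ["solo"], "beta": [1e-3], "se": [1e-4],
                           "pval": [0.5], "n": [50]})
        res = meta_analyse([t1]).set_index("probe_id")
        row = res.loc["solo"]
        assert row["beta_fe"] == pytest.approx(1e-3)
        assert np.isnan(row["Q"]) and np.isnan(row["beta_re"])

    def test_fe_ci_coverage_homogeneous(self, rng):
        # shared true effect, correct SEs: 95% CI coverage within the
        # exact binomial 99% band over 2,000 probes
        m, k, true = 2000, 5, 3e-4
        se = np.full((m, k), 1e-4)
        b = true + rng.normal(0, 1e-4, (m, k))
        tabs = [
            pd.DataFrame({"probe_id": [f"p{j:05d}" for j in range(m)],
                          "beta": b[:, i], "se": se[:, i], "pval": 0.5, "n": 100})
            for i in range(k)
        ]
        res = meta_analyse(tabs)
        cover = ((res["beta_fe"] - 1.96 * res["se_fe"] <= true)
                 & (true <= res["beta_fe"] + 1.96 * res["se_fe"])).sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], m, 0.95)
        assert lo <= cover <= hi
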