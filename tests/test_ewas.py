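import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtriage.deconv import estimate_cell_proportions, select_discriminating_sites
from methtriage.ewas import (
    EwasError,
    ModelSpec,
    encode_exposure,
    huber_fit,
    qc_exposure,
    run_ewas,
)
from methtriage.simcohort import simulate_consortium
from conftest import NULL_FRACTIONS, small_config


class TestExposureQc:
    def test_gross_outlier_flagged(self, rng):
        x = rng.normal(24, 4, 500)
        x[17] = 80.0  # ~14 SD
        flags = qc_exposure(x)
        assert flags[17] and flags.sum() == 1

    def test_no_outliers_empty(self, rng):
        assert qc_exposure(rng.normal(24, 1, 100)).sum() == 0

    def test_constant_vector_errors(self):
        with pytest.raises(EwasError):
            qc_exposure(np.full(10, 24.0))


class TestExposureEncoding:
    @pytest.mark.parametrize(
        "bmi,mode,code,included",
        [
            (25.0, "overweight_obese_vs_normal", 1.0, True),  # boundary: >= 25.0
            (17.0, "overweight_obese_vs_normal", None, False),
            (18.5, "overweight_obese_vs_normal", 0.0, True),
            (16.0, "underweight_vs_normal", 1.0, True),
            (30.0, "underweight_vs_normal", None, False),
        ],
    )
    def test_who_category_rules(self, bmi, mode, code, included):
        codes, mask = encode_exposure(np.array([bmi]), mode)
        assert bool(mask[0]) is included
        if included:
            assert codes[0] == code

    def test_underweight_set(self):
        codes, mask = encode_exposure(np.array([16.0, 20.0, 30.0]), "underweight_vs_normal")
        assert mask.tolist() == [True, True, False]
        assert codes[mask].tolist() == [1.0, 0.0]

    def test_continuous_is_identity(self):
        x = np.array([20.0, np.nan, 31.2])
        codes, mask = encode_exposure(x, "continuous")
        assert mask.tolist() == [True, False, True]
        np.testing.assert_array_equal(codes[mask], [20.0, 31.2])


def _oracle_huber_irls(x, y, c=1.345, tol=1e-12, max_iter=500):
    """Independent plain-loop IRLS with the same model definition."""
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    for _ in range(max_iter):
        r = y - x @ beta
        s = np.median(np.abs(r)) / 0.6745
        if s == 0:
            break
        w = np.minimum(1.0, c * s / np.where(np.abs(r) > 0, np.abs(r), np.inf))
        wx = x * w[:, None]
        beta_new = np.linalg.solve(x.T @ wx, wx.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestHuberFit:
    def test_equals_ols_on_clean_data(self, rng):
        # bounded noise: no residual exceeds c * scale, so every weight is 1
        x = np.column_stack([np.ones(100), rng.normal(25, 4, 100)])
        noise = 1e-4 * rng.choice([-1.0, 1.0], 100) * rng.uniform(0.4, 0.6, 100)
        y = 0.4 + 0.002 * x[:, 1] + noise
        b, _, conv = huber_fit(x, y)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert conv
        np.testing.assert_allclose(b, ols, rtol=1e-6)

    def test_constant_outcome(self, rng):
        x = np.column_stack([np.ones(50), rng.normal(0, 1, 50)])
        b, _, conv = huber_fit(x, np.full(50, 0.73))
        assert conv
        np.testing.assert_allclose(b, [0.73, 0.0], atol=1e-12)

    def test_outliers_matches_oracle_and_beats_ols(self, rng):
        n = 200
        x = np.column_stack([np.ones(n), rng.normal(25, 4, n)])
        true_slope = 1e-3
        y = 0.5 + true_slope * (x[:, 1] - 25) + rng.normal(0, 0.02, n)
        out = rng.random(n) < 0.05
        y[out] += 0.5
        b, _, conv = huber_fit(x, y, tol=1e-12, max_iter=500)
        assert conv
        oracle = _oracle_huber_irls(x, y)
        np.testing.assert_allclose(b, oracle, atol=1e-8)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert abs(b[1] - true_slope) < abs(ols[1] - true_slope)

    def test_matches_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        n = 150
        x = np.column_stack([np.ones(n), rng.normal(0, 1, n), rng.normal(0, 1, n)])
        y = 1.0 + 0.3 * x[:, 1] - 0.2 * x[:, 2] + rng.standard_t(3, n) * 0.1
        b, se, _ = huber_fit(x, y, tol=1e-10, max_iter=300)
        ref = sm.RLM(y, x, M=sm.robust.norms.HuberT(1.345)).fit(
            scale_est="mad", conv="coefs", tol=1e-10, maxiter=300
        )
        np.testing.assert_allclose(b, ref.params, atol=1e-6)
        np.testing.assert_allclose(se, ref.bse, rtol=1e-3)

    def test_rank_deficiency_names_columns(self, rng):
        x = np.column_stack([np.ones(30), rng.normal(0, 1, 30)])
        x = np.column_stack([x, x[:, 1]])
        with pytest.raises(EwasError, match="collinear"):
            huber_fit(x, rng.normal(0, 1, 30), column_names=["intercept", "a", "a_copy"])


class TestRunEwas:
    def test_recovers_planted_effect_within_three_se(self):
        cfg = small_config(
            n_cohorts=1, n_per_cohort=2000, n_probes=300, noise_sd=0.01,
            comp_shift=0.0, causal_beta=-1e-3,
            effect_class_fractions={"null": 0.9, "causal": 0.1},
        )
        cohorts, truth, _ = simulate_consortium(cfg)
        tab = run_ewas(cohorts[0], ModelSpec(adjust_cells=False)).set_index("probe_id")
        sub = tab.loc[truth.probes_of_class("causal")]
        assert (np.abs(sub["beta"] - (-1e-3)) < 3 * sub["se"]).mean() > 0.99

    def test_mutual_parental_two_rows_per_probe(self, small_consortium):
        cohorts, _, _ = small_consortium
        tab = run_ewas(cohorts[0], ModelSpec(exposure_mode="mutual_parental",
                                             adjust_cells=False))
        counts = tab.groupby("probe_id")["exposure"].agg(lambda s: sorted(set(s)))
        assert (counts.apply(lambda v: v == ["maternal", "paternal"])).all()

    def test_cell_adjustment_attenuates_cell_mediated_probes(self):
        cfg = small_config(
            n_cohorts=1, n_per_cohort=2000, n_probes=1000,
            effect_class_fractions={"null": 0.95, "cell_mediated_only": 0.05},
        )
        cohorts, truth, ref = simulate_consortium(cfg)
        c = cohorts[0]
        sites = select_discriminating_sites(ref, 120)
        props = estimate_cell_proportions(c.beta, ref, sites).proportions
        adj = run_ewas(c, ModelSpec(adjust_cells=True), props).set_index("probe_id")
        unadj = run_ewas(c, ModelSpec(adjust_cells=False)).set_index("probe_id")
        probes = truth.probes_of_class("cell_mediated_only")
        frac_atten = (np.abs(adj.loc[probes, "beta"])
                      < np.abs(unadj.loc[probes, "beta"])).mean()
        assert frac_atten > 0.9

    def test_invariant_to_sample_order(self, small_consortium, rng):
        cohorts, _, _ = small_consortium
        c = cohorts[0]
        tab = run_ewas(c, ModelSpec(adjust_cells=False))
        perm = rng.permutation(len(c.beta))
        from methtriage.simcohort import CohortDataset

        shuffled = CohortDataset(
            name=c.name, beta=c.beta.iloc[perm], phenotypes=c.phenotypes.iloc[perm],
            genotypes=c.genotypes.iloc[perm], true_props=c.true_props.iloc[perm],
        )
        tab2 = run_ewas(shuffled, ModelSpec(adjust_cells=False))
        np.testing.assert_allclose(tab["beta"], tab2["beta"], atol=1e-12)
        np.testing.assert_allclose(tab["se"], tab2["se"], atol=1e-12)

    def test_orthogonal_covariate_leaves_estimate_unchanged(self, rng):
        # noise-free linear outcome; an orthogonal regressor cannot move the slope
        n = 64
        bmi = rng.normal(25, 4, n)
        extra = rng.normal(0, 1, n)
        extra -= extra.mean()
        bmi_c = bmi - bmi.mean()
        extra -= (extra @ bmi_c) / (bmi_c @ bmi_c) * bmi_c  # orthogonalise
        y = 0.5 + 2e-3 * bmi
        x1 = np.column_stack([np.ones(n), bmi])
        x2 = np.column_stack([x1, extra])
        b1, _, _ = huber_fit(x1, y)
        b2, _, _ = huber_fit(x2, y)
        assert abs(b1[1] - b2[1]) < 1e-10

    def test_null_pvalues_uniform_ks(self):
        cfg = small_config(
            n_cohorts=1, n_per_cohort=300, n_probes=2000, comp_shift=0.0,
            effect_class_fractions=dict(NULL_FRACTIONS),
        )
        cohorts, _, _ = simulate_consortium(cfg)
        tab = run_ewas(cohorts[0], ModelSpec(adjust_cells=False))
        d = stats.kstest(tab["pval"], "uniform").statistic
        assert d < 0.05

    def test_adjust_cells_requires_props(self, small_consortium):
        cohorts, _, _ = small_consortium
        with pytest.raises(EwasError):
            run_ewas(cohorts[0], ModelSpec(adjust_cells=True))
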