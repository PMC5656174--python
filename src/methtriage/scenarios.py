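"""Reference evaluation scenarios for the synthetic consortium.

Each scenario builds a consortium under stated study conditions, runs the
pipeline machinery on it, and returns the headline recovery metrics.  They
are used by the benchmark script and the acceptance test suite; sizes are
desk-scale (see the methods note) and every scenario is fully seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .deconv import estimate_cell_proportions, select_discriminating_sites
from .ewas import ModelSpec, run_ewas
from .metastats import bonferroni_threshold, genomic_lambda, meta_analyse, attenuation_summary
from .pipeline import build_meqtl_catalog, evaluate_against_truth, parental_meta
from .simcohort import SimConfig, simulate_consortium
from .triangulate import classify_negative_control, triangulate_verdicts

__all__ = [
    "scenario_parameter_recovery",
    "scenario_type_i_control",
    "scenario_attenuation",
    "scenario_triangulation",
    "scenario_deconvolution",
]

_NULL_ONLY = {"null": 1.0, "causal": 0.0, "cell_mediated_only": 0.0,
              "genetic_confound": 0.0, "familial_confound": 0.0}


def _cell_adjusted_tables(cohorts, reference, sites_per_type=50):
    sites = select_discriminating_sites(
        reference, min(sites_per_type * reference.n_celltypes, reference.n_probes)
    )
    tabs = []
    for c in cohorts:
        props = estimate_cell_proportions(c.beta, reference, sites).proportions
        tabs.append(run_ewas(c, ModelSpec(adjust_cells=True), props))
    return tabs


def scenario_parameter_recovery(seed: int) -> dict:
    """Recovery of a planted -1e-3 beta/kg/m^2 effect at 50 CpGs.

    Five cohorts of 300 with 20,000 probes and noise SD 0.02; reports the
    mean bias of the meta-analysed causal estimates (as % of the true
    effect) and the empirical 95% CI coverage over the causal probes.
    """
    true_beta = -1e-3
    cfg = SimConfig(
        n_cohorts=5, n_per_cohort=300, n_probes=20_000, seed=seed,
        noise_sd=0.02, comp_shift=0.0, causal_beta=true_beta,
        effect_class_fractions={**_NULL_ONLY, "null": 0.9975, "causal": 0.0025},
    )
    cohorts, truth, reference = simulate_consortium(cfg)
    tabs = _cell_adjusted_tables(cohorts, reference)
    meta = meta_analyse(tabs).set_index("probe_id")
    sub = meta.loc[truth.probes_of_class("causal")]
    bias_pct = float(100.0 * (sub["beta_fe"] - true_beta).mean() / abs(true_beta))
    lo = sub["beta_fe"] - 1.96 * sub["se_fe"]
    hi = sub["beta_fe"] + 1.96 * sub["se_fe"]
    coverage = float(((lo <= true_beta) & (true_beta <= hi)).mean())
    return {
        "n_causal": int(len(sub)),
        "mean_bias_pct": bias_pct,
        "ci95_coverage": coverage,
    }


def scenario_type_i_control(seed: int, n_reps: int = 200) -> dict:
    """Family-wise error of the Bonferroni rule under the global null.

    ``n_reps`` independent null consortia (3 cohorts x 300, 2,000 probes, no
    planted effects, no composition tilt); reports the fraction of replicates
    with any Bonferroni hit in the fixed-effects meta-analysis and the
    per-cohort genomic inflation (median over replicates).
    """
    root = np.random.SeedSequence(seed, spawn_key=(101,))
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]
    n_cohorts = 3
    fwer_hits = 0
    lams = np.empty((n_reps, n_cohorts))
    for r, s in enumerate(rep_seeds):
        cfg = SimConfig(
            n_cohorts=n_cohorts, n_per_cohort=300, n_probes=2_000, seed=s,
            comp_shift=0.0, effect_class_fractions=dict(_NULL_ONLY),
            n_discriminating_per_type=20,
        )
        cohorts, _, reference = simulate_consortium(cfg)
        tabs = _cell_adjusted_tables(cohorts, reference, sites_per_type=20)
        for i, t in enumerate(tabs):
            lams[r, i] = genomic_lambda(t["pval"].dropna())
        meta = meta_analyse(tabs)
        thr = bonferroni_threshold(len(meta), 0.05)
        fwer_hits += int((meta["p_fe"] < thr).any())
    med = np.median(lams, axis=0)
    return {
        "n_reps": n_reps,
        "fwer": fwer_hits / n_reps,
        "lambda_per_cohort": [float(v) for v in med],
        "lambda_min": float(med.min()),
        "lambda_max": float(med.max()),
    }


def scenario_attenuation(seed: int) -> dict:
    """Cell-composition mediation with no direct effects.

    Five cohorts x 300 with 10,000 probes; 5% of probes are cell-mediated
    (composition tilt 0.01 per kg/m^2 on the designated type) and the rest
    null.  Reports the median attenuation of the unadjusted-significant
    probes after cell adjustment and the fraction shifting toward the null.
    """
    cfg = SimConfig(
        n_cohorts=5, n_per_cohort=300, n_probes=10_000, seed=seed,
        comp_shift=0.01,
        effect_class_fractions={**_NULL_ONLY, "null": 0.95, "cell_mediated_only": 0.05},
    )
    cohorts, truth, reference = simulate_consortium(cfg)
    sites = select_discriminating_sites(reference, 50 * reference.n_celltypes)
    adj, unadj = [], []
    for c in cohorts:
        props = estimate_cell_proportions(c.beta, reference, sites).proportions
        adj.append(run_ewas(c, ModelSpec(adjust_cells=True), props))
        unadj.append(run_ewas(c, ModelSpec(adjust_cells=False)))
    meta_adj = meta_analyse(adj)
    meta_un = meta_analyse(unadj)
    thr = bonferroni_threshold(len(meta_un), 0.05)
    hits = meta_un.loc[meta_un["p_fe"] < thr, "probe_id"]
    summary, _ = attenuation_summary(meta_un, meta_adj, hits)
    return {
        "n_significant_unadjusted": int(len(hits)),
        "median_attenuation_pct": summary["median_pct_change"],
        "frac_toward_null": summary["n_toward_null"] / max(len(hits), 1),
        "lambda_unadjusted": genomic_lambda(meta_un["p_fe"]),
        "lambda_adjusted": genomic_lambda(meta_adj["p_fe"]),
    }


def scenario_triangulation(seed: int, n_reps: int = 3) -> dict:
    """Negative-control + meQTL classification against planted truth.

    Each replicate consortium has three cohorts of 1,500 trios and 2,000
    probes: 50 causal (-1e-3 beta per kg/m^2), 50 genetic-confound, 100
    familial-confound.  Counts are pooled over ``n_reps`` independent
    replicates because classification errors within one consortium share
    the family-level latent draws (a single replicate's specificity is a
    noisy estimate of the rule's operating point).  Reports sensitivity and
    specificity of the final causal call under the default sign direction
    rule and under the significant-opposition option.
    """
    root = np.random.SeedSequence(seed, spawn_key=(103,))
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]
    tallies = {rule: {"tp": 0, "n_causal": 0, "tn": 0, "n_confound": 0}
               for rule in ("sign", "significant_opposition")}
    for s in rep_seeds:
        cfg = SimConfig(
            n_cohorts=3, n_per_cohort=1_500, n_probes=2_000, seed=s,
            causal_beta=-1e-3, n_discriminating_per_type=20,
            effect_class_fractions={
                "null": 0.90, "causal": 0.025, "cell_mediated_only": 0.0,
                "genetic_confound": 0.025, "familial_confound": 0.05,
            },
        )
        cohorts, truth, reference = simulate_consortium(cfg)
        sites = select_discriminating_sites(reference, 20 * reference.n_celltypes)
        muts = []
        for c in cohorts:
            props = estimate_cell_proportions(c.beta, reference, sites).proportions
            muts.append(run_ewas(c, ModelSpec(exposure_mode="mutual_parental",
                                              adjust_cells=True), props))
        pe = parental_meta(muts)
        catalog = build_meqtl_catalog(cohorts, truth, cfg.seed)
        for rule in tallies:
            verdicts = classify_negative_control(pe, 40.0, rule)
            report, _ = triangulate_verdicts(verdicts, catalog)
            ev = evaluate_against_truth(report, truth)
            t = tallies[rule]
            t["tp"] += round(ev["sensitivity"] * ev["n_causal_evaluated"])
            t["n_causal"] += ev["n_causal_evaluated"]
            t["tn"] += round(ev["specificity"] * ev["n_confound_evaluated"])
            t["n_confound"] += ev["n_confound_evaluated"]
    out = {
        "n_causal": tallies["sign"]["n_causal"],
        "n_confound": tallies["sign"]["n_confound"],
    }
    for rule, label in (("sign", ""), ("significant_opposition", "_sig_opposition")):
        t = tallies[rule]
        out[f"sensitivity{label}"] = t["tp"] / t["n_causal"]
        out[f"specificity{label}"] = t["tn"] / t["n_confound"]
    return out


def scenario_deconvolution(seed: int) -> dict:
    """Noise-free exactness and noisy accuracy of proportion recovery."""
    from .simcohort import simulate_reference

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(102,)))
    reference = simulate_reference(600, 6, 50, seed=seed)
    true = rng.dirichlet(np.full(6, 10.0), size=200)
    clean = true @ reference.profiles.T
    idx = [f"s{i}" for i in range(200)]
    beta0 = pd.DataFrame(clean, index=idx, columns=reference.probe_ids)
    est0 = estimate_cell_proportions(beta0, reference, reference.probe_ids,
                                     constraint="simplex")
    max_err = float(np.abs(est0.proportions.to_numpy() - true).max())
    noisy = np.clip(clean + rng.normal(0, 0.02, clean.shape), 0, 1)
    beta1 = pd.DataFrame(noisy, index=idx, columns=reference.probe_ids)
    est1 = estimate_cell_proportions(beta1, reference, reference.probe_ids,
                                     constraint="simplex")
    rmse = float(np.sqrt(np.mean((est1.proportions.to_numpy() - true) ** 2)))
    return {"noise_free_max_error": max_err, "noisy_rmse": rmse}
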