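"""Inverse-variance meta-analysis across cohorts with diagnostics.

Pools per-cohort EWAS tables (fixed and DerSimonian-Laird random effects),
reports heterogeneity and leave-one-out influence at the top hit, and the
Bonferroni accounting.
"""

from methtriage import (
    ModelSpec,
    SimConfig,
    bonferroni_threshold,
    genomic_lambda,
    meta_analyse,
    run_ewas,
    simulate_consortium,
)

cfg = SimConfig(
    n_cohorts=4, n_per_cohort=400, n_probes=3000, seed=23,
    causal_beta=-1e-3, comp_shift=0.0, n_discriminating_per_type=20,
    effect_class_fractions={"null": 0.98, "causal": 0.02},
)
cohorts, truth, reference = simulate_consortium(cfg)
tables = [run_ewas(c, ModelSpec(adjust_cells=False)) for c in cohorts]

meta = meta_analyse(tables, [c.name for c in cohorts])
thr = bonferroni_threshold(len(meta), 0.05)
hits = meta[meta["p_fe"] < thr]
print(f"{len(meta)} probes meta-analysed over {len(cohorts)} cohorts")
print(f"bonferroni threshold 0.05/{len(meta)} = {thr:.3g}; {len(hits)} hits")
print(f"meta-analysis lambda: {genomic_lambda(meta['p_fe']):.3f} "
      "(median-based, barely moved by the sparse planted signal)")

top = meta.loc[meta["p_fe"].idxmin()]
print(
    f"top hit {top['probe_id']}: beta_FE={top['beta_fe']:.2e} "
    f"(SE {top['se_fe']:.1e}), p={top['p_fe']:.2e}, I2={top['I2']:.0f}%, "
    f"tau2={top['tau2']:.2e}, max leave-one-out change {top['max_loo_pct_change']:.1f}%"
)
# I2 near 0 and a small leave-one-out change mean the pooled effect is not
# driven by heterogeneity or any single cohort
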