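"""Simulate a small mother-father-child methylation consortium.

Builds two cohorts with every effect class planted and prints the structure
the downstream analysis relies on: beta range, cell-proportion simplex,
parental BMI correlation (assortative mating) and the planted class counts.
"""

import numpy as np
from scipy import stats

from methtriage import SimConfig, simulate_consortium

cfg = SimConfig(
    n_cohorts=2, n_per_cohort=500, n_probes=2000, seed=42,
    n_discriminating_per_type=20,
    effect_class_fractions={
        "null": 0.90, "causal": 0.025, "cell_mediated_only": 0.025,
        "genetic_confound": 0.025, "familial_confound": 0.025,
    },
)
cohorts, truth, reference = simulate_consortium(cfg)

c = cohorts[0]
print(f"cohort {c.name}: {c.beta.shape[0]} samples x {c.beta.shape[1]} probes")
print(f"beta range: [{c.beta.to_numpy().min():.3f}, {c.beta.to_numpy().max():.3f}]"
      "  (methylation proportions, clipped to [0.001, 0.999])")
print("cell proportions row sums:",
      np.round(c.true_props.sum(axis=1).describe()[["min", "max"]].to_numpy(), 6))
rho = stats.spearmanr(c.phenotypes["maternal_bmi"], c.phenotypes["paternal_bmi"]).statistic
print(f"maternal-paternal BMI Spearman rho: {rho:.3f}  (assortative mating, target 0.20)")
print("planted effect classes:", truth.table["class"].value_counts().to_dict())
# each class count sets how many probes carry that confounding mechanism;
# the truth table is the oracle every recovery test scores against
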