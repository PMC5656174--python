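# Methods

This note documents the models, conventions and design choices behind
`methtriage`: the synthetic consortium generator, the per-cohort EWAS, the
meta-analysis layer, and the causal-triangulation rules. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic consortium model

### Families and exposures

Each cohort is a set of independent mother–father–child trios. Per family:

- a shared latent environment `U ~ N(0, familial_sd²)`;
- parental genotypes `G ~ Binomial(2, p)` at each confounding SNP, with the
  child receiving one allele from each parent (Mendelian transmission, so
  child genotypes are Hardy–Weinberg and parent–child genotype correlation
  is 1/2);
- maternal and paternal BMI built as
  `BMI = bmi_mean + σ_resid·z + λ_B·U + κ·Σ(G − 2p)` where `(z_m, z_p)` is
  a Gaussian copula. The residual correlation and `σ_resid` are solved so
  that the **total** parental BMI correlation equals `parental_rho` and the
  total SD equals `bmi_sd`, i.e. the shared-environment and genetic
  contributions are accounted into, not added on top of, the configured
  moments. This is what makes the generator's realized Spearman correlation
  match the configured 0.20 at large n.

### Cell composition

Base proportions follow a Dirichlet around adult-blood-like means
(granulocytes 0.55, CD4 0.15, CD8 0.08, B 0.08, NK 0.06, monocytes 0.08;
concentration 60, giving a realistic ±6% granulocyte SD). The composition–
exposure link is a log-space tilt of the designated type (default
granulocytes) by `comp_shift·(BMI − cohort mean)` followed by softmax
renormalisation. `comp_shift` defaults to 0.01 per kg/m²: a forward
calculation (`Δbeta ≈ contrast · π(1−π) · comp_shift`) puts the induced
association at a 0.4-contrast marker probe near 1e-3 beta per kg/m², the
top of the published effect range. Setting `comp_shift = 0` reproduces the
observed near-independence of estimated cell counts and maternal BMI.

### Methylation and effect classes

Per sample, probe means are the reference-profile mixture `π·Rᵀ` plus
class-specific terms, plus `N(0, noise_sd²)` noise (default 0.02 beta —
typical within-probe variability), clipped to [0.001, 0.999]. Noise is
additive on the beta scale because the analysis itself runs on untransformed
betas; a logit-scale noise model would decouple the simulation from the
analysis scale. The five classes:

| class | mechanism | default fraction |
|---|---|---|
| null | none | 0.985 |
| causal | `causal_beta·(maternal BMI − mean)` direct on child methylation | 0.0025 |
| cell_mediated_only | probe is a designated-type marker; association flows only through composition | 0.005 |
| genetic_confound | SNP with `snp_bmi_effect` = 0.4 kg/m² per allele on both parents' BMI and `snp_meth_effect` = 0.2 beta per child allele (an FTO-scale BMI variant paired with a strong meQTL, so the induced confounded slope lands in the published 1e-4–1.5e-3 range) | 0.0025 |
| familial_confound | `U` loads 1.6 kg/m² on each parent's BMI and 0.01 beta on child methylation | 0.005 |

Causal betas draw uniformly from `causal_beta_range` (default −1.5e-3 to
+1.3e-3 beta per kg/m², covering the published extremes) unless a fixed
`causal_beta` is configured. The paper-scale attenuation of direct effects
by adolescence is a division of `causal_beta` by `attenuation_factor`
(default 2.25) in independent follow-up cohorts drawn from a separate seed
stream; confounding mechanisms are left untouched, since genetics and
family environment persist.

Cell-mediated probes are *realised* as reference markers of the designated
cell type. Marker probes of the other K−1 types are labelled null but
flagged `composition_sensitive` in the truth table, because the softmax
renormalisation gives them a smaller compensatory BMI association whenever
the tilt is active; calibration checks under an active tilt should exclude
them (the global-null scenario sets the tilt to zero, where the flag is
moot).

### What the generator does not emulate

No array chemistry (probe types, dye bias), no normalisation artifacts, no
batch effects on methylation (batch is generated as a covariate but carries
no signal), no sex effects, no spatial correlation along the genome, no
heavy-tailed or heteroscedastic noise, and covariates are independent of
BMI by default (a dependence switch exists so adjustment can be shown to
matter). Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not robustness to every
artifact of real array data.

## Per-cohort EWAS

Huber M-regression per probe, IRLS with weights `min(1, c·s/|r|)`,
`c = 1.345` (95% Gaussian efficiency), scale `s = median|r|/0.6745`
re-estimated each iteration, convergence when the largest coefficient change
falls below `tol` (1e-6). Standard errors use Huber's correction-factor
asymptotic form `K²·[Σψ² s²/(n−p)]/m₁²·(X'X)⁻¹` with
`K = 1 + (p/n)·var(ψ')/m₁²`; the suite cross-checks coefficients and SEs
against an independently coded IRLS and against `statsmodels` RLM. The
implementation shares one design matrix across all probes and solves the
weighted normal equations as batched BLAS calls, which is what makes
consortium-scale runs (10⁵ probes × dozens of covariates) a matter of
seconds per cohort.

p-values come from `z = β/SE` against the standard normal rather than a t
reference, matching the METAL-style downstream pooling; at the cohort sizes
simulated (n = 300) the difference is within the λ band the suite checks.
Smoking enters as two treatment dummies (none / stopped early / throughout),
social class and batch as categorical dummies; dummy columns for categories
absent from a cohort are dropped before fitting. Estimated cell proportions
enter with the first (granulocyte) column dropped as the reference category,
since non-negative-projection estimates nearly sum to one and the full set
would be collinear with the intercept. Offspring sex is deliberately not a
covariate (it cannot confound a pre-pregnancy exposure and conditioning on
it risks collider bias). Exposure QC flags values ≥ 5 SD from the mean but
never removes them. The WHO category encoder follows the published cut-offs
literally: normal weight is 18.5–24.9, overweight/obese ≥ 25.0, so values in
(24.9, 25.0) are excluded from the contrast rather than silently assigned.

## Cell-type deconvolution

Constrained projection: per sample `min ‖R_s π − b_s‖²` with `π ≥ 0`
(default, matching the original projection method) on probes selected for
between-type range, balanced per type between hyper- and hypomethylated
markers. The simplex option solves the sum-to-one-constrained problem via a
heavily weighted auxiliary equation followed by exact renormalisation;
whether consortium cohorts renormalised their estimates is not documented,
so both behaviours are exposed with non-negativity-only as the default. Any
column subset of the reference may be used (some cohorts adjust for five of
six types).

## Meta-analysis layer

Fixed effects: `w = 1/se²`, `β_FE = Σwβ/Σw`, `SE = (Σw)^{-1/2}`.
Heterogeneity: `Q = Σw(β − β_FE)²` on k−1 df, `I² = max(0,(Q−df)/Q)·100`.
Random effects: DerSimonian–Laird `τ² = max(0, (Q−df)/(Σw − Σw²/Σw))` with
re-weighting `1/(se²+τ²)`. Probes missing in some cohorts pool over the
cohorts measuring them with k recorded; heterogeneity, random-effects and
leave-one-out columns are reported missing at k = 1, and leave-one-out
percentage change is missing when the full pooled estimate is exactly zero.
All of it is vectorised across probes; `statsmodels.combine_effects` is the
per-probe oracle in the tests.

λ is computed on the p-value scale (median implied χ²₁ over 0.4549…); the
source analysis does not state whether it used z² or p, and the two agree
when p itself came from z². The Bonferroni threshold is `α/m` over the
probes actually meta-analysed after exclusions (control probes and X/Y
chromosomes out; problematic-probe flags are carried but never cause
removal). BH-FDR wraps the standard step-up with monotonicity.

The dip statistic is defined as half the minimax gap between the midpoint
ECDF and the closest single-mode curve formed by a greatest-convex-minorant
prefix and a least-concave-majorant suffix, computed by incremental hull
construction; its p-value is calibrated by Monte Carlo against Uniform(0,1)
samples of the same n (seeded, with the null distribution cached per n).
The calibration makes the p-value valid for the statistic exactly as
defined; numerical identity with historical dip tables is not claimed. An
O(n⁴) support-line brute force over the same definition is the test oracle.

## Triangulation rules

The negative-control classifier takes the meta-analysed, mutually adjusted
parental estimates and applies: (1) same direction, (2) maternal magnitude
larger, (3) parental `I² > 40` from the two-study fixed-effects Q. All
thresholds are configuration values defaulting to the published ones; the
`I²` cut-off in particular was chosen post hoc in the source analysis and
should be read as a convention, not a calibrated operating point. A sign of
exactly zero counts as direction agreement (conservative toward
confounding; configurable).

**A structural property worth knowing**: for a probe whose true effect is
purely maternal, the mutually adjusted paternal estimate is mean-zero
sampling noise, so the raw sign comparison in criterion (1) holds with
probability 1/2 *regardless of sample size*. The three-criterion rule
therefore cannot recover more than about half of truly causal probes — the
acceptance suite measures ≈ 0.5–0.6 sensitivity at ≈ 0.94 specificity under
the default rule. The `direction_rule="significant_opposition"` option only
counts a paternal estimate against causality when it is opposite in sign
*and* nominally significant (the criterion's stated purpose is to detect an
independent opposite paternal effect, which a noise-level estimate does not
demonstrate); it reaches ≈ 0.98 sensitivity at the same specificity in the
same scenario. The sign rule remains the default because it is the
published operationalisation.

meQTL flags require an meQTL association (p < 1e-7) whose SNP is also
nominally associated with BMI in the GWAS table (p < 0.05); flagged
intrauterine candidates are demoted to likely-confounded. Probes absent
from the catalogue are not flagged. The cis window is a configuration value
with no asserted default (the source material gives both 100 kb and 1 Mb);
the synthetic catalogue marks planted-SNP rows cis and decoys trans. The
persistence look-up reports both the exact binomial tail on the count of
nominally significant adolescent probes and the KS uniformity test: the KS
framing matches the source analysis, the binomial is the directly
interpretable excess-significance statistic.

## Evaluation scenarios and problem sizes

The reference scenarios (in `methtriage.scenarios`, used by the acceptance
script and suite) run at desk scale, chosen to give stable estimates of
each operating characteristic:

- parameter recovery: 5 cohorts × 300 × 20,000 probes, 50 causal probes at
  −1e-3 beta/kg/m², noise 0.02 — bias and 95% CI coverage over the causal
  probes;
- type-I control: 200 independent global-null consortia of 3 cohorts × 300
  at 2,000 probes — family-wise error of the Bonferroni rule and per-cohort
  λ summarised as the median across replicates (a single 2,000-probe λ has
  ≈ 0.05 SD, so per-replicate values are not individually informative);
- attenuation: 5 × 300 × 10,000 with 5% cell-mediated probes and the 0.01
  composition tilt — attenuation of unadjusted-significant probes;
- triangulation: 3 replicate consortia of 3 cohorts × 1,500 trios × 2,000
  probes with fixed −1e-3 causal effects (a fixed magnitude isolates the
  classification rule from undetectably small effects), with
  sensitivity/specificity counts pooled across replicates — within one
  consortium the familial-confound probes share the same family-level
  latent draws, so their classification errors are correlated and a single
  replicate's specificity is an unstable estimate of the rule's marginal
  operating point;
- deconvolution: 200 mixtures over a 600-probe reference, noise-free and
  at 0.02 noise.

## Known limitations

- The Huber SE variant is one defensible M-estimator form; cohorts running
  other robust-regression software would produce slightly different SEs.
- The normal-approximation p-values are mildly anti-conservative below
  n ≈ 200 per cohort; the null scenarios run at n = 300 where calibration
  holds.
- The simplex deconvolution option is an augmented-system approximation of
  the equality-constrained problem (accurate to ~1e-12 before exact
  renormalisation).
- The meQTL/GWAS catalogue in the pipeline is derived from the simulated
  families themselves; a real analysis would use external catalogues with
  winner's-curse and coverage properties the simulation does not model.
- The negative-control sensitivity ceiling discussed above is a property of
  the published rule, not of this implementation.
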