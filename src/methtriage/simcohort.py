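"""Synthetic mother-father-child methylation consortia with planted truth.

The generator emulates the data-generating structure a maternal-BMI EWAS
meta-analysis assumes: several independent pregnancy cohorts, each with a
sample x CpG beta matrix in [0, 1], a phenotype table (maternal and paternal
BMI, age, smoking, parity, social class, batch), parental and child genotypes
at confounding SNPs, and latent blood cell-type proportions drawn around a
reference profile.  Every probe carries one of five effect classes:

``null``
    no direct association with maternal BMI;
``causal``
    a direct intrauterine effect ``causal_beta`` (beta units per kg/m^2)
    of maternal BMI on child methylation;
``cell_mediated_only``
    no direct effect; the probe's reference row discriminates the designated
    cell type, whose proportion is tilted by maternal BMI (``comp_shift``),
    so the association is entirely mediated by cell composition;
``genetic_confound``
    a SNP raises the parents' BMI (``snp_bmi_effect``) and, through
    Mendelian transmission, the child's methylation (``snp_meth_effect``);
``familial_confound``
    a shared family latent U loads equally on both parents' BMI and on child
    methylation.

The exported :class:`EffectTruth` table is the evaluation oracle for every
downstream recovery test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "CellReference",
    "SimConfig",
    "EffectTruth",
    "CohortDataset",
    "simulate_reference",
    "simulate_consortium",
    "simulate_adolescent_followup",
    "write_cohort",
    "write_reference",
    "write_truth",
    "read_reference",
]

EFFECT_CLASSES = (
    "null",
    "causal",
    "cell_mediated_only",
    "genetic_confound",
    "familial_confound",
)

#: Adult-whole-blood-like mean leukocyte proportions used when K == 6.
BLOOD_CELL_NAMES = ("Gran", "CD4T", "CD8T", "Bcell", "NK", "Mono")
BLOOD_CELL_MEANS = (0.55, 0.15, 0.08, 0.08, 0.06, 0.08)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellReference:
    """Reference methylation profiles for K cell types at M probes."""

    probe_ids: np.ndarray  # (M,) str
    profiles: np.ndarray  # (M, K) mean beta per cell type
    cell_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be a 2-D (M x K) matrix")
        m, k = self.profiles.shape
        if k < 2:
            raise ValueError("a cell reference needs at least two cell types")
        if len(self.probe_ids) != m or len(self.cell_names) != k:
            raise ValueError("probe_ids / cell_names do not match profile shape")
        if len(set(map(str, self.probe_ids))) != m:
            raise ValueError("duplicate probe_ids in reference")
        if np.any(self.profiles < 0) or np.any(self.profiles > 1):
            raise ValueError("reference profiles must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_celltypes(self) -> int:
        return self.profiles.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=list(self.cell_names))


@dataclass
class SimConfig:
    """Study conditions for one synthetic consortium.

    Defaults reproduce the conditions reported for the motivating consortium
    analysis at desk scale: 5 cohorts of 300 mother-father-child trios and
    20,000 autosomal probes; maternal BMI ~ 24.4 +/- 4 kg/m^2; a parental BMI
    correlation of 0.20 (assortative mating); per-kg/m^2 direct methylation
    effects of order 1e-4 to 1.5e-3; and a 2.25-fold attenuation of direct
    effects by adolescence.
    """

    n_cohorts: int = 5
    n_per_cohort: int | list[int] = 300
    n_probes: int = 20_000
    n_celltypes: int = 6
    bmi_mean: float | list[float] = 24.4
    bmi_sd: float | list[float] = 4.0
    parental_rho: float = 0.20
    comp_shift: float = 0.01  # log-composition tilt per kg/m^2 on the designated type
    designated_cell: int = 0  # index of the tilted cell type (granulocytes)
    noise_sd: float = 0.02
    attenuation_factor: float = 2.25
    effect_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.985,
            "causal": 0.0025,
            "cell_mediated_only": 0.005,
            "genetic_confound": 0.0025,
            "familial_confound": 0.005,
        }
    )
    causal_beta_range: tuple[float, float] = (-1.5e-3, 1.3e-3)
    causal_beta: float | None = None  # fixed planted effect overriding the range
    snp_freq: float = 0.3
    snp_meth_effect: float = 0.2  # beta units per child allele
    snp_bmi_effect: float = 0.4  # kg/m^2 per parental allele
    familial_sd: float = 1.0  # SD of the shared latent U
    familial_bmi_loading: float = 1.6  # kg/m^2 per unit U, both parents
    familial_meth_loading: float = 0.01  # beta units per unit U
    n_discriminating_per_type: int = 100
    dirichlet_concentration: float = 60.0
    missing_pattern: dict[int, list[str]] | None = None
    covariate_bmi_dependence: float = 0.0  # optional age/smoking dependence switch
    adolescent_n_cohorts: int = 4
    adolescent_n_per_cohort: int | list[int] | None = None
    seed: int = 0

    # -- helpers -----------------------------------------------------------

    def cohort_sizes(self) -> list[int]:
        n = self.n_per_cohort
        sizes = [int(n)] * self.n_cohorts if np.isscalar(n) else [int(v) for v in n]
        if len(sizes) != self.n_cohorts:
            raise ConfigError("n_per_cohort list does not match n_cohorts")
        return sizes

    def _per_cohort(self, value) -> list[float]:
        vals = [float(value)] * self.n_cohorts if np.isscalar(value) else [float(v) for v in value]
        if len(vals) != self.n_cohorts:
            raise ConfigError("per-cohort parameter list does not match n_cohorts")
        return vals

    def validate(self) -> None:
        fr = self.effect_class_fractions
        if set(fr) - set(EFFECT_CLASSES):
            raise ConfigError(f"unknown effect classes: {sorted(set(fr) - set(EFFECT_CLASSES))}")
        if any(v < 0 for v in fr.values()):
            raise ConfigError("effect_class_fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-8:
            raise ConfigError("effect_class_fractions must sum to 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.attenuation_factor <= 0:
            raise ConfigError("attenuation_factor must be > 0")
        if not 0.0 < self.snp_freq < 1.0:
            raise ConfigError("snp_freq must lie in (0, 1)")
        if not 0.0 <= self.parental_rho <= 1.0:
            raise ConfigError("parental_rho must lie in [0, 1]")
        if self.n_celltypes < 2:
            raise ConfigError("need at least two cell types")
        if not 0 <= self.designated_cell < self.n_celltypes:
            raise ConfigError("designated_cell out of range")
        self.cohort_sizes()


@dataclass
class EffectTruth:
    """Planted per-probe ground truth: the evaluation oracle.

    ``table`` columns: probe_id, class, causal_beta, snp_id, delta, kappa,
    familial_loading, composition_sensitive.  ``composition_sensitive`` marks
    probes whose reference row varies across cell types (including marker
    probes of non-designated types that are labelled null), so calibration
    checks under an active composition tilt can exclude them.
    """

    table: pd.DataFrame
    designated_cell: int
    cell_names: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.table["class"]) - set(EFFECT_CLASSES)
        if bad:
            raise ValueError(f"unknown effect classes in truth table: {sorted(bad)}")
        null_beta = self.table.loc[self.table["class"] != "causal", "causal_beta"]
        if not np.allclose(null_beta, 0.0):
            raise ValueError("causal_beta must be 0 for non-causal probes")

    def probes_of_class(self, cls: str) -> np.ndarray:
        return self.table.loc[self.table["class"] == cls, "probe_id"].to_numpy()


@dataclass
class CohortDataset:
    """One cohort's observable data plus (simulated) latent cell proportions."""

    name: str
    beta: pd.DataFrame  # samples x probes, values in [0, 1]
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame  # samples x SNPs, child genotypes in {0,1,2}
    true_props: pd.DataFrame  # samples x K, rows on the simplex
    parent_genotypes: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = self.beta.to_numpy()
        if b.size and (b.min() < 0 or b.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if len(self.true_props):
            rs = self.true_props.to_numpy().sum(axis=1)
            if not np.allclose(rs, 1.0, atol=1e-8):
                raise ValueError("true_props rows must sum to 1 within 1e-8")
        g = self.genotypes.to_numpy()
        if g.size and not np.isin(g, [0, 1, 2]).all():
            raise ValueError("genotype values must be in {0, 1, 2}")

    @property
    def probe_ids(self) -> np.ndarray:
        return self.beta.columns.to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.beta)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------


def _probe_ids(m: int) -> np.ndarray:
    return np.array([f"cg{i:08d}" for i in range(1, m + 1)])


def _background_profile(m: int, rng: np.random.Generator) -> np.ndarray:
    """Bimodal low/high baseline shared across cell types."""
    low = rng.random(m) < 0.5
    base = np.where(low, rng.uniform(0.03, 0.15, m), rng.uniform(0.85, 0.97, m))
    return base


def _build_reference(
    m: int,
    k: int,
    disc_index: dict[int, np.ndarray],
    rng: np.random.Generator,
    cell_names: tuple[str, ...] | None = None,
    min_contrast: float = 0.3,
) -> CellReference:
    """Construct a reference with explicit discriminating index sets per type.

    For each type, half of its discriminating probes are hypermethylated in
    that type and half hypomethylated, with contrast >= ``min_contrast``
    against every other type.
    """
    base = _background_profile(m, rng)
    profiles = np.tile(base[:, None], (1, k))
    for t, idx in disc_index.items():
        idx = np.asarray(idx)
        n = len(idx)
        hyper = np.zeros(n, dtype=bool)
        hyper[: n // 2 + n % 2] = True
        rng.shuffle(hyper)
        contrast = rng.uniform(min_contrast, min_contrast + 0.2, n)
        others_val = np.where(hyper, rng.uniform(0.05, 0.45, n), rng.uniform(0.55, 0.95, n))
        own_val = np.where(hyper, others_val + contrast, others_val - contrast)
        profiles[idx, :] = others_val[:, None]
        profiles[idx, t] = own_val
    profiles = np.clip(profiles, 0.0, 1.0)
    if cell_names is None:
        cell_names = BLOOD_CELL_NAMES if k == 6 else tuple(f"cell{t}" for t in range(k))
    return CellReference(_probe_ids(m), profiles, tuple(cell_names))


def simulate_reference(
    m: int,
    k: int,
    n_discriminating_per_type: int,
    seed: int,
    cell_names: tuple[str, ...] | None = None,
) -> CellReference:
    """Simulate a cell-type reference profile matrix.

    Each of the K types receives ``n_discriminating_per_type`` probes whose
    profile differs from all other types by at least 0.3 beta; the remaining
    probes share a bimodal low/high background across types.
    """
    if m < k * n_discriminating_per_type:
        raise ConfigError(
            f"n_probes={m} too small for {k} x {n_discriminating_per_type} discriminating probes"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(m)
    disc = {
        t: np.sort(order[t * n_discriminating_per_type : (t + 1) * n_discriminating_per_type])
        for t in range(k)
    }
    return _build_reference(m, k, disc, rng, cell_names)


# ---------------------------------------------------------------------------
# consortium simulation
# ---------------------------------------------------------------------------


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    m = cfg.n_probes
    counts = {c: int(round(cfg.effect_class_fractions.get(c, 0.0) * m)) for c in EFFECT_CLASSES}
    counts["null"] += m - sum(counts.values())  # rounding slack goes to null
    if counts["null"] < 0:
        raise ConfigError("effect_class_fractions leave no room for null probes")
    labels = np.concatenate([np.repeat(c, n) for c, n in counts.items()])
    rng.shuffle(labels)
    return labels


def _make_truth(cfg: SimConfig, rng: np.random.Generator) -> tuple[EffectTruth, CellReference]:
    cfg.validate()
    classes = _assign_classes(cfg, rng)
    m, k = cfg.n_probes, cfg.n_celltypes
    probe_ids = _probe_ids(m)

    cell_idx = np.flatnonzero(classes == "cell_mediated_only")
    null_idx = np.flatnonzero(classes == "null")
    n_disc = cfg.n_discriminating_per_type
    need = n_disc * (k - 1)
    if len(null_idx) < need:
        raise ConfigError("not enough null probes to host non-designated cell-type markers")
    other_marker = rng.choice(null_idx, size=need, replace=False)
    disc_index: dict[int, np.ndarray] = {}
    pos = 0
    for t in range(k):
        if t == cfg.designated_cell:
            disc_index[t] = cell_idx
        else:
            disc_index[t] = np.sort(other_marker[pos : pos + n_disc])
            pos += n_disc
    reference = _build_reference(m, k, disc_index, rng)

    causal_beta = np.zeros(m)
    causal_idx = np.flatnonzero(classes == "causal")
    if cfg.causal_beta is not None:
        causal_beta[causal_idx] = cfg.causal_beta
    else:
        lo, hi = cfg.causal_beta_range
        causal_beta[causal_idx] = rng.uniform(lo, hi, len(causal_idx))

    snp_id = np.array([""] * m, dtype=object)
    delta = np.zeros(m)
    kappa = np.zeros(m)
    gen_idx = np.flatnonzero(classes == "genetic_confound")
    for j, g in enumerate(gen_idx):
        snp_id[g] = f"rs{j + 1:06d}"
        delta[g] = cfg.snp_meth_effect
        kappa[g] = cfg.snp_bmi_effect

    loading = np.zeros(m)
    fam_idx = np.flatnonzero(classes == "familial_confound")
    loading[fam_idx] = cfg.familial_meth_loading

    contrast = reference.profiles.max(axis=1) - reference.profiles.min(axis=1)
    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "class": classes,
            "causal_beta": causal_beta,
            "snp_id": snp_id,
            "delta": delta,
            "kappa": kappa,
            "familial_loading": loading,
            "composition_sensitive": contrast >= 0.05,
        }
    )
    truth = EffectTruth(table, cfg.designated_cell, reference.cell_names)
    return truth, reference


def _simulate_genotypes(
    n: int, s: int, p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parental genotypes ~ Binomial(2, p); child by Mendelian transmission."""
    g_m = rng.binomial(2, p, size=(n, s))
    g_p = rng.binomial(2, p, size=(n, s))
    # transmit one allele from each parent: heterozygotes pass 0/1 fairly
    a_m = rng.binomial(1, g_m / 2.0)
    a_p = rng.binomial(1, g_p / 2.0)
    return g_m, g_p, a_m + a_p


def _covariates(n: int, bmi: np.ndarray, bmi_mean: float, dep: float,
                rng: np.random.Generator, batch_label: str) -> pd.DataFrame:
    age = rng.normal(30.0, 4.5, n)
    smoke_p = np.tile([0.75, 0.10, 0.15], (n, 1))
    if dep:
        age = age + dep * (bmi - bmi_mean)
        # tilt smoking-throughout probability with BMI, renormalised
        smoke_p[:, 2] *= np.exp(0.05 * dep * (bmi - bmi_mean))
        smoke_p /= smoke_p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    smoking = np.select(
        [u < smoke_p[:, 0], u < smoke_p[:, 0] + smoke_p[:, 1]],
        ["none", "stopped_early"],
        default="throughout",
    )
    return pd.DataFrame(
        {
            "maternal_age": age,
            "smoking": pd.Categorical(smoking, categories=["none", "stopped_early", "throughout"]),
            "parity": rng.binomial(1, 0.45, n),
            "social_class": pd.Categorical(
                rng.choice(["I_II", "III", "IV_V"], size=n, p=[0.3, 0.4, 0.3])
            ),
            "batch": pd.Categorical(
                np.where(rng.random(n) < 0.5, f"{batch_label}_b1", f"{batch_label}_b2")
            ),
        }
    )


def _simulate_one_cohort(
    name: str,
    n: int,
    bmi_mean: float,
    bmi_sd: float,
    cfg: SimConfig,
    truth: EffectTruth,
    reference: CellReference,
    rng: np.random.Generator,
    attenuation: float = 1.0,
    probe_subset: list[str] | None = None,
) -> CohortDataset:
    t = truth.table
    m = len(t)
    snp_probe_idx = np.flatnonzero(t["snp_id"].to_numpy() != "")
    s = len(snp_probe_idx)
    kappa = cfg.snp_bmi_effect
    lam_b = cfg.familial_bmi_loading if (t["familial_loading"] > 0).any() else 0.0

    # --- family-level exposures -------------------------------------------
    u = rng.normal(0.0, cfg.familial_sd, n)
    g_m, g_p, g_c = _simulate_genotypes(n, s, cfg.snp_freq, rng)
    gcen = 2.0 * cfg.snp_freq
    v_gen = s * 2.0 * cfg.snp_freq * (1 - cfg.snp_freq) * kappa**2 if s else 0.0
    v_fam = (lam_b * cfg.familial_sd) ** 2
    resid_var = bmi_sd**2 - v_gen - v_fam
    if resid_var <= 0:
        raise ConfigError(
            "bmi_sd too small for the configured genetic and familial BMI contributions"
        )
    # residual copula correlation chosen so the TOTAL parental correlation,
    # including the shared-U contribution, equals parental_rho
    rho_resid = (cfg.parental_rho * bmi_sd**2 - v_fam) / resid_var
    if not -1.0 < rho_resid < 1.0:
        raise ConfigError("parental_rho unreachable given familial BMI loading")
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho_resid], [rho_resid, 1.0]], size=n, method="cholesky"
    )
    sd_resid = np.sqrt(resid_var)
    gen_m = kappa * (g_m - gcen).sum(axis=1) if s else 0.0
    gen_p = kappa * (g_p - gcen).sum(axis=1) if s else 0.0
    bmi_m = bmi_mean + sd_resid * z[:, 0] + lam_b * u + gen_m
    bmi_p = bmi_mean + sd_resid * z[:, 1] + lam_b * u + gen_p

    # --- cell composition --------------------------------------------------
    k = cfg.n_celltypes
    base = np.asarray(BLOOD_CELL_MEANS) if k == 6 else np.full(k, 1.0 / k)
    pi0 = rng.dirichlet(base * cfg.dirichlet_concentration, size=n)
    logw = np.log(np.clip(pi0, 1e-12, None))
    logw[:, cfg.designated_cell] += cfg.comp_shift * (bmi_m - bmi_mean)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    props = w / w.sum(axis=1, keepdims=True)

    # --- methylation --------------------------------------------------------
    mu = props @ reference.profiles.T  # (n, M)
    causal = t["causal_beta"].to_numpy() / attenuation
    nz = np.flatnonzero(causal)
    if nz.size:
        mu[:, nz] += np.outer(bmi_m - bmi_mean, causal[nz])
    if s:
        mu[:, snp_probe_idx] += (g_c - gcen) * t["delta"].to_numpy()[snp_probe_idx]
    fam = t["familial_loading"].to_numpy()
    nzf = np.flatnonzero(fam)
    if nzf.size:
        mu[:, nzf] += np.outer(u, fam[nzf])
    if cfg.noise_sd > 0:
        mu += rng.normal(0.0, cfg.noise_sd, size=mu.shape)
    beta = np.clip(mu, 0.001, 0.999)

    sample_ids = pd.Index([f"{name}_s{i:04d}" for i in range(1, n + 1)], name="sample_id")
    pheno = _covariates(n, bmi_m, bmi_mean, cfg.covariate_bmi_dependence, rng, name)
    pheno.insert(0, "maternal_bmi", bmi_m)
    pheno.insert(1, "paternal_bmi", bmi_p)
    pheno.index = sample_ids

    snp_names = t["snp_id"].to_numpy()[snp_probe_idx]
    beta_df = pd.DataFrame(beta, index=sample_ids, columns=t["probe_id"].to_numpy())
    if probe_subset is not None:
        beta_df = beta_df.loc[:, [p_ for p_ in beta_df.columns if p_ in set(probe_subset)]]
    geno = pd.DataFrame(g_c, index=sample_ids, columns=snp_names)
    return CohortDataset(
        name=name,
        beta=beta_df,
        phenotypes=pheno,
        genotypes=geno,
        true_props=pd.DataFrame(props, index=sample_ids, columns=list(reference.cell_names)),
        parent_genotypes={
            "maternal": pd.DataFrame(g_m, index=sample_ids, columns=snp_names),
            "paternal": pd.DataFrame(g_p, index=sample_ids, columns=snp_names),
        },
    )


def simulate_consortium(
    config: SimConfig,
) -> tuple[list[CohortDataset], EffectTruth, CellReference]:
    """Simulate a multi-cohort newborn consortium with planted ground truth.

    Returns the cohorts, the per-probe :class:`EffectTruth` oracle and the
    cell-type reference used to compose the beta matrices.  Identical configs
    (including ``seed``) reproduce identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed, spawn_key=(0,))
    streams = root.spawn(1 + config.n_cohorts)
    truth, reference = _make_truth(config, np.random.default_rng(streams[0]))
    means = config._per_cohort(config.bmi_mean)
    sds = config._per_cohort(config.bmi_sd)
    cohorts = []
    for i, n in enumerate(config.cohort_sizes()):
        subset = None if config.missing_pattern is None else config.missing_pattern.get(i)
        cohorts.append(
            _simulate_one_cohort(
                f"cohort{i + 1:02d}",
                n,
                means[i],
                sds[i],
                config,
                truth,
                reference,
                np.random.default_rng(streams[1 + i]),
                probe_subset=subset,
            )
        )
    return cohorts, truth, reference


def simulate_adolescent_followup(
    truth: EffectTruth, config: SimConfig, reference: CellReference
) -> list[CohortDataset]:
    """Independent follow-up cohorts with direct effects attenuated.

    New individuals are drawn from fresh random streams (spawn key (1,), so
    there is no sample overlap with the newborn consortium); planted causal
    effects are divided by ``config.attenuation_factor`` while the
    cell-composition, genetic and familial confounding structure is preserved.
    """
    config.validate()
    n_coh = config.adolescent_n_cohorts
    n_per = config.adolescent_n_per_cohort
    if n_per is None:
        n_per = config.cohort_sizes()[0]
    sizes = [int(n_per)] * n_coh if np.isscalar(n_per) else [int(v) for v in n_per]
    if len(sizes) != n_coh:
        raise ConfigError("adolescent_n_per_cohort list does not match adolescent_n_cohorts")
    root = np.random.SeedSequence(config.seed, spawn_key=(1,))
    streams = root.spawn(n_coh)
    mean0 = config._per_cohort(config.bmi_mean)[0]
    sd0 = config._per_cohort(config.bmi_sd)[0]
    return [
        _simulate_one_cohort(
            f"adolescent{i + 1:02d}",
            sizes[i],
            mean0,
            sd0,
            config,
            truth,
            reference,
            np.random.default_rng(streams[i]),
            attenuation=config.attenuation_factor,
        )
        for i in range(n_coh)
    ]


# ---------------------------------------------------------------------------
# file output (tab-separated interchange formats)
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortDataset, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.beta.to_csv(d / "beta.tsv", sep="\t")
    cohort.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t")
    cohort.genotypes.to_csv(d / "genotypes.tsv", sep="\t")
    cohort.true_props.to_csv(d / "true_props.tsv", sep="\t")


def write_reference(reference: CellReference, path: str | Path) -> None:
    reference.to_frame().to_csv(path, sep="\t")


def read_reference(path: str | Path) -> CellReference:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellReference(df.index.to_numpy().astype(str), df.to_numpy(), tuple(df.columns))


def write_truth(truth: EffectTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
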