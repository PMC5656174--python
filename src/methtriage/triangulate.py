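"""Causal triangulation: negative control, meQTL flags, persistence.

Paternal BMI serves as a negative-control exposure: shared family genetics
and postnatal environment confound maternal and paternal BMI alike, but only
maternal BMI can act through the intrauterine environment.  After mutual
adjustment (parental BMIs are correlated through assortative mating), a
probe supports an intrauterine effect when

1. the maternal and paternal estimates share a direction (no independent
   opposite paternal effect),
2. the maternal estimate is larger in magnitude, and
3. the two estimates are heterogeneous (I^2 > 40 in a two-study
   fixed-effects meta-analysis of the pair).

A probe whose methylation is driven by a SNP that is itself associated with
BMI in a GWAS catalogue (meQTL p < 1e-7 and GWAS p < 0.05) is flagged as
genetically confounded, and flagged candidates are demoted.  Finally,
newborn hits are looked up in an independent adolescent meta-analysis for
direction concordance, nominal significance in excess of chance, and effect
attenuation.

The default direction rule is the raw sign comparison of the mutually
adjusted estimates (zero counting as agreement).  Because the mutually
adjusted paternal estimate at a truly maternal-only probe is mean-zero
sampling noise, this rule discards about half of genuinely causal probes by
coin-flip; ``direction_rule='significant_opposition'`` instead only counts a
paternal estimate against causality when it is opposite in sign *and*
nominally significant.  See the methods note for the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metastats import bh_fdr, ks_uniformity

__all__ = [
    "ParentalEstimates",
    "MeqtlCatalog",
    "parental_heterogeneity",
    "classify_negative_control",
    "meqtl_flag",
    "triangulate_verdicts",
    "persistence_lookup",
]

VERDICTS = ("discordant", "shared_confounding", "intrauterine_candidate")
FINAL_CLASSES = ("causal_candidate", "likely_confounded", "discordant")


@dataclass
class ParentalEstimates:
    """Mutually adjusted, meta-analysed maternal and paternal estimates.

    ``table`` columns: probe_id, beta_maternal, se_maternal, beta_paternal,
    se_paternal (and optionally p_maternal / p_paternal, needed by the
    ``significant_opposition`` direction rule).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"probe_id", "beta_maternal", "se_maternal", "beta_paternal", "se_paternal"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"ParentalEstimates table missing columns: {sorted(missing)}")
        if (self.table[["se_maternal", "se_paternal"]] <= 0).any().any():
            raise ValueError("parental standard errors must be > 0")


@dataclass
class MeqtlCatalog:
    """meQTL rows (snp_id, probe_id, meqtl_p, cis_flag) + GWAS look-up table."""

    meqtl: pd.DataFrame
    gwas: pd.DataFrame

    def __post_init__(self) -> None:
        for df, pcol in ((self.meqtl, "meqtl_p"), (self.gwas, "gwas_p")):
            p = df[pcol]
            if ((p <= 0) | (p > 1)).any():
                raise ValueError(f"{pcol} must lie in (0, 1]")


def parental_heterogeneity(
    maternal: tuple[float, float], paternal: tuple[float, float]
) -> float:
    """I^2 of a two-study fixed-effects meta of the parental estimates."""
    (bm, sm), (bp, sp) = maternal, paternal
    if sm <= 0 or sp <= 0:
        raise ValueError("standard errors must be > 0")
    q = (bm - bp) ** 2 / (sm**2 + sp**2)
    return 0.0 if q <= 1.0 else float((q - 1.0) / q * 100.0)


def _two_study_q(bm, sm, bp, sp):
    # k=2 fixed effects: Q reduces to the squared standardised difference
    return (bm - bp) ** 2 / (sm**2 + sp**2)


def classify_negative_control(
    pe: ParentalEstimates,
    i2_threshold: float = 40.0,
    direction_rule: str = "sign",
    opposition_alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the three negative-control criteria to every probe.

    Returns one row per probe with the same_direction and maternal_larger
    flags, the maternal/paternal magnitude ratio, the parental I^2, and the
    verdict: ``discordant`` (criterion 1 fails), ``shared_confounding``
    (criterion 1 holds but 2 or 3 fails — consistent parental estimates are
    evidence for familial/genetic confounding), or
    ``intrauterine_candidate`` (all three hold).
    """
    if direction_rule not in ("sign", "significant_opposition"):
        raise ValueError("direction_rule must be 'sign' or 'significant_opposition'")
    t = pe.table
    bm, sm = t["beta_maternal"].to_numpy(), t["se_maternal"].to_numpy()
    bp, sp = t["beta_paternal"].to_numpy(), t["se_paternal"].to_numpy()
    same = np.sign(bm) * np.sign(bp) >= 0  # zero counts as agreement
    if direction_rule == "significant_opposition":
        zp = np.abs(bp / sp)
        p_pat = 2.0 * stats.norm.sf(zp)
        same = same | (p_pat >= opposition_alpha)
    larger = np.abs(bm) > np.abs(bp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(bm) / np.abs(bp)
    q = _two_study_q(bm, sm, bp, sp)
    i2 = np.where(q <= 1.0, 0.0, (q - 1.0) / np.maximum(q, 1e-300) * 100.0)
    verdict = np.where(
        ~same,
        "discordant",
        np.where(larger & (i2 > i2_threshold), "intrauterine_candidate", "shared_confounding"),
    )
    return pd.DataFrame(
        {
            "probe_id": t["probe_id"].to_numpy(),
            "same_direction": same,
            "maternal_larger": larger,
            "maternal_pat_ratio": ratio,
            "parental_I2": i2,
            "verdict": verdict,
        }
    )


def meqtl_flag(
    probe_id: str,
    catalog: MeqtlCatalog,
    meqtl_alpha: float = 1e-7,
    gwas_alpha: float = 0.05,
) -> tuple[bool, list[str]]:
    """Flag a probe as genetically confounded via its meQTLs.

    True iff at least one SNP is an meQTL for the probe (p < ``meqtl_alpha``)
    and nominally associated with BMI in the GWAS table (p < ``gwas_alpha``).
    A probe absent from the catalogue is not flagged.
    """
    rows = catalog.meqtl[catalog.meqtl["probe_id"] == probe_id]
    if rows.empty:
        return False, []
    hits = rows[rows["meqtl_p"] < meqtl_alpha].merge(catalog.gwas, on="snp_id", how="inner")
    snps = sorted(hits.loc[hits["gwas_p"] < gwas_alpha, "snp_id"].unique())
    return bool(snps), snps


def triangulate_verdicts(
    verdicts: pd.DataFrame,
    catalog: MeqtlCatalog | None = None,
    meqtl_alpha: float = 1e-7,
    gwas_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Combine negative-control verdicts with meQTL flags into final classes.

    ``causal_candidate`` iff the verdict is intrauterine_candidate and the
    probe is not meQTL-flagged; intrauterine candidates with a flag, and all
    shared_confounding probes, become ``likely_confounded``; discordant
    probes stay ``discordant``.  Also returns the summary attrition counts.
    """
    rep = verdicts.copy()
    if catalog is not None:
        flags, snps = zip(*(meqtl_flag(p, catalog, meqtl_alpha, gwas_alpha)
                            for p in rep["probe_id"]))
        rep["meqtl_confounded"] = list(flags)
        rep["meqtl_snps"] = [",".join(s) for s in snps]
    else:
        rep["meqtl_confounded"] = False
        rep["meqtl_snps"] = ""
    final = np.where(
        rep["verdict"] == "discordant",
        "discordant",
        np.where(
            (rep["verdict"] == "intrauterine_candidate") & ~rep["meqtl_confounded"],
            "causal_candidate",
            "likely_confounded",
        ),
    )
    rep["final_class"] = final
    counts = {
        "n_probes": int(len(rep)),
        "discordant": int((rep["verdict"] == "discordant").sum()),
        "shared_confounding": int((rep["verdict"] == "shared_confounding").sum()),
        "intrauterine_candidates": int((rep["verdict"] == "intrauterine_candidate").sum()),
        "meqtl_flagged": int(rep["meqtl_confounded"].sum()),
        "causal_candidates": int((rep["final_class"] == "causal_candidate").sum()),
    }
    return rep, counts


def persistence_lookup(
    newborn_meta: pd.DataFrame,
    adolescent_meta: pd.DataFrame,
    probes,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Look up newborn hits in the independent adolescent meta-analysis.

    Per probe: direction concordance, adolescent p, BH q over the looked-up
    set, and the newborn/adolescent effect-magnitude ratio.  The summary
    reports the concordant count, the nominally significant count with both
    an exact binomial excess-significance test and a KS uniformity test on
    the adolescent p-values, and the median attenuation ratio over
    concordant probes.
    """
    probes = pd.Index(probes)
    nb = newborn_meta.set_index("probe_id")
    ad = adolescent_meta.set_index("probe_id")
    missing = probes.difference(nb.index).union(probes.difference(ad.index))
    if len(missing):
        raise ValueError(f"probes absent from one of the meta tables: {list(missing[:5])}")
    bcol = "beta_fe" if "beta_fe" in nb.columns else "beta"
    pcol = "p_fe" if "p_fe" in nb.columns else "pval"
    b_nb = nb.loc[probes, bcol].to_numpy()
    b_ad = ad.loc[probes, bcol].to_numpy()
    p_ad = ad.loc[probes, pcol].to_numpy()
    concordant = np.sign(b_nb) * np.sign(b_ad) >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(b_nb) / np.abs(b_ad)
    q_ad = bh_fdr(p_ad)
    per_probe = pd.DataFrame(
        {
            "probe_id": probes,
            "beta_newborn": b_nb,
            "beta_adolescent": b_ad,
            "concordant_direction": concordant,
            "p_adolescent": p_ad,
            "q_adolescent": q_ad,
            "newborn_over_adolescent_ratio": ratio,
        }
    )
    n = len(probes)
    n_sig = int((p_ad < alpha).sum())
    binom_p = float(stats.binomtest(n_sig, n, alpha, alternative="greater").pvalue) if n else np.nan
    ks_d, ks_p = ks_uniformity(p_ad) if n else (np.nan, np.nan)
    summary = {
        "n_probes": n,
        "n_concordant": int(concordant.sum()),
        "n_nominal_sig": n_sig,
        "n_fdr_sig": int((q_ad < alpha).sum()),
        "binomial_excess_p": binom_p,
        "ks_D": ks_d,
        "ks_p": ks_p,
        "median_attenuation_ratio": float(np.nanmedian(ratio[concordant]))
        if concordant.any()
        else np.nan,
    }
    return per_probe, summary
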