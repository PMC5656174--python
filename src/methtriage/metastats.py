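"""Meta-analysis of per-cohort EWAS summary tables.

Implements the consortium toolchain: probe filtering (control and sex-
chromosome probes out, everything measured in at least one cohort in),
inverse-variance fixed-effects pooling with METAL column semantics,
DerSimonian-Laird random effects, Cochran's Q / I-squared heterogeneity,
leave-one-out influence, genomic inflation lambda, Bonferroni and
Benjamini-Hochberg multiplicity, cell-adjustment attenuation summaries, and
the distributional diagnostics (Kolmogorov-Smirnov uniformity of p-values,
Hartigan dip for multimodal beta distributions at flagged probes).

All probe-level routines are vectorised across the table; the scalar
operations (``fixed_effects_meta`` etc.) expose the same arithmetic for a
single probe.  Problematic-probe (Naeem-style) annotation is carried as a
flag and never used for removal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._dip import dip_statistic, dip_test  # noqa: F401  (re-exported)

__all__ = [
    "filter_probes",
    "fixed_effects_meta",
    "heterogeneity",
    "random_effects_meta",
    "leave_one_out",
    "meta_analyse",
    "genomic_lambda",
    "bonferroni_threshold",
    "bh_fdr",
    "attenuation_summary",
    "ks_uniformity",
    "dip_test",
    "dip_statistic",
]

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549364...

META_COLUMNS = [
    "probe_id", "k", "beta_fe", "se_fe", "p_fe", "Q", "df", "p_het", "I2",
    "tau2", "beta_re", "se_re", "p_re", "max_loo_pct_change",
]


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------

_SEX_CHROMS = {"X": "X", "chrX": "X", "Y": "Y", "chrY": "Y"}
_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def filter_probes(
    tables: list[pd.DataFrame], annotation: pd.DataFrame
) -> tuple[list[pd.DataFrame], dict[str, int], pd.Series]:
    """Drop control probes and X/Y probes from every cohort table.

    Every probe_id appearing in any table must be annotated (unannotated
    probes are an error).  Probes measured in at least one cohort are kept.
    Returns the filtered tables, exclusion counts per reason, and the
    per-cohort coverage histogram (how many retained probes are measured in
    exactly k cohorts).
    """
    ann = annotation.set_index("probe_id")
    bad_chrom = set(ann["chrom"].astype(str)) - set(_SEX_CHROMS) - _AUTOSOMES
    if bad_chrom:
        raise ValueError(f"chromosomes outside the declared vocabulary: {sorted(bad_chrom)}")
    seen = pd.Index(np.unique(np.concatenate([t["probe_id"].to_numpy() for t in tables])))
    unannotated = seen.difference(ann.index)
    if len(unannotated):
        raise ValueError(f"unannotated probes: {list(unannotated[:5])} ...")
    sub = ann.loc[seen]
    is_control = (sub["probe_class"].astype(str) == "control").to_numpy()
    chrom = sub["chrom"].astype(str).map(_SEX_CHROMS).to_numpy()
    counts = {
        "control": int(is_control.sum()),
        "X": int(((chrom == "X") & ~is_control).sum()),
        "Y": int(((chrom == "Y") & ~is_control).sum()),
    }
    keep = set(seen[~is_control & ~np.isin(chrom, ["X", "Y"])])
    filtered = [t.loc[t["probe_id"].isin(keep)].reset_index(drop=True) for t in tables]
    coverage = (
        pd.concat([t["probe_id"] for t in filtered]).value_counts().value_counts().sort_index()
    )
    coverage.index.name = "n_cohorts"
    return filtered, counts, coverage


# ---------------------------------------------------------------------------
# single-probe arithmetic
# ---------------------------------------------------------------------------


def _as_arrays(estimates) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(estimates, dtype=float)
    b, se = arr[:, 0], arr[:, 1]
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    return b, se


def fixed_effects_meta(estimates) -> tuple[float, float, float]:
    """Inverse-variance-weighted fixed-effects pool of (beta, se) pairs."""
    b, se = _as_arrays(estimates)
    if len(b) == 0:
        raise ValueError("fixed_effects_meta needs at least one study")
    w = 1.0 / se**2
    beta_fe = float(np.sum(w * b) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    p_fe = float(2.0 * stats.norm.sf(abs(beta_fe / se_fe)))
    return beta_fe, se_fe, p_fe


def heterogeneity(estimates) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value and I^2 (percent, floored at 0)."""
    b, se = _as_arrays(estimates)
    k = len(b)
    if k < 2:
        raise ValueError("heterogeneity needs at least two studies")
    w = 1.0 / se**2
    beta_fe = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta_fe) ** 2))
    p_het = float(stats.chi2.sf(q, k - 1))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, p_het, i2


def random_effects_meta(estimates) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects pool: (tau2, beta_re, se_re, p_re)."""
    b, se = _as_arrays(estimates)
    k = len(b)
    if k < 2:
        raise ValueError("random_effects_meta needs at least two studies")
    w = 1.0 / se**2
    q, _, _ = heterogeneity(estimates)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    ws = 1.0 / (se**2 + tau2)
    beta_re = float(np.sum(ws * b) / np.sum(ws))
    se_re = float(np.sum(ws) ** -0.5)
    p_re = float(2.0 * stats.norm.sf(abs(beta_re / se_re)))
    return tau2, beta_re, se_re, p_re


def leave_one_out(estimates) -> pd.DataFrame:
    """Fixed-effects estimate omitting each study in turn, with % change."""
    b, se = _as_arrays(estimates)
    k = len(b)
    if k < 2:
        raise ValueError("leave_one_out needs at least two studies")
    w = 1.0 / se**2
    sw, swb = np.sum(w), np.sum(w * b)
    beta_full = swb / sw
    beta_wo = (swb - w * b) / (sw - w)
    if beta_full == 0:
        pct = np.full(k, np.nan)
    else:
        pct = 100.0 * np.abs(beta_wo - beta_full) / abs(beta_full)
    return pd.DataFrame({"beta_fe_without": beta_wo, "pct_change": pct})


# ---------------------------------------------------------------------------
# vectorised meta-analysis over cohort tables
# ---------------------------------------------------------------------------


def meta_analyse(tables: list[pd.DataFrame], cohort_names: list[str] | None = None) -> pd.DataFrame:
    """Meta-analyse per-cohort EWAS tables into one row per probe.

    Probes missing in some cohorts are pooled over the cohorts that measured
    them, with ``k`` recorded.  Heterogeneity, random-effects and
    leave-one-out columns are missing for k = 1.  Output is sorted by
    probe_id and invariant to cohort input order.
    """
    if cohort_names is None:
        cohort_names = [f"cohort{i}" for i in range(len(tables))]
    if len(cohort_names) != len(tables):
        raise ValueError("cohort_names must match tables")
    frames = []
    for name, t in zip(cohort_names, tables):
        f = t[["probe_id", "beta", "se"]].copy()
        f["cohort"] = name
        frames.append(f)
    long = pd.concat(frames, ignore_index=True).dropna(subset=["beta", "se"])
    if (long["se"] <= 0).any():
        raise ValueError("all standard errors must be > 0")
    b = long.pivot_table(index="probe_id", columns="cohort", values="beta", aggfunc="first")
    s = long.pivot_table(index="probe_id", columns="cohort", values="se", aggfunc="first")
    bm, sm = b.to_numpy(), s.to_numpy()
    w = 1.0 / sm**2
    k = np.sum(~np.isnan(bm), axis=1)
    sw = np.nansum(w, axis=1)
    swb = np.nansum(w * bm, axis=1)
    beta_fe = swb / sw
    se_fe = sw**-0.5
    p_fe = 2.0 * stats.norm.sf(np.abs(beta_fe / se_fe))
    p_fe = np.maximum(p_fe, np.finfo(float).tiny)

    q = np.nansum(w * (bm - beta_fe[:, None]) ** 2, axis=1)
    df = k - 1.0
    multi = k >= 2
    p_het = np.where(multi, stats.chi2.sf(q, np.maximum(df, 1)), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(multi & (q > 0), np.maximum(0.0, (q - df) / q) * 100.0, np.where(multi, 0.0, np.nan))
        denom = sw - np.nansum(w**2, axis=1) / sw
        tau2 = np.where(multi & (denom > 0), np.maximum(0.0, (q - df) / denom), np.where(multi, 0.0, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        ws = 1.0 / (sm**2 + tau2[:, None])
        sws = np.nansum(ws, axis=1)
        beta_re = np.where(multi, np.nansum(ws * bm, axis=1) / sws, np.nan)
        se_re = np.where(multi, sws**-0.5, np.nan)
        p_re = 2.0 * stats.norm.sf(np.abs(beta_re / se_re))

    with np.errstate(divide="ignore", invalid="ignore"):
        beta_wo = (swb[:, None] - w * bm) / (sw[:, None] - w)
        pct = 100.0 * np.abs(beta_wo - beta_fe[:, None]) / np.abs(beta_fe)[:, None]
        pct = np.where(np.isnan(bm) | ~multi[:, None] | (beta_fe == 0)[:, None], np.nan, pct)
        max_loo = np.full(len(beta_fe), np.nan)
        has_any = multi & (beta_fe != 0) & ~np.all(np.isnan(pct), axis=1)
        if has_any.any():
            max_loo[has_any] = np.nanmax(pct[has_any], axis=1)

    out = pd.DataFrame(
        {
            "probe_id": b.index.to_numpy(),
            "k": k.astype(int),
            "beta_fe": beta_fe,
            "se_fe": se_fe,
            "p_fe": p_fe,
            "Q": np.where(multi, q, np.nan),
            "df": np.where(multi, df, np.nan),
            "p_het": p_het,
            "I2": i2,
            "tau2": tau2,
            "beta_re": beta_re,
            "se_re": se_re,
            "p_re": p_re,
            "max_loo_pct_change": max_loo,
        }
    )
    return out.sort_values("probe_id", ignore_index=True)


# ---------------------------------------------------------------------------
# inflation, multiplicity, attenuation, diagnostics
# ---------------------------------------------------------------------------


def genomic_lambda(pvalues) -> float:
    """Genomic inflation factor from p-values.

    lambda = median of the implied 1-df chi-square statistics divided by the
    null median 0.4549...; lambda near 1 indicates well-calibrated tests.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0 or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_MEDIAN_1DF)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attenuation_summary(
    unadjusted: pd.DataFrame, adjusted: pd.DataFrame, probes=None
) -> tuple[dict, pd.DataFrame]:
    """Quantify how cell adjustment moves effect estimates.

    Per probe: percentage change in estimate 100*|b_un - b_adj|/|b_un|, a
    toward-the-null flag (|b_adj| < |b_un|) and a precision-increase flag
    (se_adj < se_un).  The summary reports the median percentage change, the
    count attenuated by >= 10% and the count with increased precision — the
    diagnostics by which cell-composition mediation is recognised.
    """
    un = unadjusted.set_index("probe_id")
    ad = adjusted.set_index("probe_id")
    if probes is None:
        probes = un.index.intersection(ad.index)
    probes = pd.Index(probes)
    missing = probes.difference(un.index).union(probes.difference(ad.index))
    if len(missing):
        raise ValueError(f"probes absent from one of the tables: {list(missing[:5])}")
    bcol = "beta_fe" if "beta_fe" in un.columns else "beta"
    scol = "se_fe" if "se_fe" in un.columns else "se"
    bu, ba = un.loc[probes, bcol].to_numpy(), ad.loc[probes, bcol].to_numpy()
    su, sa = un.loc[probes, scol].to_numpy(), ad.loc[probes, scol].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(bu != 0, 100.0 * np.abs(bu - ba) / np.abs(bu), np.nan)
    per_probe = pd.DataFrame(
        {
            "probe_id": probes,
            "beta_unadjusted": bu,
            "beta_adjusted": ba,
            "pct_change": pct,
            "toward_null": np.abs(ba) < np.abs(bu),
            "precision_increased": sa < su,
        }
    )
    summary = {
        "n_probes": int(len(probes)),
        "median_pct_change": float(np.nanmedian(pct)) if len(probes) else np.nan,
        "n_attenuated_10pct": int(np.nansum(pct >= 10.0)),
        "n_toward_null": int(per_probe["toward_null"].sum()),
        "n_precision_increased": int(per_probe["precision_increased"].sum()),
    }
    return summary, per_probe


def ks_uniformity(pvalues) -> tuple[float, float]:
    """One-sample KS test of p-values against Uniform(0, 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)
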