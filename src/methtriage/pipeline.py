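"""End-to-end orchestration: simulate -> deconvolve -> EWAS -> meta -> triangulate.

``run_full_pipeline`` strings the whole analysis into one reproducible run
directory.  Stages communicate through the declared tab-separated formats,
so any stage can be re-run in isolation from its input files.  A single
global seed is expanded into per-stage streams through numpy SeedSequence
spawn keys (documented scheme: (0,) newborn simulation, (1,) adolescent
simulation, (2,) annotation, (3,) catalogue), so stage-level reruns
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import deconv, metastats
from .ewas import ModelSpec, run_ewas
from .io import read_ewas_table, write_ewas_table
from .simcohort import (
    CellReference,
    CohortDataset,
    EffectTruth,
    SimConfig,
    simulate_adolescent_followup,
    simulate_consortium,
    write_cohort,
    write_reference,
    write_truth,
)
from .triangulate import (
    MeqtlCatalog,
    ParentalEstimates,
    classify_negative_control,
    persistence_lookup,
    triangulate_verdicts,
)

log = logging.getLogger("methtriage")

__all__ = ["RunConfig", "run_full_pipeline", "build_annotation", "build_meqtl_catalog",
           "parental_meta", "evaluate_against_truth"]


@dataclass
class RunConfig:
    """Configuration for a full synthetic-consortium run."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "methtriage_run"
    alpha: float = 0.05
    i2_threshold: float = 40.0
    meqtl_alpha: float = 1e-7
    gwas_alpha: float = 0.05
    direction_rule: str = "sign"
    deconv_sites_per_type: int = 50
    deconv_constraint: str = "nonneg"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# synthetic side-inputs derived from the simulation
# ---------------------------------------------------------------------------


def build_annotation(truth: EffectTruth, seed: int) -> pd.DataFrame:
    """Synthetic probe annotation mirroring array bookkeeping.

    A small, deterministic subset of effect-free probes is marked as control
    probes or assigned to the X/Y chromosomes (at roughly the published
    array proportions), so the exclusion funnel is exercised without
    discarding planted signal; all remaining probes are autosomal CpGs.
    """
    t = truth.table
    m = len(t)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    eligible = np.flatnonzero((t["class"] == "null").to_numpy()
                              & ~t["composition_sensitive"].to_numpy())
    n_control = max(1, round(m * 65 / 485_577))
    n_x = max(1, round(m * 11_232 / 485_577))
    n_y = max(1, round(m * 416 / 485_577))
    pick = rng.choice(eligible, size=min(n_control + n_x + n_y, len(eligible)), replace=False)
    chrom = np.array([str(1 + i % 22) for i in range(m)], dtype=object)
    probe_class = np.array(["cpg"] * m, dtype=object)
    probe_class[pick[:n_control]] = "control"
    chrom[pick[n_control : n_control + n_x]] = "X"
    chrom[pick[n_control + n_x : n_control + n_x + n_y]] = "Y"
    naeem = rng.random(m) < 0.05
    return pd.DataFrame(
        {
            "probe_id": t["probe_id"].to_numpy(),
            "chrom": chrom,
            "position": (1 + np.arange(m)) * 1000,
            "probe_class": probe_class,
            "gene": "",
            "naeem_flag": naeem,
        }
    )


def build_meqtl_catalog(
    cohorts: list[CohortDataset], truth: EffectTruth, seed: int
) -> MeqtlCatalog:
    """Derive meQTL and BMI-GWAS look-up tables from the simulated families.

    Emulates the external catalogues by actually testing, in the pooled
    cohorts, each planted SNP against methylation at its probe (meQTL p) and
    each maternal genotype against maternal BMI (GWAS p).  Each SNP is also
    tested against a few unrelated probes to populate null trans rows.
    """
    snp_probe = truth.table.loc[truth.table["snp_id"] != "", ["snp_id", "probe_id"]]
    if snp_probe.empty:
        return MeqtlCatalog(
            meqtl=pd.DataFrame(columns=["snp_id", "probe_id", "meqtl_p", "cis_flag"]),
            gwas=pd.DataFrame(columns=["snp_id", "gwas_beta", "gwas_p"]),
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    geno = pd.concat([c.genotypes for c in cohorts])
    geno_m = pd.concat([c.parent_genotypes["maternal"] for c in cohorts])
    bmi_m = pd.concat([c.phenotypes["maternal_bmi"] for c in cohorts]).to_numpy()
    common = [c.beta.columns for c in cohorts]
    shared = common[0]
    for cc in common[1:]:
        shared = shared.intersection(cc)
    null_pool = [p for p in truth.probes_of_class("null") if p in set(shared)]

    def _assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        res = stats.linregress(x, y)
        return float(res.slope), float(max(res.pvalue, np.finfo(float).tiny))

    meqtl_rows, gwas_rows = [], []
    for snp, probe in snp_probe.itertuples(index=False):
        g = geno[snp].to_numpy(dtype=float)
        meth = pd.concat([c.beta[probe] for c in cohorts]).to_numpy()
        slope, p = _assoc(g, meth)
        meqtl_rows.append((snp, probe, p, 1))
        for decoy in rng.choice(null_pool, size=min(3, len(null_pool)), replace=False):
            meth0 = pd.concat([c.beta[decoy] for c in cohorts]).to_numpy()
            _, p0 = _assoc(g, meth0)
            meqtl_rows.append((snp, decoy, p0, 0))
        gb, gp = _assoc(geno_m[snp].to_numpy(dtype=float), bmi_m)
        gwas_rows.append((snp, gb, gp))
    return MeqtlCatalog(
        meqtl=pd.DataFrame(meqtl_rows, columns=["snp_id", "probe_id", "meqtl_p", "cis_flag"]),
        gwas=pd.DataFrame(gwas_rows, columns=["snp_id", "gwas_beta", "gwas_p"]),
    )


def parental_meta(mutual_tables: list[pd.DataFrame]) -> ParentalEstimates:
    """Meta-analyse per-cohort mutually adjusted tables per parent."""
    mats = [t[t["exposure"] == "maternal"] for t in mutual_tables]
    pats = [t[t["exposure"] == "paternal"] for t in mutual_tables]
    mm = metastats.meta_analyse(mats).set_index("probe_id")
    pm = metastats.meta_analyse(pats).set_index("probe_id")
    probes = mm.index.intersection(pm.index)
    table = pd.DataFrame(
        {
            "probe_id": probes,
            "beta_maternal": mm.loc[probes, "beta_fe"].to_numpy(),
            "se_maternal": mm.loc[probes, "se_fe"].to_numpy(),
            "p_maternal": mm.loc[probes, "p_fe"].to_numpy(),
            "beta_paternal": pm.loc[probes, "beta_fe"].to_numpy(),
            "se_paternal": pm.loc[probes, "se_fe"].to_numpy(),
            "p_paternal": pm.loc[probes, "p_fe"].to_numpy(),
        }
    )
    return ParentalEstimates(table)


def evaluate_against_truth(
    report: pd.DataFrame, truth: EffectTruth
) -> dict:
    """Sensitivity/specificity of the final causal call against planted truth."""
    merged = report.merge(truth.table[["probe_id", "class"]], on="probe_id", how="left")
    causal = merged["class"] == "causal"
    confound = merged["class"].isin(["genetic_confound", "familial_confound"])
    called = merged["final_class"] == "causal_candidate"
    sens = float((called & causal).sum() / causal.sum()) if causal.sum() else np.nan
    spec = float((~called & confound).sum() / confound.sum()) if confound.sum() else np.nan
    return {
        "n_causal_evaluated": int(causal.sum()),
        "n_confound_evaluated": int(confound.sum()),
        "sensitivity": sens,
        "specificity": spec,
    }


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _bonferroni_hits(meta: pd.DataFrame, threshold: float) -> pd.Index:
    return pd.Index(meta.loc[meta["p_fe"] < threshold, "probe_id"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def run_full_pipeline(config: RunConfig) -> Path:
    """Run the whole synthetic-consortium analysis; returns the run directory.

    Emits per-cohort EWAS tables (cell-adjusted and unadjusted), meta tables
    for both models, the attenuation summary, Bonferroni hit lists and their
    overlap, negative-control and triangulation reports, the adolescent
    persistence report, per-cohort and meta-analysis lambdas, a
    truth-evaluation block, and a machine-readable summary with a manifest
    (config hash + seed).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    stage = "simulate"
    try:
        cohorts, truth, reference = simulate_consortium(config.sim)
        adolescents = simulate_adolescent_followup(truth, config.sim, reference)
        write_reference(reference, out / "reference.tsv")
        write_truth(truth, out / "truth.tsv")
        for c in cohorts + adolescents:
            write_cohort(c, out / "cohorts" / c.name)
        log.info("simulated %d newborn and %d adolescent cohorts, %d probes",
                 len(cohorts), len(adolescents), config.sim.n_probes)

        stage = "deconv"
        sites = deconv.select_discriminating_sites(
            reference, min(config.deconv_sites_per_type * reference.n_celltypes,
                           reference.n_probes),
        )
        props = {}
        for c in cohorts + adolescents:
            usable = [s_ for s_ in sites if s_ in c.beta.columns]
            est = deconv.estimate_cell_proportions(
                c.beta, reference, usable, constraint=config.deconv_constraint
            )
            props[c.name] = est.proportions
            est.proportions.to_csv(out / "cohorts" / c.name / "cell_props.tsv", sep="\t")

        stage = "ewas"
        spec_adj = ModelSpec(exposure_mode="continuous", adjust_cells=True)
        spec_unadj = ModelSpec(exposure_mode="continuous", adjust_cells=False)
        spec_mutual = ModelSpec(exposure_mode="mutual_parental", adjust_cells=True)
        ewas_dir = out / "ewas"
        ewas_dir.mkdir(exist_ok=True)
        lambdas: dict[str, dict[str, float]] = {}
        for c in cohorts:
            t_adj = run_ewas(c, spec_adj, props[c.name])
            t_un = run_ewas(c, spec_unadj)
            t_mut = run_ewas(c, spec_mutual, props[c.name])
            write_ewas_table(t_adj, ewas_dir / f"{c.name}_adjusted.tsv")
            write_ewas_table(t_un, ewas_dir / f"{c.name}_unadjusted.tsv")
            write_ewas_table(t_mut, ewas_dir / f"{c.name}_mutual.tsv")
            lambdas[c.name] = {
                "adjusted": metastats.genomic_lambda(t_adj["pval"].dropna()),
                "unadjusted": metastats.genomic_lambda(t_un["pval"].dropna()),
            }
        for c in adolescents:
            write_ewas_table(run_ewas(c, spec_adj, props[c.name]),
                             ewas_dir / f"{c.name}_adjusted.tsv")

        stage = "meta"
        annotation = build_annotation(truth, config.sim.seed)
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        names = [c.name for c in cohorts]
        adj_tables = [read_ewas_table(ewas_dir / f"{n}_adjusted.tsv") for n in names]
        un_tables = [read_ewas_table(ewas_dir / f"{n}_unadjusted.tsv") for n in names]
        adj_f, excl_counts, coverage = metastats.filter_probes(adj_tables, annotation)
        un_f, _, _ = metastats.filter_probes(un_tables, annotation)
        log.info("probe exclusions: %s", excl_counts)
        meta_adj = metastats.meta_analyse(adj_f, names)
        meta_un = metastats.meta_analyse(un_f, names)
        meta_adj.to_csv(out / "meta_adjusted.tsv", sep="\t", index=False)
        meta_un.to_csv(out / "meta_unadjusted.tsv", sep="\t", index=False)
        m_tested = len(meta_adj)
        thr = metastats.bonferroni_threshold(m_tested, config.alpha)
        hits_adj = _bonferroni_hits(meta_adj, thr)
        hits_un = _bonferroni_hits(meta_un, thr)
        overlap = hits_adj.intersection(hits_un)
        for nm, h in (("hits_adjusted", hits_adj), ("hits_unadjusted", hits_un),
                      ("hits_overlap", overlap)):
            pd.Series(sorted(h), name="probe_id").to_csv(out / f"{nm}.txt", index=False)
        lambdas["meta"] = {
            "adjusted": metastats.genomic_lambda(meta_adj["p_fe"]),
            "unadjusted": metastats.genomic_lambda(meta_un["p_fe"]),
        }
        log.info("bonferroni threshold %.3g: %d unadjusted, %d adjusted, %d overlap hits",
                 thr, len(hits_un), len(hits_adj), len(overlap))

        stage = "attenuation"
        att_summary, att_table = metastats.attenuation_summary(
            meta_un, meta_adj, probes=sorted(hits_un) if len(hits_un) else None
        )
        att_table.to_csv(out / "attenuation.tsv", sep="\t", index=False)

        stage = "triangulate"
        mut_tables = [read_ewas_table(ewas_dir / f"{n}_mutual.tsv") for n in names]
        pe = parental_meta(mut_tables)
        focus = overlap if len(overlap) else pd.Index(pe.table["probe_id"])
        pe_focus = ParentalEstimates(
            pe.table[pe.table["probe_id"].isin(set(focus))].reset_index(drop=True)
        )
        verdicts = classify_negative_control(
            pe_focus, i2_threshold=config.i2_threshold, direction_rule=config.direction_rule
        )
        catalog = build_meqtl_catalog(cohorts, truth, config.sim.seed)
        catalog.meqtl.to_csv(out / "meqtl_catalog.tsv", sep="\t", index=False)
        catalog.gwas.to_csv(out / "gwas_catalog.tsv", sep="\t", index=False)
        report, tri_counts = triangulate_verdicts(
            verdicts, catalog, config.meqtl_alpha, config.gwas_alpha
        )
        report.to_csv(out / "triangulation.tsv", sep="\t", index=False)
        log.info("triangulation funnel: %s", tri_counts)

        stage = "persistence"
        adol_names = [c.name for c in adolescents]
        adol_tables = [read_ewas_table(ewas_dir / f"{n}_adjusted.tsv") for n in adol_names]
        adol_f, _, _ = metastats.filter_probes(adol_tables, annotation)
        meta_adol = metastats.meta_analyse(adol_f, adol_names)
        meta_adol.to_csv(out / "meta_adolescent.tsv", sep="\t", index=False)
        look = [p for p in sorted(overlap) if p in set(meta_adol["probe_id"])]
        if look:
            per_probe, persist = persistence_lookup(meta_adj, meta_adol, look, config.alpha)
            per_probe.to_csv(out / "persistence.tsv", sep="\t", index=False)
        else:
            persist = {"n_probes": 0}

        stage = "evaluate"
        truth_eval = evaluate_against_truth(report, truth)

        summary.update(
            {
                "manifest": {
                    "config_hash": config.config_hash(),
                    "seed": config.sim.seed,
                    "version": 1,
                },
                "n_probes_tested": m_tested,
                "bonferroni_threshold": thr,
                "exclusions": excl_counts,
                "coverage_histogram": {str(k): int(v) for k, v in coverage.items()},
                "lambdas": lambdas,
                "hits": {
                    "unadjusted": len(hits_un),
                    "adjusted": len(hits_adj),
                    "overlap": len(overlap),
                },
                "attenuation": att_summary,
                "triangulation": tri_counts,
                "persistence": persist,
                "truth_evaluation": truth_eval,
            }
        )
        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
        )
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise
    return out
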