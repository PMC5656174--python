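"""Tab-separated interchange formats.

The EWAS summary format is the METAL-compatible table with the exact header
``probe_id, beta, se, pval, n`` (an optional ``exposure`` column is allowed
for mutually adjusted parental models).  Validation is strict: a missing
header column, an unparsable row or a non-positive standard error is
rejected with its line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_ewas_table",
    "write_ewas_table",
    "read_annotation",
    "read_meqtl_catalog",
]

EWAS_COLUMNS = ["probe_id", "beta", "se", "pval", "n"]


class TableFormatError(ValueError):
    pass


def write_ewas_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EWAS_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"EWAS table missing columns: {missing}")
    cols = EWAS_COLUMNS + (["exposure"] if "exposure" in table.columns else [])
    table.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ewas_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an EWAS summary table; round-trips write_ewas_table."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    missing = [c for c in EWAS_COLUMNS if c not in header]
    if missing:
        raise TableFormatError(f"{path.name}: missing required column(s) {missing}")
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    for col in ("beta", "se", "pval"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise TableFormatError(
                f"{path.name}: non-numeric {col} at line {int(bad[0]) + 2}"
            )
        df[col] = vals
    bad_se = df.index[df["se"].notna() & (df["se"] <= 0)]
    if len(bad_se):
        raise TableFormatError(f"{path.name}: se <= 0 at line {int(bad_se[0]) + 2}")
    bad_p = df.index[df["pval"].notna() & ((df["pval"] <= 0) | (df["pval"] > 1))]
    if len(bad_p):
        raise TableFormatError(f"{path.name}: pval outside (0, 1] at line {int(bad_p[0]) + 2}")
    n = pd.to_numeric(df["n"], errors="coerce")
    bad_n = df.index[n.isna() | (n < 0)]
    if len(bad_n):
        raise TableFormatError(f"{path.name}: invalid n at line {int(bad_n[0]) + 2}")
    df["n"] = n.astype(int)
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    need = {"probe_id", "chrom", "probe_class"}
    missing = need - set(df.columns)
    if missing:
        raise TableFormatError(f"annotation missing columns: {sorted(missing)}")
    return df


def read_meqtl_catalog(meqtl_path: str | Path, gwas_path: str | Path):
    from .triangulate import MeqtlCatalog

    meqtl = pd.read_csv(meqtl_path, sep="\t", dtype={"snp_id": str, "probe_id": str})
    gwas = pd.read_csv(gwas_path, sep="\t", dtype={"snp_id": str})
    for df, need in (
        (meqtl, {"snp_id", "probe_id", "meqtl_p"}),
        (gwas, {"snp_id", "gwas_p"}),
    ):
        missing = need - set(df.columns)
        if missing:
            raise TableFormatError(f"catalogue missing columns: {sorted(missing)}")
    if "cis_flag" not in meqtl.columns:
        meqtl["cis_flag"] = np.nan
    return MeqtlCatalog(meqtl=meqtl, gwas=gwas)
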