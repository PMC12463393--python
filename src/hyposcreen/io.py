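"""File I/O: MatrixMarket count triplets, TSV metadata, GMT gene sets,
subtype catalogs, TF regulons and GWAS summary statistics.

On-disk layout for expression data follows the sparse-triplet convention:
``matrix.mtx`` holds cells × genes counts with 1-based MatrixMarket
indices, ``genes.tsv`` one row per gene (symbol, is_mito, is_tf) and
``cells.tsv`` one row per cell (cell_id, group, cell_type).  Internally
everything is 0-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    SubtypeCatalog,
    ValidationError,
)

log = logging.getLogger(__name__)

GWAS_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "eaf", "n"]


# ----------------------------------------------------------------- counts
def read_counts(mtx_path, genes_path, cells_path) -> ExpressionDataset:
    """Load an expression dataset from MatrixMarket + TSV metadata.

    Validates dimensions, integer non-negative counts and unique gene
    symbols / cell ids; derived QC fields (total UMI, mito percent) are
    populated on load.
    """
    M = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", dtype={"symbol": str})
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    if "symbol" not in genes.columns:
        raise ValidationError(f"{genes_path}: missing 'symbol' column")
    if "cell_id" not in cells.columns:
        raise ValidationError(f"{cells_path}: missing 'cell_id' column")
    if M.shape[0] != len(cells):
        raise ValidationError(
            f"matrix has {M.shape[0]} rows but {cells_path} lists {len(cells)} cells"
        )
    if M.shape[1] != len(genes):
        raise ValidationError(
            f"matrix has {M.shape[1]} columns but {genes_path} lists {len(genes)} genes"
        )
    var = genes.set_index("symbol")
    obs = cells.set_index("cell_id")
    return ExpressionDataset(M, obs, var)


def write_counts(d: ExpressionDataset, outdir) -> None:
    """Write ``matrix.mtx``, ``genes.tsv`` and ``cells.tsv`` under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), d.counts.tocoo(), field="integer", symmetry="general"
    )
    genes = d.var[["is_mito", "is_tf"]].astype(int).reset_index()
    genes = genes.rename(columns={genes.columns[0]: "symbol"})
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = d.obs[["group", "cell_type"]].reset_index()
    cells = cells.rename(columns={cells.columns[0]: "cell_id"})
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


# ------------------------------------------------------------------- GMT
def read_gene_sets(gmt_path, source: str = "custom") -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...).

    Duplicate members within a set are dropped (first occurrence kept)
    with a logged warning; lines with an empty member list are rejected
    with a warning and skipped.
    """
    coll = GeneSetCollection()
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            name, _desc, members = parts[0], parts[1] if len(parts) > 1 else "", parts[2:]
            members = [m for m in members if m]
            if not members:
                log.warning("%s:%d: gene set %r has no members; skipped", gmt_path, lineno, name)
                continue
            seen, unique = set(), []
            for m in members:
                if m in seen:
                    log.warning("%s:%d: duplicate member %r in set %r dropped", gmt_path, lineno, m, name)
                else:
                    seen.add(m)
                    unique.append(m)
            coll.add(GeneSet(name=name, members=tuple(unique), source=source))
    return coll


def write_gene_sets(coll: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.source, *gs.members]) + "\n")


# --------------------------------------------------------------- catalogs
def read_subtype_catalog(path) -> SubtypeCatalog:
    """TSV with columns subtype, gene, category (peptide|receptor)."""
    return SubtypeCatalog(pd.read_csv(path, sep="\t"))


def write_subtype_catalog(cat: SubtypeCatalog, path) -> None:
    cat.table.to_csv(path, sep="\t", index=False)


def read_regulons(path) -> dict:
    """TF regulon TSV (tf, target, weight) → {tf: [(target, weight), ...]}."""
    df = pd.read_csv(path, sep="\t")
    required = {"tf", "target", "weight"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: regulon table needs columns {sorted(required)}")
    regulons: dict = {}
    for tf, grp in df.groupby("tf", sort=False):
        regulons[tf] = list(zip(grp["target"], grp["weight"].astype(float)))
    return regulons


# ------------------------------------------------------------------ GWAS
def read_gwas_summary(path) -> pd.DataFrame:
    """GWAS summary TSV (snp, effect_allele, other_allele, beta, se, pval,
    eaf, n) with basic sanity validation."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ValidationError(f"{path}: duplicate SNP id {dup!r}")
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "snp"].iloc[0]
        raise ValidationError(f"{path}: non-positive se at SNP {bad!r}")
    valid = set("ACGT")
    alleles = set(df["effect_allele"]) | set(df["other_allele"])
    if not alleles <= valid:
        raise ValidationError(f"{path}: invalid allele codes {sorted(alleles - valid)}")
    return df[GWAS_COLUMNS].copy()


def write_gwas_summary(df: pd.DataFrame, path) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ld_table(path) -> pd.DataFrame:
    """Optional pairwise LD table (snp_a, snp_b, r2)."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_a", "snp_b", "r2"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: LD table needs columns {sorted(required)}")
    return df
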