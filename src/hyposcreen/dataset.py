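"""Core in-memory containers for expression data and gene sets.

The central object is :class:`ExpressionDataset`: a sparse cells × genes
raw count matrix with cell metadata (sample group, coarse cell type, and
derived QC fields) and gene metadata (mitochondrial / transcription-factor
flags).  Raw counts are kept throughout the analysis because several
operations are defined on them directly — gene-set fraction scores are
percentages of raw counts, and subtype membership is a raw ``count > 0``
rule — while marker and differential tests run on a CP10K + log1p
normalized layer derived on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

GROUPS = ("Y", "O", "O.T")

CELL_COLUMNS = ("group", "cell_type")
GENE_COLUMNS = ("is_mito", "is_tf")


class ValidationError(ValueError):
    """Raised when an input file or matrix violates the data contract."""


class ExpressionDataset:
    """Sparse cells × genes raw counts plus cell and gene metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows, genes in columns.
        Accepts any scipy sparse matrix or a dense array; stored as CSR.
    obs
        Cell metadata indexed by unique cell id with at least columns
        ``group`` (one of ``Y``, ``O``, ``O.T``) and ``cell_type``.
    var
        Gene metadata indexed by unique gene symbol with boolean columns
        ``is_mito`` and ``is_tf``.

    Derived columns ``total_umi`` and ``pct_mito`` (percent of counts in
    mitochondrial genes, 0–100) are (re)computed at construction.
    """

    def __init__(self, counts, obs: pd.DataFrame, var: pd.DataFrame):
        X = sp.csr_matrix(counts)
        if X.shape != (len(obs), len(var)):
            raise ValidationError(
                f"count matrix is {X.shape} but metadata describe "
                f"{len(obs)} cells and {len(var)} genes"
            )
        if X.nnz and X.data.min() < 0:
            raise ValidationError("negative count entries")
        if X.nnz and not np.allclose(X.data, np.round(X.data)):
            raise ValidationError("non-integer count entries")
        X.data = X.data.astype(np.int64)
        if not obs.index.is_unique:
            dup = obs.index[obs.index.duplicated()][0]
            raise ValidationError(f"duplicate cell id: {dup!r}")
        if not var.index.is_unique:
            dup = var.index[var.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol: {dup!r}")
        for col in CELL_COLUMNS:
            if col not in obs.columns:
                raise ValidationError(f"cells table missing column {col!r}")
        bad = set(obs["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        for col in GENE_COLUMNS:
            if col not in var.columns:
                raise ValidationError(f"genes table missing column {col!r}")

        self.counts: sp.csr_matrix = X
        self.obs = obs.copy()
        self.var = var.copy()
        self.var["is_mito"] = self.var["is_mito"].astype(bool)
        self.var["is_tf"] = self.var["is_tf"].astype(bool)
        self._recompute_qc()
        self._normalized: sp.csr_matrix | None = None
        self._expressed: np.ndarray | None = None

    # ------------------------------------------------------------------
    def _recompute_qc(self) -> None:
        total = np.asarray(self.counts.sum(axis=1)).ravel()
        mito_mask = self.var["is_mito"].to_numpy()
        mito = np.asarray(self.counts[:, mito_mask].sum(axis=1)).ravel()
        self.obs["total_umi"] = total.astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
        self.obs["pct_mito"] = pct

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.obs.index

    @property
    def gene_symbols(self) -> pd.Index:
        return self.var.index

    def gene_indices(self, symbols) -> np.ndarray:
        """Positions of ``symbols`` in the gene axis (all must exist)."""
        idx = self.var.index.get_indexer(list(symbols))
        missing = [s for s, i in zip(symbols, idx) if i < 0]
        if missing:
            raise KeyError(f"gene(s) not in dataset: {missing[:5]}")
        return idx

    def subset_cells(self, mask) -> "ExpressionDataset":
        """New dataset restricted to cells selected by a boolean mask or
        positional index array; cell order is preserved."""
        mask = np.asarray(mask)
        pos = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionDataset(self.counts[pos], self.obs.iloc[pos], self.var)

    # ------------------------------------------------------------------
    @property
    def normalized(self) -> sp.csr_matrix:
        """CP10K + log1p layer (cells × genes, CSR float), computed once
        from raw counts.  Cells with zero total counts are rejected —
        they should never survive QC."""
        if self._normalized is None:
            total = self.obs["total_umi"].to_numpy()
            if (total == 0).any():
                zero = self.obs.index[total == 0][0]
                raise ValidationError(
                    f"cell {zero!r} has zero total counts; run qc_filter first"
                )
            X = self.counts.astype(np.float64).tocsr(copy=True)
            scale = 1e4 / total
            X = sp.diags(scale) @ X
            X = X.tocsr()
            np.log1p(X.data, out=X.data)
            self._normalized = X
        return self._normalized

    def normalized_dense(self) -> np.ndarray:
        return np.asarray(self.normalized.todense())

    @property
    def expressed(self) -> np.ndarray:
        """Dense boolean cells × genes mask of raw count > 0 (cached)."""
        if self._expressed is None:
            self._expressed = np.asarray((self.counts > 0).todense())
        return self._expressed

    # ------------------------------------------------------------------
    def to_anndata(self):
        """Export to :class:`anndata.AnnData` (counts in ``layers['counts']``,
        normalized layer in ``X``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.normalized.copy(),
            obs=self.obs.copy(),
            var=self.var.copy(),
            layers={"counts": self.counts.copy()},
        )
        return adata

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionDataset({self.n_cells} cells × {self.n_genes} genes; "
            f"groups {dict(self.obs['group'].value_counts())})"
        )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneSet:
    """A named gene list (pathway, signature, or custom set)."""

    name: str
    members: tuple
    source: str = "custom"

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered, name-keyed collection of :class:`GeneSet`."""

    sets: dict = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene-set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list:
        return list(self.sets)


@dataclass
class SubtypeCatalog:
    """Curated subtype table: one row per (subtype, defining gene, category).

    Category distinguishes neuropeptide/hormone-secreting subtypes
    (``peptide``) from receptor-expressing subtypes (``receptor``).
    """

    table: pd.DataFrame  # columns: subtype, gene, category

    CATEGORIES = ("peptide", "receptor")

    def __post_init__(self):
        required = {"subtype", "gene", "category"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"catalog needs columns {sorted(required)}")
        if self.table["subtype"].duplicated().any():
            dup = self.table.loc[self.table["subtype"].duplicated(), "subtype"].iloc[0]
            raise ValidationError(f"duplicate subtype name {dup!r}")
        bad = set(self.table["category"]) - set(self.CATEGORIES)
        if bad:
            raise ValidationError(f"invalid categories {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subtypes(self) -> list:
        return self.table["subtype"].tolist()

    def category_of(self, subtype: str) -> str:
        row = self.table.loc[self.table["subtype"] == subtype]
        if row.empty:
            raise KeyError(subtype)
        return row["category"].iloc[0]
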