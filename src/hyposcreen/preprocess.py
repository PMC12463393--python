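"""Cell-level QC filtering and normalization.

QC removes nuclei with unusually high UMI totals (ambient/doublet-like
profiles) or a high mitochondrial fraction (damaged nuclei).  Both bounds
are inclusive: a cell at exactly the UMI or mito threshold is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .config import AnalysisConfig
from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    n_umi_violations: int
    n_mito_violations: int


def qc_filter(
    d: ExpressionDataset, cfg: AnalysisConfig | None = None, return_report: bool = False
):
    """Remove cells with total UMI ≥ ``qc_max_umi`` or mitochondrial
    percent ≥ ``qc_max_mito_pct``; cell order is preserved.

    A cell can violate both criteria; per-criterion violation counts are
    logged (and returned when ``return_report``).  Raises if no cell
    survives.
    """
    cfg = cfg or AnalysisConfig()
    umi = d.obs["total_umi"].to_numpy()
    mito = d.obs["pct_mito"].to_numpy()
    umi_bad = umi >= cfg.qc_max_umi
    mito_bad = mito >= cfg.qc_max_mito_pct
    keep = ~(umi_bad | mito_bad)
    report = QCReport(
        n_input=d.n_cells,
        n_kept=int(keep.sum()),
        n_umi_violations=int(umi_bad.sum()),
        n_mito_violations=int(mito_bad.sum()),
    )
    log.info(
        "QC: kept %d/%d cells (%d UMI ≥ %d, %d mito ≥ %.1f%%)",
        report.n_kept, report.n_input, report.n_umi_violations,
        cfg.qc_max_umi, report.n_mito_violations, cfg.qc_max_mito_pct,
    )
    if report.n_kept == 0:
        raise ValueError("QC removed every cell; downstream analysis undefined")
    filtered = d.subset_cells(keep)
    if return_report:
        return filtered, report
    return filtered


def normalize_log1p(d: ExpressionDataset) -> sp.csr_matrix:
    """CP10K + log1p normalized layer (cells × genes CSR).

    Each cell's counts are scaled to a total of 10,000 and log(1+x)
    transformed.  The layer is derived from raw counts and cached on the
    dataset, so applying it repeatedly is idempotent; raw counts remain
    untouched.  Cells with zero totals are rejected.
    """
    return d.normalized
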