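"""Analysis configuration: every tunable threshold of the pipeline.

Defaults reproduce the study protocol the pipeline implements: QC cut-offs
of 8,000 UMIs and 15% mitochondrial counts (both inclusive), TF retention
at mean raw count > 0.1, Pearson significance at p < 0.05, a 15-cell floor
for auROC comparisons, a 10-cell floor for subtype count ranking, 6-cell
subsamples (and a 6-cell floor) for perturbation prioritization, top/bottom
20 rank screens requiring hits in at least 4 of the score sets, Seurat-style
DEG thresholds, and the Mendelian-randomization instrument rules
(p < 1e-5, clumping r² < 0.001, F ≥ 10, IVW p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class DEGThresholds:
    min_pct: float = 0.1
    logfc: float = 0.25
    avg_diff: float = 0.1
    adj_p: float = 0.05


@dataclass
class MRThresholds:
    instrument_p: float = 1e-5
    clump_r2: float = 0.001
    min_f: float = 10.0
    ivw_p: float = 0.05
    palindromic_eaf_tol: float = 0.08
    n_boot: int = 1000
    mode_bandwidth_factor: float = 1.0


@dataclass
class AnalysisConfig:
    qc_max_umi: int = 8000
    qc_max_mito_pct: float = 15.0
    tf_min_mean: float = 0.1
    corr_p: float = 0.05
    auroc_min_cells: int = 15
    subtype_min_cells: int = 10
    augur_subsample_size: int = 6
    augur_min_cells: int = 6
    augur_n_subsamples: int = 50
    augur_n_trees: int = 8
    augur_n_hvg: int = 250
    screen_k: int = 20
    screen_min_hits: int = 4
    deg: DEGThresholds = field(default_factory=DEGThresholds)
    mr: MRThresholds = field(default_factory=MRThresholds)
    seed: int = 0

    def __post_init__(self):
        if self.qc_max_umi <= 0 or not (0 <= self.qc_max_mito_pct <= 100):
            raise ValueError("QC thresholds out of domain")
        if not (0 < self.corr_p < 1) or not (0 < self.mr.ivw_p < 1):
            raise ValueError("p-value thresholds must be in (0, 1)")
        for name in ("auroc_min_cells", "subtype_min_cells",
                     "augur_subsample_size", "augur_min_cells",
                     "screen_k", "screen_min_hits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "deg" in d and isinstance(d["deg"], dict):
            d["deg"] = DEGThresholds(**d["deg"])
        if "mr" in d and isinstance(d["mr"], dict):
            d["mr"] = MRThresholds(**d["mr"])
        return cls(**d)
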