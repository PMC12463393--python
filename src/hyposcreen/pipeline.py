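"""Stage-based pipeline runner driven by a YAML configuration.

A run executes the requested stages in their canonical order
(qc → score → subtype → signatures → prioritize → screens → mr), writing
one TSV per result table into the run directory plus a plain-text log
recording package version, seed and parameters.  Every output table
carries the configuration hash in a header comment, and identical
configurations (including the seed) reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .dataset import ExpressionDataset, GeneSetCollection
from .io import (
    read_counts,
    read_gene_sets,
    read_gwas_summary,
    read_ld_table,
    read_subtype_catalog,
    write_gene_sets,
)
from .mr import METHODS, run_mr
from .preprocess import qc_filter
from .scoring import score_collection
from .signatures import (
    derive_signature_pair,
    intersection_screen,
    quarter_group_proportions,
    quartile_partition,
    rank_subtype_scores,
    validate_opposing,
)
from .simulate import (
    SimExpressionConfig,
    default_subtype_catalog,
    simulate_expression,
)
from .subtypes import assign_subtypes, count_rank, prioritize, weighted_proportions
from .scoring import score_fraction

log = logging.getLogger(__name__)

STAGE_ORDER = ("qc", "score", "subtype", "signatures", "prioritize", "screens", "mr")


class PipelineError(RuntimeError):
    pass


def _config_hash(cfg_dict: dict) -> str:
    canon = yaml.safe_dump(cfg_dict, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


class PipelineRun:
    """State carried across stages of one pipeline execution."""

    def __init__(self, cfg_dict: dict, outdir: Path):
        if "seed" not in cfg_dict:
            raise PipelineError(
                "configuration has no 'seed'; set an explicit integer seed "
                "to make the run reproducible"
            )
        self.cfg_dict = cfg_dict
        self.hash = _config_hash(cfg_dict)
        self.outdir = outdir
        self.analysis = AnalysisConfig.from_dict(
            {**cfg_dict.get("analysis", {}), "seed": cfg_dict["seed"]}
        )
        self.dataset: ExpressionDataset | None = None
        self.scores: pd.DataFrame | None = None
        self.assignment = None
        self.signature_pair = None
        self.gene_sets: GeneSetCollection | None = None

    # -------------------------------------------------------------- input
    def load_input(self) -> None:
        cfg = self.cfg_dict
        if "input" in cfg:
            paths = cfg["input"]
            self.dataset = read_counts(paths["counts"], paths["genes"], paths["cells"])
        elif "simulate" in cfg:
            sim = dict(cfg["simulate"])
            sim.setdefault("seed", cfg["seed"])
            self.dataset, _truth = simulate_expression(SimExpressionConfig(**sim))
        else:
            raise PipelineError("configuration needs either 'input' or 'simulate'")
        if "gene_sets" in cfg:
            self.gene_sets = read_gene_sets(cfg["gene_sets"])

    def _catalog(self):
        if "catalog" in self.cfg_dict:
            return read_subtype_catalog(self.cfg_dict["catalog"])
        return default_subtype_catalog()

    def _neurons(self) -> ExpressionDataset:
        mask = (self.dataset.obs["cell_type"] == "Neuron").to_numpy()
        return self.dataset.subset_cells(mask)

    # -------------------------------------------------------------- stages
    def stage_qc(self) -> None:
        filtered, report = qc_filter(self.dataset, self.analysis, return_report=True)
        self.dataset = filtered
        _write_table(
            pd.DataFrame([report.__dict__]), self.outdir / "qc_report.tsv", self.hash
        )
        _write_table(
            self.dataset.obs.reset_index(), self.outdir / "qc_cells.tsv", self.hash
        )

    def stage_score(self) -> None:
        if self.gene_sets is None:
            raise PipelineError("stage 'score' needs 'gene_sets' in the configuration")
        self.scores = score_collection(self.dataset, self.gene_sets)
        _write_table(
            self.scores.rename_axis("cell_id").reset_index(),
            self.outdir / "scores.tsv", self.hash,
        )

    def stage_subtype(self) -> None:
        self.assignment = assign_subtypes(self.dataset, self._catalog())
        props = weighted_proportions(self.assignment, self.dataset)
        _write_table(props.reset_index(), self.outdir / "subtype_proportions.tsv", self.hash)
        ref = self.cfg_dict.get("reference_group", "Y")
        ranks = count_rank(self.assignment, self.dataset, ref, self.analysis)
        _write_table(ranks, self.outdir / f"subtype_counts_{ref}.tsv", self.hash)

    def stage_signatures(self) -> None:
        if self.gene_sets is None:
            raise PipelineError("stage 'signatures' needs 'gene_sets'")
        names = self.cfg_dict.get("signature_pathways", self.gene_sets.names)
        sub = GeneSetCollection()
        for n in names:
            sub.add(self.gene_sets[n])
        neurons = self._neurons()
        self.signature_pair = derive_signature_pair(neurons, sub, self.analysis)
        write_gene_sets(self.signature_pair.to_collection(),
                        self.outdir / "signatures.gmt")
        prov = {
            "pathways": list(self.signature_pair.pathways),
            "c1_up": list(self.signature_pair.c1_up),
            "c4_up": list(self.signature_pair.c4_up),
            "marker_counts": {
                k: {q: int(v) for q, v in d.items()}
                for k, d in self.signature_pair.marker_counts.items()
            },
            "config_hash": self.hash,
        }
        (self.outdir / "signatures_provenance.yaml").write_text(
            yaml.safe_dump(prov, sort_keys=True)
        )
        rows = []
        for n in names:
            part = quartile_partition(score_fraction(neurons, self.gene_sets[n]), n)
            qp = quarter_group_proportions(part, neurons)
            for g, row in qp.iterrows():
                rows.append({"pathway": n, "group": g, **row.to_dict()})
        _write_table(pd.DataFrame(rows), self.outdir / "quarter_proportions.tsv", self.hash)
        if self.signature_pair.c1_up and self.signature_pair.c4_up:
            check = validate_opposing(self.signature_pair, neurons)
            _write_table(pd.DataFrame([check]), self.outdir / "signature_check.tsv", self.hash)

    def stage_prioritize(self) -> None:
        if self.assignment is None:
            self.assignment = assign_subtypes(self.dataset, self._catalog())
        pair = tuple(self.cfg_dict.get("prioritize_pair", ("O", "Y")))
        table = prioritize(self.dataset, self.assignment, pair, self.analysis)
        _write_table(table, self.outdir / "prioritization.tsv", self.hash)

    def stage_screens(self) -> None:
        if self.assignment is None:
            self.assignment = assign_subtypes(self.dataset, self._catalog())
        if self.scores is None:
            raise PipelineError("stage 'screens' needs stage 'score' first")
        score_table = self.scores
        if self.signature_pair is not None and self.signature_pair.c1_up:
            sig_scores = score_collection(
                self.dataset, self.signature_pair.to_collection()
            )
            score_table = pd.concat([score_table, sig_scores], axis=1)
        ref = self.cfg_dict.get("reference_group", "Y")
        result = rank_subtype_scores(
            self.assignment, score_table, self.dataset, ref, self.analysis
        )
        for name, df in result.stats.items():
            safe = name.replace("/", "_").replace(" ", "_")
            _write_table(df, self.outdir / f"rank_{safe}.tsv", self.hash)
        hits = intersection_screen(result, self.analysis)
        _write_table(hits["top"], self.outdir / "screen_hits_top.tsv", self.hash)
        _write_table(hits["bottom"], self.outdir / "screen_hits_bottom.tsv", self.hash)

    def stage_mr(self) -> None:
        mr_cfg = self.cfg_dict.get("mr")
        if not mr_cfg:
            raise PipelineError("stage 'mr' needs an 'mr' section (exposure/outcome paths)")
        exposure = read_gwas_summary(mr_cfg["exposure"])
        outcome = read_gwas_summary(mr_cfg["outcome"])
        ld = read_ld_table(mr_cfg["ld"]) if "ld" in mr_cfg else None
        result = run_mr(
            exposure, outcome,
            exposure_name=mr_cfg.get("exposure_name", "exposure"),
            outcome_name=mr_cfg.get("outcome_name", "outcome"),
            ld=ld, cfg=self.analysis,
            bidirectional=mr_cfg.get("bidirectional", True),
        )
        rows, screen_rows = [], []
        for direction in ("forward", "reverse"):
            if direction not in result:
                continue
            res = result[direction]
            for m in METHODS:
                f = res.fits.get(m)
                if f:
                    rows.append({"exposure": res.exposure, "outcome": res.outcome,
                                 "direction": direction, "method": m,
                                 "estimate": f.estimate, "se": f.se, "p": f.p,
                                 "odds_ratio": f.odds_ratio, "n_snps": f.n_snps})
            screen_rows.append({
                "exposure": res.exposure, "outcome": res.outcome,
                "direction": direction, "estimable": res.estimable,
                "concordant": res.concordant, "ivw_p": res.ivw_p,
                "pass": res.passed, "heterogeneity": res.heterogeneity,
                "pleiotropy": res.pleiotropy, "reason": res.reason,
                "class": result.get("class", ""),
            })
        _write_table(pd.DataFrame(rows), self.outdir / "mr_methods.tsv", self.hash)
        _write_table(pd.DataFrame(screen_rows), self.outdir / "mr_screen.tsv", self.hash)


def run_pipeline(config_path, outdir=None) -> Path:
    """Execute the stages listed in a YAML configuration; returns the run
    directory.  Unknown stage names and missing inputs are errors."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict):
        raise PipelineError(f"{config_path}: not a mapping")
    stages = cfg.get("stages", list(STAGE_ORDER))
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}; valid: {list(STAGE_ORDER)}")
    out = Path(outdir or cfg.get("outdir", "hyposcreen_run"))
    out.mkdir(parents=True, exist_ok=True)

    run = PipelineRun(cfg, out)
    if any(s != "mr" for s in stages):
        run.load_input()

    with open(out / "run.log", "w") as fh:
        fh.write(f"hyposcreen {__version__}\n")
        fh.write(f"config_hash: {run.hash}\n")
        fh.write(f"seed: {cfg['seed']}\n")
        fh.write("parameters:\n")
        fh.write(yaml.safe_dump(cfg, sort_keys=True))
        for s in STAGE_ORDER:
            if s in stages:
                fh.write(f"stage: {s}\n")
                getattr(run, f"stage_{s}")()
    return out
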