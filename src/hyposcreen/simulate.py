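"""Synthetic data generators with planted, recoverable ground truth.

Two generators cover the two data domains of the pipeline:

* :func:`simulate_expression` emits a negative-binomial snRNA-seq count
  matrix emulating a three-group hypothalamus design — young (Y), old (O)
  and old treated with 17α-estradiol (O.T) — with a dominant neuron class
  among ~10 coarse cell types, sparse near-binary neuropeptide/receptor
  genes that define overlapping neuron subtypes, two anti-correlated
  transcriptional programs (a "metabolic" program A, high in O, and a
  "synaptic" program B, high in Y, with O.T intermediate), flagged
  mitochondrial genes, and explicitly planted QC violators.

* :func:`simulate_gwas_pair` emits paired exposure/outcome GWAS summary
  statistics under a linear causal model with optional pleiotropy, weak
  instruments, and a separate panel of SNPs acting directly on the
  outcome (so that reverse-direction analyses have genuine instruments).

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import ExpressionDataset, GeneSet, GeneSetCollection, SubtypeCatalog

GROUPS = ("Y", "O", "O.T")

#: Coarse cell-type labels; the first is the dominant neuron class.
CELL_TYPES = (
    "Neuron", "Astrocyte", "Oligodendrocyte", "Microglia", "OPC",
    "Endothelial", "Ependymal", "Tanycyte", "Pericyte", "VSMC",
)

#: Default subtype-defining genes: (symbol, category, per-group expression
#: probability among neurons).  Probabilities are loosely graded so group
#: proportions differ, as in the study's proportion figures.
DEFAULT_SUBTYPE_GENES = (
    ("Oxt",   "peptide",  {"Y": 0.10, "O": 0.12, "O.T": 0.22}),
    ("Avp",   "peptide",  {"Y": 0.10, "O": 0.12, "O.T": 0.18}),
    ("Crh",   "peptide",  {"Y": 0.15, "O": 0.15, "O.T": 0.15}),
    ("Gnrh1", "peptide",  {"Y": 0.08, "O": 0.08, "O.T": 0.08}),
    ("Agrp",  "peptide",  {"Y": 0.25, "O": 0.20, "O.T": 0.12}),
    ("Pomc",  "peptide",  {"Y": 0.25, "O": 0.20, "O.T": 0.12}),
    ("Kiss1", "peptide",  {"Y": 0.10, "O": 0.10, "O.T": 0.10}),
    ("Sct",   "peptide",  {"Y": 0.08, "O": 0.08, "O.T": 0.08}),
    ("Prlh",  "peptide",  {"Y": 0.10, "O": 0.10, "O.T": 0.10}),
    ("Ghrl",  "peptide",  {"Y": 0.08, "O": 0.08, "O.T": 0.08}),
    ("Esr1",  "receptor", {"Y": 0.15, "O": 0.15, "O.T": 0.15}),
    ("Ar",    "receptor", {"Y": 0.12, "O": 0.12, "O.T": 0.12}),
    ("Insr",  "receptor", {"Y": 0.20, "O": 0.20, "O.T": 0.20}),
    ("Prlr",  "receptor", {"Y": 0.15, "O": 0.15, "O.T": 0.15}),
    ("Mc3r",  "receptor", {"Y": 0.10, "O": 0.10, "O.T": 0.10}),
    ("Npy1r", "receptor", {"Y": 0.12, "O": 0.12, "O.T": 0.12}),
    ("Lepr",  "receptor", {"Y": 0.12, "O": 0.12, "O.T": 0.12}),
    ("Glp2r", "receptor", {"Y": 0.10, "O": 0.10, "O.T": 0.10}),
)

#: Per-group intensity multipliers of the two opposing programs under the
#: default study conditions: the metabolic program is highest in aged
#: animals, the synaptic one in young, treatment intermediate in both.
DEFAULT_PROGRAM_A_INTENSITY = {"Y": 1.0, "O": 3.0, "O.T": 1.5}
DEFAULT_PROGRAM_B_INTENSITY = {"Y": 3.0, "O": 1.0, "O.T": 1.5}

_PROGRAM_SIZE = 25


def _default_program(prefix: str) -> tuple:
    return tuple(f"{prefix}{i:02d}" for i in range(1, _PROGRAM_SIZE + 1))


@dataclass
class SimExpressionConfig:
    """Study-condition parameters of the expression simulator."""

    n_cells_per_group: dict = field(
        default_factory=lambda: {"Y": 1000, "O": 1000, "O.T": 1000}
    )
    n_genes: int = 2000
    n_celltypes: int = 10
    neuron_fraction: float = 0.6
    subtype_genes: tuple = DEFAULT_SUBTYPE_GENES
    program_A_genes: tuple = field(default_factory=lambda: _default_program("MetA"))
    program_B_genes: tuple = field(default_factory=lambda: _default_program("SynB"))
    program_A_intensity: dict = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_A_INTENSITY)
    )
    program_B_intensity: dict = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_B_INTENSITY)
    )
    #: Program expression follows a bursty-activity model: each cell has
    #: a latent activity z = log(group intensity of program A) + sd·ε.
    #: Cells in the top ``program_on_fraction`` of z express program A at
    #: ``program_boost`` times baseline; cells in the bottom fraction
    #: express program B at the boost.  Outside the active subpopulations
    #: a weak continuous gradient exp(±program_gradient·z) preserves the
    #: ordering.  This couples the two programs anti-correlated cell to
    #: cell and concentrates their contrast in the extreme quarters of
    #: any score partition.
    program_cell_sd: float = 0.5
    program_on_fraction: float = 0.15
    program_boost: float = 3.0
    program_gradient: float = 0.3
    mito_gene_count: int = 10
    qc_violator_fraction: float = 0.02
    nb_dispersion: float = 2.0
    #: Optional planted perturbation: in cells of ``perturbation_group``
    #: belonging to ``perturbed_subtype``, program-A means are multiplied
    #: by ``perturbation_factor``.
    perturbed_subtype: str | None = None
    perturbation_factor: float = 4.0
    perturbation_group: str = "O.T"
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_cells_per_group) != set(GROUPS):
            raise ValueError(f"group labels must be exactly {set(GROUPS)}")
        if any(n <= 0 for n in self.n_cells_per_group.values()):
            raise ValueError("cell counts must be positive")
        overlap = set(self.program_A_genes) & set(self.program_B_genes)
        if overlap:
            raise ValueError(f"program gene lists overlap: {sorted(overlap)[:5]}")
        if not (0 < self.neuron_fraction <= 1):
            raise ValueError("neuron_fraction must be in (0, 1]")
        if not (0 <= self.qc_violator_fraction <= 1):
            raise ValueError("qc_violator_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        n_named = (
            self.mito_gene_count
            + len(self.subtype_genes)
            + len(self.program_A_genes)
            + len(self.program_B_genes)
        )
        if self.n_genes < n_named:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than {n_named} named genes"
            )
        if self.perturbed_subtype is not None:
            names = {g for g, _, _ in self.subtype_genes}
            if self.perturbed_subtype not in names:
                raise ValueError(
                    f"perturbed_subtype {self.perturbed_subtype!r} not in subtype genes"
                )
            if self.perturbation_group not in GROUPS:
                raise ValueError("perturbation_group must be one of Y/O/O.T")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated expression dataset."""

    program_A_genes: tuple
    program_B_genes: tuple
    program_A_intensity: dict
    program_B_intensity: dict
    perturbed_subtypes: tuple
    qc_violator_cells: tuple
    program_activity: np.ndarray  # per-cell latent z

    def to_dict(self) -> dict:
        return {
            "program_A_genes": list(self.program_A_genes),
            "program_B_genes": list(self.program_B_genes),
            "program_A_intensity": dict(self.program_A_intensity),
            "program_B_intensity": dict(self.program_B_intensity),
            "perturbed_subtypes": list(self.perturbed_subtypes),
            "qc_violator_cells": list(self.qc_violator_cells),
        }


def default_subtype_catalog() -> SubtypeCatalog:
    """Catalog matching :data:`DEFAULT_SUBTYPE_GENES` (subtype named
    after its defining gene)."""
    rows = [
        {"subtype": g, "gene": g, "category": cat}
        for g, cat, _ in DEFAULT_SUBTYPE_GENES
    ]
    return SubtypeCatalog(pd.DataFrame(rows))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + mean²/θ."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_expression(config: SimExpressionConfig):
    """Generate a count matrix with planted structure.

    Returns ``(ExpressionDataset, SimTruth)``.  Baseline gene means are
    log-normal; program genes' means are multiplied by the configured
    per-group intensity (times a per-cell latent factor); subtype genes
    are near-binary, expressed with the configured per-group probability
    in neurons and absent elsewhere; QC violators are planted explicitly
    so filter counts are exactly predictable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- gene universe -------------------------------------------------
    mito_genes = [f"mt-{i}" for i in range(1, config.mito_gene_count + 1)]
    subtype_names = [g for g, _, _ in config.subtype_genes]
    named = mito_genes + subtype_names + list(config.program_A_genes) + list(
        config.program_B_genes
    )
    n_filler = config.n_genes - len(named)
    filler = [f"gene{i:04d}" for i in range(1, n_filler + 1)]
    symbols = named + filler
    if len(set(symbols)) != len(symbols):
        raise ValueError("gene name collision between named and filler genes")

    var = pd.DataFrame(
        {
            "is_mito": [s in set(mito_genes) for s in symbols],
            "is_tf": False,
        },
        index=pd.Index(symbols, name="symbol"),
    )
    # flag a deterministic slice of filler genes as TFs for TF-filter tests
    tf_slice = [s for s in filler[: max(1, n_filler // 10)]]
    var.loc[tf_slice, "is_tf"] = True

    sym_pos = {s: i for i, s in enumerate(symbols)}
    a_idx = np.array([sym_pos[g] for g in config.program_A_genes])
    b_idx = np.array([sym_pos[g] for g in config.program_B_genes])
    mito_idx = np.array([sym_pos[g] for g in mito_genes])
    subtype_idx = {g: sym_pos[g] for g in subtype_names}

    # --- cells ---------------------------------------------------------
    groups, types = [], []
    for g in GROUPS:
        n = config.n_cells_per_group[g]
        n_neu = int(round(n * config.neuron_fraction))
        others = CELL_TYPES[1 : config.n_celltypes]
        t = ["Neuron"] * n_neu + [
            others[i % len(others)] for i in range(n - n_neu)
        ]
        groups += [g] * n
        types += t
    n_cells = len(groups)
    obs = pd.DataFrame(
        {"group": groups, "cell_type": types},
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    group_arr = np.array(groups)
    is_neuron = np.array([t == "Neuron" for t in types])

    # --- mean structure ------------------------------------------------
    base = rng.lognormal(mean=np.log(0.3), sigma=1.0, size=config.n_genes)
    base[mito_idx] = 3.0
    base[a_idx] = 1.0
    base[b_idx] = 1.0
    # subtype genes are handled separately (near-binary); silence baseline
    for g in subtype_names:
        base[sym_pos[g]] = 0.0

    # latent activity: group intensity shift plus per-cell noise; the two
    # programs read it with opposite sign
    shift_a = np.log([config.program_A_intensity[g] for g in group_arr])
    shift_b = np.log([config.program_B_intensity[g] for g in group_arr])
    eps = rng.normal(size=n_cells)
    z_a = shift_a + config.program_cell_sd * eps
    z_b = shift_b - config.program_cell_sd * eps
    on_a = z_a >= np.quantile(z_a, 1.0 - config.program_on_fraction)
    on_b = z_b >= np.quantile(z_b, 1.0 - config.program_on_fraction)
    mult_a = np.where(on_a, config.program_boost,
                      np.exp(config.program_gradient * z_a))
    mult_b = np.where(on_b, config.program_boost,
                      np.exp(config.program_gradient * z_b))
    z = z_a

    # subtype membership indicators, decided before sampling so a planted
    # perturbation can target the member cells
    member: dict = {}
    for g, _cat, probs in config.subtype_genes:
        p = np.array([probs[grp] for grp in group_arr])
        on = (rng.random(n_cells) < p) & is_neuron
        member[g] = on

    mean = np.tile(base, (n_cells, 1))
    mean[:, a_idx] *= mult_a[:, None]
    mean[:, b_idx] *= mult_b[:, None]

    perturbed: tuple = ()
    if config.perturbed_subtype is not None:
        target = member[config.perturbed_subtype] & (
            group_arr == config.perturbation_group
        )
        mean[np.ix_(target, a_idx)] *= config.perturbation_factor
        perturbed = (config.perturbed_subtype,)

    counts = _nb_sample(rng, mean, config.nb_dispersion)

    # near-binary subtype genes: count ≥ 1 for members, 0 otherwise
    for g in subtype_names:
        col = np.zeros(n_cells, dtype=np.int64)
        on = member[g]
        col[on] = 1 + rng.poisson(0.5, size=int(on.sum()))
        counts[:, subtype_idx[g]] = col

    # --- planted QC violators ------------------------------------------
    n_viol = int(round(config.qc_violator_fraction * n_cells))
    viol_cells: list = []
    if n_viol:
        viol = rng.choice(n_cells, size=n_viol, replace=False)
        filler_idx = sym_pos[filler[-1]]
        for k, i in enumerate(sorted(viol)):
            total = counts[i].sum()
            if k % 2 == 0:  # UMI violator: push total to ≥ 8000
                counts[i, filler_idx] += max(0, 8000 - total) + int(rng.integers(0, 500))
            else:  # mito violator: push mito percent to ≥ 15, total stays small
                mito_total = counts[i, mito_idx].sum()
                need = int(np.ceil((0.15 * total - mito_total) / 0.85)) + 2
                counts[i, mito_idx[0]] += max(need, 0)
            viol_cells.append(obs.index[i])

    d = ExpressionDataset(sp.csr_matrix(counts), obs, var)
    truth = SimTruth(
        program_A_genes=tuple(config.program_A_genes),
        program_B_genes=tuple(config.program_B_genes),
        program_A_intensity=dict(config.program_A_intensity),
        program_B_intensity=dict(config.program_B_intensity),
        perturbed_subtypes=perturbed,
        qc_violator_cells=tuple(viol_cells),
        program_activity=z,
    )
    return d, truth


def make_program_pathways(
    truth: SimTruth,
    n_pathways: int = 6,
    coverage: float = 0.8,
    n_background: int = 15,
    background_genes: tuple = (),
    seed: int = 0,
) -> GeneSetCollection:
    """Six synthetic pathways, each a random subset of program-A genes
    plus inert background genes.

    All six score positively on the planted metabolic program, so their
    quartile partitions orient identically — the construction under which
    intersecting per-quarter unique markers across pathways recovers the
    planted programs (program A as the c1-up signature, program B as the
    c4-up one).
    """
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    a = list(truth.program_A_genes)
    bg = list(background_genes)
    for i in range(n_pathways):
        k = max(2, int(round(coverage * len(a))))
        members = list(rng.choice(a, size=k, replace=False))
        if bg:
            members += list(
                rng.choice(bg, size=min(n_background, len(bg)), replace=False)
            )
        coll.add(GeneSet(name=f"pathway_{i + 1}", members=tuple(members), source="synthetic"))
    return coll


# ======================================================================
#  GWAS summary-statistic simulation
# ======================================================================

_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass
class GwasSimConfig:
    """Two-trait GWAS simulation under a linear causal model.

    ``n_snps`` SNPs act on the exposure (true effects N(0, sd²)); the
    outcome effect of each is ``causal_effect`` times its exposure effect
    plus a pleiotropic term and estimation noise.  A further
    ``n_outcome_snps`` act directly on the outcome (effects N(0, sd²)),
    giving reverse-direction analyses genuine instruments; their exposure
    effects are ``reverse_causal_effect`` times the direct effect.
    Standard errors follow the 1/√(2·maf·(1−maf)·n) scaling.
    """

    n_snps: int = 100
    exposure_effect_sd: float = 0.045
    causal_effect: float = 0.3
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    maf_range: tuple = (0.05, 0.5)
    weak_fraction: float = 0.0
    #: scale of weak instruments' effect sd relative to the strong ones
    weak_scale: float = 0.05
    n_outcome_snps: int = 100
    outcome_effect_sd: float | None = None
    reverse_causal_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo ≤ hi ≤ 0.5")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be ≥ 2")
        if not (0 <= self.weak_fraction <= 1):
            raise ValueError("weak_fraction must be in [0, 1]")
        if self.pleiotropy_sd < 0 or self.exposure_effect_sd <= 0:
            raise ValueError("effect scales out of domain")


@dataclass
class GwasSummaryPair:
    """Harmonizable exposure/outcome summary-statistic tables over a
    shared SNP panel."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame


@dataclass
class GwasTruth:
    causal_effect: float
    reverse_causal_effect: float
    exposure_panel: tuple
    outcome_panel: tuple
    weak_snps: tuple
    true_exposure_beta: dict
    true_outcome_beta: dict


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return np.minimum(2.0 * norm.sf(np.abs(beta / se)), 1.0)


def simulate_gwas_pair(config: GwasSimConfig):
    """Generate one exposure/outcome GWAS summary pair.

    SNPs are mutually independent (LD r² = 0 by construction).  Returns
    ``(GwasSummaryPair, GwasTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_fwd, n_rev = config.n_snps, config.n_outcome_snps
    n = n_fwd + n_rev
    out_sd = (
        config.outcome_effect_sd
        if config.outcome_effect_sd is not None
        else config.exposure_effect_sd
    )

    snps = np.array([f"rs{i + 1}" for i in range(n)])
    maf = rng.uniform(*config.maf_range, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    # true per-allele effects
    b_exp_true = np.zeros(n)
    b_exp_true[:n_fwd] = rng.normal(0.0, config.exposure_effect_sd, size=n_fwd)
    n_weak = int(round(config.weak_fraction * n_fwd))
    weak = rng.choice(n_fwd, size=n_weak, replace=False) if n_weak else np.array([], int)
    b_exp_true[weak] *= config.weak_scale

    g_out_direct = np.zeros(n)
    if n_rev:
        g_out_direct[n_fwd:] = rng.normal(0.0, out_sd, size=n_rev)

    pleio = np.zeros(n)
    pleio[:n_fwd] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_fwd)

    b_out_true = config.causal_effect * b_exp_true + pleio + g_out_direct
    # direct outcome SNPs feed back into the exposure only under a
    # reverse causal effect
    b_exp_true = b_exp_true + config.reverse_causal_effect * g_out_direct

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    beta_exp = b_exp_true + rng.normal(0.0, se_exp)
    beta_out = b_out_true + rng.normal(0.0, se_out)

    def table(beta, se, nsamp):
        return pd.DataFrame(
            {
                "snp": snps,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": beta,
                "se": se,
                "pval": _wald_p(beta, se),
                "eaf": maf,
                "n": nsamp,
            }
        )

    pair = GwasSummaryPair(
        exposure=table(beta_exp, se_exp, config.n_exposure),
        outcome=table(beta_out, se_out, config.n_outcome),
    )
    truth = GwasTruth(
        causal_effect=config.causal_effect,
        reverse_causal_effect=config.reverse_causal_effect,
        exposure_panel=tuple(snps[:n_fwd]),
        outcome_panel=tuple(snps[n_fwd:]),
        weak_snps=tuple(snps[weak]),
        true_exposure_beta=dict(zip(snps, b_exp_true)),
        true_outcome_beta=dict(zip(snps, b_out_true)),
    )
    return pair, truth


# ======================================================================
#  Deterministic toy fixture
# ======================================================================

_TOY_SEED = 20240817


def make_toy_fixture() -> ExpressionDataset:
    """A deterministic 60-cell × 100-gene dataset for exact QC tests.

    Built from a fixed internal seed and then adjusted so that exactly
    three cells (the last three) exceed the 8,000-UMI bound — one of them
    at exactly 8,000 to pin the inclusive boundary — and exactly two
    cells exceed the 15% mitochondrial bound.  All remaining 55 cells are
    verified at construction time to violate neither bound, so
    ``qc_filter`` retains exactly 55 of 60 cells.  Regenerating and
    writing the fixture yields byte-identical files.
    """
    rng = np.random.default_rng(_TOY_SEED)
    n_cells, n_genes = 60, 100
    mito = [f"mt-{i}" for i in range(1, 6)]
    special = ["Oxt", "Avp", "Crh", "Esr1", "Insr"]
    filler = [f"gene{i:03d}" for i in range(1, n_genes - len(mito) - len(special) + 1)]
    symbols = mito + special + filler

    mean = np.full(n_genes, 1.0)
    mean[:5] = 0.4            # mito genes kept low so no accidental violator
    counts = rng.poisson(mean, size=(n_cells, n_genes))

    # subtype genes expressed in a deterministic subset of neurons
    for j, g in enumerate(special):
        on = rng.random(n_cells) < 0.3
        counts[:, 5 + j] = np.where(on, 1 + rng.poisson(0.5, n_cells), 0)

    # planted mito violators: cells 55, 56
    for i in (55, 56):
        total = counts[i].sum()
        need = int(np.ceil((0.15 * total - counts[i, :5].sum()) / 0.85)) + 2
        counts[i, 0] += max(need, 0)
    # planted UMI violators: cells 57 (exactly at the bound), 58, 59
    for i, target in ((57, 8000), (58, 8600), (59, 9200)):
        counts[i, -1] += target - counts[i].sum()

    totals = counts.sum(axis=1)
    pct = 100.0 * counts[:, :5].sum(axis=1) / totals
    umi_bad = totals >= 8000
    mito_bad = pct >= 15.0
    assert umi_bad.sum() == 3 and mito_bad.sum() == 2
    assert not np.any(umi_bad & mito_bad)

    obs = pd.DataFrame(
        {
            "group": [GROUPS[i % 3] for i in range(n_cells)],
            "cell_type": ["Neuron" if i % 3 != 2 else "Astrocyte" for i in range(n_cells)],
        },
        index=pd.Index([f"toy{i:02d}" for i in range(n_cells)], name="cell_id"),
    )
    var = pd.DataFrame(
        {"is_mito": [s.startswith("mt-") for s in symbols], "is_tf": False},
        index=pd.Index(symbols, name="symbol"),
    )
    return ExpressionDataset(sp.csr_matrix(counts), obs, var)
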