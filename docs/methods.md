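# Methods

This note documents the models and procedures implemented in
`hyposcreen`, the choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Data model and preprocessing

An `ExpressionDataset` holds sparse non-negative integer counts
(cells × genes), cell metadata (sample group ∈ {Y, O, O.T}, coarse cell
type, derived total UMI and mitochondrial percent) and gene metadata
(`is_mito`, `is_tf`). Mitochondrial genes are identified by an explicit
flag rather than a symbol prefix, because symbol conventions differ
between organisms and annotation builds.

QC removes cells with total UMI ≥ 8,000 or mitochondrial percent ≥ 15.
Both bounds are **inclusive**; the toy fixture plants one violator at
exactly 8,000 UMIs to pin this. The filter is order-preserving and
idempotent.

Two expression layers coexist deliberately:

* **raw counts** — used by gene-set fraction scores (percent of counts in
  the set) and by the subtype membership rule (count > 0), both of which
  are defined on counts;
* **CP10K + log1p** — used by marker tests, differential expression,
  subtype profiles and TF activity, which need a variance-stabilized
  layer. Counts per cell are scaled to 10,000 and log(1+x) transformed.
  The normalization target for marker detection was an open choice; CP10K
  is the default of the dominant single-cell toolchains and is recorded
  in the configuration.

## Pathway scoring, TF activity, correlation

The fraction score of set *S* in cell *i* is
100·Σ_{g∈S} c_ig / Σ_g c_ig. It is invariant to sequencing depth and
sums to 100 over a disjoint cover of the gene universe. TFs are retained
when their mean raw count across cells is strictly greater than 0.1.

TF activity uses the univariate linear model: for each cell, ordinary
least squares of the cell's normalized expression across all genes on a
TF's target-weight vector (weight 0 outside the regulon, intercept
included); the activity is the slope t-statistic, computed in closed form
via the correlation identity t = r·√((n−2)/(1−r²)). Constant cells have
activity 0; zero-weight-variance regulons are reported missing. The
activity is antisymmetric under weight negation.

Pearson correlation reports use the exact t-transform p-value and flag
significance at raw p < 0.05 (no multiplicity adjustment — the gate the
screening protocol specifies; configurable). Whether correlations should
be computed per cell or on group-aggregated scores was open; per-cell is
the default.

## Quartile partition and opposing signatures

For one pathway, neurons pooled across the three groups are sorted by
fraction score (descending, ties broken by stable cell id) and cut into
four contiguous blocks whose sizes differ by at most one (earlier blocks
take the remainder), c1 = highest quarter. The Tukey five-number summary
of the score is reported alongside as the classical hinge description of
the same split; the equal-count rule, not hinge intervals, defines the
blocks, because hinge-based assignment cannot guarantee equal cell
numbers under ties.

Per quarter, one-vs-rest Wilcoxon rank-sum markers (positive only) must
satisfy min.pct ≥ 0.1, mean log-difference ≥ 0.25 and BH-adjusted
p < 0.05. A **unique** marker is a gene passing in exactly one quarter.
The c1-up (resp. c4-up) signature is the set of genes that are unique c1
(c4) markers in *every* supplied pathway partition. Orientation matters:
c1 is always the high-score quarter, and the supplied pathways must be
positively aligned with a common program axis for the intersection to be
meaningful — the synthetic pathway builder therefore emits sets all
loaded on the same planted program. The derived pair is validated by
requiring the two signatures' per-cell fraction scores to correlate
negatively.

The rank-sum machinery ranks each gene column once per cell population
and reuses the ranks across all quarters and pathway partitions (ranks do
not depend on the grouping), which makes the six-pathway derivation on
3,000 × 2,000 data run in seconds.

## auROC ranking, DEG, screens, ORA

auROC between two groups is U/(n₁·n₂) with ties counting one half —
verified exactly against brute-force all-pairs enumeration — with a
tie-corrected normal-approximation two-sided p. Comparisons require at
least 15 cells per side.

Pairwise differential expression uses the bimodal likelihood-ratio test:
each group's expression is modeled as a point mass at zero plus a normal
on the positive log-normalized values; the 2-df LRT compares pooled vs
per-group fits. Genes pass pre-filters min.pct ≥ 0.1 and
|mean log difference| ≥ 0.25, BH adjustment, and a final
|avg_diff| > 0.1 gate. On discrete count data this test family is known
to be anticonservative in its raw p-values (we measure ~10% at nominal
5% under a matched null); BH across ~2,000 genes absorbs this in
practice, and the null benchmark asserts the post-BH call rate rather
than a nominal raw rate.

Subtype rank screens average each score over a subtype's cells **in the
reference group only**, rank descending (alphabetical tie-break), and
intersect top-K (bottom-K) membership across score sets: a hit must
appear in at least `screen_min_hits` (default 4) of the lists with
K = 20. Screens are monotone in K. Over-representation uses the exact
hypergeometric tail with BH FDR < 0.05.

## Supervised subtypes and prioritization

Membership is exactly reproducible from the count matrix: neurons with
raw count > 0 for the defining gene. Count rankings exclude subtypes
below 10 cells in the reference group (inclusive at 10). Weighted
proportions divide a subtype's members per group by that group's total
neuron count; a cross-group relative share (the three proportions scaled
to unit sum) is emitted for display. Similarity between subtypes is
reported as two matrices — Pearson r of mean normalized profiles over the
common gene panel, and membership Jaccard — because a single "similarity
index" is underdetermined and overlap-driven similarity is expected by
construction.

Prioritization draws, per subtype and repetition (R = 50), six cells per
condition without replacement, selects the subtype's top 250
highest-variance genes, and evaluates a random forest (8 trees, 3-fold
stratified CV) by pooling held-out class probabilities into one AUC per
repetition; the subtype score is the mean AUC. Tree and feature counts
are desk-scale choices: with six-cell subsamples the AUC averages over
repetitions long before large ensembles pay off. Sub-streams are keyed by
a stable hash of the subtype name, so a subtype's score does not depend
on which other subtypes are present.

## Mendelian randomization

Instrument selection: exposure p < 1e-5; greedy clumping in ascending-p
order at r² < 0.001 against a user-supplied LD table (SNPs are assumed
independent, with a log notice, when no table is given — the synthetic
panels are independent by construction); F = (β/se)², instruments with
F < 10 discarded (F = 10 retained). Harmonization aligns outcome effects
to the exposure effect allele, flipping signs for swapped or
strand-flipped alleles and dropping palindromic SNPs with |eaf − 0.5| <
0.08 (a common harmonization default; configurable).

Per-SNP Wald ratios β_out/β_exp carry first-order standard errors
se_out/|β_exp|. Estimators:

* **IVW** — inverse-variance-weighted mean of ratios; the standard error
  is scaled by max(1, √(Q/(k−1))) (multiplicative random effects with a
  fixed-effects floor, the dominant toolchain default; fixed-effects
  available). Under a well-specified null this floor makes the test
  mildly conservative (measured rejection ≈ 0.04 at nominal 0.05 with
  ~50 instruments).
* **MR-Egger** — weighted regression of outcome on exposure betas with
  intercept (weights 1/se_out²), exposure effects oriented positive;
  t-distribution p on k−2 df; the intercept is the pleiotropy test. The
  slope is unidentifiable when all exposure betas coincide; that case is
  reported as not fitted.
* **Weighted median** — interpolated 50% point of the weight-cumulative
  ratio distribution; parametric bootstrap se (1,000 draws, seeded).
* **Simple/weighted mode** — mode of the (weighted) Gaussian-kernel ratio
  density, bandwidth φ·0.9·min(sd, mad)·k^(−1/5) with φ = 1; bootstrap
  se. Bootstrap can be disabled (`n_boot = 0`) for large screens, where
  only estimate signs and the IVW p enter the decision.

Heterogeneity is Cochran's Q of the ratios about the fixed-effect IVW
mean (χ², k−1 df). The screening rule: a direction passes iff all five
estimates share one sign (equivalently all OR = exp(β) on the same side
of 1) and IVW p < 0.05; heterogeneity and pleiotropy flags annotate but
never gate. Bidirectional classification runs the screen with exposure
and outcome roles swapped and labels the pair forward-only /
reverse-only / bidirectional / none. Whether the p-threshold should be
multiplicity-adjusted across many outcomes was open; the unadjusted
printed threshold is used.

## Synthetic data: what it emulates

`simulate_expression` draws counts from a negative binomial
(variance μ + μ²/θ, shared θ = 2) over log-normal baseline means, with:

* three groups (Y, O, O.T), ten coarse cell types, neurons dominant;
* two disjoint 25-gene programs with opposing group intensity —
  metabolic A (O = 3, O.T = 1.5, Y = 1) and synaptic B (mirror image) —
  expressed through a **bursty-activity model**: each cell has latent
  activity z = log(group intensity) + 0.5·ε; the top 15% of cells by z
  express program A at 3× baseline, the bottom 15% express program B at
  3×, and a weak exp(0.3·z) gradient orders the remainder. The burst
  concentrates the programs' one-vs-rest contrast in the extreme quarters
  of any score partition, so mid-quarters have no unique markers — the
  regime in which quarter-intersection signature derivation is
  well-posed — while the gradient keeps group proportions monotone across
  quarters. A graded-only model was tried first and rejected: it makes
  the second quarter weakly but significantly elevated, which empties the
  intersected signatures.
* near-binary subtype genes (present with a per-group probability in
  neurons, absent elsewhere) matching the count > 0 membership rule;
* flagged mitochondrial genes and explicitly planted QC violators
  (alternating UMI ≥ 8,000 and mito ≥ 15% constructions), so filter
  counts are exactly predictable;
* an optional planted perturbation: one subtype's program-A means
  multiplied by 4 in one group. The prioritization benchmark plants this
  on otherwise group-flat programs, because with the full group contrast
  every subtype separates and the ranking saturates; the flat background
  isolates the planted signal as the only true effect.

`simulate_gwas_pair` draws per-SNP exposure effects N(0, 0.045²), MAF
uniform on (0.05, 0.5), standard errors 1/√(2·maf·(1−maf)·n) with
n = 50,000 per trait, outcome effects causal·β + pleiotropy + noise, and
Wald p-values; SNPs are independent by construction. A second panel of
SNPs acts directly on the outcome so reverse-direction analyses have
genuine instruments rather than failing vacuously. The effect scale was
chosen so that roughly half of 100 SNPs pass the p < 1e-5 instrument
gate (~50 instruments, typical F ≈ 20–100) while mediated outcome
associations of exposure SNPs rarely reach instrument significance —
the regime in which a forward-only causal structure is identifiable
without Steiger filtering. Weak instruments (effects shrunk 20-fold) can
be mixed in to exercise the F filter.

The deterministic toy fixture (60 cells × 100 genes, fixed internal
seed) plants exactly 3 UMI violators and 2 mitochondrial violators and
verifies at construction that no other cell violates either bound.

## What the benchmarks do and do not show

The synthetic generator omits ambient RNA, doublets, batch structure and
spatial effects, and its programs are cleanly disjoint gene sets.
Passing benchmarks therefore demonstrate that the procedures are
implemented correctly and recover planted structure under the stated
noise model — not that the biological conclusions of any particular
study are reproducible, which would require the original deposited data
and curated gene lists. Headline quantities derived from real data
(specific signature gene identities, trait hits, hormone levels) are out
of scope by design.

## Numerical choices and degenerate inputs

* Rank-sum p-values use the tie-corrected normal approximation without
  continuity correction (matching the fast single-cell implementations);
  constant features report p = 1.
* Quartile ties: stable cell-id order; identical scores still yield
  near-equal blocks.
* Mode estimators fall back to the weighted mean when the bandwidth rule
  degenerates (all ratios equal); all-equal ratios report Q = 0, p = 1.
* Zero exposure betas are dropped before ratio formation; zero-total
  cells are rejected rather than normalized.
* All stochastic components (simulation, subsampling, cross-validation,
  bootstrap) derive from explicit integer seeds; pipeline reruns with the
  same YAML configuration are byte-identical, and every output table
  carries the configuration hash.

## Benchmark problem sizes

Signature recovery runs on 3,000 neurons × 2,000 genes through six
pathway partitions; prioritization on 900 cells × 2,000 genes with nine
subtypes over ten seeds; MR calibration on 500 null replicates and
recovery on 200 replicates of ~50-instrument panels; the auROC oracle on
1,000 random instances. These sizes were chosen as the smallest at which
the planted effects are comfortably identifiable.
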