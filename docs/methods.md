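# Methods

## Scope and data model

The pipeline operates downstream of primary data processing: it consumes
gene x sample integer count matrices with two-level group labels (bulk),
cell x gene counts with per-cell population and stage labels (single cell,
already clustered and typed), a per-guide screen table, a ligand-receptor
interaction table, gene lists (surface atlas, blacklist), long-form
survival tables and dose-response tables. Alignment, counting, single-cell
clustering and cell typing are out of scope by design.

## Differential expression

Bulk two-group testing uses a Welch t-test per gene on log2(CPM + 1) with
the fold-change defined as log2((mean CPM_disease + 0.5) / (mean
CPM_control + 0.5)) and Benjamini-Hochberg adjustment across genes. This is
a deliberately transparent stand-in for a negative-binomial GLM: it is
closed-form, easy to validate against hand arithmetic and Monte-Carlo
oracles, and has well-calibrated type-I error on the negative-binomial
counts the generator produces (verified at 0.03-0.07 for alpha = 0.05 in
the acceptance suite). It is not a small-sample-optimal NB test; users
analysing real RNA-seq at n < 5 per group should expect less power than
DESeq2-style shrinkage estimators.

## Receptor cascade

Selection gates are strict inequalities: padj < alpha (default 0.05) and
log2FC > 0. Screen dropout aggregates guides by the per-gene median of
log2 fold-changes with an inclusive threshold (median <= -log2(fold),
default fold 2, i.e. "two-fold or more"); the median was chosen over the
mean for robustness to single outlier guides and is configurable. The
blacklist of genes misannotated as cell-surface ships as a 16-gene input
file, not hard-coded. Disease categories (both / AML_only / bcCML_only)
are computed from the per-disease upregulated sets after the surface and
screen gates. Ligand-based exclusion distinguishes receptors with zero
interaction-table rows (no_known_ligand) from receptors whose ligands all
fail the enrichment call (no_enriched_ligand). The ledger asserts the
conservation identity |candidates| = |survivors| + sum of per-reason
exclusions on every run.

## Ligand enrichment

Candidate ligands are tested one-vs-rest per population with the
Mann-Whitney rank-sum test on per-cell library-size-normalized (10,000
counts, log1p) expression. Exact p-values are computed by full relabeling
enumeration when n1 + n2 <= 10 (two-sided: probability of a U at least as
far from n1 n2 / 2 as observed); larger samples use the normal
approximation with tie and continuity correction. A call passes with
BH-adjusted p < 0.05, log2FC > 0 and detection fraction >= 0.1 in the
target population; the detection gate mirrors common single-cell marker
defaults, and populations below 10 cells are skipped to avoid rank-sum
degeneracy. Fold-changes of 5 or higher are capped at 5 in the exported
edge weights. Stages are pooled for enrichment by default; a per-stage
mode exists because it is genuinely ambiguous which is preferable — pooling
gains power for steady ligands, per-stage testing is more faithful for
transient ones.

## Temporal classes

"Expressed" means detection fraction >= theta_expr (default 0.1) in a
(population, stage) group. Classes are decided in the order lost,
transient, population_shift, steady; first match wins:

- lost: expressed at naive in some population, expressed nowhere at end;
- transient: not expressed at naive, expressed at an interior stage, not
  expressed at end;
- population_shift: expressed at every stage, but the argmax-expressing
  population differs between stages (ties broken lexicographically, so
  input population order cannot change labels);
- steady: some single population expressed at all four stages with
  trajectory coefficient of variation < theta_cv (default 0.5);
- otherwise unclassified.

The lost rule requires expression at the naive stage specifically; a gene
first detected at initiation and gone by the end is transient (it rose and
fell), which keeps the two classes disjoint. Trajectory clustering
z-scores each gene's four-stage trajectory, uses 1 - Pearson correlation
as distance with average-linkage hierarchical clustering, diverts
zero-variance genes to a dedicated "flat" cluster, and tags cluster
consensus trajectories increasing/decreasing by Spearman correlation with
stage index at |rho| >= 0.8 — with four points only near-perfect
monotonicity qualifies, which is the honest bar; the same rule tags
population-proportion trends.

## Survival

The expression split is the sample median with ties assigned to the high
stratum (< cutoff vs >= cutoff), matching the convention that yields an
80/81 split of 161 distinct values. The log-rank statistic accumulates
observed and expected events and the hypergeometric variance over distinct
event times, skipping the variance contribution when a single subject
remains at risk. The hazard ratio is the Pike O/E ratio
(O1/E1)/(O2/E2) with a log-scale Wald 95% CI using sqrt(1/E1 + 1/E2);
it is closed-form and directly checkable per event time, which is why it
was preferred over a Cox partial-likelihood estimate (deliberately
omitted). Prioritization flags poor prognosis when the hazard ratio
exceeds 1 and the test is significant on the BH-adjusted p-value across
the receptor panel (default); a raw-p mode is available. The adjusted
default keeps the family-wise false-flag rate low enough that, on the
synthetic panel of 22 receptors with two prognostic genes, exactly the
planted pair is flagged in >= 90% of replicates.

## Synergy

The median-effect fit is ordinary least squares on
log10(fa/(1-fa)) = m log10 D - m log10 Dm, the canonical linearization; no
weighting is applied. Fractions affected of exactly 0 or 1 are rejected
rather than clipped — clipping silently manufactures leverage points at
infinite log-odds. The combination index is CI = d1/Dx1(fa) + d2/Dx2(fa);
the two addends are emitted as the normalized-isobologram coordinates, so
CI equals their sum as a structural identity. A sham self-combination
(one drug split 50/50 against its own curve) returns CI = 1 exactly.

## Synthetic study conditions

The generator's defaults define the reference study:

- Bulk: 500 genes, 8 samples per group per disease, negative-binomial
  counts with Var = mu + phi mu^2 (phi = 0.1), gene baselines log-uniform
  on (1, 1000) shared between diseases. Planted receptors (three shared,
  two AML-only, one bcCML-only; log2FC 2-2.5) have baselines floored at 30
  counts, reflecting that curated surface-receptor candidates are
  expressed genes, not threshold-level noise.
- Screen: 4 guides per gene, per-guide log2FC ~ Normal(effect, 0.3);
  planted dropouts (true receptors and decoys) at effect -1.5.
- Niche: four populations over four stages, 300 cells per stage, cells
  assigned multinomially with proportions drifting the way the leukaemia
  niche remodels (MSC 0.15->0.30, osteolineage 0.15->0.22, arteriolar
  endothelium 0.20->0.28, sinusoidal endothelium 0.50->0.20); Poisson
  counts around population x stage means. Planted ligands express at mean
  3 per cell in their population under four templates — steady
  (mu, mu, mu, mu), lost (mu, mu, mu, ~0), transient (~0, mu, mu, ~0),
  population_shift (mu throughout, expressing population switches at the
  expansion stage); off-target expression is 0.01 and unplanted panel
  genes sit at 0.3 everywhere. A depth-padding gene holds the expected
  per-cell total constant across groups so that library-size normalization
  cannot turn unplanted genes into spurious compositional markers —
  real single-cell data has no such padding, so passing recovery tests
  here does not certify robustness to strong compositional shifts.
- Decoy design: every failure mode of the cascade is planted — three
  blacklisted receptors, two ligand-less receptors, two receptors whose
  only ligands stay flat, and ten decoy interaction pairs joining
  background ligands to random receptors, so false edges can only arise
  through genuine false-positive enrichment calls.
- Survival: 22-receptor panel, 161 patients per gene (the standard TCGA
  LAML cohort size for this analysis), expression ~ Normal(10, 2),
  exponential event times with rate h0 exp(beta (x - 10)), h0 = 0.1,
  uniform censoring on (0, 30); two planted prognostic receptors at
  beta = 0.6 per expression unit (hazard ratio ~3.3 per SD), the rest
  null.
- Synergy: two drugs with (m, Dm) = (2, 1) and (1.5, 10) on five-point
  two-fold dose grids.

Effect sizes for ligand temporal classes are free parameters of the
generator, not estimates of any real dataset. Each generator draws from an
independent, named substream of one root seed; identical configurations
produce byte-identical outputs, which the suite asserts.

What the generator does not emulate: read-level data, UMI/ambient-RNA
artifacts, doublets, batch effects, overdispersed (non-Poisson)
single-cell noise, dependence between the bulk and single-cell
compartments, and non-exponential hazards. Recovery results should be read
as verification of the pipeline's logic under its stated model, not as
power estimates for real cohorts.

## Numerical and reproducibility choices

Problem sizes in the replicate-based suites (200 interactome replicates,
100 survival replicates, 50 temporal replicates, 2,000-replicate and
2,000-gene null calibrations) keep a full verification run around a minute
on one CPU while leaving binomial noise on the measured rates well inside
the asserted bands. All exported numerics are rounded to six significant
digits so reruns diff byte-identically; BH uses a stable sort so ties are
reproducible; degenerate inputs (zero-total samples or cells, all-equal
expression splits, zero log-rank variance with unequal observed/expected
events, fa at 0 or 1) raise errors naming the offender rather than
propagating NaNs.
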