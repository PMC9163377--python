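# Methods

## Scope

`gbmstates` re-implements, as a tested library, the bespoke computations of
a glioblastoma (GBM) single-cell RNA-seq workflow: cell/gene quality
control, chromosome-level CNV malignancy scoring, permutation-calibrated
single-sample GSEA (ssGSEA) annotation of tumor cellular states, signature
survival stratification with the Mantel–Cox log-rank test, and cohort
composition/correlation statistics including the regulon specificity score.
A synthetic-data generator plants every structure the downstream stages
assume, so all guarantees are testable against known ground truth.
Upstream steps (read alignment, graph clustering, embedding, batch
correction, the internals of dedicated doublet callers, regulon network
inference) are out of scope; the pipeline consumes their outputs (count
matrices, doublet masks, regulon activity matrices) as inputs.

## Synthetic cohorts

`simulate_cohort` draws UMI counts from a gamma–Poisson (negative binomial)
model with a shared dispersion.  Per cell: a lognormal library size
(`libsize_logmean`, default log 10 000; `libsize_logsd` 0.35), a
Beta(`mito_beta_a`=2, `mito_beta_b`=30) mitochondrial fraction (mean ≈ 6%),
and an exact per-sample tumor/normal split (`tumor_fraction`, default 0.6;
normal cells model the diploid oligodendrocyte-like reference the CNV step
needs).  Per gene: a fixed lognormal relative-abundance profile
(`abundance_logsd`, default 0.5).  Tumor cells multiply gene means by a
whole-chromosome fold change (`cnv_profile`, default chr7 ×1.5 / chr10
×0.5, the canonical GBM gain/loss) and, for the cell's planted state, by
`signature_boost` (default 2.0) on that state's signature genes; weights
are renormalized so library size and mitochondrial fraction are respected.
Doublets (rate 0.05) replace a cell's counts by the sum of its own and a
same-sample partner's counts, giving an exactly testable ground-truth mask.

Design notes:

- CNV is a whole-chromosome mean fold change — the malignancy score only
  consumes chromosome averages, so segmental events would add nothing the
  pipeline can see.
- Dispersion (default r = 5) and abundance spread (0.5) describe a
  deduplicated-UMI panel: UMI counts are near-Poisson, and the 3 000-gene
  universe behaves like an informative panel rather than a whole
  transcriptome with its extreme abundance tails.  These values were set so
  that the structures the generator advertises (a 2× signature boost,
  ±50% chromosome folds) are statistically recoverable at cohort sizes of
  a few hundred cells — the generator's purpose is to plant recoverable
  structure, and a noise regime that hides its own planted effects would
  test nothing downstream.
- What the generator does not emulate: ambient RNA, batch effects, UMI
  saturation, segmental CNVs, cell-cycle or other shared programs beyond
  the planted states, and realistic whole-transcriptome abundance tails.
  Passing tests therefore demonstrate correctness of the computations and
  recoverability of planted structure, not performance on real tissue.

`simulate_bulk_survival` gives each patient a latent standard-normal
signature activity z, adds z to the log-expression of the signature genes,
and draws event times from an exponential with hazard h₀·exp(β·z)
(h₀ = 0.1).  Censoring happens with probability `censor_rate` at a uniform
fraction of the event time.

## Quality control

Three cell rules, applied exactly once with per-sample means computed over
all pre-filter cells: detected genes strictly between half and twice the
sample mean; mitochondrial fraction strictly below 20%; not flagged in the
doublet mask.  All inequalities are strict, reading "less than twice and
more than half" and "less than 20%" literally; the bounds can be made
inclusive via a parameter.  Gene filtering (after cell filtering) keeps
genes expressed in at least 10 cells, inclusive.  Re-applying the cell
rules after removal would recompute the per-sample means and could remove
further cells; the pipeline deliberately applies the rule set once.
Mitochondrial genes are identified by an annotation flag, not a name
prefix.  The built-in doublet heuristic (top library-size quantile plus
co-expression of two disjoint marker sets) is demo-grade; real runs should
supply an external mask.

## CNV malignancy score

Counts are normalized to log2(counts-per-thousand + 1), which removes
per-cell depth exactly (doubling all counts of a cell leaves its row
unchanged).  Genes expressed in fewer than 100 cells and HLA genes on chr6
(which mimic CNVs in immune cells) are removed; the per-cell,
per-chromosome unweighted mean of the surviving genes forms the cells ×
chromosomes profile.  The mitochondrial contig is excluded by default: it
carries no copy-number information and its expression share is a quality
covariate whose Beta-distributed variation would otherwise dominate the
standardized profile.

Each cell's chromosome averages are z-scored across chromosomes, then each
chromosome column is standardized across cells, and PC1 of the resulting
matrix is the malignancy score.  The per-cell z-scoring step is load-
bearing: cell-level technical axes — detection rate and mitochondrial load
— shift every chromosome of a cell coherently and otherwise capture PC1,
burying the CNV contrast in PC2 (on the synthetic benchmark: PC1 AUC 0.51
against truth without the per-cell step, 0.9999 with it).  The alternative
(column standardization only) remains available via `zscore_axis=
"chromosome"`.  Zero-variance columns are zero-filled and recorded; a
fully degenerate profile (all cells identical) yields all-zero scores.

PC1's sign is arbitrary, so the score is oriented: with a reference
population (e.g. oligodendrocytes) the reference mean is made the lower
one; otherwise cells with higher chr7-minus-chr10 mean expression score
higher (chr7 gain / chr10 loss being the GBM hallmark).  Tumor calling is
either a midpoint threshold between reference and remaining means
(`reference`) or a two-component Gaussian mixture with the upper component
called tumor (`gmm2`); the underlying score is a continuum and no single
threshold is canonical, so both rules are explicit and recorded.

## ssGSEA, permutation p-values, state annotation

For one cell, genes are ranked by expression descending (ties broken by a
fixed gene-order key: smaller column index first) and

ES = Σᵢ [P_in^w(i) − P_out(i)],

the running difference between the weighted in-set ECDF (weights
v^τ, v = N − position + 1, τ = 0.25, normalized to sum 1) and the uniform
out-of-set ECDF.  Because gene j contributes to exactly v_j partial sums,
this collapses to a closed form evaluated in O(|S|) per set after one
ranking per cell:

ES = Σ_{j∈S} v_j^{1+τ} / Σ_{j∈S} v_j^τ − (T − Σ_{j∈S} v_j)/(N − |S|),
T = N(N+1)/2.

The tests verify this against an independent quadratic-time running-sum
oracle to 1e-9.  ES depends on expression only through ranks and is
invariant under strictly monotone transforms.  Optional min–max
normalization divides all scores by the global ES range.

Empirical p-values compare each observed ES with the ES of random
same-size gene sets drawn from the expressed-gene universe (equivalent to
permuting gene labels; this preserves each cell's expression distribution).
Per-cell label shuffling is available via `scheme="percell"`.  The +1
pseudo-count convention p = (1 + #{null ≥ obs})/(n_perm + 1) avoids p = 0;
1000 permutations and α = 0.05 are the defaults.

Annotation is hierarchical: stem-like if the stem set has p < α and
ES > 0; otherwise the state with the lowest p among the six cellular
states, provided p < α and its ES > 0; otherwise un-annotated.  An ES of
exactly 0 does not annotate.  Ties on the lowest p go to the larger ES,
then to the declared state order.

A calibration property worth stating explicitly: when the observed
signatures are themselves random gene sets (no planted enrichment), they
are exchangeable with the permutation null, so each signature's p-value is
uniform and each of the seven signatures annotates a null cell with
probability ≈ α.  The expected annotated fraction of a null cohort is
therefore 1 − (1 − α)⁷ ≈ 0.30 — a structural property of testing seven
signatures at α = 0.05 per cell without multiplicity correction (the
workflow applies none), not a defect of the implementation.  Only planted
(non-exchangeable) signal can push the un-annotated fraction above
1 − α per set.

## Survival stratification

Patients are scored by ssGSEA of the signature on bulk expression, ranked
high to low, and split: the upper ⌈n/2⌉ form the "higher" group (ceiling on
odd n; boundary ties broken by patient order).  The Kaplan–Meier estimator
and the Mantel–Cox log-rank test are implemented from first principles —
S(t) as the product limit over death times with censored subjects leaving
the risk set after their time (deaths before censorings at ties), and the
log-rank statistic (ΣO − ΣE)²/ΣVar with hypergeometric expectations and
variances per death time, referred to χ²(1).  Both are cross-checked
against lifelines in the tests; calibration (type-I ≈ 5%) and power are
measured by simulation in the acceptance script.

## Cohort statistics

Composition tables are sample × category cross-tabulations with
row-normalized proportions.  Count correlations use Pearson's r with the
two-sided t-distribution p-value (n − 2 df); Spearman is available since
the choice is not canonical.  The regulon specificity score for a target
label is RSS = 1 − sqrt(JSD₂(P_r, P_c)) where P_r is the regulon's
activity normalized over cells, P_c the normalized indicator of the label,
and JSD₂ the base-2 Jensen–Shannon divergence — 1 for a regulon uniformly
active exactly on the target cells, 0 for disjoint support, invariant to
positive rescaling of the activity.

## Numerical choices and degenerate inputs

- Zero-total cells are an error in normalization (named in the message);
  zero-total cells in QC get mito fraction 0 plus a degenerate flag.
- "Expressed" always means nonzero raw count, for both the 10-cell and
  100-cell gene filters.
- The 100-cell gene filter is applied after QC cell filtering.
- Rank ties in ssGSEA use a stable fixed gene key so results are exactly
  reproducible across runs and platforms.
- All simulation randomness flows through a single integer seed per
  operation; fixed seeds give bit-identical outputs.

## Problem sizes

The test suite and the acceptance script run cohorts of 100–2 100 cells
over 1 500–3 000 genes, 200–1 000 permutations, and 300–2 000 survival
replicates — sizes at which every planted effect is comfortably detectable
and the full suite completes in a few minutes on one CPU.
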