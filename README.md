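# gbmstates

A tested re-implementation of the core single-cell computations used to
dissect glioblastoma (GBM) tumors: quality control, chromosome-level CNV
malignancy scoring, permutation-calibrated ssGSEA annotation of tumor
cellular states, signature-based survival stratification, and cohort
composition/correlation statistics.  It is aimed at computational
biologists who want these bespoke steps as reusable, unit-tested library
functions rather than one-off analysis scripts, together with a synthetic
cohort generator that plants every structure the pipeline assumes so the
whole chain can be validated against known ground truth.

## What it computes

- **QC** — cells are kept when their detected-gene count lies strictly
  between half and twice the per-sample mean, mitochondrial reads are
  under 20% of counts, and they are not flagged doublets; genes are kept
  when expressed in ≥ 10 cells.
- **Malignancy score** — counts → log2(CPK + 1); per-cell, per-chromosome
  mean expression (genes in < 100 cells and chr6 HLA genes removed); each
  cell's chromosome averages z-scored, columns standardized, PC1 oriented
  so a normal reference (e.g. oligodendrocytes) scores low.  Large CNVs
  such as the GBM chr7 gain / chr10 loss separate malignant from diploid
  cells along this axis.
- **ssGSEA state annotation** — per-cell enrichment score
  ES = Σᵢ [P_in^w(i) − P_out(i)] with rank weights v^0.25, compared to
  random same-size gene sets (1000 permutations,
  p = (1 + #{null ≥ obs})/(n_perm + 1)); cells become stem-like if the
  stem set has p < 0.05 and ES > 0, else take the lowest-p state with
  p < 0.05 and ES > 0, else stay un-annotated.
- **Survival** — patients scored by signature ssGSEA, split at the median
  (upper 50% = "higher"), compared by a first-principles Kaplan–Meier
  estimator and Mantel–Cox log-rank test (χ², 1 df).
- **Cohort statistics** — composition tables, Pearson/Spearman count
  correlations, and the regulon specificity score
  RSS = 1 − sqrt(JSD₂(activity, label indicator)).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import gbmstates as g
from sklearn.metrics import roc_auc_score

cfg = g.SimConfig(n_samples=2, n_cells_per_sample=300, seed=0)
ann = g.make_gene_annotation(cfg)
sigs = g.make_signatures(ann, g.STATES, 50, seed=0)
adata, truth = g.simulate_cohort(cfg, ann, sigs)

report = g.compute_qc(adata, ann, doublet_mask=truth.is_doublet.to_numpy())
kept = g.filter_genes(g.filter_cells(adata, report), min_cells=10)
truth = truth.loc[kept.obs_names]

norm = g.normalize_log_cpk(kept)
profile = g.chromosome_profile(norm, ann, min_cells=100)
scores = g.malignancy_scores(profile, reference_cells=truth.index[~truth.is_tumor])
call = g.call_malignant(scores, method="reference")
print("AUC:", round(roc_auc_score(truth.is_tumor, scores.score), 4))
print("call accuracy:", round((call == truth.is_tumor).mean(), 4))
```

prints

```
AUC: 0.9998
call accuracy: 0.9929
```

i.e. on a 600-cell cohort in which tumor cells carry the planted chr7
gain and chr10 loss, the oriented PC1 of the chromosome profile separates
tumor from normal cells essentially perfectly (AUC 0.9998), and the
midpoint threshold against the oligodendrocyte-like reference calls 99.3%
of cells correctly.

A command-line interface mirrors the stages:

```
gbmstates simulate --config cfg.yaml --outdir sim --seed 1
gbmstates qc --matrix sim --annotation sim/genes.tsv --out qcdir
gbmstates cnvscore --matrix qcdir --annotation sim/genes.tsv --out scores.tsv
gbmstates annotate --matrix qcdir --signatures sim/signatures.gmt \
    --stem stem-like --states AC-like MES1-like MES2-like OPC-like NPC1-like NPC2-like \
    --nperm 1000 --seed 1 --out anndir
```

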