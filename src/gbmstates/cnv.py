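"""Chromosome-level CNV malignancy scoring.

Large copy-number events shift the mean expression of whole chromosomes, so
malignant cells separate from diploid cells along the first principal
component of the cells x chromosomes matrix of per-chromosome mean
log2(CPK + 1) values (CPK = counts per thousand molecules).  Genes expressed
in fewer than 100 cells are discarded first, as are HLA genes on chr6 (they
can mimic CNVs in immune cells).  Each chromosome column is z-scored across
cells before PCA; the PC1 sign is arbitrary, so the score is oriented either
against a supplied normal reference population or by the GBM hallmark that
cells with higher chr7 - chr10 mean expression should score higher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "ChromosomeProfile",
    "MalignancyScores",
    "normalize_log_cpk",
    "chromosome_profile",
    "malignancy_scores",
    "call_malignant",
]


def normalize_log_cpk(adata: AnnData) -> AnnData:
    """log2(1000 * count / cell_total + 1); removes per-cell depth."""
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    total = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {list(adata.obs_names[zero[:5]])}"
        )
    norm = sp.csr_matrix(X, copy=True).astype(float)
    scale = np.repeat(1000.0 / total, np.diff(norm.indptr))
    norm.data = np.log2(norm.data * scale + 1.0)
    out = adata.copy()
    out.X = norm
    return out


@dataclass
class ChromosomeProfile:
    """Cells x chromosomes mean log2-CPK values."""

    values: pd.DataFrame
    n_genes_used: pd.Series


def chromosome_profile(
    norm: AnnData,
    annotation: pd.DataFrame,
    min_cells: int = 100,
    exclude_hla: bool = True,
    exclude_chromosomes: Sequence[str] = ("chrM",),
) -> ChromosomeProfile:
    """Per-cell, per-chromosome unweighted mean of surviving genes.

    Genes expressed (nonzero) in fewer than ``min_cells`` cells are dropped;
    HLA-flagged genes are dropped when ``exclude_hla``.  The mitochondrial
    contig is excluded by default: it carries no copy-number signal and its
    expression share is a quality covariate, not a chromosome.  A chromosome
    that loses all its genes is dropped with a warning.
    """
    missing = set(norm.var_names) - set(annotation.index)
    if missing:
        raise ValueError("annotation does not cover all genes")
    X = norm.X if sp.issparse(norm.X) else sp.csr_matrix(norm.X)
    prevalence = np.asarray((X != 0).sum(axis=0)).ravel()
    ann = annotation.loc[norm.var_names]
    keep = prevalence >= min_cells
    if exclude_hla:
        keep &= ~ann["is_hla"].to_numpy()
    chroms: List[str] = []
    cols = {}
    n_used = {}
    for chrom in pd.unique(ann["chromosome"]):
        if chrom in exclude_chromosomes:
            continue
        gmask = keep & (ann["chromosome"].to_numpy() == chrom)
        n = int(gmask.sum())
        if n == 0:
            warnings.warn(
                f"chromosome {chrom} lost all genes after filtering; dropped",
                stacklevel=2,
            )
            continue
        cols[chrom] = np.asarray(X[:, gmask].mean(axis=1)).ravel()
        n_used[chrom] = n
        chroms.append(chrom)
    values = pd.DataFrame(cols, index=norm.obs_names, columns=chroms)
    return ChromosomeProfile(values=values, n_genes_used=pd.Series(n_used))


@dataclass
class MalignancyScores:
    """Oriented PC1 of the z-scored chromosome profile, per cell."""

    score: pd.Series
    explained_variance_ratio: np.ndarray
    orientation: str
    reference_cells: Optional[pd.Index] = None
    degenerate_chromosomes: List[str] = field(default_factory=list)
    call: Optional[pd.Series] = None


def malignancy_scores(
    profile: ChromosomeProfile,
    reference_cells: Optional[Sequence[str]] = None,
    zscore_axis: str = "cell",
) -> MalignancyScores:
    """Z-score the chromosome averages, take PC1, orient the sign.

    ``zscore_axis="cell"`` (default) z-scores each cell's chromosome
    averages across chromosomes and then standardizes every chromosome
    column before PCA: the per-cell step projects out cell-level technical
    axes (detection rate, mitochondrial load) that otherwise shift every
    chromosome coherently and can dominate PC1, leaving the relative
    chromosome pattern that copy-number events produce.
    ``zscore_axis="chromosome"`` standardizes each chromosome across cells
    only.

    With ``reference_cells`` (putative normal cells, e.g. oligodendrocytes)
    the sign is chosen so the reference mean score is the lower one; without
    a reference the chr7-minus-chr10 heuristic is used.  Zero-variance
    chromosome columns are zero-filled and recorded; if every column is
    degenerate all scores are 0.
    """
    if zscore_axis not in ("cell", "chromosome"):
        raise ValueError(f"unknown zscore_axis {zscore_axis!r}")
    V = profile.values
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 chromosomes")
    W = V
    if zscore_axis == "cell":
        row_sd = V.std(axis=1, ddof=0)
        W = (V.sub(V.mean(axis=1), axis=0)).div(row_sd.replace(0.0, 1.0), axis=0)
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    Z = (W - mean).div(sd.replace(0.0, 1.0), axis=1)
    Z[degenerate] = 0.0
    n_ok = V.shape[1] - len(degenerate)

    if n_ok == 0:
        score = pd.Series(0.0, index=V.index)
        return MalignancyScores(
            score=score,
            explained_variance_ratio=np.zeros(V.shape[1]),
            orientation="degenerate",
            reference_cells=pd.Index(reference_cells) if reference_cells is not None else None,
            degenerate_chromosomes=degenerate,
        )
    if n_ok < 2:
        raise ValueError("fewer than 2 non-degenerate chromosomes")

    pca = PCA(n_components=min(Z.shape))
    coords = pca.fit_transform(Z.to_numpy())
    score = pd.Series(coords[:, 0], index=V.index)

    ref_index = None
    if reference_cells is not None:
        ref_index = pd.Index(reference_cells)
        if not ref_index.isin(V.index).all():
            raise ValueError("reference cells missing from the profile")
        ref_mask = V.index.isin(ref_index)
        if ref_mask.all() or not ref_mask.any():
            raise ValueError("reference must be a proper nonempty subset of cells")
        flip = score[ref_mask].mean() > score[~ref_mask].mean()
        orientation = "reference-low"
    else:
        for c in ("chr7", "chr10"):
            if c not in V.columns:
                raise ValueError(
                    "no reference cells given and chr7/chr10 heuristic "
                    f"unavailable ({c} missing)"
                )
        delta = (V["chr7"] - V["chr10"]).to_numpy()
        cov = np.cov(score.to_numpy(), delta)[0, 1]
        flip = cov < 0
        orientation = "chr7-minus-chr10-high"
    if flip:
        score = -score
    return MalignancyScores(
        score=score,
        explained_variance_ratio=pca.explained_variance_ratio_,
        orientation=orientation,
        reference_cells=ref_index,
        degenerate_chromosomes=degenerate,
    )


def call_malignant(scores: MalignancyScores, method: str = "reference") -> pd.Series:
    """Binarize malignancy scores into a tumor call.

    ``reference``: threshold at the midpoint between the reference-cell mean
    and the remaining-cell mean (strictly above = tumor).  ``gmm2``: fit a
    two-component Gaussian mixture; the upper-mean component is tumor.
    """
    s = scores.score
    if method == "reference":
        if scores.reference_cells is None:
            raise ValueError("'reference' calling needs reference cells")
        ref_mask = s.index.isin(scores.reference_cells)
        thr = 0.5 * (s[ref_mask].mean() + s[~ref_mask].mean())
        call = pd.Series(s.to_numpy() > thr, index=s.index, name="call")
    elif method == "gmm2":
        if s.std(ddof=0) == 0:
            raise ValueError("scores are degenerate; gmm2 cannot separate")
        gmm = GaussianMixture(n_components=2, random_state=0)
        labels = gmm.fit_predict(s.to_numpy().reshape(-1, 1))
        upper = int(np.argmax(gmm.means_.ravel()))
        call = pd.Series(labels == upper, index=s.index, name="call")
    else:
        raise ValueError(f"unknown calling method {method!r}")
    scores.call = call
    return call
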