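"""Cell- and gene-level quality control.

Three cell-level rules are applied exactly once, with per-sample means taken
over all pre-filter cells of the sample:

(i)  the number of detected genes must be more than half and less than twice
     the sample mean (strict inequalities on both sides);
(ii) mitochondrial reads must make up less than 20% of the cell's counts
     (strict);
(iii) the cell must not be flagged as a doublet (the mask is supplied
     externally — simulation truth, a file, or the naive heuristic below).

After cell filtering, genes are kept only when expressed (nonzero) in at
least ``min_cells`` cells (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["QCReport", "compute_qc", "filter_cells", "filter_genes", "naive_doublet_mask"]


@dataclass
class QCReport:
    """Per-cell QC metrics plus per-sample mean detected-gene counts."""

    cells: pd.DataFrame
    sample_mean_genes: pd.Series
    mito_max: float = 0.2


def _dense_ops(X):
    if sp.issparse(X):
        return X
    return sp.csr_matrix(X)


def compute_qc(
    adata: AnnData,
    annotation: pd.DataFrame,
    doublet_mask: Optional[Sequence[bool]] = None,
    mito_max: float = 0.2,
    inclusive_bounds: bool = False,
) -> QCReport:
    """Compute per-cell QC metrics and rule flags.

    ``inclusive_bounds`` relaxes rule (i) to non-strict inequalities (the
    strict reading is the default).  Cells with zero total counts get
    ``mito_fraction`` 0 and a ``zero_total`` flag.
    """
    missing = set(adata.var_names) - set(annotation.index)
    if missing:
        raise ValueError(
            f"{len(missing)} genes missing from the annotation "
            f"(e.g. {sorted(missing)[:3]})"
        )
    X = _dense_ops(adata.X)
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_flags = annotation.loc[adata.var_names, "is_mito"].to_numpy()
    mito_counts = np.asarray(X[:, mito_flags].sum(axis=1)).ravel()
    zero_total = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(zero_total, 0.0, mito_counts / np.where(zero_total, 1, total))

    samples = adata.obs["sample"].astype(str)
    cells = pd.DataFrame(
        {
            "sample": samples.values,
            "genes_detected": genes_detected,
            "total_counts": total,
            "mito_fraction": mito_fraction,
            "zero_total": zero_total,
        },
        index=adata.obs_names,
    )
    sample_mean = cells.groupby("sample")["genes_detected"].mean()
    mean_per_cell = samples.map(sample_mean).to_numpy(dtype=float)
    if inclusive_bounds:
        pass_bounds = (genes_detected >= mean_per_cell / 2) & (
            genes_detected <= 2 * mean_per_cell
        )
    else:
        pass_bounds = (genes_detected > mean_per_cell / 2) & (
            genes_detected < 2 * mean_per_cell
        )
    cells["pass_gene_bounds"] = pass_bounds
    cells["pass_mito"] = mito_fraction < mito_max
    if doublet_mask is None:
        cells["pass_doublet"] = True
    else:
        doublet_mask = np.asarray(doublet_mask, dtype=bool)
        if doublet_mask.shape[0] != adata.n_obs:
            raise ValueError("doublet mask length does not match cell count")
        cells["pass_doublet"] = ~doublet_mask
    return QCReport(cells=cells, sample_mean_genes=sample_mean, mito_max=mito_max)


def filter_cells(
    adata: AnnData,
    report: QCReport,
    doublet_mask: Optional[Sequence[bool]] = None,
) -> AnnData:
    """Keep cells passing all three rules; cell order is preserved."""
    if not report.cells.index.equals(adata.obs_names):
        raise ValueError("QC report is not aligned with the matrix")
    keep = (
        report.cells["pass_gene_bounds"]
        & report.cells["pass_mito"]
        & report.cells["pass_doublet"]
    ).to_numpy()
    if doublet_mask is not None:
        doublet_mask = np.asarray(doublet_mask, dtype=bool)
        if doublet_mask.shape[0] != adata.n_obs:
            raise ValueError("doublet mask length does not match cell count")
        keep &= ~doublet_mask
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    return adata[keep].copy()


def filter_genes(adata: AnnData, min_cells: int = 10) -> AnnData:
    """Keep genes with nonzero counts in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    X = _dense_ops(adata.X)
    prevalence = np.asarray((X > 0).sum(axis=0)).ravel()
    return adata[:, prevalence >= min_cells].copy()


def naive_doublet_mask(
    adata: AnnData,
    markers_a: Sequence[str],
    markers_b: Sequence[str],
    libsize_quantile: float = 0.9,
) -> np.ndarray:
    """Demo-grade doublet heuristic: a cell is flagged when its library size
    sits in the top quantile AND it co-expresses two disjoint marker sets.

    This is a stand-in for a dedicated doublet caller and is intended for
    demonstrations only; the pipeline normally consumes an external mask.
    """
    X = _dense_ops(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    cut = np.quantile(total, libsize_quantile)
    pos_a = [adata.var_names.get_loc(g) for g in markers_a if g in adata.var_names]
    pos_b = [adata.var_names.get_loc(g) for g in markers_b if g in adata.var_names]
    has_a = np.asarray((X[:, pos_a] > 0).sum(axis=1)).ravel() > 0 if pos_a else np.zeros(adata.n_obs, bool)
    has_b = np.asarray((X[:, pos_b] > 0).sum(axis=1)).ravel() > 0 if pos_b else np.zeros(adata.n_obs, bool)
    return (total >= cut) & has_a & has_b
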