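"""Per-cell single-sample GSEA, a permutation null, and state annotation.

The enrichment score (ES) for a gene set S in one cell ranks all N genes by
expression (descending, ties broken by a fixed gene-order key) and sums, over
ranked positions i, the difference between the weighted in-set ECDF and the
uniform out-of-set ECDF:

    ES = sum_i [ P_in^w(i) - P_out(i) ],
    P_in^w(i) = sum_{j in S, pos_j <= i} v_j^tau / sum_{j in S} v_j^tau,
    P_out(i)  = #{j not in S, pos_j <= i} / (N - |S|),

where v_j = N - pos_j + 1 is the rank value (N for the top gene) and tau is
the rank-weighting exponent (0.25 by default).  Because each gene j
contributes to exactly (N - pos_j + 1) partial sums, the double sum collapses
to the closed form

    ES = sum_{j in S} v_j^(1+tau) / sum_{j in S} v_j^tau
         - (T - sum_{j in S} v_j) / (N - |S|),     T = N(N+1)/2,

which is what this module evaluates; a quadratic-time running-sum evaluation
is used as the independent oracle in the tests.  ES depends on expression
only through ranks, so it is invariant under strictly monotone transforms.

Empirical p-values compare each observed ES with the ES of random same-size
gene sets drawn from the expressed-gene universe (equivalent to permuting
gene labels), with the +1 pseudo-count convention
p = (1 + #{null >= observed}) / (n_perm + 1).

State annotation is hierarchical: a tumor cell is stem-like if the stem set
has p < alpha and ES > 0; otherwise it takes the state with the lowest
p-value among the six cellular states provided that p < alpha and its ES > 0;
otherwise it is un-annotated.  An ES of exactly 0 does not annotate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "EnrichmentTable",
    "ssgsea_cell",
    "ssgsea_matrix",
    "permutation_pvalues",
    "annotate_states",
    "UNANNOTATED",
]

UNANNOTATED = "un-annotated"

MatrixLike = Union[AnnData, pd.DataFrame]


@dataclass
class EnrichmentTable:
    """Cells x signatures enrichment scores and (optionally) p-values."""

    es: pd.DataFrame
    pval: Optional[pd.DataFrame] = None
    n_perm: int = 0
    tau: float = 0.25


def _as_dense(matrix: MatrixLike) -> Tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(matrix, AnnData):
        X = matrix.X.toarray() if sp.issparse(matrix.X) else np.asarray(matrix.X)
        return np.asarray(X, dtype=float), matrix.obs_names, matrix.var_names
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix.index, matrix.columns
    raise TypeError("matrix must be an AnnData or a DataFrame")


def _rank_values(X: np.ndarray) -> np.ndarray:
    """Rank value v = N - position for each gene in each row.

    Ties are broken by the fixed gene-order key: among equal expression
    values the gene with the smaller column index ranks higher.
    """
    n = X.shape[1]
    order = np.argsort(-X, axis=1, kind="stable")
    v = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    v[rows, order] = n - np.arange(n)[None, :]
    return v


def _es_from_ranks(v_set: np.ndarray, n: int, tau: float) -> np.ndarray:
    """Closed-form ES given the rank values of the set genes (cells x k)."""
    k = v_set.shape[1]
    if k >= n:
        raise ValueError("gene set must be smaller than the gene universe")
    vf = v_set.astype(float)
    w = vf**tau
    in_term = (w * vf).sum(axis=1) / w.sum(axis=1)
    t = n * (n + 1) / 2.0
    out_term = (t - vf.sum(axis=1)) / (n - k)
    return in_term - out_term


def ssgsea_cell(
    expr: pd.Series, gene_set: Sequence[str], tau: float = 0.25
) -> float:
    """ES of one gene set in one cell; set genes absent from ``expr`` are
    ignored, and at least one must be present."""
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("no gene of the set is present in the expression vector")
    if len(set(gene_set)) != len(list(gene_set)):
        raise ValueError("gene set contains duplicate genes")
    v = _rank_values(expr.to_numpy(dtype=float)[None, :])
    pos = expr.index.get_indexer(present)
    return float(_es_from_ranks(v[:, pos], expr.size, tau)[0])


def ssgsea_matrix(
    matrix: MatrixLike,
    signatures: Mapping[str, Sequence[str]],
    tau: float = 0.25,
    minmax_normalize: bool = False,
    on_missing: str = "error",
) -> EnrichmentTable:
    """ES of every signature in every cell of a normalized matrix.

    ``on_missing`` controls sets with no gene present in the matrix:
    ``"error"`` raises, ``"nan"`` records NaN for that signature.
    """
    X, cells, genes = _as_dense(matrix)
    v = _rank_values(X)
    n = X.shape[1]
    es = {}
    for name, gene_set in signatures.items():
        if len(set(gene_set)) != len(list(gene_set)):
            raise ValueError(f"signature {name!r} contains duplicate genes")
        pos = genes.get_indexer([g for g in gene_set if g in genes])
        if pos.size == 0:
            if on_missing == "nan":
                es[name] = np.full(X.shape[0], np.nan)
                continue
            raise ValueError(f"signature {name!r} has no gene in the matrix")
        es[name] = _es_from_ranks(v[:, pos], n, tau)
    table = pd.DataFrame(es, index=cells)
    if minmax_normalize:
        rng = np.nanmax(table.to_numpy()) - np.nanmin(table.to_numpy())
        if rng > 0:
            table = table / rng
    return EnrichmentTable(es=table, tau=tau)


def permutation_pvalues(
    matrix: MatrixLike,
    signatures: Mapping[str, Sequence[str]],
    tau: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "geneset",
    minmax_normalize: bool = False,
) -> EnrichmentTable:
    """Observed ES plus empirical p-values from a permutation null.

    ``scheme="geneset"`` (default) draws, per permutation and signature, a
    random same-size gene set from the expressed-gene universe, shared by all
    cells; ``scheme="percell"`` draws an independent random set for every
    cell (equivalent to shuffling gene labels within each cell).  p-values
    use the +1 pseudo-count convention, so min p = 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if scheme not in ("geneset", "percell"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    X, cells, genes = _as_dense(matrix)
    n_cells, n = X.shape
    v = _rank_values(X)
    observed = ssgsea_matrix(matrix, signatures, tau=tau).es

    universe = np.flatnonzero((X != 0).any(axis=0))
    if universe.size == 0:
        universe = np.arange(n)
    sizes = {
        name: genes.get_indexer([g for g in gs if g in genes]).size
        for name, gs in signatures.items()
    }
    for name, k in sizes.items():
        if k == 0:
            raise ValueError(f"signature {name!r} has no gene in the matrix")
        if k > universe.size:
            raise ValueError(
                f"signature {name!r} is larger than the expressed-gene universe"
            )

    rng = np.random.default_rng(seed)
    counts = {name: np.zeros(n_cells, dtype=np.int64) for name in signatures}
    for _ in range(n_perm):
        for name, k in sizes.items():
            if scheme == "geneset":
                null_pos = rng.choice(universe, size=k, replace=False)
                null_es = _es_from_ranks(v[:, null_pos], n, tau)
            else:
                null_pos = np.argsort(
                    rng.random((n_cells, universe.size)), axis=1
                )[:, :k]
                v_set = np.take_along_axis(v[:, universe], null_pos, axis=1)
                null_es = _es_from_ranks(v_set, n, tau)
            counts[name] += null_es >= observed[name].to_numpy()
    pval = pd.DataFrame(
        {name: (1.0 + c) / (n_perm + 1.0) for name, c in counts.items()},
        index=cells,
    )
    es = observed
    if minmax_normalize:
        rng_ = np.nanmax(es.to_numpy()) - np.nanmin(es.to_numpy())
        if rng_ > 0:
            es = es / rng_
    return EnrichmentTable(es=es, pval=pval, n_perm=n_perm, tau=tau)


def annotate_states(
    table: EnrichmentTable,
    stem_set: str,
    state_sets: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hierarchical per-cell state annotation (stem first, then lowest p).

    Ties on the lowest p-value are broken by the larger ES, then by the
    declared ``state_sets`` order.  Returns a DataFrame with ``label``,
    ``winning_es`` and ``winning_p`` per cell; for un-annotated cells the
    winning columns record the best (lowest-p) state's values.
    """
    if table.pval is None:
        raise ValueError("enrichment table has no p-values")
    needed = [stem_set, *state_sets]
    missing = [s for s in needed if s not in table.es.columns]
    if missing:
        raise ValueError(f"missing signatures in the enrichment table: {missing}")

    es = table.es[needed]
    pv = table.pval[needed]
    labels = []
    win_es = []
    win_p = []
    state_order = {s: i for i, s in enumerate(state_sets)}
    for cell in es.index:
        stem_p = pv.at[cell, stem_set]
        stem_e = es.at[cell, stem_set]
        if stem_p < alpha and stem_e > 0:
            labels.append(stem_set)
            win_es.append(stem_e)
            win_p.append(stem_p)
            continue
        cand = sorted(
            state_sets,
            key=lambda s: (pv.at[cell, s], -es.at[cell, s], state_order[s]),
        )
        best = cand[0]
        best_p = pv.at[cell, best]
        best_e = es.at[cell, best]
        if best_p < alpha and best_e > 0:
            labels.append(best)
        else:
            labels.append(UNANNOTATED)
        win_es.append(best_e)
        win_p.append(best_p)
    return pd.DataFrame(
        {"label": labels, "winning_es": win_es, "winning_p": win_p},
        index=es.index,
    )
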