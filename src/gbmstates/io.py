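"""Readers and writers for the plain-text formats the pipeline consumes.

Count matrices travel as a 10x-style MTX triplet (``matrix.mtx`` with genes as
rows and cells as columns, ``barcodes.tsv``, ``features.tsv``) or as a dense
cells x genes TSV.  Gene annotations, cell truth tables, QC reports and
survival tables are TSV; gene signatures are GMT (name, description, genes).
"""

from __future__ import annotations

import os
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "read_mtx_dir",
    "write_mtx_dir",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gmt",
    "write_gmt",
]


def write_mtx_dir(adata: AnnData, outdir: str) -> None:
    """Write an MTX triplet.

    ``barcodes.tsv`` carries two columns (cell id, sample label) so the sample
    assignment survives the round trip; ``features.tsv`` carries gene ids.
    """
    os.makedirs(outdir, exist_ok=True)
    mat = sp.csc_matrix(adata.X.T)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat, field="integer")
    samples = adata.obs["sample"] if "sample" in adata.obs else pd.Series(
        ["sample1"] * adata.n_obs, index=adata.obs_names
    )
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        for cell, smp in zip(adata.obs_names, samples):
            fh.write(f"{cell}\t{smp}\n")
    with open(os.path.join(outdir, "features.tsv"), "w") as fh:
        for gene in adata.var_names:
            fh.write(f"{gene}\n")


def read_mtx_dir(indir: str) -> AnnData:
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    counts = sp.csr_matrix(mat.T)
    barcodes = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )
    features = pd.read_csv(
        os.path.join(indir, "features.tsv"), sep="\t", header=None
    )
    obs = pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="cell_id"))
    obs["sample"] = (
        barcodes[1].astype(str).values if barcodes.shape[1] > 1 else "sample1"
    )
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene_id"))
    return AnnData(X=counts, obs=obs, var=var)


def write_dense_tsv(adata: AnnData, path: str) -> None:
    """Dense cells x genes TSV with a leading ``sample`` column."""
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    df = pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names)
    df.insert(0, "sample", adata.obs.get("sample", "sample1"))
    df.to_csv(path, sep="\t", index_label="cell_id")


def read_dense_tsv(path: str) -> AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "sample" in df.columns:
        samples = df.pop("sample").astype(str)
    else:
        samples = pd.Series("sample1", index=df.index)
    obs = pd.DataFrame({"sample": samples.values}, index=df.index.astype(str))
    counts = sp.csr_matrix(df.to_numpy())
    var = pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene_id"))
    return AnnData(X=counts, obs=obs, var=var)


def write_gene_annotation(annotation: pd.DataFrame, path: str) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    ann["is_mito"] = ann["is_mito"].astype(bool)
    ann["is_hla"] = ann["is_hla"].astype(bool)
    return ann


def read_gmt(path: str) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(
    signatures: Mapping[str, Sequence[str]],
    path: str,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
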