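import numpy as np
import pandas as pd
import pytest

import gbmstates as g


@pytest.fixture(scope="session")
def small_cfg():
    return g.SimConfig(
        n_samples=2,
        n_cells_per_sample=100,
        n_genes=500,
        n_hla_genes=5,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    ann = g.make_gene_annotation(small_cfg)
    sigs = g.make_signatures(ann, g.STATES, 15, small_cfg.seed)
    adata, truth = g.simulate_cohort(small_cfg, ann, sigs)
    return adata, truth, ann, sigs


@pytest.fixture()
def toy_counts():
    """Tiny deterministic cells x genes matrix with a mito gene and samples."""
    genes = ["gA", "gB", "gC", "gD", "gMT"]
    ann = pd.DataFrame(
        {
            "chromosome": ["chr1", "chr1", "chr2", "chr2", "chrM"],
            "is_mito": [False, False, False, False, True],
            "is_hla": [False] * 5,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    counts = np.array(
        [
            [10, 5, 0, 0, 5],
            [0, 0, 8, 2, 0],
            [1, 1, 1, 1, 16],
            [4, 4, 4, 4, 4],
            [0, 0, 0, 0, 0],
            [3, 0, 3, 0, 0],
        ]
    )
    import scipy.sparse as sp
    from anndata import AnnData

    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(
            {"sample": ["s1", "s1", "s1", "s2", "s2", "s2"]},
            index=[f"c{i}" for i in range(6)],
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    return adata, ann
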