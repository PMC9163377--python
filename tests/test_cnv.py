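import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

import gbmstates as g


def _adata(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    cells = cells or [f"c{i}" for i in range(counts.shape[0])]
    return AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"sample": ["s"] * len(cells)}, index=cells),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )


def _annotation(genes, chrom_of, hla=()):
    return pd.DataFrame(
        {
            "chromosome": [chrom_of[gn] for gn in genes],
            "is_mito": [False] * len(genes),
            "is_hla": [gn in hla for gn in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestNormalizeLogCpk:
    def test_forced_arithmetic(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [1, 999, 0]
        norm = g.normalize_log_cpk(_adata(counts))
        row = norm.X.toarray()[0]
        assert row[0] == pytest.approx(1.0)  # log2(1000*1/1000 + 1)
        assert row[2] == 0.0

    def test_depth_invariance(self):
        counts = np.array([[3, 5, 0, 2]])
        a = g.normalize_log_cpk(_adata(counts)).X.toarray()
        b = g.normalize_log_cpk(_adata(counts * 2)).X.toarray()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=(5, 4))
        counts[:, 0] += 1  # no zero-total cells
        norm = g.normalize_log_cpk(_adata(counts)).X.toarray()
        tot = counts.sum(axis=1, keepdims=True)
        expected = np.log2(1000.0 * counts / tot + 1.0)
        np.testing.assert_allclose(norm, expected, atol=1e-12)

    def test_zero_total_cell_named_in_error(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            g.normalize_log_cpk(_adata(counts))


class TestChromosomeProfile:
    def test_prevalence_filter_excludes_99_of_100(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:, 0] = 1  # everywhere
        counts[:99, 1] = 1  # 99 cells only
        adata = _adata(counts)
        ann = _annotation(["g0", "g1"], {"g0": "chr1", "g1": "chr1"})
        norm = g.normalize_log_cpk(adata)
        prof = g.chromosome_profile(norm, ann, min_cells=100)
        assert prof.n_genes_used["chr1"] == 1

    def test_hla_genes_never_contribute(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 9, size=(10, 4))
        genes = ["a", "b", "hla1", "c"]
        adata = _adata(counts, genes=genes)
        ann = _annotation(
            genes,
            {"a": "chr6", "b": "chr6", "hla1": "chr6", "c": "chr2"},
            hla={"hla1"},
        )
        norm = g.normalize_log_cpk(adata)
        prof = g.chromosome_profile(norm, ann, min_cells=1, exclude_hla=True)
        N = norm.X.toarray()
        np.testing.assert_allclose(
            prof.values["chr6"].to_numpy(), N[:, :2].mean(axis=1), atol=1e-12
        )
        prof2 = g.chromosome_profile(norm, ann, min_cells=1, exclude_hla=False)
        np.testing.assert_allclose(
            prof2.values["chr6"].to_numpy(), N[:, :3].mean(axis=1), atol=1e-12
        )

    def test_hand_averaged_two_chromosome_toy(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 10, size=(4, 5))
        genes = [f"g{i}" for i in range(5)]
        chrom_of = {"g0": "chr1", "g1": "chr1", "g2": "chr1", "g3": "chr2", "g4": "chr2"}
        adata = _adata(counts, genes=genes)
        ann = _annotation(genes, chrom_of)
        norm = g.normalize_log_cpk(adata)
        prof = g.chromosome_profile(norm, ann, min_cells=1)
        N = norm.X.toarray()
        np.testing.assert_allclose(
            prof.values["chr1"].to_numpy(), N[:, :3].mean(axis=1), atol=1e-12
        )
        np.testing.assert_allclose(
            prof.values["chr2"].to_numpy(), N[:, 3:].mean(axis=1), atol=1e-12
        )

    def test_empty_chromosome_dropped_with_warning(self):
        counts = np.array([[1, 1], [2, 1]])
        adata = _adata(counts)
        ann = _annotation(["g0", "g1"], {"g0": "chr1", "g1": "chr2"})
        counts2 = counts.copy()
        counts2[:, 1] = 0
        adata2 = _adata(counts2)
        norm = g.normalize_log_cpk(adata2)
        with pytest.warns(UserWarning, match="chr2"):
            prof = g.chromosome_profile(norm, ann, min_cells=1)
        assert list(prof.values.columns) == ["chr1"]


def _profile_from(values, chroms, cells=None):
    cells = cells or [f"c{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=cells, columns=chroms)
    return g.ChromosomeProfile(
        values=df, n_genes_used=pd.Series(1, index=chroms)
    )


class TestMalignancyScores:
    def test_identical_cells_give_zero_scores(self):
        prof = _profile_from(np.ones((5, 3)), ["chr1", "chr7", "chr10"])
        scores = g.malignancy_scores(prof, reference_cells=["c0"])
        assert (scores.score == 0).all()
        assert scores.orientation == "degenerate"

    def test_orientation_contract_on_planted_cohort(self, planted_cnv):
        # the binding contract: reference mean at or below non-reference mean
        scores, truth = planted_cnv
        ref_mask = truth.index.isin(truth.index[~truth.is_tumor])
        assert scores.score[ref_mask].mean() <= scores.score[~ref_mask].mean()

    def test_pc1_has_maximal_explained_variance(self, planted_cnv):
        scores, _ = planted_cnv
        evr = scores.explained_variance_ratio
        assert (evr[0] >= evr[1:]).all()

    def test_score_invariant_to_input_ordering(self):
        rng = np.random.default_rng(4)
        V = rng.normal(size=(30, 5))
        chroms = ["chr1", "chr7", "chr9", "chr10", "chr12"]
        prof = _profile_from(V, chroms)
        s1 = g.malignancy_scores(prof, reference_cells=[f"c{i}" for i in range(5)])
        perm = rng.permutation(30)
        prof2 = _profile_from(
            V[perm][:, [1, 0, 2, 4, 3]],
            [chroms[j] for j in [1, 0, 2, 4, 3]],
            cells=[f"c{i}" for i in perm],
        )
        s2 = g.malignancy_scores(prof2, reference_cells=[f"c{i}" for i in range(5)])
        np.testing.assert_allclose(
            s1.score.sort_index().to_numpy(),
            s2.score.sort_index().to_numpy(),
            atol=1e-9,
        )

    def test_heuristic_orientation_needs_chr7_chr10(self):
        prof = _profile_from(np.random.default_rng(0).normal(size=(10, 2)), ["chr1", "chr2"])
        with pytest.raises(ValueError, match="chr7"):
            g.malignancy_scores(prof)

    def test_depth_rescaling_leaves_score_unchanged(self, planted_cnv_inputs):
        adata, truth, ann = planted_cnv_inputs
        ref = truth.index[~truth.is_tumor]
        norm1 = g.normalize_log_cpk(adata)
        scaled = adata.copy()
        scaled.X = scaled.X * 3
        norm2 = g.normalize_log_cpk(scaled)
        p1 = g.chromosome_profile(norm1, ann, min_cells=20)
        p2 = g.chromosome_profile(norm2, ann, min_cells=20)
        s1 = g.malignancy_scores(p1, reference_cells=ref)
        s2 = g.malignancy_scores(p2, reference_cells=ref)
        np.testing.assert_allclose(s1.score, s2.score, atol=1e-9)


class TestCallMalignant:
    def test_midpoint_threshold_on_separated_clusters(self):
        score = pd.Series(
            [-2.0, -2.1, -1.9, 2.0, 2.1, 1.9],
            index=[f"c{i}" for i in range(6)],
        )
        scores = g.MalignancyScores(
            score=score,
            explained_variance_ratio=np.array([1.0]),
            orientation="reference-low",
            reference_cells=pd.Index(["c0", "c1", "c2"]),
        )
        call = g.call_malignant(scores, method="reference")
        assert list(call) == [False, False, False, True, True, True]

    def test_equal_scores_reference_calls_none(self):
        score = pd.Series([1.0] * 4, index=[f"c{i}" for i in range(4)])
        scores = g.MalignancyScores(
            score=score,
            explained_variance_ratio=np.array([1.0]),
            orientation="degenerate",
            reference_cells=pd.Index(["c0"]),
        )
        assert not g.call_malignant(scores, method="reference").any()

    def test_gmm_on_degenerate_scores_raises(self):
        score = pd.Series([1.0] * 4, index=[f"c{i}" for i in range(4)])
        scores = g.MalignancyScores(
            score=score,
            explained_variance_ratio=np.array([1.0]),
            orientation="degenerate",
        )
        with pytest.raises(ValueError):
            g.call_malignant(scores, method="gmm2")

    def test_unknown_method_rejected(self):
        score = pd.Series([0.0, 1.0], index=["a", "b"])
        scores = g.MalignancyScores(
            score=score, explained_variance_ratio=np.array([1.0]), orientation="x"
        )
        with pytest.raises(ValueError):
            g.call_malignant(scores, method="median")


@pytest.fixture(scope="module")
def planted_cnv_inputs():
    cfg = g.SimConfig(
        n_samples=1,
        n_cells_per_sample=300,
        n_genes=1500,
        tumor_fraction=0.5,
        cnv_profile={"chr7": 1.5, "chr10": 0.5},
        state_fractions={},
        doublet_rate=0.0,
        seed=31,
    )
    ann = g.make_gene_annotation(cfg)
    adata, truth = g.simulate_cohort(cfg, ann, {})
    return adata, truth, ann


@pytest.fixture(scope="module")
def planted_cnv(planted_cnv_inputs):
    adata, truth, ann = planted_cnv_inputs
    norm = g.normalize_log_cpk(adata)
    prof = g.chromosome_profile(norm, ann, min_cells=20)
    scores = g.malignancy_scores(
        prof, reference_cells=truth.index[~truth.is_tumor]
    )
    return scores, truth


def test_planted_cnv_cohort_separates(planted_cnv):
    from sklearn.metrics import roc_auc_score

    scores, truth = planted_cnv
    auc = roc_auc_score(truth.is_tumor, scores.score)
    assert auc >= 0.98
    call = g.call_malignant(scores, method="reference")
    assert (call == truth.is_tumor).mean() >= 0.95
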