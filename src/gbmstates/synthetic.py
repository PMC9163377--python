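"""Synthetic GBM cohort generator.

Emulates the statistical structure the downstream pipeline assumes: a
multi-sample cohort of negative-binomially distributed UMI counts in which
tumor cells carry whole-chromosome copy-number fold changes (the GBM hallmark
being chr7 gain / chr10 loss), tumor cells occupy transcriptional states whose
signature genes are up-regulated by a common fold, mitochondrial reads take a
Beta-distributed fraction of each cell's library, and a fraction of cells are
heterotypic doublets formed by summing two cells' counts.  A designated normal
population (oligodendrocyte-like) is always present so the CNV procedure has a
diploid reference.  A bulk survival cohort whose hazard is log-linear in a
latent signature activity is generated separately.

All latent labels (tumor status, state, doublet flag, true mito fraction) are
returned as a truth table so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "STATES",
    "SimConfig",
    "default_chromosomes",
    "make_gene_annotation",
    "make_signatures",
    "simulate_cohort",
    "simulate_bulk_survival",
]

#: the seven tumor-cell programs that can be planted (six states + stem-like)
STATES = (
    "stem-like",
    "AC-like",
    "MES1-like",
    "MES2-like",
    "OPC-like",
    "NPC1-like",
    "NPC2-like",
)

MITO_CHROM = "chrM"


def default_chromosomes(n_genes: int, n_mito: int = 13) -> Dict[str, int]:
    """Distribute ``n_genes`` over chr1..chr22 plus a mitochondrial contig."""
    if n_genes <= n_mito + 22:
        raise ValueError("n_genes too small for the default chromosome layout")
    nuclear = n_genes - n_mito
    base, extra = divmod(nuclear, 22)
    chroms = {f"chr{i}": base + (1 if i <= extra else 0) for i in range(1, 23)}
    chroms[MITO_CHROM] = n_mito
    return chroms


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_cohort`.

    Defaults emulate a 7-sample GBM cohort in which tumor cells dominate,
    carry a chr7 gain and chr10 loss, and occupy the seven programs with the
    stated fractions (tumor cells left without a state get no signature boost
    and should come out un-annotated).
    """

    n_samples: int = 7
    n_cells_per_sample: int = 500
    n_genes: int = 3000
    chromosomes: Optional[Dict[str, int]] = None
    n_hla_genes: int = 20
    tumor_fraction: float = 0.6
    cnv_profile: Dict[str, float] = field(
        default_factory=lambda: {"chr7": 1.5, "chr10": 0.5}
    )
    state_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "stem-like": 0.05,
            "AC-like": 0.15,
            "MES1-like": 0.15,
            "MES2-like": 0.10,
            "OPC-like": 0.10,
            "NPC1-like": 0.10,
            "NPC2-like": 0.10,
        }
    )
    signature_boost: float = 2.0
    nb_dispersion: float = 5.0
    abundance_logsd: float = 0.5
    libsize_logmean: float = math.log(10000.0)
    libsize_logsd: float = 0.35
    mito_beta_a: float = 2.0
    mito_beta_b: float = 30.0
    doublet_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosomes is None:
            self.chromosomes = default_chromosomes(self.n_genes)
        if min(self.n_samples, self.n_cells_per_sample, self.n_genes) <= 0:
            raise ValueError("cohort dimensions must be positive")
        if sum(self.chromosomes.values()) != self.n_genes:
            raise ValueError(
                "per-chromosome gene counts must sum to n_genes "
                f"({sum(self.chromosomes.values())} != {self.n_genes})"
            )
        if any(c < 0 for c in self.chromosomes.values()):
            raise ValueError("chromosome gene counts must be nonnegative")
        if self.n_hla_genes > self.chromosomes.get("chr6", 0):
            raise ValueError("n_hla_genes exceeds the chr6 gene count")
        for name, p in [
            ("tumor_fraction", self.tumor_fraction),
            ("doublet_rate", self.doublet_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(f <= 0 for f in self.cnv_profile.values()):
            raise ValueError("CNV fold changes must be positive")
        if any(not 0.0 <= f <= 1.0 for f in self.state_fractions.values()):
            raise ValueError("state fractions must lie in [0, 1]")
        if sum(self.state_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("state fractions must sum to at most 1")
        if any(s not in STATES for s in self.state_fractions):
            raise ValueError("unknown state in state_fractions")
        if self.signature_boost < 1.0:
            raise ValueError("signature_boost must be >= 1")
        if self.nb_dispersion <= 0 or self.mito_beta_a <= 0 or self.mito_beta_b <= 0:
            raise ValueError("dispersion and Beta parameters must be positive")


def make_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene table (chromosome, mito flag, HLA flag) implied by the config.

    Genes are laid out in chromosome blocks in the config's declared order;
    the HLA-flagged genes are a random (seeded) subset of chr6.
    """
    rng = np.random.default_rng(config.seed)
    chroms: List[str] = []
    for chrom, n in config.chromosomes.items():
        chroms.extend([chrom] * n)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    ann = pd.DataFrame(
        {
            "chromosome": chroms,
            "is_mito": [c == MITO_CHROM for c in chroms],
            "is_hla": False,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    if config.n_hla_genes:
        chr6_pos = np.flatnonzero(ann["chromosome"].to_numpy() == "chr6")
        picked = rng.choice(chr6_pos, size=config.n_hla_genes, replace=False)
        ann.iloc[np.sort(picked), ann.columns.get_loc("is_hla")] = True
    return ann


def make_signatures(
    annotation: pd.DataFrame,
    set_names: Sequence[str],
    genes_per_set: int,
    seed: int,
) -> Dict[str, List[str]]:
    """Disjoint same-size gene sets sampled (without replacement) from the
    nuclear (non-mitochondrial) gene universe."""
    if genes_per_set <= 0:
        raise ValueError("genes_per_set must be positive")
    universe = annotation.index[~annotation["is_mito"]].to_numpy()
    need = genes_per_set * len(set_names)
    if need > universe.size:
        raise ValueError(
            f"requested {need} signature genes but only {universe.size} "
            "non-mitochondrial genes are available"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(universe, size=need, replace=False)
    return {
        name: sorted(picked[i * genes_per_set : (i + 1) * genes_per_set])
        for i, name in enumerate(set_names)
    }


def _state_assignment(
    rng: np.random.Generator, n_tumor: int, fractions: Mapping[str, float]
) -> np.ndarray:
    names = list(fractions) + [None]
    probs = list(fractions.values())
    probs.append(max(0.0, 1.0 - sum(probs)))
    probs = np.asarray(probs) / np.sum(probs)
    idx = rng.choice(len(names), size=n_tumor, p=probs)
    return np.asarray([names[i] for i in idx], dtype=object)


def simulate_cohort(
    config: SimConfig,
    annotation: pd.DataFrame,
    signatures: Mapping[str, Sequence[str]],
) -> Tuple[AnnData, pd.DataFrame]:
    """Draw a cohort of UMI count profiles plus its ground-truth table.

    Counts are gamma-Poisson (negative binomial with shared dispersion): each
    cell draws a lognormal library size and a Beta mitochondrial fraction; the
    nuclear gene means are a fixed lognormal abundance profile, multiplied for
    tumor cells by the chromosome fold change and (for the cell's state) the
    signature boost, then renormalized so library size and mito fraction are
    respected on average.  Doublet cells are replaced by the sum of their own
    and a same-sample partner's counts.
    """
    for state in config.state_fractions:
        if config.state_fractions[state] > 0 and state not in signatures:
            raise ValueError(f"no signature provided for planted state {state!r}")
    for name, genes in signatures.items():
        missing = set(genes) - set(annotation.index)
        if missing:
            raise ValueError(f"signature {name!r} references unknown genes")

    rng = np.random.default_rng(config.seed)
    n_cells = config.n_samples * config.n_cells_per_sample
    n_genes = config.n_genes
    gene_ids = annotation.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    chrom = annotation["chromosome"].to_numpy()
    is_mito = annotation["is_mito"].to_numpy()
    nuc = ~is_mito

    samples = np.repeat(
        [f"S{i + 1}" for i in range(config.n_samples)], config.n_cells_per_sample
    )
    cell_ids = np.array(
        [f"{s}_C{i:05d}" for i, s in enumerate(samples)], dtype=object
    )

    # exact per-sample tumor counts, positions shuffled within each sample
    is_tumor = np.zeros(n_cells, dtype=bool)
    n_tum_per = int(round(config.tumor_fraction * config.n_cells_per_sample))
    for s in range(config.n_samples):
        lo = s * config.n_cells_per_sample
        pos = rng.permutation(config.n_cells_per_sample)[:n_tum_per]
        is_tumor[lo + pos] = True

    state = np.full(n_cells, None, dtype=object)
    state[is_tumor] = _state_assignment(rng, int(is_tumor.sum()), config.state_fractions)

    libsize = rng.lognormal(config.libsize_logmean, config.libsize_logsd, n_cells)
    mito_frac = rng.beta(config.mito_beta_a, config.mito_beta_b, n_cells)
    if not is_mito.any():
        mito_frac = np.zeros(n_cells)

    base_w = rng.lognormal(0.0, config.abundance_logsd, n_genes)

    # chromosome fold vector shared by all tumor cells (nuclear genes only)
    fold = np.ones(n_genes)
    for c, f in config.cnv_profile.items():
        fold[(chrom == c) & nuc] = f

    mu = np.empty((n_cells, n_genes))
    groups: Dict[Tuple[bool, Optional[str]], np.ndarray] = {}
    for i in range(n_cells):
        groups.setdefault((bool(is_tumor[i]), state[i]), []).append(i)  # type: ignore[arg-type]
    for (tum, st), idx_list in groups.items():
        idx = np.asarray(idx_list)
        w = base_w.copy()
        if tum:
            w = w * fold
            if st is not None:
                sig_pos = [gene_pos[g] for g in signatures[st]]
                w[sig_pos] = w[sig_pos] * config.signature_boost
        w_nuc = w[nuc]
        p_nuc = w_nuc / w_nuc.sum()
        mu[np.ix_(idx, np.flatnonzero(nuc))] = (
            ((1.0 - mito_frac[idx]) * libsize[idx])[:, None] * p_nuc[None, :]
        )
        if is_mito.any():
            w_mit = base_w[is_mito]
            p_mit = w_mit / w_mit.sum()
            mu[np.ix_(idx, np.flatnonzero(is_mito))] = (
                (mito_frac[idx] * libsize[idx])[:, None] * p_mit[None, :]
            )

    r = config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    is_doublet = rng.random(n_cells) < config.doublet_rate
    if is_doublet.any():
        original = counts.copy()
        for i in np.flatnonzero(is_doublet):
            s = i // config.n_cells_per_sample
            lo = s * config.n_cells_per_sample
            partner = lo + int(rng.integers(config.n_cells_per_sample - 1))
            if partner >= i:
                partner += 1
            counts[i] = original[i] + original[partner]

    truth = pd.DataFrame(
        {
            "sample": samples,
            "is_tumor": is_tumor,
            "state": state,
            "is_doublet": is_doublet,
            "mito_fraction_true": mito_frac,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"sample": samples}, index=truth.index),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    return adata, truth


def simulate_bulk_survival(
    n_patients: int,
    signature: Sequence[str],
    beta: float,
    censor_rate: float,
    seed: int,
    n_genes: int = 1000,
    baseline_hazard: float = 0.1,
    signature_effect: float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk expression + survival cohort with hazard h0*exp(beta*z).

    Each patient carries a latent standard-normal signature activity ``z``;
    log-scale expression is unit-normal noise with ``signature_effect * z``
    added to the signature genes.  Event times are exponential with hazard
    ``baseline_hazard * exp(beta * z)``; with probability ``censor_rate`` a
    patient is censored at a uniform fraction of their event time.

    Returns ``(expression, clinical)``: patients x genes expression and a
    clinical table with ``time``, ``event`` and the latent truth ``z``.
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    signature = list(signature)
    n_bg = max(0, n_genes - len(signature))
    genes = signature + [f"BG{i:05d}" for i in range(n_bg)]
    patients = pd.Index([f"P{i:03d}" for i in range(n_patients)], name="patient_id")

    z = rng.normal(0.0, 1.0, n_patients)
    expr = rng.normal(0.0, 1.0, (n_patients, len(genes)))
    expr[:, : len(signature)] += signature_effect * z[:, None]
    expression = pd.DataFrame(expr, index=patients, columns=genes)

    hazard = baseline_hazard * np.exp(beta * z)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(n_patients) < censor_rate
    time = np.where(censored, event_time * rng.random(n_patients), event_time)
    clinical = pd.DataFrame(
        {"time": time, "event": ~censored, "z": z}, index=patients
    )
    return expression, clinical
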