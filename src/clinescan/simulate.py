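"""Synthetic allele-count datasets with known structure and known effects.

The generator runs the analysis model forwards: each SNP gets an ancestral
frequency ``alpha ~ Uniform(0.05, 0.95)``, transformed population frequencies
``theta ~ N(alpha 1 + sum_v beta_v Y_v, alpha(1-alpha) Omega*)`` and binomial
counts with success probability ``clamp(theta)`` — the same clamp the
likelihood uses, so generator and model agree about the latent scale.  A
minority of causal SNPs carry a nonzero linear effect ``beta*`` on one
variable; synthetic gene intervals allow genic/non-genic classification, and
causal SNPs can be placed near genes with elevated odds (``genic_bias``) to
plant an enrichment signal.

What this emulates: the across-population covariance structure of
SNP-frequency data, environmental gradients, sampling noise and genic
annotation.  What it does not: linkage disequilibrium between SNPs (SNPs are
independent given Omega), ascertainment bias, and non-linear responses.
"""

from __future__ import annotations

import numpy as np

from .model import CLAMP_EPS
from .types import (
    AlleleCountMatrix,
    CovarianceMatrix,
    EnvironmentMatrix,
    GeneIntervals,
)

__all__ = [
    "SyntheticTruth",
    "make_covariance",
    "make_environment",
    "place_genes",
    "simulate_dataset",
]

from dataclasses import dataclass


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset: a SNP is causal iff its beta is nonzero."""

    omega_true: CovarianceMatrix
    alpha_true: np.ndarray  # L
    beta_true: np.ndarray  # L x V
    causal: np.ndarray  # L x V bool
    genic_bias: float = 1.0
    theta_true: np.ndarray | None = None  # L x P latent (unclamped) frequencies

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.causal = np.asarray(self.causal, dtype=bool)
        if not np.array_equal(self.causal, self.beta_true != 0):
            raise ValueError("causal must mark exactly the nonzero effects")
        if self.genic_bias < 1:
            raise ValueError("genic_bias must be >= 1")


def make_covariance(
    P: int,
    seed: int = 0,
    model: str = "star-tree",
    shared: float = 0.1,
    private: float = 0.1,
) -> CovarianceMatrix:
    """A positive-definite P x P covariance for simulation.

    star-tree: populations radiate from a common ancestor, giving a shared
    off-diagonal term (the root branch) plus per-population private drift on
    the diagonal — ``Omega = shared * J + diag(private_p)``, with private
    branch lengths jittered around ``private``.  random-wishart draws
    ``Omega ~ W(P + 2, (private / (P + 2)) I) + shared * J`` for a rougher
    structure.  Defaults put total diagonal drift near 0.2, a worldwide-scale
    differentiation (F_ST ~ 0.1-0.2).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    rng = np.random.default_rng(seed)
    J = np.ones((P, P))
    if model == "star-tree":
        priv = private * rng.uniform(0.5, 1.5, size=P)
        omega = shared * J + np.diag(priv)
    elif model == "random-wishart":
        G = rng.standard_normal((P, P + 2)) * np.sqrt(private / (P + 2))
        omega = G @ G.T + shared * J + 1e-3 * np.eye(P)
    else:
        raise ValueError(f"unknown covariance model {model!r}")
    return CovarianceMatrix(omega=omega)


def make_environment(P: int, seed: int = 0) -> EnvironmentMatrix:
    """Default simulation environment: one latitude-like gradient, one noise control.

    Variable 'gradient' increases linearly across populations (a clinal
    signal); 'noise' is a random standardized vector with no structure.  Both
    rows have mean 0 and population sd 1.
    """
    if P < 2:
        raise ValueError("need at least 2 populations for a gradient")
    rng = np.random.default_rng(seed)
    grad = np.arange(P, dtype=float)
    noise = rng.standard_normal(P)
    vals = np.vstack([grad, noise])
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return EnvironmentMatrix(
        var_names=["gradient", "noise"], values=vals, standardized=True
    )


def place_genes(
    genome_length: int,
    n_genes: int,
    gene_length: int,
    seed: int = 0,
    chrom: str = "chr1",
) -> GeneIntervals:
    """Uniformly place non-overlapping genes of fixed length on one chromosome."""
    if n_genes * gene_length > genome_length:
        raise ValueError(
            f"cannot pack {n_genes} genes of {gene_length} bp into {genome_length} bp"
        )
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        empty = np.array([], dtype=np.int64)
        return GeneIntervals(
            chrom=np.array([], dtype=object), start=empty, end=empty.copy()
        )
    # order statistics of the free space, shifted by the accumulated gene lengths
    free = genome_length - n_genes * gene_length
    gaps = np.sort(rng.integers(0, free + 1, size=n_genes))
    starts = gaps + np.arange(n_genes) * gene_length
    return GeneIntervals(
        chrom=np.array([chrom] * n_genes, dtype=object),
        start=starts.astype(np.int64),
        end=(starts + gene_length).astype(np.int64),
        name=np.array([f"gene_{i + 1}" for i in range(n_genes)], dtype=object),
    )


def _merge_near_gene_regions(genes: GeneIntervals, near: int, genome_length: int):
    """Union of gene intervals padded by ``near`` bp, clipped to the genome."""
    if len(genes) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    g = genes.sorted()
    starts = np.maximum(g.start - near, 0)
    ends = np.minimum(g.end + near, genome_length)
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _sample_positions_in(regions: np.ndarray, n: int, rng: np.random.Generator):
    lengths = regions[:, 1] - regions[:, 0]
    total = lengths.sum()
    offs = rng.integers(0, total, size=n)
    idx = np.searchsorted(np.cumsum(lengths), offs, side="right")
    within = offs - np.concatenate([[0], np.cumsum(lengths)])[idx]
    return regions[idx, 0] + within


def simulate_dataset(
    P: int = 8,
    L: int = 1000,
    n_chrom: int = 50,
    omega: CovarianceMatrix | None = None,
    env: EnvironmentMatrix | None = None,
    effects: dict | None = None,
    genome_length: int = 100_000_000,
    n_genes: int = 400,
    gene_length: int = 20_000,
    genic_bias: float = 1.0,
    near_threshold: int = 10_000,
    seed: int = 0,
) -> tuple[AlleleCountMatrix, GeneIntervals, SyntheticTruth]:
    """Simulate an allele-count dataset with known truth.

    ``effects`` maps variable name -> (n_causal, beta_magnitude); causal SNPs
    are disjoint across variables and carry effects of alternating sign.
    ``genic_bias`` multiplies the odds that a causal SNP lands within
    ``near_threshold`` of a gene.  Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if omega is None:
        omega = make_covariance(P, seed=rng.integers(2**31))
    if env is None:
        env = make_environment(P, seed=rng.integers(2**31))
    if not env.standardized:
        raise ValueError("environment must be standardized")
    if env.n_pops != P or omega.n_pops != P:
        raise ValueError("omega/env dimensions must match P")
    effects = effects or {}
    V = env.n_vars

    # causal assignment, disjoint across variables
    beta_true = np.zeros((L, V))
    order = rng.permutation(L)
    used = 0
    for name, (n_causal, magnitude) in effects.items():
        v = env.var_names.index(name)
        if used + n_causal > L:
            raise ValueError("more causal SNPs requested than SNPs simulated")
        idx = order[used : used + n_causal]
        used += n_causal
        signs = np.where(np.arange(n_causal) % 2 == 0, 1.0, -1.0)
        beta_true[idx, v] = magnitude * signs
    causal_any = np.any(beta_true != 0, axis=1)

    # genes and SNP positions
    genes = place_genes(genome_length, n_genes, gene_length, seed=rng.integers(2**31))
    pos = rng.integers(0, genome_length, size=L)
    if genic_bias > 1.0 and causal_any.any() and len(genes) > 0:
        regions = _merge_near_gene_regions(genes, near_threshold, genome_length)
        g_frac = (regions[:, 1] - regions[:, 0]).sum() / genome_length
        p_genic = genic_bias * g_frac / (genic_bias * g_frac + (1.0 - g_frac))
        c_idx = np.where(causal_any)[0]
        go_genic = rng.random(len(c_idx)) < p_genic
        n_in = int(go_genic.sum())
        if n_in:
            pos[c_idx[go_genic]] = _sample_positions_in(regions, n_in, rng)
        # the rest keep their uniform positions (may still fall near genes by chance)
    order_pos = np.argsort(pos, kind="stable")
    pos = pos[order_pos]
    beta_true = beta_true[order_pos]
    causal_any = causal_any[order_pos]

    # latent frequencies and counts
    alpha = rng.uniform(0.05, 0.95, size=L)
    s = alpha * (1.0 - alpha)
    chol = np.linalg.cholesky(omega.omega)
    z = rng.standard_normal((L, P))
    mean = alpha[:, None] + beta_true @ env.values
    theta = mean + np.sqrt(s)[:, None] * (z @ chol.T)
    p = np.clip(theta, CLAMP_EPS, 1.0 - CLAMP_EPS)
    count1 = rng.binomial(n_chrom, p)

    width = max(4, len(str(L)))
    counts = AlleleCountMatrix(
        snp_ids=[f"snp_{i + 1:0{width}d}" for i in range(L)],
        chrom=np.array(["chr1"] * L, dtype=object),
        pos=pos.astype(np.int64),
        count1=count1,
        ntotal=np.full((L, P), n_chrom, dtype=np.int64),
    )
    truth = SyntheticTruth(
        omega_true=omega,
        alpha_true=alpha,
        beta_true=beta_true,
        causal=beta_true != 0,
        genic_bias=float(genic_bias),
        theta_true=theta,
    )
    return counts, genes, truth
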