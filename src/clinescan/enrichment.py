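"""Genic vs non-genic enrichment in empirical tails, with block-bootstrap significance.

A SNP is *genic* if it lies within ``near_threshold`` (default 10 kb) of an
annotated gene and *non-genic* if it lies more than ``far_threshold`` (default
50 kb) from every gene; SNPs in between are ambiguous and excluded from every
count.  Enrichment in an empirical-p tail is the ratio of genic:non-genic odds
in the tail to the genome-wide odds::

    enrichment = (n_g / n_ng) / (N_g / N_ng)

Significance comes from a block bootstrap that preserves the local correlation
of SNP signals: the genome is partitioned into contiguous 500-kb windows, and
each replicate resamples W windows with replacement (W = number of non-empty
windows), pools their SNPs and recomputes the enrichment.  The enriched
fraction is the proportion of replicates with enrichment above 1, mapped to a
0-3 star significance code.
"""

from __future__ import annotations

import numpy as np

from .types import EnrichmentResult, GeneIntervals, GenicLabels

__all__ = [
    "classify_genic",
    "enrichment_statistic",
    "block_bootstrap_significance",
    "stars",
]

DEFAULT_NEAR = 10_000
DEFAULT_FAR = 50_000
DEFAULT_BLOCK = 500_000
DEFAULT_REPS = 10_000


def _distance_to_genes(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distance in bp from each position to the nearest interval (0 if inside)."""
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    ends = ends[order]
    # running maximum of ends handles overlapping/contained intervals
    cummax_end = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, pos, side="right")
    dist = np.full(pos.shape, np.inf)
    has_left = idx > 0
    left_end = np.where(has_left, cummax_end[np.maximum(idx - 1, 0)], 0)
    inside = has_left & (pos < left_end)
    dist_left = np.where(has_left, np.maximum(pos - left_end + 1, 0), np.inf)
    # pos >= left interval end => distance past the last covered base
    dist_left = np.where(has_left & (pos >= left_end), pos - left_end + 1, dist_left)
    has_right = idx < len(starts)
    dist_right = np.where(has_right, starts[np.minimum(idx, len(starts) - 1)] - pos, np.inf)
    dist = np.minimum(dist_left, dist_right)
    dist[inside] = 0.0
    return dist


def classify_genic(
    chrom: np.ndarray,
    pos: np.ndarray,
    genes: GeneIntervals,
    near: int = DEFAULT_NEAR,
    far: int = DEFAULT_FAR,
) -> GenicLabels:
    """Label each SNP genic (<= near bp from a gene), nongenic (> far bp) or ambiguous.

    Distances are measured to the nearest interval edge on the same
    chromosome; with no gene on the chromosome the distance is infinite
    (hence nongenic).
    """
    if near >= far:
        raise ValueError("near threshold must be < far threshold")
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    labels = np.empty(len(pos), dtype=object)
    dist = np.full(len(pos), np.inf)
    for c in np.unique(chrom.astype(str)):
        snp_mask = chrom.astype(str) == c
        gene_mask = genes.chrom.astype(str) == c
        if gene_mask.any():
            dist[snp_mask] = _distance_to_genes(
                pos[snp_mask], genes.start[gene_mask], genes.end[gene_mask]
            )
    labels[dist <= near] = "genic"
    labels[dist > far] = "nongenic"
    labels[(dist > near) & (dist <= far)] = "ambiguous"
    return GenicLabels(labels=labels, near_threshold=near, far_threshold=far)


def _counts(labels: np.ndarray, in_tail: np.ndarray):
    genic = labels == "genic"
    nongenic = labels == "nongenic"
    return (
        int((genic & in_tail).sum()),
        int((nongenic & in_tail).sum()),
        int(genic.sum()),
        int(nongenic.sum()),
    )


def _enrichment_value(n_g, n_ng, N_g, N_ng):
    if n_ng == 0 or N_g == 0 or N_ng == 0:
        return np.nan, True
    return (n_g / n_ng) / (N_g / N_ng), False


def enrichment_statistic(
    labels: GenicLabels,
    in_tail: np.ndarray,
    tail_cutoff: float = np.nan,
    variable: str = "",
) -> EnrichmentResult:
    """Tail enrichment of genic over non-genic SNPs (no significance attached)."""
    in_tail = np.asarray(in_tail, dtype=bool)
    if in_tail.shape[0] != len(labels):
        raise ValueError("in_tail must align with labels")
    n_g, n_ng, N_g, N_ng = _counts(labels.labels, in_tail)
    value, degenerate = _enrichment_value(n_g, n_ng, N_g, N_ng)
    return EnrichmentResult(
        enrichment=float(value) if not degenerate else float("nan"),
        n_g=n_g,
        n_ng=n_ng,
        N_g=N_g,
        N_ng=N_ng,
        tail_cutoff=tail_cutoff,
        variable=variable,
        degenerate=degenerate,
    )


def stars(enriched_fraction: float) -> int:
    """Map a bootstrap enriched fraction to the 0-3 star significance code.

    < 0.95 -> 0; [0.95, 0.975) -> 1; [0.975, 0.99) -> 2; >= 0.99 -> 3 (the
    upper boundary is taken as inclusive to make the map total).
    """
    f = float(enriched_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValueError("enriched fraction must lie in [0, 1]")
    if f < 0.95:
        return 0
    if f < 0.975:
        return 1
    if f < 0.99:
        return 2
    return 3


def block_bootstrap_significance(
    pvalues: np.ndarray,
    labels: GenicLabels,
    chrom: np.ndarray,
    pos: np.ndarray,
    tail_cutoff: float,
    block: int = DEFAULT_BLOCK,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    variable: str = "",
) -> EnrichmentResult:
    """Enrichment with block-bootstrap significance.

    Windows are anchored at coordinate 0 per chromosome (window =
    ``floor(pos / block)``); each replicate draws W non-empty windows with
    replacement and recomputes the enrichment from the pooled per-window
    counts.  A replicate with a non-empty tail and no non-genic tail SNPs
    counts as enriched (the limit is +inf); an empty-tail replicate counts as
    not enriched.  Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pvalues = np.asarray(pvalues, dtype=float)
    pos = np.asarray(pos, dtype=np.int64)
    chrom = np.asarray(chrom, dtype=object)
    lab = labels.labels
    keep = lab != "ambiguous"  # ambiguous SNPs leave every pool
    in_tail = pvalues <= tail_cutoff

    observed = enrichment_statistic(labels, in_tail, tail_cutoff, variable)

    # per-window counts over non-ambiguous SNPs
    win_key = np.array(
        [f"{c}:{w}" for c, w in zip(chrom[keep].astype(str), pos[keep] // block)]
    )
    uniq, win_idx = np.unique(win_key, return_inverse=True)
    W = len(uniq)
    if W == 0:
        raise ValueError("no window contains usable SNPs")
    genic = lab[keep] == "genic"
    tail = in_tail[keep]
    cnt = np.zeros((W, 4), dtype=np.int64)  # n_g, n_ng, N_g, N_ng per window
    np.add.at(cnt[:, 0], win_idx[genic & tail], 1)
    np.add.at(cnt[:, 1], win_idx[~genic & tail], 1)
    np.add.at(cnt[:, 2], win_idx[genic], 1)
    np.add.at(cnt[:, 3], win_idx[~genic], 1)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, W, size=(reps, W))
    # sum counts over the sampled windows per replicate
    sums = cnt[picks].sum(axis=1)  # reps x 4
    n_g, n_ng, N_g, N_ng = sums.T
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (n_g / n_ng) / (N_g / N_ng)
    enriched = enr > 1.0
    # degenerate replicates: non-genic tail empty but genic tail occupied => enriched
    enriched |= (n_ng == 0) & (n_g > 0)
    # empty-tail replicates stay not enriched
    enriched &= (n_g + n_ng) > 0
    frac = float(enriched.sum() / reps)

    return EnrichmentResult(
        enrichment=observed.enrichment,
        n_g=observed.n_g,
        n_ng=observed.n_ng,
        N_g=observed.N_g,
        N_ng=observed.N_ng,
        tail_cutoff=tail_cutoff,
        variable=variable,
        enriched_fraction=frac,
        stars=stars(frac),
        degenerate=observed.degenerate,
    )
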