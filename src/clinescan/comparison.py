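"""Agreement between independent scan runs.

An MCMC scan is stochastic: two runs on identical data with different seeds
give different Bayes factors.  This module quantifies that run-to-run
variability the way a replication study would: Pearson correlations of log10
Bayes factors and of empirical p-values, overlap of the empirical-p tails at
fixed cutoffs, overlap of rank-matched bins of 1,000 SNPs, and averaging of
log Bayes factors across runs (the geometric mean of the BFs), which is the
recommended way to stabilise results before ranking.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .types import ComparisonReport, ScanResult, TailOverlapMatrix

__all__ = [
    "log_bf_correlation",
    "pvalue_correlation",
    "average_pairwise_correlations",
    "tail_overlap",
    "tail_overlap_matrix",
    "ranked_bin_overlap",
    "average_runs",
    "paired_wilcoxon_correlations",
    "compare_runs",
]

DEFAULT_TAIL_CUTOFFS = (0.05, 0.01, 0.005, 0.001)
DEFAULT_RANK_BIN_SIZE = 1000


def _check_aligned(runA: ScanResult, runB: ScanResult) -> None:
    if runA.snp_ids != runB.snp_ids:
        raise ValueError("runs must cover the same SNPs in the same order")
    if runA.var_names != runB.var_names:
        raise ValueError("runs must cover the same variables")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def log_bf_correlation(runA: ScanResult, runB: ScanResult, variable) -> float:
    """Pearson correlation of log10 Bayes factors over all SNPs."""
    _check_aligned(runA, runB)
    v = runA.var_index(variable)
    return _pearson(runA.log10_bf[:, v], runB.log10_bf[:, v])


def pvalue_correlation(runA: ScanResult, runB: ScanResult, variable) -> float:
    """Pearson correlation of empirical p-values over all SNPs."""
    _check_aligned(runA, runB)
    v = runA.var_index(variable)
    if runA.empirical_p is None or runB.empirical_p is None:
        raise ValueError("both runs need empirical p values")
    return _pearson(runA.empirical_p[:, v], runB.empirical_p[:, v])


def average_pairwise_correlations(
    runs: list[ScanResult], statistic: str = "log_bf"
) -> np.ndarray:
    """Mean Pearson r over all unordered run pairs, per variable."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    fn = log_bf_correlation if statistic == "log_bf" else pvalue_correlation
    V = runs[0].n_vars
    out = np.zeros(V)
    pairs = list(itertools.combinations(runs, 2))
    for a, b in pairs:
        for v in range(V):
            out[v] += fn(a, b, v)
    return out / len(pairs)


def tail_overlap(pA: np.ndarray, pB: np.ndarray, cutA: float, cutB: float) -> float:
    """Proportion of shared tail SNPs relative to the smaller tail.

    0 when either tail is empty.  Symmetric under swapping (pA, cutA) with
    (pB, cutB); equals 1 whenever one tail nests inside the other.
    """
    inA = np.asarray(pA) <= cutA
    inB = np.asarray(pB) <= cutB
    nA, nB = int(inA.sum()), int(inB.sum())
    if nA == 0 or nB == 0:
        return 0.0
    return float((inA & inB).sum() / min(nA, nB))


def tail_overlap_matrix(
    runA: ScanResult,
    runB: ScanResult,
    cutoffs=DEFAULT_TAIL_CUTOFFS,
    variable=None,
) -> TailOverlapMatrix:
    """Tail overlap over a cutoff grid, averaged over variables unless one is given."""
    _check_aligned(runA, runB)
    if runA.empirical_p is None or runB.empirical_p is None:
        raise ValueError("both runs need empirical p values")
    cutoffs = np.asarray(cutoffs, dtype=float)
    K = len(cutoffs)
    vs = range(runA.n_vars) if variable is None else [runA.var_index(variable)]
    mat = np.zeros((K, K))
    for v in vs:
        for i, ca in enumerate(cutoffs):
            for j, cb in enumerate(cutoffs):
                mat[i, j] += tail_overlap(
                    runA.empirical_p[:, v], runB.empirical_p[:, v], ca, cb
                )
    mat /= len(list(vs))
    return TailOverlapMatrix(cutoffs=cutoffs, proportions=mat)


def _rank_order(p: np.ndarray) -> np.ndarray:
    # stable: ties in p resolved by SNP input order
    return np.argsort(p, kind="stable")


def ranked_bin_overlap(
    runA: ScanResult,
    runB: ScanResult,
    bin_size: int = DEFAULT_RANK_BIN_SIZE,
    variable=None,
) -> np.ndarray:
    """Overlap of rank-matched p-value bins (windows of ``bin_size`` SNPs).

    SNPs are ordered by empirical p (lowest first) in each run; bin k of run A
    is intersected with bin k of run B.  Returns per-bin proportions averaged
    over variables unless a single variable is requested; a trailing partial
    bin is included with its own size as denominator.
    """
    _check_aligned(runA, runB)
    if runA.empirical_p is None or runB.empirical_p is None:
        raise ValueError("both runs need empirical p values")
    L = runA.n_snps
    if L < bin_size:
        raise ValueError(f"need at least bin_size ({bin_size}) SNPs, got {L}")
    n_bins = (L + bin_size - 1) // bin_size
    vs = range(runA.n_vars) if variable is None else [runA.var_index(variable)]
    out = np.zeros(n_bins)
    for v in vs:
        ordA = _rank_order(runA.empirical_p[:, v])
        ordB = _rank_order(runB.empirical_p[:, v])
        for k in range(n_bins):
            lo, hi = k * bin_size, min((k + 1) * bin_size, L)
            shared = np.intersect1d(ordA[lo:hi], ordB[lo:hi]).size
            out[k] += shared / (hi - lo)
    return out / len(list(vs))


def average_runs(runs: list[ScanResult]) -> ScanResult:
    """Average log10 Bayes factors across runs (geometric mean of the BFs).

    Empirical p-values are dropped; recompute them on the averaged table.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to average")
    first = runs[0]
    for r in runs[1:]:
        _check_aligned(first, r)
    log10_bf = np.mean([r.log10_bf for r in runs], axis=0)
    return ScanResult(
        snp_ids=list(first.snp_ids),
        var_names=list(first.var_names),
        log10_bf=log10_bf,
        empirical_p=None,
        chrom=first.chrom,
        pos=first.pos,
        seed=None,
        iterations=first.iterations,
    )


def paired_wilcoxon_correlations(corrsA, corrsB) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on per-variable mean correlations.

    Used to test whether one experimental condition (e.g. 5x more MCMC
    iterations) yields systematically higher between-run correlations.
    """
    a = np.asarray(corrsA, dtype=float)
    b = np.asarray(corrsB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    if np.all(d == 0):
        raise ValueError("degenerate pairing: all differences zero")
    return float(stats.wilcoxon(b, a, alternative="two-sided", method="exact").pvalue)


def compare_runs(
    runA: ScanResult,
    runB: ScanResult,
    name_a: str = "runA",
    name_b: str = "runB",
    cutoffs=DEFAULT_TAIL_CUTOFFS,
    bin_size: int = DEFAULT_RANK_BIN_SIZE,
) -> ComparisonReport:
    """Full pairwise comparison: correlations, tail overlap and ranked-bin overlap."""
    V = runA.n_vars
    return ComparisonReport(
        run_a=name_a,
        run_b=name_b,
        var_names=list(runA.var_names),
        log_bf_correlation=np.array([log_bf_correlation(runA, runB, v) for v in range(V)]),
        pvalue_correlation=np.array([pvalue_correlation(runA, runB, v) for v in range(V)]),
        tail_overlap=tail_overlap_matrix(runA, runB, cutoffs=cutoffs),
        ranked_bin_overlap=ranked_bin_overlap(runA, runB, bin_size=bin_size)
        if runA.n_snps >= bin_size
        else np.zeros(0),
    )
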