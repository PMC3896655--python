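"""Domain containers shared by all clinescan modules.

Conventions: L SNPs, P populations, V environmental variables.  Allele data
are stored as *counts* (copies of the counted allele and total sampled
chromosomes), environmental data as a V x P real matrix, and the null
population structure as a P x P covariance matrix Omega on the
transformed-allele-frequency scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AlleleCountMatrix",
    "EnvironmentMatrix",
    "GeneIntervals",
    "CovarianceMatrix",
    "NullPosteriorDraws",
    "BetaPrior",
    "ScanResult",
    "FrequencyBins",
    "GenicLabels",
    "EnrichmentResult",
    "TailOverlapMatrix",
    "ComparisonReport",
    "StabilityConfig",
]


def _as_2d_int(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{name} must contain integers")
        arr = arr.astype(np.int64)
    return arr.astype(np.int64)


@dataclass
class AlleleCountMatrix:
    """Per-SNP, per-population allele counts with genomic positions.

    ``count1`` holds copies of the counted allele, ``ntotal`` the number of
    sampled chromosomes; both are L x P.  ``panel`` optionally groups SNPs by
    ascertainment panel (each panel gets its own null covariance).
    """

    snp_ids: list[str]
    chrom: np.ndarray  # L, str labels
    pos: np.ndarray  # L, non-negative int
    count1: np.ndarray  # L x P
    ntotal: np.ndarray  # L x P
    pop_names: list[str] | None = None
    panel: np.ndarray | None = None  # L, str labels

    def __post_init__(self) -> None:
        self.count1 = _as_2d_int(self.count1, "count1")
        self.ntotal = _as_2d_int(self.ntotal, "ntotal")
        if self.count1.shape != self.ntotal.shape:
            raise ValueError("count1 and ntotal must have identical shapes")
        L, P = self.count1.shape
        if P < 1:
            raise ValueError("need at least one population")
        if np.any(self.count1 < 0) or np.any(self.ntotal < 0):
            raise ValueError("allele counts must be non-negative")
        if np.any(self.count1 > self.ntotal):
            raise ValueError("count1 must not exceed ntotal")
        if len(self.snp_ids) != L:
            raise ValueError("snp_ids length must equal number of SNP rows")
        if len(set(self.snp_ids)) != L:
            raise ValueError("snp_ids must be unique")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.chrom.shape != (L,) or self.pos.shape != (L,):
            raise ValueError("chrom and pos must be per-SNP vectors")
        if np.any(self.pos < 0):
            raise ValueError("positions must be non-negative")
        if self.pop_names is not None and len(self.pop_names) != P:
            raise ValueError("pop_names length must equal number of populations")
        if self.panel is not None:
            self.panel = np.asarray(self.panel, dtype=object)
            if self.panel.shape != (L,):
                raise ValueError("panel must be a per-SNP vector")

    @property
    def n_snps(self) -> int:
        return self.count1.shape[0]

    @property
    def n_pops(self) -> int:
        return self.count1.shape[1]

    def take_snps(self, idx) -> "AlleleCountMatrix":
        idx = np.asarray(idx)
        return AlleleCountMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            count1=self.count1[idx],
            ntotal=self.ntotal[idx],
            pop_names=self.pop_names,
            panel=None if self.panel is None else self.panel[idx],
        )


@dataclass
class EnvironmentMatrix:
    """Per-variable, per-population environmental values (V x P)."""

    var_names: list[str]
    values: np.ndarray
    standardized: bool = False
    pop_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be V x P")
        if len(self.var_names) != self.values.shape[0]:
            raise ValueError("var_names length must equal number of rows")
        if self.pop_names is not None and len(self.pop_names) != self.values.shape[1]:
            raise ValueError("pop_names length must equal number of populations")
        if self.standardized:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1)
            if np.any(np.abs(mu) > 1e-9) or np.any(np.abs(sd - 1.0) > 1e-9):
                raise ValueError("standardized flag set but rows are not standardized")

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def n_pops(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneIntervals:
    """Gene annotations as 0-based half-open intervals, sortable by (chrom, start)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n = len(self.chrom)
        if self.start.shape != (n,) or self.end.shape != (n,):
            raise ValueError("chrom, start, end must have equal length")
        if np.any(self.start >= self.end):
            raise ValueError("intervals require start < end")
        if self.name is not None:
            self.name = np.asarray(self.name, dtype=object)
            if self.name.shape != (n,):
                raise ValueError("name must match interval count")

    def __len__(self) -> int:
        return len(self.chrom)

    def sorted(self) -> "GeneIntervals":
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return GeneIntervals(
            chrom=self.chrom[order],
            start=self.start[order],
            end=self.end[order],
            name=None if self.name is None else self.name[order],
        )


@dataclass
class CovarianceMatrix:
    """P x P across-population covariance Omega of transformed allele frequencies."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 2 or self.omega.shape[0] != self.omega.shape[1]:
            raise ValueError("omega must be square")
        if not np.allclose(self.omega, self.omega.T, atol=1e-9):
            raise ValueError("omega must be symmetric")
        # smallest eigenvalue must be positive
        ev = np.linalg.eigvalsh(self.omega)
        if ev[0] <= 0:
            raise ValueError(f"omega must be positive definite (min eigenvalue {ev[0]:g})")

    @property
    def n_pops(self) -> int:
        return self.omega.shape[0]


@dataclass
class NullPosteriorDraws:
    """Retained MCMC samples from the null model posterior.

    ``omega`` is T x P x P, ``alpha`` T x L, ``theta`` T x L x P, with
    ``iteration`` recording the MCMC iteration index of each retained sample.
    """

    omega: np.ndarray
    alpha: np.ndarray
    theta: np.ndarray
    iteration: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.iteration = np.asarray(self.iteration, dtype=np.int64)
        T = self.omega.shape[0]
        if not (self.alpha.shape[0] == self.theta.shape[0] == self.iteration.shape[0] == T):
            raise ValueError("draw arrays must share the leading sample dimension")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha draws must lie in (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.omega.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alpha.shape[1]

    @property
    def n_pops(self) -> int:
        return self.omega.shape[1]


@dataclass(frozen=True)
class BetaPrior:
    """Prior on the linear environmental effect beta (symmetric about 0).

    family 'normal': beta ~ N(0, scale^2); 'uniform': beta ~ U(-scale, scale);
    'point-mass': beta = 0 exactly (the alternative collapses onto the null).
    The default scale is deliberately small: beta acts on the
    transformed-frequency scale, where a single population's drift standard
    deviation is sqrt(alpha(1-alpha) * Omega_pp) ~ 0.1, and a unit-information
    prior (information comparable to one population's drift) keeps Bayes
    factors near 1 for null SNPs instead of drowning them in an Occam penalty.
    """

    family: Literal["normal", "uniform", "point-mass"] = "normal"
    scale: float = 0.05

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform", "point-mass"):
            raise ValueError(f"unknown beta prior family {self.family!r}")
        if self.family == "point-mass":
            if self.scale != 0:
                object.__setattr__(self, "scale", 0.0)
        elif self.scale <= 0:
            raise ValueError("scale must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(0.0, self.scale, size=n)
        if self.family == "uniform":
            return rng.uniform(-self.scale, self.scale, size=n)
        return np.zeros(n)


@dataclass
class ScanResult:
    """Per-SNP, per-variable log10 Bayes factors and (optionally) empirical p."""

    snp_ids: list[str]
    var_names: list[str]
    log10_bf: np.ndarray  # L x V
    empirical_p: np.ndarray | None = None  # L x V, in (0, 1]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    seed: int | None = None
    iterations: int | None = None

    def __post_init__(self) -> None:
        self.log10_bf = np.asarray(self.log10_bf, dtype=float)
        L, V = len(self.snp_ids), len(self.var_names)
        if self.log10_bf.shape != (L, V):
            raise ValueError("log10_bf must be L x V")
        if not np.all(np.isfinite(self.log10_bf)):
            raise ValueError("log10_bf must be finite")
        if self.empirical_p is not None:
            self.empirical_p = np.asarray(self.empirical_p, dtype=float)
            if self.empirical_p.shape != (L, V):
                raise ValueError("empirical_p must be L x V")
            if np.any(self.empirical_p <= 0) or np.any(self.empirical_p > 1):
                raise ValueError("empirical p values must lie in (0, 1]")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def var_index(self, variable: str | int) -> int:
        if isinstance(variable, str):
            return self.var_names.index(variable)
        return int(variable)


@dataclass
class FrequencyBins:
    """Assignment of SNPs to global-allele-frequency bins."""

    bin_id: np.ndarray  # L, int >= 0
    bin_count: int
    scheme: Literal["equal-count", "equal-width"]
    maf: np.ndarray  # L, in [0, 0.5]

    def __post_init__(self) -> None:
        self.bin_id = np.asarray(self.bin_id, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.bin_id.shape != self.maf.shape:
            raise ValueError("bin_id and maf must align")
        if np.any(self.bin_id < 0) or np.any(self.bin_id >= self.bin_count):
            raise ValueError("bin ids out of range")
        if np.any(self.maf < 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in [0, 0.5]")


@dataclass
class GenicLabels:
    """Per-SNP genic / non-genic / ambiguous classification."""

    labels: np.ndarray  # L, values in {"genic", "nongenic", "ambiguous"}
    near_threshold: int = 10_000
    far_threshold: int = 50_000

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.near_threshold >= self.far_threshold:
            raise ValueError("near_threshold must be < far_threshold")
        bad = set(np.unique(self.labels)) - {"genic", "nongenic", "ambiguous"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EnrichmentResult:
    """Genic/non-genic enrichment in an empirical tail with bootstrap significance."""

    enrichment: float
    n_g: int
    n_ng: int
    N_g: int
    N_ng: int
    tail_cutoff: float
    variable: str = ""
    enriched_fraction: float | None = None
    stars: int | None = None
    degenerate: bool = False


@dataclass
class TailOverlapMatrix:
    """K x K tail-overlap proportions over a grid of p-value cutoffs.

    Row = cutoff applied to run A, column = cutoff applied to run B.
    """

    cutoffs: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        K = len(self.cutoffs)
        if self.proportions.shape != (K, K):
            raise ValueError("proportions must be K x K")
        if np.any((self.proportions < 0) | (self.proportions > 1)):
            raise ValueError("overlap proportions must lie in [0, 1]")


@dataclass
class ComparisonReport:
    """Agreement summary between two independent scan runs."""

    run_a: str
    run_b: str
    var_names: list[str]
    log_bf_correlation: np.ndarray  # V
    pvalue_correlation: np.ndarray  # V
    tail_overlap: TailOverlapMatrix
    ranked_bin_overlap: np.ndarray  # per rank-bin proportions (variable-averaged)

    def __post_init__(self) -> None:
        for r in (self.log_bf_correlation, self.pvalue_correlation):
            arr = np.asarray(r, dtype=float)
            if np.any(np.abs(arr) > 1 + 1e-12):
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class StabilityConfig:
    """Configuration of a multi-run stability experiment."""

    n_runs: int = 5
    iterations: int = 100_000
    seeds: Sequence[int] = ()
    tail_cutoffs: Sequence[float] = (0.05, 0.01, 0.005, 0.001)
    n_bins: int = 12
    enrichment_reps: int = 10_000
    exclude_populations: Sequence[str] = ()
    output_dir: str = "stability_out"
    covariance_iterations: int | None = None
    covariance_output_interval: int | None = None
    ranked_bin_size: int = 1000

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not self.seeds:
            self.seeds = tuple(range(1, self.n_runs + 1))
        self.seeds = tuple(int(s) for s in self.seeds)
        if len(self.seeds) != self.n_runs:
            raise ValueError("need one seed per run")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        cuts = tuple(float(c) for c in self.tail_cutoffs)
        if any(not (0 < c < 1) for c in cuts):
            raise ValueError("tail cutoffs must lie in (0, 1)")
        if not all(a > b for a, b in zip(cuts[:-1], cuts[1:])):
            raise ValueError("tail cutoffs must be strictly decreasing")
        self.tail_cutoffs = cuts
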