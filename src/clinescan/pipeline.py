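"""Orchestration of multi-run stability experiments.

A stability experiment mirrors the design of a replication study: estimate
the null covariance once, run several independently seeded Bayes-factor scans
on the same data, convert each to empirical p-values, and report (i) per-run
result tables, (ii) pairwise comparison tables (correlations, tail overlap,
ranked-bin overlap), (iii) genic/non-genic enrichment per run and for the
run-averaged Bayes factors.  The whole bundle is a pure function of
(input files, config), so a rerun is byte-identical.
"""

from __future__ import annotations

import itertools
import logging
import sys
import time
import tomllib
from pathlib import Path

import numpy as np

from . import io as cio
from .comparison import average_pairwise_correlations, average_runs, compare_runs
from .enrichment import block_bootstrap_significance, classify_genic
from .model import estimate_null_covariance, run_scan, standardize_environment
from .pvalues import assign_bins, empirical_pvalues, global_maf
from .types import (
    AlleleCountMatrix,
    CovarianceMatrix,
    EnvironmentMatrix,
    GeneIntervals,
    ScanResult,
    StabilityConfig,
)

__all__ = ["exclude_populations", "stability_workflow", "load_config"]

log = logging.getLogger("clinescan")


def exclude_populations(
    counts: AlleleCountMatrix, env: EnvironmentMatrix, names
) -> tuple[AlleleCountMatrix, EnvironmentMatrix]:
    """Drop named populations from both structures (e.g. outlying climates).

    Requires population names on both inputs; the environment should be
    re-standardized downstream.
    """
    names = list(names)
    if not names:
        return counts, env
    if counts.pop_names is None or env.pop_names is None:
        raise ValueError("population names are required to exclude populations")
    for n in names:
        if n not in counts.pop_names:
            raise ValueError(
                f"unknown population {n!r}; available: {', '.join(counts.pop_names)}"
            )
    keep = [i for i, n in enumerate(counts.pop_names) if n not in names]
    kept_names = [counts.pop_names[i] for i in keep]
    new_counts = AlleleCountMatrix(
        snp_ids=list(counts.snp_ids),
        chrom=counts.chrom,
        pos=counts.pos,
        count1=counts.count1[:, keep],
        ntotal=counts.ntotal[:, keep],
        pop_names=kept_names,
        panel=counts.panel,
    )
    env_keep = [i for i, n in enumerate(env.pop_names) if n not in names]
    new_env = EnvironmentMatrix(
        var_names=list(env.var_names),
        values=env.values[:, env_keep],
        standardized=False,
        pop_names=kept_names,
    )
    return new_counts, new_env


def load_config(path) -> StabilityConfig:
    """Read a TOML stability config."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return StabilityConfig(**raw)


def _scan_one_panel(counts, env, omega, iterations, seed):
    return run_scan(counts, env, omega=omega, iterations=iterations, seed=seed)


def _estimate_per_panel(counts: AlleleCountMatrix, iterations, output_interval, seed):
    """One covariance per ascertainment panel (single shared panel by default)."""
    if counts.panel is None:
        cov, _ = estimate_null_covariance(
            counts, iterations=iterations, output_interval=output_interval, seed=seed
        )
        return {None: cov}
    out = {}
    for i, p in enumerate(sorted(set(counts.panel.astype(str)))):
        sub = counts.take_snps(np.where(counts.panel.astype(str) == p)[0])
        cov, _ = estimate_null_covariance(
            sub, iterations=iterations, output_interval=output_interval, seed=seed + i
        )
        out[p] = cov
    return out


def _scan_with_panels(counts, env, covs, iterations, seed) -> ScanResult:
    if counts.panel is None:
        return _scan_one_panel(counts, env, covs[None], iterations, seed)
    parts = []
    index_parts = []
    for p, cov in covs.items():
        idx = np.where(counts.panel.astype(str) == p)[0]
        sub = counts.take_snps(idx)
        parts.append(_scan_one_panel(sub, env, cov, iterations, seed))
        index_parts.append(idx)
    order = np.argsort(np.concatenate(index_parts), kind="stable")
    all_idx = np.concatenate(index_parts)[order]
    log10_bf = np.concatenate([p.log10_bf for p in parts])[order]
    assert np.array_equal(all_idx, np.arange(counts.n_snps))
    return ScanResult(
        snp_ids=list(counts.snp_ids),
        var_names=list(env.var_names),
        log10_bf=log10_bf,
        chrom=counts.chrom,
        pos=counts.pos,
        seed=seed,
        iterations=iterations,
    )


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def stability_workflow(
    config: StabilityConfig,
    counts: AlleleCountMatrix,
    env: EnvironmentMatrix,
    genes: GeneIntervals | None = None,
    covariance: CovarianceMatrix | None = None,
) -> dict:
    """Run the full multi-run experiment and write the report bundle.

    Returns a manifest dict mapping artifact names to file paths.  Stage
    timings are logged to stderr; output files carry no timestamps so a rerun
    with the same inputs and config is byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {}

    if config.exclude_populations:
        counts, env = exclude_populations(counts, env, config.exclude_populations)
    env = standardize_environment(env)

    # stage 1: null covariance, estimated once and shared by all runs
    t0 = time.time()
    if covariance is not None:
        covs = {None: covariance}
    else:
        cov_iter = config.covariance_iterations or config.iterations
        cov_out = config.covariance_output_interval or max(cov_iter // 20, 1)
        try:
            covs = _estimate_per_panel(counts, cov_iter, cov_out, seed=config.seeds[0])
        except ValueError as exc:
            raise ValueError(f"covariance stage failed: {exc}") from exc
    for pname, cov in covs.items():
        tag = "" if pname is None else f".{pname}"
        path = out / f"covariance{tag}.txt"
        cio.write_matrixfile(cov, path)
        manifest[f"covariance{tag}"] = path
    log.info("covariance stage done in %.1fs", time.time() - t0)

    # stage 2: independently seeded scans + empirical p values
    maf = global_maf(counts)
    bins = assign_bins(maf, n_bins=min(config.n_bins, counts.n_snps))
    runs: list[ScanResult] = []
    for r, seed in enumerate(config.seeds, start=1):
        t0 = time.time()
        try:
            scan = _scan_with_panels(counts, env, covs, config.iterations, seed)
        except ValueError as exc:
            raise ValueError(f"scan stage (run {r}) failed: {exc}") from exc
        scan = empirical_pvalues(scan, bins)
        path = out / f"scan_run{r}.tsv"
        cio.write_results(scan, path)
        manifest[f"scan_run{r}"] = path
        runs.append(scan)
        log.info("scan run %d (seed %d) done in %.1fs", r, seed, time.time() - t0)

    # stage 3: pairwise comparisons (correlation / tail overlap / ranked bins)
    pairs = list(itertools.combinations(range(len(runs)), 2))
    reports = {
        (i, j): compare_runs(
            runs[i],
            runs[j],
            name_a=f"run{i + 1}",
            name_b=f"run{j + 1}",
            cutoffs=config.tail_cutoffs,
            bin_size=config.ranked_bin_size,
        )
        for i, j in pairs
    }
    corr_rows = []
    for i, j in pairs:
        rep = reports[(i, j)]
        for v, name in enumerate(rep.var_names):
            corr_rows.append(
                (
                    rep.run_a,
                    rep.run_b,
                    name,
                    _fmt(rep.log_bf_correlation[v]),
                    _fmt(rep.pvalue_correlation[v]),
                )
            )
    _write_tsv(
        out / "correlations.tsv",
        ["run_a", "run_b", "variable", "log_bf_r", "pvalue_r"],
        corr_rows,
    )
    manifest["correlations"] = out / "correlations.tsv"

    mean_logbf_r = average_pairwise_correlations(runs, "log_bf")
    mean_p_r = average_pairwise_correlations(runs, "pvalue")
    _write_tsv(
        out / "correlations_mean.tsv",
        ["variable", "mean_log_bf_r", "mean_pvalue_r"],
        [
            (name, _fmt(mean_logbf_r[v]), _fmt(mean_p_r[v]))
            for v, name in enumerate(env.var_names)
        ],
    )
    manifest["correlations_mean"] = out / "correlations_mean.tsv"

    overlap_rows = []
    K = len(config.tail_cutoffs)
    for i, j in pairs:
        rep = reports[(i, j)]
        for a in range(K):
            for b in range(K):
                overlap_rows.append(
                    (
                        f"run{i + 1}",
                        f"run{j + 1}",
                        config.tail_cutoffs[a],
                        config.tail_cutoffs[b],
                        _fmt(rep.tail_overlap.proportions[a, b]),
                    )
                )
    _write_tsv(
        out / "tail_overlap.tsv",
        ["run_a", "run_b", "cutoff_a", "cutoff_b", "overlap"],
        overlap_rows,
    )
    manifest["tail_overlap"] = out / "tail_overlap.tsv"

    if counts.n_snps >= config.ranked_bin_size:
        arr = np.array([reports[(i, j)].ranked_bin_overlap for i, j in pairs])  # pairs x bins
        _write_tsv(
            out / "ranked_bin_overlap.tsv",
            ["bin_start_rank", "bin_end_rank", "mean_overlap", "sd_overlap"],
            [
                (
                    k * config.ranked_bin_size + 1,
                    min((k + 1) * config.ranked_bin_size, counts.n_snps),
                    _fmt(arr[:, k].mean()),
                    _fmt(arr[:, k].std()),
                )
                for k in range(arr.shape[1])
            ],
        )
        manifest["ranked_bin_overlap"] = out / "ranked_bin_overlap.tsv"

    # stage 4: run-averaged Bayes factors with fresh empirical p values
    avg = average_runs(runs)
    avg = empirical_pvalues(avg, bins)
    cio.write_results(avg, out / "scan_averaged.tsv")
    manifest["scan_averaged"] = out / "scan_averaged.tsv"

    # stage 5: genic/non-genic enrichment per run and for the average
    if genes is not None:
        labels = classify_genic(counts.chrom, counts.pos, genes)
        enr_rows = []
        named_runs = [(f"run{r + 1}", sc) for r, sc in enumerate(runs)]
        named_runs.append(("averaged", avg))
        for rname, sc in named_runs:
            for v, vname in enumerate(env.var_names):
                for ci, cutoff in enumerate(config.tail_cutoffs):
                    res = block_bootstrap_significance(
                        sc.empirical_p[:, v],
                        labels,
                        counts.chrom,
                        counts.pos,
                        tail_cutoff=cutoff,
                        reps=config.enrichment_reps,
                        seed=config.seeds[0] * 1000 + v * 10 + ci,
                        variable=vname,
                    )
                    enr_rows.append(
                        (
                            rname,
                            vname,
                            cutoff,
                            _fmt(res.enrichment) if not res.degenerate else "NA",
                            _fmt(res.enriched_fraction),
                            res.stars,
                        )
                    )
        _write_tsv(
            out / "enrichment.tsv",
            ["run", "variable", "tail_cutoff", "enrichment", "enriched_fraction", "stars"],
            enr_rows,
        )
        manifest["enrichment"] = out / "enrichment.tsv"

    # run log: seeds and iteration counts per run, no timestamps
    _write_tsv(
        out / "run_log.tsv",
        ["run", "seed", "iterations"],
        [(f"run{r + 1}", s, config.iterations) for r, s in enumerate(config.seeds)],
    )
    manifest["run_log"] = out / "run_log.tsv"
    return manifest
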