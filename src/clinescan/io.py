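"""Readers and writers for the Bayenv text dialects, BED annotations and
result tables.

Bayenv dialects:

* SNPSFILE — two whitespace-separated lines per SNP; line 1 = copies of the
  counted allele per population, line 2 = copies of the other allele.
* ENVIRONFILE — one line per environmental variable, one column per
  population.
* MATRIXFILE — square whitespace-separated covariance matrix, one row per
  line.

The SNPSFILE carries no SNP identifiers or coordinates, so a sidecar TSV with
columns ``snp_id``, ``chrom``, ``pos`` (and optionally ``panel``) is the
canonical companion; without it, synthetic ids ``snp_0001...`` are generated
and SNPs are placed on "chr1" spaced 1 kb apart.  Parsing treats any run of
spaces/tabs as a separator and ignores blank lines.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AlleleCountMatrix,
    CovarianceMatrix,
    EnvironmentMatrix,
    GeneIntervals,
    ScanResult,
)

__all__ = [
    "FormatError",
    "read_snpsfile",
    "write_snpsfile",
    "read_environfile",
    "write_environfile",
    "read_matrixfile",
    "write_matrixfile",
    "read_bed",
    "write_bed",
    "read_results",
    "write_results",
    "read_sidecar",
    "write_sidecar",
]


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


def _numeric_lines(path) -> list[list[str]]:
    lines = []
    with open(path) as fh:
        for raw in fh:
            fields = raw.split()
            if fields:
                lines.append(fields)
    return lines


def _parse_int_table(lines: list[list[str]], path) -> np.ndarray:
    width = len(lines[0])
    out = np.empty((len(lines), width), dtype=np.int64)
    for i, fields in enumerate(lines):
        if len(fields) != width:
            raise FormatError(
                f"{path}: ragged rows (line {i + 1} has {len(fields)} fields, expected {width})"
            )
        for j, tok in enumerate(fields):
            try:
                val = int(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer field {tok!r} at line {i + 1}, column {j + 1}"
                ) from None
            if val < 0:
                raise FormatError(f"{path}: negative count at line {i + 1}, column {j + 1}")
            out[i, j] = val
    return out


def read_sidecar(path) -> pd.DataFrame:
    """Read the SNP sidecar TSV (snp_id, chrom, pos[, panel])."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: sidecar missing required column {col!r}")
    return df


def write_sidecar(counts: AlleleCountMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": counts.snp_ids,
            "chrom": counts.chrom.astype(str),
            "pos": counts.pos,
        }
    )
    if counts.panel is not None:
        df["panel"] = counts.panel.astype(str)
    df.to_csv(path, sep="\t", index=False)


def read_snpsfile(path, sidecar=None) -> AlleleCountMatrix:
    """Read a Bayenv SNPSFILE (two lines per SNP) into an AlleleCountMatrix.

    Line 1 of each pair holds counted-allele copies per population, line 2 the
    other-allele copies; totals are their elementwise sum.
    """
    lines = _numeric_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty SNPSFILE (no SNPs)")
    if len(lines) % 2 != 0:
        raise FormatError(f"{path}: odd number of lines ({len(lines)}); SNPSFILE needs two per SNP")
    table = _parse_int_table(lines, path)
    count1 = table[0::2]
    count2 = table[1::2]
    L = count1.shape[0]
    if sidecar is not None:
        meta = read_sidecar(sidecar) if not isinstance(sidecar, pd.DataFrame) else sidecar
        if len(meta) != L:
            raise FormatError(
                f"sidecar has {len(meta)} rows but SNPSFILE has {L} SNPs"
            )
        snp_ids = meta["snp_id"].astype(str).tolist()
        chrom = meta["chrom"].to_numpy(dtype=object)
        pos = meta["pos"].to_numpy(dtype=np.int64)
        panel = (
            meta["panel"].to_numpy(dtype=object) if "panel" in meta.columns else None
        )
    else:
        width = int(math.log10(max(L, 1))) + 1 if L else 1
        snp_ids = [f"snp_{i + 1:0{max(4, width)}d}" for i in range(L)]
        chrom = np.array(["chr1"] * L, dtype=object)
        pos = np.arange(L, dtype=np.int64) * 1000
        panel = None
    return AlleleCountMatrix(
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        count1=count1,
        ntotal=count1 + count2,
        panel=panel,
    )


def write_snpsfile(counts: AlleleCountMatrix, path) -> None:
    with open(path, "w") as fh:
        for l in range(counts.n_snps):
            c1 = counts.count1[l]
            c2 = counts.ntotal[l] - counts.count1[l]
            fh.write("\t".join(str(int(v)) for v in c1) + "\n")
            fh.write("\t".join(str(int(v)) for v in c2) + "\n")


def read_environfile(path, var_names: list[str] | None = None) -> EnvironmentMatrix:
    """Read a Bayenv ENVIRONFILE (one row per variable, one column per population)."""
    lines = _numeric_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty ENVIRONFILE")
    width = len(lines[0])
    values = np.empty((len(lines), width), dtype=float)
    for i, fields in enumerate(lines):
        if len(fields) != width:
            raise FormatError(
                f"{path}: ragged rows (line {i + 1} has {len(fields)} fields, expected {width})"
            )
        for j, tok in enumerate(fields):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {tok!r} at line {i + 1}, column {j + 1}"
                ) from None
    if var_names is None:
        var_names = [f"env_{i + 1}" for i in range(values.shape[0])]
    return EnvironmentMatrix(var_names=var_names, values=values, standardized=False)


def write_environfile(env: EnvironmentMatrix, path) -> None:
    with open(path, "w") as fh:
        for row in env.values:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrixfile(path) -> CovarianceMatrix:
    """Read a MATRIXFILE (square whitespace-separated matrix)."""
    lines = _numeric_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty MATRIXFILE")
    try:
        mat = np.array([[float(tok) for tok in row] for row in lines])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry in matrix ({exc})") from None
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: matrix must be square, got shape {mat.shape}")
    return CovarianceMatrix(omega=mat)


def write_matrixfile(cov: CovarianceMatrix, path) -> None:
    with open(path, "w") as fh:
        for row in cov.omega:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_bed(path) -> GeneIntervals:
    """Read BED3+ gene annotations (0-based half-open, preserved verbatim)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    any_names = False
    with open(path) as fh:
        for i, raw in enumerate(fh):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i + 1} has fewer than 3 BED fields")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer coordinates at line {i + 1}"
                ) from None
            if s >= e:
                raise FormatError(f"{path}: start >= end at line {i + 1} ({s} >= {e})")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
            if len(fields) >= 4:
                names.append(fields[3])
                any_names = True
            else:
                names.append("")
    return GeneIntervals(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        name=np.array(names, dtype=object) if any_names else None,
    )


def write_bed(genes: GeneIntervals, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(genes)):
            fields = [str(genes.chrom[i]), str(genes.start[i]), str(genes.end[i])]
            if genes.name is not None:
                fields.append(str(genes.name[i]))
            fh.write("\t".join(fields) + "\n")


def write_results(scan: ScanResult, path) -> None:
    """Write a scan result as a TSV: snp_id, chrom, pos, per-variable log10 BF and p.

    Empirical-p columns are left empty when p values have not been computed.
    Non-finite Bayes factors are an error.
    """
    if not np.all(np.isfinite(scan.log10_bf)):
        raise FormatError("cannot write non-finite log10 Bayes factors")
    L = scan.n_snps
    data: dict[str, object] = {
        "snp_id": scan.snp_ids,
        "chrom": scan.chrom.astype(str) if scan.chrom is not None else ["chr1"] * L,
        "pos": scan.pos if scan.pos is not None else np.zeros(L, dtype=np.int64),
    }
    df = pd.DataFrame(data)
    for v, name in enumerate(scan.var_names):
        df[f"{name}.log10bf"] = [f"{x:.17g}" for x in scan.log10_bf[:, v]]
        if scan.empirical_p is not None:
            df[f"{name}.p"] = [f"{x:.17g}" for x in scan.empirical_p[:, v]]
        else:
            df[f"{name}.p"] = ""
    with open(path, "w") as fh:
        if scan.seed is not None or scan.iterations is not None:
            fh.write(f"# seed={scan.seed} iterations={scan.iterations}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> ScanResult:
    """Read a results TSV written by :func:`write_results`."""
    seed = iterations = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                if k == "seed" and v != "None":
                    seed = int(v)
                if k == "iterations" and v != "None":
                    iterations = int(v)
            df = pd.read_csv(fh, sep="\t", dtype={"snp_id": str, "chrom": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing header column {col!r}")
    bf_cols = [c for c in df.columns if c.endswith(".log10bf")]
    if not bf_cols:
        raise FormatError(f"{path}: no log10bf columns found")
    var_names = [c[: -len(".log10bf")] for c in bf_cols]
    log10_bf = np.column_stack([df[c].to_numpy(dtype=float) for c in bf_cols])
    p_cols = [f"{v}.p" for v in var_names]
    for c in p_cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing header column {c!r}")
    if df[p_cols].isna().all().all():
        empirical_p = None
    else:
        empirical_p = np.column_stack([df[c].to_numpy(dtype=float) for c in p_cols])
    return ScanResult(
        snp_ids=df["snp_id"].tolist(),
        var_names=var_names,
        log10_bf=log10_bf,
        empirical_p=empirical_p,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        seed=seed,
        iterations=iterations,
    )
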