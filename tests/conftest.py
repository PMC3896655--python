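import numpy as np
import pytest

import clinescan as cs


@pytest.fixture(scope="session")
def small_dataset():
    """A small null dataset shared by read-only tests: L=200, P=6, n=40."""
    env = cs.make_environment(6, seed=3)
    omega = cs.make_covariance(6, seed=2)
    counts, genes, truth = cs.simulate_dataset(
        P=6, L=200, n_chrom=40, omega=omega, env=env, seed=11,
        genome_length=20_000_000, n_genes=100, gene_length=20_000,
    )
    return counts, env, omega, genes, truth


@pytest.fixture(scope="session")
def small_scan(small_dataset):
    """A scanned + p-valued run on the small dataset (fixed omega, short chain)."""
    counts, env, omega, genes, truth = small_dataset
    scan = cs.run_scan(counts, env, omega=omega, iterations=1000, seed=5, thin=25)
    bins = cs.assign_bins(cs.global_maf(counts), n_bins=4)
    return cs.empirical_pvalues(scan, bins)
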