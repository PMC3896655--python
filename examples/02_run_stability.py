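"""How replicable is one MCMC scan?  Compare independently seeded runs.

Three scans with different seeds on identical data disagree noticeably;
longer chains and averaging log Bayes factors across runs both tighten the
agreement.

Run:  python examples/02_run_stability.py
"""

import numpy as np

import clinescan as cs

env = cs.make_environment(P=8, seed=3)
omega = cs.make_covariance(P=8, seed=2)
counts, _, _ = cs.simulate_dataset(
    P=8, L=600, n_chrom=50, omega=omega, env=env,
    effects={"gradient": (30, 0.4)}, seed=9,
)
cov, _ = cs.estimate_null_covariance(counts, iterations=6000, output_interval=750, seed=5)
bins = cs.assign_bins(cs.global_maf(counts), n_bins=8)


def scans(iterations, seeds):
    out = []
    for s in seeds:
        r = cs.run_scan(counts, env, omega=cov, iterations=iterations, seed=s, thin=25)
        out.append(cs.empirical_pvalues(r, bins))
    return out


short = scans(1500, [101, 102, 103])
long = scans(7500, [201, 202, 203])

c_short = cs.average_pairwise_correlations(short, "log_bf").mean()
c_long = cs.average_pairwise_correlations(long, "log_bf").mean()
print(f"mean pairwise log-BF correlation, 1x iterations: {c_short:.3f}")
print(f"mean pairwise log-BF correlation, 5x iterations: {c_long:.3f}")

# overlap of the empirical 0.05 tails between two short runs
ov = cs.tail_overlap(short[0].empirical_p[:, 0], short[1].empirical_p[:, 0], 0.05, 0.05)
print(f"0.05-tail overlap between two short runs: {ov:.2f}")

# averaging three runs before ranking stabilises the result
avg_a = cs.average_runs(short)
avg_b = cs.average_runs(long)
r_single = cs.log_bf_correlation(short[0], long[0], 0)
r_avg = cs.log_bf_correlation(avg_a, avg_b, 0)
print(f"single-run vs single-run correlation:   {r_single:.3f}")
print(f"3-run average vs 3-run average:         {r_avg:.3f}")

# The correlations are well below 1: a single run's SNP ranking is partly an
# artifact of its seed.  Longer chains and run averaging both push agreement up,
# which is why multi-run averaging is the recommended protocol.
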