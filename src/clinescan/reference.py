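"""Brute-force Monte Carlo reference for Bayes factors on tiny problems.

This estimator shares no code with the MCMC sampler: it integrates the null
and alternative marginal likelihoods by self-normalised importance sampling
from the *prior* — ``alpha ~ Uniform(0, 1)`` and ``theta | alpha ~
N(alpha 1, alpha(1-alpha) Omega)`` — weighting each draw by its binomial
likelihood, with Gauss-Legendre quadrature over ``beta``.  It is exact in the
limit of many draws but scales poorly, so it is meant for validating the
importance-sampling scan on a handful of SNPs with a few populations, not for
production scans.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .types import AlleleCountMatrix, BetaPrior, CovarianceMatrix

__all__ = ["bruteforce_log10_bf"]


def _beta_quadrature(prior: BetaPrior, n_points: int):
    """Nodes and log-weights integrating the beta prior to total weight 1."""
    if prior.family == "point-mass":
        return np.zeros(1), np.zeros(1)
    x, w = np.polynomial.legendre.leggauss(n_points)
    if prior.family == "uniform":
        nodes = prior.scale * x
        logw = np.log(w) - np.log(2.0)  # density 1/(2*scale) times jacobian scale
    else:  # normal: integrate over +-8 sd
        half = 8.0 * prior.scale
        nodes = half * x
        logw = np.log(w * half) + norm.logpdf(nodes, scale=prior.scale)
        logw -= logsumexp(logw)  # renormalise truncation (negligible at 8 sd)
    return nodes, logw


def bruteforce_log10_bf(
    counts: AlleleCountMatrix,
    Y_row: np.ndarray,
    omega: CovarianceMatrix,
    prior: BetaPrior = BetaPrior(),
    n_draws: int = 1_000_000,
    n_beta_points: int = 1_000,
    seed: int = 0,
    chunk: int = 10_000,
) -> np.ndarray:
    """log10 Bayes factors for all SNPs in ``counts`` against one variable.

    Draws ``(alpha, theta)`` independently from the prior once and reuses them
    for every SNP (only the binomial weights differ), so the cost is dominated
    by the ``n_draws x n_beta_points`` ratio table.
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y_row, dtype=float)
    om = omega.omega
    P = om.shape[0]
    chol = np.linalg.cholesky(om)
    oinv = np.linalg.inv(om)
    yoy = float(Y @ oinv @ Y)
    nodes, logw = _beta_quadrature(prior, n_beta_points)

    count1 = counts.count1
    ntotal = counts.ntotal
    L = count1.shape[0]

    # accumulate log-sum-exp pieces per SNP across chunks
    num_max = np.full(L, -np.inf)
    num_sum = np.zeros(L)
    den_max = np.full(L, -np.inf)
    den_sum = np.zeros(L)

    eps = 1e-4
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        done += m
        alpha = rng.uniform(0.0, 1.0, size=m)
        s = alpha * (1.0 - alpha)
        z = rng.standard_normal((m, P))
        theta = alpha[:, None] + np.sqrt(s)[:, None] * (z @ chol.T)
        p = np.clip(theta, eps, 1.0 - eps)
        # binomial log-weights per draw per SNP (coefficient cancels in the BF)
        logp = np.log(p)
        log1mp = np.log1p(-p)
        logw_bin = count1 @ logp.T + (ntotal - count1) @ log1mp.T  # L x m
        # prior-ratio term: r' Oinv (beta Y) etc., per draw
        r = theta - alpha[:, None]
        a = (r @ (oinv @ Y)) / s  # m
        c = yoy / s  # m
        zmat = nodes[None, :] * a[:, None] - 0.5 * (nodes**2)[None, :] * c[:, None]
        log_ratio = logsumexp(zmat + logw[None, :], axis=1)  # m, integrates beta prior

        for tgt_max, tgt_sum, extra in (
            (den_max, den_sum, None),
            (num_max, num_sum, log_ratio),
        ):
            vals = logw_bin if extra is None else logw_bin + extra[None, :]
            cmax = vals.max(axis=1)
            new_max = np.maximum(tgt_max, cmax)
            scale_old = np.exp(tgt_max - new_max, where=np.isfinite(tgt_max), out=np.zeros(L))
            tgt_sum *= scale_old
            tgt_sum += np.exp(vals - new_max[:, None]).sum(axis=1)
            tgt_max[:] = new_max

    log_bf = (num_max + np.log(num_sum)) - (den_max + np.log(den_sum))
    return log_bf / np.log(10.0)
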