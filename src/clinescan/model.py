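"""Null covariance estimation and Bayes-factor scans.

The model: for SNP ``l`` the vector of transformed population allele
frequencies ``theta_l`` (unconstrained reals) is multivariate normal around
the ancestral frequency ``alpha_l``::

    theta_l | Omega, alpha_l, beta ~ N(alpha_l * 1 + beta * Y,
                                       alpha_l (1 - alpha_l) Omega)

with ``beta = 0`` under the null.  Observed allele counts are binomial with
success probability ``clamp(theta, eps, 1 - eps)`` (the latent frequencies
are not constrained to [0, 1]; only the clamp enters the observation model).
Priors: ``alpha ~ Uniform(0, 1)``; ``Omega ~ Inverse-Wishart(nu0 = P, I)``
with a conjugate Gibbs update; ``theta`` and ``alpha`` move by Gaussian
random-walk Metropolis with step sizes adapted to a 20-40% acceptance rate
during burn-in and frozen afterwards.

Bayes factors are computed by importance sampling over retained null-posterior
draws: the binomial factors cancel in the ratio of alternative to null
densities, so

    BF = E_draws,beta [ N(theta; alpha 1 + beta Y, s Omega)
                        / N(theta; alpha 1, s Omega) ],   s = alpha (1 - alpha)

averaged over retained ``(theta, alpha, Omega)`` draws and draws of ``beta``
from its prior.  A single null MCMC therefore prices every environmental
variable at once.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, invwishart, multivariate_normal

from .types import (
    AlleleCountMatrix,
    BetaPrior,
    CovarianceMatrix,
    EnvironmentMatrix,
    NullPosteriorDraws,
    ScanResult,
)

__all__ = [
    "CLAMP_EPS",
    "standardize_environment",
    "loglik_snp",
    "sample_null_posterior",
    "estimate_null_covariance",
    "bayes_factor",
    "run_scan",
]

CLAMP_EPS = 1e-4

# default importance-sampling draw counts
DEFAULT_N_BETA_DRAWS = 200
DEFAULT_THIN = 100
DEFAULT_BURNIN_FRAC = 0.5


def standardize_environment(env: EnvironmentMatrix) -> EnvironmentMatrix:
    """Center each variable to mean 0 and scale to population (divide-by-P) sd 1.

    Standardization makes the beta-prior scale comparable across variables.
    Idempotent; a constant variable is an error.
    """
    values = np.asarray(env.values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    for i, name in enumerate(env.var_names):
        if sd[i, 0] == 0 or len(np.unique(values[i])) < 2:
            raise ValueError(f"constant variable {name!r} cannot be standardized")
    return EnvironmentMatrix(
        var_names=list(env.var_names),
        values=(values - mu) / sd,
        standardized=True,
        pop_names=env.pop_names,
    )


def _clamp(theta: np.ndarray) -> np.ndarray:
    return np.clip(theta, CLAMP_EPS, 1.0 - CLAMP_EPS)


def _binom_loglik(count1, ntotal, theta):
    """Binomial log likelihood without the theta-free coefficient, summed over pops."""
    p = _clamp(theta)
    return np.sum(count1 * np.log(p) + (ntotal - count1) * np.log1p(-p), axis=-1)


def loglik_snp(count1_row, ntotal_row, theta, alpha, omega, beta=0.0, Y_row=None):
    """Full log density of one SNP: MVN prior on theta times binomial likelihood.

    ``beta = 0`` (or ``Y_row`` of zeros) gives the null density.
    """
    count1_row = np.asarray(count1_row, dtype=np.int64)
    ntotal_row = np.asarray(ntotal_row, dtype=np.int64)
    theta = np.asarray(theta, dtype=float)
    om = omega.omega if isinstance(omega, CovarianceMatrix) else CovarianceMatrix(np.asarray(omega)).omega
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    P = om.shape[0]
    mean = np.full(P, alpha)
    if beta != 0.0:
        if Y_row is None:
            raise ValueError("beta != 0 requires an environmental row Y_row")
        mean = mean + beta * np.asarray(Y_row, dtype=float)
    s = alpha * (1.0 - alpha)
    mvn = multivariate_normal.logpdf(theta, mean=mean, cov=s * om)
    binll = binom.logpmf(count1_row, ntotal_row, _clamp(theta)).sum()
    return float(mvn + binll)


def _check_counts(counts: AlleleCountMatrix) -> None:
    pooled1 = counts.count1.sum(axis=1)
    pooledn = counts.ntotal.sum(axis=1)
    if np.any(pooledn == 0):
        raise ValueError("every SNP needs at least one sampled chromosome")
    fixed = (pooled1 == 0) | (pooled1 == pooledn)
    if np.all(fixed):
        raise ValueError("degenerate counts: all SNPs carry fixed alleles")


def _mcmc(
    count1: np.ndarray,
    ntotal: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
    omega: np.ndarray,
    sample_omega: bool,
    burnin: int,
    thin: int,
    output_interval: int | None = None,
    fix_alpha: np.ndarray | None = None,
):
    """Shared Metropolis-within-Gibbs loop over (theta, alpha[, Omega]).

    Returns (draws, output_matrices).  All proposals are vectorized across
    SNPs; theta moves as a joint P-vector per SNP.  With ``fix_alpha`` the
    ancestral frequencies are held at the given values instead of being
    sampled — the covariance posterior is explored *given* the ancestral
    frequencies, which is what identifies the shared (all-ones) component of
    Omega; with a flat prior on alpha that direction would be absorbed by the
    per-SNP ancestral frequencies.
    """
    L, P = count1.shape
    nu0 = P  # inverse-Wishart prior degrees of freedom, scale = identity

    phat = (count1 + 0.5) / (ntotal + 1.0)
    theta = phat.copy()
    if fix_alpha is not None:
        alpha = np.asarray(fix_alpha, dtype=float).copy()
    else:
        alpha = np.clip(phat.mean(axis=1), 0.02, 0.98)
    omega = np.array(omega, dtype=float)
    oinv = np.linalg.inv(omega)

    def quad(r):
        return np.einsum("lp,pq,lq->l", r, oinv, r)

    s = alpha * (1.0 - alpha)
    r = theta - alpha[:, None]
    q = quad(r)
    bll = _binom_loglik(count1, ntotal, theta)

    step_t = np.full(L, 0.1)
    step_a = np.full(L, 0.1)
    acc_t = np.zeros(L)
    acc_a = np.zeros(L)
    step_j = 0.02
    acc_j = 0.0
    window = 25

    def _logdet_and_trinv(m):
        c = np.linalg.cholesky(m)
        ld = 2.0 * np.log(np.diag(c)).sum()
        cinv = np.linalg.inv(c)
        return ld, cinv.T @ cinv  # logdet, inverse

    def _invwishart_logprior(ld, inv):
        # Inverse-Wishart(nu0, I): -(nu0+P+1)/2 log|O| - tr(O^-1)/2, up to const
        return -0.5 * (nu0 + P + 1) * ld - 0.5 * np.trace(inv)

    rec_omega: list[np.ndarray] = []
    rec_alpha: list[np.ndarray] = []
    rec_theta: list[np.ndarray] = []
    rec_iter: list[int] = []
    out_mats: list[np.ndarray] = []

    eye = np.eye(P)
    for it in range(1, iterations + 1):
        # --- theta update (joint P-vector random walk per SNP)
        prop = theta + step_t[:, None] * rng.standard_normal((L, P))
        rp = prop - alpha[:, None]
        qp = quad(rp)
        bllp = _binom_loglik(count1, ntotal, prop)
        logr = (bllp - bll) - (qp - q) / (2.0 * s)
        acc = np.log(rng.random(L)) < logr
        theta[acc] = prop[acc]
        q[acc] = qp[acc]
        bll[acc] = bllp[acc]
        acc_t += acc

        # --- alpha update (scalar random walk, uniform(0,1) prior)
        if fix_alpha is None:
            aprop = alpha + step_a * rng.standard_normal(L)
            valid = (aprop > 0.0) & (aprop < 1.0)
            aprop_safe = np.where(valid, aprop, 0.5)
            sp = aprop_safe * (1.0 - aprop_safe)
            rp = theta - aprop_safe[:, None]
            qp = quad(rp)
            logr = -0.5 * P * (np.log(sp) - np.log(s)) - qp / (2.0 * sp) + q / (2.0 * s)
            acc = valid & (np.log(rng.random(L)) < logr)
            alpha[acc] = aprop_safe[acc]
            s[acc] = sp[acc]
            q[acc] = qp[acc]
            acc_a += acc

        # --- Omega Gibbs update (conjugate inverse-Wishart)
        if sample_omega:
            r = theta - alpha[:, None]
            scale = eye + np.einsum("lp,lq->pq", r / s[:, None], r)
            scale = 0.5 * (scale + scale.T)
            omega = invwishart.rvs(df=nu0 + L, scale=scale, random_state=rng)
            omega = np.atleast_2d(omega)
            oinv = np.linalg.inv(omega)
            q = quad(r)

            # --- extra Metropolis move along the shared-drift direction.
            # The all-ones component of Omega is confounded with the per-SNP
            # ancestral frequencies, so the Gibbs update alone mixes it very
            # slowly; a direct Omega + eps*J proposal with theta/alpha held
            # fixed walks along that ridge.
            eps = step_j * rng.standard_normal()
            prop_om = omega + eps * np.ones((P, P))
            try:
                ld_p, inv_p = _logdet_and_trinv(prop_om)
                ld_c, inv_c = _logdet_and_trinv(omega)
                qp = np.einsum("lp,pq,lq->l", r, inv_p, r)
                logr = (
                    -0.5 * L * (ld_p - ld_c)
                    - 0.5 * np.sum((qp - q) / s)
                    + _invwishart_logprior(ld_p, inv_p)
                    - _invwishart_logprior(ld_c, inv_c)
                )
                if np.log(rng.random()) < logr:
                    omega = prop_om
                    oinv = inv_p
                    q = qp
                    acc_j += 1.0
            except np.linalg.LinAlgError:
                pass  # proposal not positive definite: reject

        # --- step-size adaptation, burn-in only
        if it <= burnin and it % window == 0:
            step_t *= np.exp(0.6 * (acc_t / window - 0.3))
            step_a *= np.exp(0.6 * (acc_a / window - 0.3))
            np.clip(step_t, 1e-3, 2.0, out=step_t)
            np.clip(step_a, 1e-3, 2.0, out=step_a)
            acc_t[:] = 0.0
            acc_a[:] = 0.0
            if sample_omega:
                step_j *= float(np.exp(0.6 * (acc_j / window - 0.3)))
                step_j = float(np.clip(step_j, 1e-5, 0.5))
                acc_j = 0.0

        if output_interval is not None and it % output_interval == 0:
            out_mats.append(omega.copy())
        if it > burnin and (it - burnin) % thin == 0:
            rec_omega.append(omega.copy())
            rec_alpha.append(alpha.copy())
            rec_theta.append(theta.copy())
            rec_iter.append(it)

    draws = NullPosteriorDraws(
        omega=np.array(rec_omega),
        alpha=np.array(rec_alpha),
        theta=np.array(rec_theta),
        iteration=np.array(rec_iter),
    )
    return draws, out_mats


def sample_null_posterior(
    counts: AlleleCountMatrix,
    omega: CovarianceMatrix,
    iterations: int,
    seed: int,
    burnin_frac: float = DEFAULT_BURNIN_FRAC,
    thin: int = DEFAULT_THIN,
) -> NullPosteriorDraws:
    """Sample (theta, alpha) from the per-SNP null posterior with Omega fixed.

    This is the per-run MCMC behind each Bayes-factor scan: the covariance is
    estimated once and shared across runs, while each run redraws the
    importance samples under its own seed.
    """
    _check_counts(counts)
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    burnin = int(iterations * burnin_frac)
    if (iterations - burnin) < thin:
        raise ValueError(
            f"iterations={iterations} leaves no retained draws at thin={thin}; increase iterations"
        )
    rng = np.random.default_rng(seed)
    draws, _ = _mcmc(
        counts.count1,
        counts.ntotal,
        iterations,
        rng,
        omega=omega.omega,
        sample_omega=False,
        burnin=burnin,
        thin=thin,
    )
    return draws


def estimate_null_covariance(
    counts: AlleleCountMatrix,
    iterations: int = 100_000,
    output_interval: int = 5_000,
    seed: int = 0,
    burnin_frac: float = DEFAULT_BURNIN_FRAC,
    thin: int = DEFAULT_THIN,
) -> tuple[CovarianceMatrix, NullPosteriorDraws]:
    """Estimate the null across-population covariance Omega by MCMC.

    The chain outputs its current Omega every ``output_interval`` iterations
    and the estimate is the elementwise average of the last three output
    matrices.  Retained posterior draws are returned alongside for reuse.

    A structural caveat shared by this whole model family: the genome-wide
    *shared* component of Omega (its all-ones direction) is only weakly
    identified, because a deviation common to every population at a SNP can
    be re-attributed to that SNP's ancestral frequency.  Contrasts between
    populations are recovered accurately; the absolute shared level is partly
    shrunk toward the inverse-Wishart prior.  Environmental variables are
    standardized to mean zero across populations, so Bayes factors are nearly
    insensitive to this component.
    """
    if counts.n_snps < 2:
        raise ValueError("need at least 2 SNPs to estimate a covariance matrix")
    if iterations < 3 * output_interval:
        raise ValueError(
            f"iterations ({iterations}) must be >= 3 * output_interval ({output_interval})"
        )
    _check_counts(counts)
    P = counts.n_pops
    rng = np.random.default_rng(seed)
    burnin = int(iterations * burnin_frac)
    draws, out_mats = _mcmc(
        counts.count1,
        counts.ntotal,
        iterations,
        rng,
        omega=0.1 * np.eye(P),
        sample_omega=True,
        burnin=burnin,
        thin=thin,
        output_interval=output_interval,
    )
    est = np.mean(out_mats[-3:], axis=0)
    est = 0.5 * (est + est.T)
    return CovarianceMatrix(omega=est), draws


def _log10_bf_table(
    draws: NullPosteriorDraws,
    Y: np.ndarray,
    prior: BetaPrior,
    n_beta_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """log10 Bayes factors (L x V) by importance sampling over null draws."""
    T, L, P = draws.theta.shape
    V = Y.shape[0]
    if T == 0:
        raise ValueError("empty posterior draws")
    if prior.family == "point-mass":
        return np.zeros((L, V))
    beta = prior.draw(n_beta_draws, rng)  # B
    beta2 = beta * beta
    fixed_omega = bool(np.all(draws.omega == draws.omega[0]))
    oinv = np.linalg.inv(draws.omega[0]) if fixed_omega else None

    per_t = np.empty((T, L, V))
    logB = np.log(n_beta_draws)
    for t in range(T):
        if not fixed_omega:
            oinv = np.linalg.inv(draws.omega[t])
        alpha = draws.alpha[t]
        s = alpha * (1.0 - alpha)  # L
        r = draws.theta[t] - alpha[:, None]  # L x P
        a = (r @ (oinv @ Y.T)) / s[:, None]  # L x V: r' Oinv Y / s
        c = np.einsum("vp,pq,vq->v", Y, oinv, Y)[None, :] / s[:, None]  # L x V
        # log importance ratio per beta draw: beta * a - beta^2 * c / 2
        z = beta[None, None, :] * a[..., None] - 0.5 * beta2[None, None, :] * c[..., None]
        if not np.all(np.isfinite(z)):
            bad = np.argwhere(~np.isfinite(z))
            raise ValueError(f"non-finite importance ratio at draw {t}, index {bad[0]}")
        per_t[t] = logsumexp(z, axis=2) - logB
    log_bf = logsumexp(per_t, axis=0) - np.log(T)
    return log_bf / np.log(10.0)


def bayes_factor(
    snp_index: int,
    Y_row: np.ndarray,
    draws: NullPosteriorDraws,
    prior: BetaPrior = BetaPrior(),
    n_beta_draws: int = DEFAULT_N_BETA_DRAWS,
    seed: int = 0,
) -> float:
    """Importance-sampling Bayes factor for a single SNP and variable."""
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    sub = NullPosteriorDraws(
        omega=draws.omega,
        alpha=draws.alpha[:, [snp_index]],
        theta=draws.theta[:, [snp_index], :],
        iteration=draws.iteration,
    )
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y_row, dtype=float)[None, :]
    log10_bf = _log10_bf_table(sub, Y, prior, n_beta_draws, rng)
    return float(10.0 ** log10_bf[0, 0])


def run_scan(
    counts: AlleleCountMatrix,
    env: EnvironmentMatrix,
    draws: NullPosteriorDraws | None = None,
    omega: CovarianceMatrix | None = None,
    iterations: int = 100_000,
    seed: int = 0,
    prior: BetaPrior = BetaPrior(),
    n_beta_draws: int = DEFAULT_N_BETA_DRAWS,
    burnin_frac: float = DEFAULT_BURNIN_FRAC,
    thin: int = DEFAULT_THIN,
) -> ScanResult:
    """Scan every SNP against every environmental variable.

    Either precomputed null-posterior ``draws`` or a fixed ``omega`` (from
    :func:`estimate_null_covariance`) must be supplied; with ``omega`` a fresh
    per-SNP null MCMC is run under ``seed``, which is what makes independent
    seeded scans genuinely independent runs.
    """
    if not env.standardized:
        raise ValueError("environment must be standardized before scanning")
    if env.n_pops != counts.n_pops:
        raise ValueError(
            f"environment has {env.n_pops} populations but counts have {counts.n_pops}"
        )
    rng = np.random.default_rng(seed)
    if draws is None:
        if omega is None:
            raise ValueError("run_scan needs either posterior draws or a covariance matrix")
        draws = sample_null_posterior(
            counts, omega, iterations=iterations, seed=seed, burnin_frac=burnin_frac, thin=thin
        )
        # beta draws continue from an offset stream so they differ from the MCMC stream
        rng = np.random.default_rng((seed, 1))
    else:
        if draws.n_snps != counts.n_snps:
            raise ValueError("draws do not match the SNP count")
    log10_bf = _log10_bf_table(draws, env.values, prior, n_beta_draws, rng)
    return ScanResult(
        snp_ids=list(counts.snp_ids),
        var_names=list(env.var_names),
        log10_bf=log10_bf,
        empirical_p=None,
        chrom=counts.chrom,
        pos=counts.pos,
        seed=seed,
        iterations=iterations,
    )
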