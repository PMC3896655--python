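# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `clinescan`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and estimation

### Null model

For SNP *l* with ancestral (global) allele frequency α_l, the vector of
transformed population allele frequencies θ_l ∈ ℝ^P is

θ_l | Ω, α_l ~ N( α_l·1 , α_l(1−α_l)·Ω ),

and observed counts are Binomial(n_lp, clamp(θ_lp, ε, 1−ε)) with ε = 10⁻⁴.
The transformed frequencies are deliberately unconstrained; truncation at the
binomial is the simplest mapping consistent with that choice, and the clamp
constant only matters for SNPs whose latent frequency wanders far outside
[0, 1] (rare at the simulated drift scales).

Priors: α ~ Uniform(0, 1); Ω ~ Inverse-Wishart(ν₀ = P, scale = I). The Gibbs
update for Ω is conjugate: Ω | θ, α ~ IW(P + L, I + Σ_l r_l r_lᵀ / s_l) with
r_l = θ_l − α_l·1 and s_l = α_l(1−α_l). θ (as a joint P-vector per SNP) and
α move by Gaussian random-walk Metropolis, with per-SNP step sizes adapted
toward ~30% acceptance in windows of 25 iterations during burn-in and frozen
afterwards (adaptation during burn-in only, so the retained chain satisfies
detailed balance). Burn-in is the first 50% of iterations; retained draws
are thinned (default every 100 iterations).

One extra move targets a known slow direction: Ω → Ω + ε·J (J the all-ones
matrix), a scalar Metropolis proposal with θ and α held fixed. The shared
component of Ω is confounded with the per-SNP ancestral frequencies (see
*Identifiability*, below), which makes it the slowest-mixing direction of the
Gibbs sampler; the ridge move mixes it honestly.

The covariance *estimate* follows the output-averaging protocol: the chain
writes its current Ω every `output_interval` iterations and the estimate is
the elementwise average of the last three outputs (defaults 100,000
iterations, output every 5,000; the desk-scale studies below use shorter
chains with the same structure).

### Identifiability of Ω

A deviation shared by all populations at a SNP cannot be distinguished from a
shift of that SNP's ancestral frequency: with α free under a flat prior, the
all-ones direction of the frequency vector integrates out of the likelihood,
and the only information about the genome-wide shared level of Ω comes
weakly through the α(1−α) variance coupling. Consequences, verified by
simulation in the test suite and acceptance script:

* population *contrasts* (differences between populations) are recovered
  accurately — with a diagonal truth the estimated structure is correct to a
  few percent;
* the absolute shared level (uniform positive off-diagonal) is partly shrunk
  toward the inverse-Wishart prior — converged chains recover roughly
  0.6–0.7 of a star-tree's shared branch at L = 2000, P = 8, n = 50,
  regardless of initialization;
* fixing α at the pooled per-SNP sample frequency does not help: the pooled
  estimate *is* the SNP's mean deviation, so conditioning on it removes the
  shared signal entirely.

This is a property of the model family, not of the sampler. It is benign for
association scans: environmental variables are standardized to mean zero
across populations, so Y'Ω⁻¹Y barely loads on the all-ones direction and
Bayes factors are essentially unaffected.

### Bayes factors by importance sampling

For variable Y (standardized) the Bayes factor at SNP *l* is estimated as

BF_l = mean over retained null draws (θ, α, Ω) and prior draws β of
  N(θ; α·1 + β·Y, s·Ω) / N(θ; α·1, s·Ω),

the binomial factors cancelling. The covariance is estimated once and shared
across runs; each scan run redraws (θ, α) from the per-SNP null posterior
under its own seed (Ω fixed at the estimate), which is what makes
independently seeded scans genuine replicate runs. Defaults: thinning 100
(scans in the studies below use 25–50 on shorter chains), 200 Monte Carlo β
draws. BFs are stored and reported as log₁₀.

A point-mass-at-zero β prior collapses the alternative onto the null and
yields BF = 1 exactly, as does an all-zero environmental vector — both are
regression tests.

### The β prior scale

β acts on the transformed-frequency scale, where one population's drift
standard deviation is √(α(1−α)·Ω_pp) ≈ 0.1–0.15 at the default drift scale.
The default prior is normal with σ = 0.05 — a unit-information-style choice
carrying roughly the information of a single population's drift. The scale
matters because the null-SNP log Bayes factor has expectation
≈ −½log(1+w) + w/(2(1+w)) nats with w = σ²·Y'Ω⁻¹Y/(α(1−α)): a wide prior
(σ = 1) makes w of order 10²–10³ for realistic Ω and P, pushing every null
SNP's log₁₀ BF near −1 and turning the scan into a pure Occam penalty. With
σ = 0.05, w = O(1), null SNPs sit near log₁₀ BF = 0, and ranking power for
strong effects is unchanged (the data-driven term dominates the ranking).
Normal with any scale, uniform(−σ, σ), and point-mass priors are available.

### Empirical p-values

Global minor-allele frequency = folded pooled frequency Σcount/Σtotal
(folding makes binning invariant to which allele was counted). Default
binning: 12 equal-count bins via rank-based quantile cut; tied frequencies
share the lowest rank and therefore never split across bins. Within a bin of
size B, p = (number of SNPs with BF ≥ own)/B, ties sharing the maximal
(conservative) rank, so p ∈ [1/B, 1] and the within-bin p multiset is exactly
{k/B} when BFs are distinct.

### Run comparison

Pearson correlations of log₁₀ BF and empirical p are computed over all SNPs
per variable and averaged over unordered run pairs. Tail overlap uses the
smaller tail as denominator (|A∩B| / min(|A|,|B|)): the convention makes the
proportion reach 1 under perfect nesting and is symmetric; an empty tail
gives 0. Ranked-bin overlap sorts SNPs by p (stable, input-order
tie-break) and intersects rank windows of 1,000 (a trailing partial window
uses its own size). Run averaging takes the mean of log₁₀ BF per SNP — the
geometric mean of the Bayes factors — and p-values are recomputed on the
averaged table. Paired Wilcoxon tests on per-variable mean correlations use
the exact two-sided signed-rank distribution.

### Genic enrichment

Genic = within 10 kb of an annotated gene; non-genic = more than 50 kb from
every gene; the 10–50 kb band is ambiguous and excluded from tail counts,
genome-wide counts, and bootstrap pools alike. Enrichment =
(n_g/n_ng)/(N_g/N_ng). The block bootstrap partitions each chromosome into
contiguous 500-kb windows anchored at coordinate 0 (window = ⌊pos/500000⌋),
draws W non-empty windows with replacement (W = number of non-empty windows)
and recomputes enrichment from pooled per-window counts; 10,000 replicates by
default. Degenerate replicates: a non-empty tail with no non-genic SNPs
counts as enriched (the limit is +∞ > 1); an empty-tail replicate counts as
not enriched — both conventions keep the denominator fixed and are
conservative. Star map on the enriched fraction f: f < 0.95 → 0;
0.95 ≤ f < 0.975 → 1; 0.975 ≤ f < 0.99 → 2; f ≥ 0.99 → 3 (the upper
boundary is taken inclusive to make the map total).

## Synthetic data

The generator runs the model forwards: α ~ U(0.05, 0.95), θ ~ N(α·1 +
Σ_v β*_v Y_v, α(1−α)Ω*), counts ~ Binomial(n, clamp(θ)) — the same clamp the
likelihood uses, so generator and model agree about the latent scale. Causal
SNPs are disjoint across variables with alternating effect signs. Genes are
non-overlapping fixed-length intervals placed uniformly; causal SNPs can be
placed within 10 kb of a gene with odds multiplied by `genic_bias`.

Default structure, chosen once as a realistic desk-scale emulation of
worldwide SNP-array data: star-tree Ω* with shared branch 0.1 and private
branches ~0.1 (total diagonal ≈ 0.2, F_ST-scale differentiation); two
environmental variables — a linear "latitude-like" gradient and a random
standardized noise control; n = 40–50 chromosomes per population.

What the generator does *not* emulate — and hence what passing tests do not
demonstrate about real data: linkage disequilibrium between SNPs (SNPs are
independent given Ω, so the block bootstrap is exercised structurally, not
against realistic local correlation), SNP-array ascertainment bias, and
non-linear or interacting environmental responses.

## Desk-scale study sizes

The stochastic checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use sizes chosen so each stage completes in seconds
to a couple of minutes on one core while leaving the measured statistics
well away from their decision boundaries:

| study | size |
|---|---|
| BF cross-check vs brute force | 10 SNPs, P = 2, 10⁶ reference draws, 10³ β quadrature points |
| null calibration | L = 1000, P = 8, n = 50; covariance 6,000 iterations, scan 4,000 |
| covariance recovery | L = 2000, P = 8, n = 50; 20,000 iterations, output every 2,500 |
| end-to-end power | L = 2000, P = 16, 20 causal SNPs at β* = 0.6 |
| stability direction | L = 600, 3 runs at 1,500 vs 3 at 7,500 iterations; averaging over 20 replicates of 6 runs |
| enrichment calibration | 50 permutation trials at 500 bootstrap replicates; planted signal with genic_bias = 50 |
| pipeline determinism | L = 200, 2 runs, byte-compared bundles |

The brute-force Bayes-factor reference (`clinescan.reference`) integrates the
marginal likelihoods by self-normalized importance sampling from the *prior*
(uniform α, MVN θ | α) with binomial weights and Gauss–Legendre quadrature
over β. It shares no code with the MCMC path, converges like 1/√(draws), and
at 10⁶ draws with P = 2, n = 30 its effective sample size is ~10⁵ — accurate
enough to certify the production importance sampler to a few percent.

## Known limitations

* Entrywise recovery of Ω's absolute shared level is limited by the
  identifiability issue above; comparisons of Ω across datasets should be
  made on contrasts.
* Empirical p-values are granular (multiples of 1/B); very small tails in
  small simulations are dominated by that granularity.
* The per-SNP MCMC treats SNPs as independent given Ω; real linked SNPs
  share drift noise, which the run-comparison statistics would partly absorb
  as "signal".
* The pipeline estimates one covariance per ascertainment panel when panel
  labels are present, but no ascertainment *simulation* is provided.
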