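# Methods

## The model

Repeated assessment scores `y_pt` (person `p`, timepoint `t = 0..T−1`,
default T = 8) follow a linear latent growth model

    y_pt ~ F(η_pt, σ),   η_pt = β0_p + β1_p X_t,   (β0_p, β1_p) ~ MVN(μ_β, Σ_β),

where the response family F is Gaussian, location–scale Student-t
(robustness through heavy tails), or asymmetric Laplace with quantile
p = 0.5 (Bayesian median regression; check function ρ_p(u) = u(p − 1{u<0}),
density p(1−p)/σ · exp(−ρ_p((y−η)/σ))). Throughout, the second family
parameter is a **scale**, not a variance: the reference analyses report
σ = 21.90 / 14.55 / 7.67 for the three families on the same data, and these
magnitudes are only mutually consistent as scales. Timepoints are coded
0..T−1 so that the intercept is the initial level and μβ1 the average
progress per assessment interval; 1-based input codings are rejected, not
silently shifted.

Priors (identical across families unless noted): `μβ0 ~ t(0.3, 2.5, 3)`
read as (location, scale, df); improper flat prior on μβ1 (implemented as a
zero log-contribution; posterior propriety rests on the likelihood);
half-t(0, 2.5, 3) on σβ0, σβ1 and σ; LKJ(1) on the 2×2 correlation matrix,
which is uniform in ρ; `ν ~ Γ(shape 2, rate 0.10)` truncated to ν > 1
(Student-t only). Assumptions worth stating: linear growth (no quadratic
term), no school/class clustering, complete data (the intended inputs are
factor scores, which exist for every cell), and residuals exchangeable
across persons and timepoints within family.

## Sampler

The posterior is sampled by a vectorized data-augmentation Gibbs sampler
(no gradient-based backend; the recorded `max_treedepth` / `adapt_delta`
settings apply only to such backends and are ignored here).

* **Student-t** as a Gaussian scale mixture: `w_pt ~ Γ(ν/2, ν/2)`,
  `y | w ~ N(η, σ²/w)`. The degrees of freedom move by random-walk
  Metropolis on `log ν` targeting the *marginal* t likelihood (mixing
  weights integrated out, then refreshed), which sidesteps the notoriously
  slow ν–w coupling; the step size adapts toward 44% acceptance during
  warmup only.
* **Asymmetric Laplace** via the exponential mean–variance mixture of
  Bayesian quantile regression: `y = η + θz + sqrt(τ²σz) u`,
  `z ~ Exp(mean σ)`, `θ = (1−2p)/(p(1−p))`, `τ² = 2/(p(1−p))`; `1/z` has an
  inverse-Gaussian full conditional (sampled by the
  Michael–Schucany–Haas transformation).
* **Person effects**: closed-form bivariate normal updates, vectorized as
  2×2 solves across persons.
* **Latent mean μ_β**: the Student-t prior on μβ0 is itself augmented as a
  Gamma scale mixture, keeping the update conjugate.
* **Latent covariance Σ_β**: independence Metropolis–Hastings with an
  inverse-Wishart proposal whose kernel equals the conditional likelihood
  (df N−3, scale the centered scatter of the effects); the half-t/LKJ prior
  enters only through the acceptance ratio (with the Jacobian
  4·s0²·s1² between the matrix and (s0, s1, ρ) parameterizations), so
  acceptance runs near 90%+.
* **Residual scale**: independence MH with an inverse-gamma proposal
  matched to the conditional likelihood (in σ² for Gaussian/t, in σ for the
  ALD, where the conditional is inverse-gamma with shape 3n/2 − 1); the
  half-t prior again only affects the near-unity acceptance ratio.
* **Interweaving (ASIS)**: after the centered updates, two non-centered
  moves re-express the effects as standardized deviations and update
  (a) the Cholesky factor of Σ_β and (b) μ_β directly against the
  observation weights. Profiling showed the centered sampler's μ↔β and
  Σ↔β couplings throttle effective sample sizes (slope-SD ESS ~60 per
  1000 draws; μ ESS ~50 under strong shrinkage); the interweaved sampler
  reaches ESS in the hundreds-to-thousands at the same cost (~2× per
  iteration, ~10× in ESS/second for the worst parameter).

Defaults mirror the reference chain settings: 4 chains, 4000 iterations for
the Gaussian family and 6000 for the robust families, half discarded as
warmup (the reference analyses report totals only; half warmup is this
package's reading). Initial values are per-person least squares, jittered
per chain; the residual-scale start is floored at 0.1·SD(y) because with
T = 2 the per-person line interpolates the data. A fit report flags any
parameter with rank-normalized split R-hat ≥ 1.01 or bulk/tail ESS ≤ 400.

`fit_model` accepts `fixed={...}` to freeze blocks (used by conjugate
validation tests) and `obs_mask` to drop cells from the likelihood (used by
exact leave-one-out refits). Chains are seeded by splitting one master seed
through `numpy.random.SeedSequence`; identical seeds give bit-identical
draws.

## Diagnostics

`split_rhat`, `ess_bulk` and `ess_tail` implement the rank-normalized
split-chain methodology (chains halved; average ranks for ties; Blom 3/8
offset in the normal-scores transform; R-hat is the max of the bulk and
folded variants; ESS uses chain-averaged FFT autocovariances with Geyer's
initial positive and monotone sequence estimators; tail ESS is the minimum
over the 5%/95% quantile indicators with R type-7 quantiles). The tests
require agreement with an independent reference implementation (arviz) to
1e-6 on fixed draws; observed agreement is ~1e-10.

## Model comparison

Pointwise log-likelihood is **conditional on the drawn person effects**
(the convention of the reference software): under the marginal convention
the person-specific fit differences that separate the families would
largely integrate out, and ELPD gaps of the reported magnitude only arise
conditionally. A marginal option exists for the Gaussian family (closed
form); for the robust families it would require numerical integration per
cell and is deliberately not implemented.

PSIS-LOO: importance ratios are inverse pointwise likelihoods; the largest
20% of ratios per observation (minimum 5) are replaced by expected order
statistics of a generalized Pareto distribution fitted to the exceedances
(quantile-profile posterior-mean estimator, weakly regularized toward
k = 0.5), weights are truncated at the raw maximum and self-normalized.
Pareto k is reported per observation with the usual 0.5/0.7/1.0 quality
bands. The ELPD standard error is sqrt(n · var(pointwise)); difference SEs
use the pointwise differences against the best model, whose own row is
exactly 0.00/0.00. Exact leave-one-observation-out (refit per held-out
cell, scored by the log posterior-mean conditional density) is provided as
the brute-force oracle; on 10-observation toys with the population scales
known, PSIS agrees with it to ~0.1–0.2 nats. With the full hierarchy free
on so few observations, importance ratios have k ≈ 1 and PSIS is invalid by
its own diagnostic — that regime is outside the method's contract.

Posterior predictive replication is conditional (each replicate keeps its
draw's person effects and redraws residuals); kernel-density overlays use
the Gaussian KDE with the Silverman normal-reference bandwidth. Person
summaries are EAP means and posterior SDs; *relative precision* divides a
person's posterior SD by the posterior-mean latent SD of the same
coordinate (smaller = more precise).

## Scoring chain

Response-time validity bounds are the per-subscale empirical 5% and 99.5%
quantiles (linear-interpolation quantile convention; the choice moves
bounds only in the third decimal). Validity is the closed interval
`lower ≤ rt ≤ upper`. CISRT ("correct item summed residual time") awards a
correct *and valid* response its residual time `upper − rt`; invalid (too
fast or too slow) or incorrect responses earn 0 — fast guessing is never
rewarded. Item scores are divided by the bound width, scaled by 10 (the
declared [0, 10] mapping; the source procedure states only the target
range) and averaged per person × timepoint × subscale. Mahalanobis
screening uses the sample mean/covariance and a chi-square(T) cutoff with
default α = 0.001 (the conventional value for this procedure; the reference
analysis does not state its α, and ~5% of a clean-normal sample is flagged
at α = 0.05 by construction).

Factor scores use the Bartlett estimator computed jointly over all
24 indicators × 8 factors so cross-time residual covariances are honored;
the measurement model (equal loadings and intercepts over time, word-level
loading fixed to 1, free word/text cross-time residual covariances) is
supplied, not estimated — CFA fitting is out of scope, and the
strong-invariance structure licenses a single parameter set. Factor
determinacy is the classical regression-score determinacy computed from the
full model-implied covariance (what CFA software reports): for parallel
indicators the Bartlett-score determinacy equals sqrt(α), which cannot
exceed .90 while α stays in the mid-.70s, so the > .90 requirement is only
meaningful for the regression-score index, where correlated factors across
timepoints borrow strength. Bollen's ω₁ is the variance ratio
`(1'λ)²φ / (1'Σ_block 1)` on a timepoint block (cross-time residual
covariances lie outside the block and do not enter the denominator).

## Synthetic data

Score-level generation follows the model exactly; the generator's defaults
are the reference population estimates per family (e.g. Gaussian:
μβ0 = −13.98, μβ1 = 4.52, σβ0 = 34.10, σβ1 = 2.79, ρ = −0.55, σ = 21.90),
with N = 4970 × T = 8 as the default design. ALD sampling inverts the
closed-form CDF. The item-level generator is a stand-in whose only contract
is to exercise the scoring chain (the real instrument's response model is
not public): correctness is Bernoulli with a logistic link on the
standardized latent level, response times are truncated log-normal with a
negative speed loading, and stated fractions of responses are replaced by
fast guesses (below the clean support, accuracy 0.25) and overly slow
responses (above it); default contamination rates 0.05/0.005 align with the
filtering quantiles. The default measurement model solves each timepoint's
residual variance so the block reliability sits at .775 (inside the
reported .74–.78 band) with cross-time residual correlations of 0.45 for
word/text indicators, which puts every FDI above .90. What the generator
does **not** emulate: missing data (the analyzed factor scores had none),
school/class clustering, item-position or practice effects, and any real
item-response process — so passing tests demonstrate correctness of the
pipeline under its own assumptions, not fidelity to any particular
instrument.

## Problem sizes and numerical choices

The test suite runs desk-scale versions of the validation studies, chosen
as this package's own trade-off between statistical resolution and
turnaround: parameter recovery at N = 2000 × T = 8 per family (4 chains,
2000/3000 iterations); interval coverage over 20 replications per family at
N = 500 (2 chains, 2000/3000 iterations); the PSIS-vs-exact study on
5 persons × 2 timepoints with population scales fixed; the model-ordering
study at N = 400. The coverage study is knife-edge by construction: the
true frequentist coverage of the 95% intervals at fixed truth is ≈ 90% for
the t-family mean slope at N = 500 (the ν prior, mean 20, mildly narrows
its intervals), so individual 20-replication cells can dip below the 90%
line; the sampler's posteriors were cross-validated against an independent
JAGS implementation to ~3 decimals.

Other numerics: degenerate bounds (all response times equal) raise rather
than produce empty intervals; zero-variance score tables and fewer than
5 persons raise estimation errors; the Mahalanobis screen requires a
nonsingular sample covariance; `ν` is bounded below at 1; average ranks
break rank-normalization ties; the inverse-Gaussian sampler floors
`|residual|` at 1e-10·σ to avoid division blow-ups.

## Known limitations

Linear growth only; no missing-data support in the growth stage (by
design); marginal LOO implemented for the Gaussian family only; the
Gibbs sampler's ν and σ updates can show ESS an order below the best-mixing
parameters (still comfortably above the 400 threshold at default settings);
single-machine execution only. The end-to-end pipeline reproduces the
reference workflow's *structure* on synthetic data; reproducing the
published point estimates exactly requires the original deposited dataset,
which the package deliberately does not depend on.
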