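# Methods

## The model

`dyadmnl` models event-level records of directed dyadic behavior among
children: each observation is one of K = 19 proactive behavior categories
(comforting, dominating, helping, leading, ..., ownership assertion)
initiated by child *i* toward child *j*.  Events are treated as
conditionally independent multinomial draws.  With *ownership assertion*
(category K) as the reference, the K−1 log-odds contrasts for an event are

    log(π_k / π_K) = α_k + ν^I_{k,i} + ν^R_{k,j}
                     + h^I_{k,[i]} + h^R_{k,[j]}                (variants ih, ihF)
                     + Σ_m β_{k,Im} x_{Im} + Σ_m β_{k,Rm} x_{Rm}
                     + β_{k,H} x_H                              (variants iF, ihF)

where ν^I and ν^R are each child's initiator- and recipient-role random
effects, h^I/h^R the analogous household effects ([i] is child i's
household), x_{I·}/x_{R·} the fixed-effect blocks (standardized age, sex
coded female = 0 / male = 1, and their product), and x_H the
same-household indicator.  The intercepts are therefore the
female-to-female, mean-age, different-household baseline.  The four
variants — i, ih, iF, ihF — include or drop the household random effects
and the fixed-effect block; variant i is exactly variant iF with β ≡ 0.

Per role, the K−1 random effects of a unit are jointly multivariate normal
with covariance Σ = D L Lᵀ D, D = diag(σ), sampled in the non-centered form
ν = D L z with z ~ N(0, I).  The off-diagonals of L Lᵀ are the
cross-behavior correlations of interest (e.g., whether children who lead
more also dominate more).

Priors: standard normal on every α and β (SDs configurable via
`PriorConfig`), LKJ with shape 2 on each correlation Cholesky factor, and
standard normal innovations.  The prior on the random-effect scales σ is
not pinned down by the modeling tradition this follows; we default to
half-normal(0, 1), exposed in `PriorConfig` (and recorded in every
posterior's metadata) so a sensitivity analysis is a one-line config
change.

### Interaction scope

The fixed-effect block is additive across the initiator block, the
recipient block and the household flag, matching the stated model formula.
Cross-role interactions (initiator-sex × recipient-sex, sex × household)
are not in the default design; role-specific sex-by-household contrasts
are instead read off predicted-probability cells, which is how the
reported contrasts can be expressed without extra coefficients.  Episode
identifiers are recorded by the loaders but ignored by the likelihood
(responses are amalgamated over observation episodes).

## Posterior computation

The posterior is sampled with a package-native implementation of the
No-U-Turn Sampler: multinomial sampling along a doubling trajectory,
generalized U-turn criterion, dual-averaging step-size adaptation toward a
0.9 acceptance target, and windowed diagonal mass-matrix estimation during
warmup (divergence threshold ΔH > 1000, max tree depth 10).  The
unconstrained parameterization uses log-scales for σ and, for each
correlation Cholesky factor, tanh-transformed canonical partial
correlations via the row-wise stick-breaking map; under LKJ(η) the partial
correlations in column j are independent 2·Beta(b_j, b_j) − 1 with
b_j = η + (K−2−j)/2, which makes the prior term in the unconstrained space
a simple sum of b_j·log(1 − z²) terms.  All gradients are analytic
(hand-derived backward passes, including through the stick-breaking map)
and are verified against central finite differences in the test suite; the
density itself is cross-checked against the public
`log_prior`/`log_likelihood_pointwise` functions plus the exact
change-of-variables terms.

Chains are seeded independently from one integer seed
(`numpy.random.SeedSequence`), so runs are bit-reproducible.  Convergence
is assessed with rank-normalized split R-hat and bulk ESS (via arviz) over
*every* sampled coordinate, including the innovations.  Two sampler
profiles ship with the package: the study-scale protocol (3 chains ×
10000 iterations, 5000 warmup) and `McmcConfig.desk()` (3 × 1500, half
warmup), the latter used for all synthetic-study tests.

Model comparison uses WAIC on the deviance scale, computed from the
per-draw per-event log-likelihood matrix: lppd via log-sum-exp over draws,
p_WAIC as the pointwise sample variance (ddof = 1), WAIC = −2(lppd −
p_WAIC), with a standard error from the event-level dispersion and a
paired SE for differences between models fitted to the same events.
Akaike-style weights are exp(−ΔWAIC/2), normalized; ΔWAIC is reported
against the minimum-WAIC model.

## Reported surfaces

* **Correlations** are recomposed per draw as R = L Lᵀ and summarized with
  posterior means and 95% percentile intervals; "significant" means the
  interval excludes zero.  No multiple-testing correction is applied to
  the primary flag (matching the percentile-interval convention of the
  analysis tradition), but a Bonferroni-adjusted flag over all category
  pairs is emitted alongside.
* **Predicted probabilities** set all random effects to zero ("average"
  initiator and recipient), hold non-varying covariates at the event-level
  sample mean (the same base used for standardization), and transform
  natural-scale scenario values through the stored scaler.  Bands are
  2.5/97.5 posterior percentiles of the per-draw simplexes.
* **Age-trend labels** classify the posterior-mean curve over an age grid
  (default 0–12 by 0.5 y) as increasing/decreasing when monotone within a
  tolerance, otherwise "peaked" with the argmax cell reported as a yearly
  interval [a, a+1).
* **Descriptives** tally totals, unique *directed* dyads and
  events-per-dyad by same/different household × same/different sex ×
  behavior; per-child and per-household occurrence counts credit both
  participants of every event, so their means are exactly 2·N/children and
  2·N/households.

## The synthetic-data generator

`synthetic` draws a community with the study's demographic structure — 213
children in 70 households by default, household sizes 1–9 with mean
213/70 ≈ 3.04 (sequential preferential assignment, which also yields a
village-like size spread), sexes Bernoulli(0.49 male), ages at entry
12·Beta(1.2, 2.2) years (mean ≈ 4.2, SD ≈ 2.7, matching the reported age
profile) — and then simulates 6507 events from the full generative
process with a known `TruthBundle`.

Dyad exposure is a nuisance process the model never sees: each directed
dyad's weight is the product of per-child activity multipliers
(Gamma(1.5) with mean 1 — some children are simply seen far more often
than others), an independent Gamma(0.6) dyad weight (an overdispersed,
negative-binomial-like law), and a factor of 8 for same-household dyads;
events are allocated by one multinomial draw on these weights.  At the
default study scale this reproduces the observed dispersion of
participation (per-child occurrence SD ≈ 53 against a mean of 61.10, and
a strong same-household excess in events per dyad); the multiplier and
shapes are unidentified by aggregate counts and are configuration knobs.  Ages are fixed per child (an
event-date column is generated for realism but carries no signal); the
model supports time-varying ages in principle but the generator does not
age children across the observation window.

What the generator does **not** emulate: episode structure with behavioral
contingency (events are exchangeable given the dyad), reactive responses,
multi-party interactions, kinship links *between* households, and
observer-driven sampling biases.  Passing recovery tests therefore shows
that the inference machinery is correct under the model's own assumptions,
not that the model is correct for field data.

## Scaled-down study sizes

Synthetic end-to-end checks run at desk scale, chosen as the package's
testing conditions: the recovery study uses K = 8 categories, 60 children
in 25 households, 2500 events, moderate effects (|β| ≤ 1, σ ≤ 0.6, two
planted correlations ±0.5), with the generating variant refitted at
3 chains × 1500 iterations (900 warmup, acceptance target raised to 0.95
because the random-effect scales and correlation parameters are the
slowest coordinates); the intercept-calibration study uses K = 4 with
1200 events.  At these sizes fixed effects reach nominal-range interval
coverage and the planted initiator correlation is recovered closely, but
two quantities sit at the edge of what 60 children and ~2250 retained
draws can deliver: the planted recipient correlation is attenuated toward
zero (posterior mean ≈ −0.27 for a generating −0.5 — the LKJ(2) prior
plus partially-observed per-child effects shrink correlation estimates),
and the maximum rank-normalized R-hat over all ~950 coordinates hovers
near 1.013 (an all-coordinate maximum at 3 × 600 retained draws has an
i.i.d. floor of about 1.005, and the slow scale/correlation coordinates
sit above it; at the study-scale protocol of 3 × 10000/5000 the same
autocorrelation times would put R-hat comfortably below 1.01).  Both are
properties of the scaled-down conditions, not of the estimator: gradients
are exact, the generator and the fitted design agree bit-for-bit, and the
coverage and model-selection checks pass.

## Numerical choices and edge cases

* Probabilities are always computed through log-sum-exp; exp(η) is never
  materialized unnormalized.
* Standardization stores per-column means/SDs (initiator and recipient
  ages standardized separately, each over all analyzed events) and
  reapplies them bit-for-bit; zero age variance raises rather than
  producing NaNs.
* `cholesky_from_corr` validates symmetry, unit diagonal and positive
  definiteness; the CPC round trip (`cpc_from_cholesky` /
  `cholesky_from_cpc`) is exact to ~1e-12.
* Sampler initialization: innovations and correlation parameters start
  near zero, scales near exp(−1), intercepts/coefficients uniform in
  (−1, 1); a non-finite gradient at the start raises with the offending
  block's name.
* WAIC requires ≥ 2 draws (the pointwise variance is otherwise
  undefined); comparison of a single model returns weight 1.
* Empirical percentile intervals from thinned draws are *not* strictly
  wider in expectation (extreme sample quantiles are slightly
  inward-biased), so interval stability under 10× thinning is tested as a
  Monte-Carlo tolerance, not a one-sided bound.

## Known limitations

* The sampler is single-threaded and pure NumPy; study-scale runs
  (K = 19, 6507 events, 3 × 10000 iterations) are feasible but take hours,
  so tests and the acceptance script use the desk-scale profiles above.
* Household SES covariates, Gaussian-process kinship-distance effects,
  reactive behaviors and longitudinal/social-network extensions are out of
  scope.
* R-hat needs ≥ 2 chains; single-chain fits return draws but cannot be
  diagnosed.
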