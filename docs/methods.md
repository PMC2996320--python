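# Methods

## Observer model and simulated protocol

An observer is a pair of sensitivity maps plus a stochastic choice rule.
The *true map* assigns each contrast level a Quick–Weibull psychometric
curve

    p(e) = 0.5 + 0.5 · 2^(−(e/τ)^β),

with position τ (degrees; the 75%-correct eccentricity) and steepness β.
It generates 2AFC calibration responses as independent Bernoulli draws and
must satisfy dominance on the 18-point stimulus grid (probability correct
strictly increasing in contrast at fixed eccentricity, strictly decreasing
in eccentricity at fixed contrast); construction fails otherwise, naming
the offending eccentricity. The *subjective map* is a second curve triple
driving decision-phase choices: under the default rule the probability of
choosing target A over B is `logistic(noise · (p̂_A − p̂_B))` in subjective
probability correct, with `noise` an inverse temperature (`noise = ∞` gives
a deterministic maximiser). Two further generative hooks exist:

- **Cross-contrast mapping transforms.** Because any single subjective map
  composes to the identity around the contrast cycle (an exact property of
  the family, see below), intransitive behaviour requires mapping-specific
  distortion. A transform `(intercept, slope)` per directed mapping
  re-maps the first target's eccentricity in log space before comparison.
  The `corkscrew_observer` preset multiplies each veridical transform slope
  by `composite_slope^(1/3)` (re-anchored at a 5° pivot), so the cycle
  composes to `composite_slope` instead of 1 — the generative analogue of
  choices that spiral outward across contrasts.
- **Lexicographic semiorder rule.** Compare eccentricity first: if the
  difference exceeds a threshold (default 2°) the nearer target wins;
  otherwise the higher contrast wins, with an optional lapse probability.
  This rule produces genuine preference cycles.

The simulated protocol reproduces the experiment's design exactly:
calibration of 3 contrasts × 18 eccentricities (evenly spaced 2°–12.2°,
spacing 0.6°) × 5 blocks × 6 repetitions (half top / half bottom within
each cell, shuffled within block) = 1620 trials; then a decision phase of
12 one-up one-down staircases (3 directed mappings low→med, med→high,
high→low × anchor levels p ∈ {0.6, 0.7, 0.8, 0.9}, 70 trials each = 840)
randomly interleaved with 90 equi-contrast and 90 equi-eccentricity
dominance trials anchored at each fitted curve's p = 0.75 eccentricity.
Staircase anchors are placed by inverting the observer's *fitted*
calibration curves, as in the protocol; an anchor falling outside the
stimulus range is a design error (the stimulus cannot be displayed).

### Default study conditions

| parameter | default | rationale |
| --- | --- | --- |
| true map τ (LOW/MED/HIGH) | 4.8 / 6.0 / 7.0 ° | sensitivity near ceiling at 2°, near chance at 12° for LOW; all 12 staircase anchors (≈3.0°–10.0°) and the three p=0.75 dominance eccentricities inside the range with margin for fit noise |
| true map β | 2.5 / 2.6 / 2.7 | ordinary psychometric steepness; slightly increasing with contrast so the β-ratio structure of the transforms is exercised |
| choice noise | 30 | puts the stochastic veridical observer's dominance error rate at ~8–9%, the scale observed in human data, while staircases stay stochastic (median ~40 reversals per 70 trials) |
| staircase step | 0.6° | one stimulus-grid spacing; the natural movement unit |
| staircase start | the fixed anchor's eccentricity | symmetric, unbiased start |
| reward | $5 per correct attempt | the protocol's stake |
| bootstrap resamples B | 10,000 (500 with `fast`) | protocol-scale inference vs. scaled runs |

Even with these margins, binomial noise in 540 trials/contrast leaves a
~0.3% chance per observer that a fitted anchor escapes the range; batch
drivers (the acceptance script) replace such an observer with a fresh
seed, as a study would replace a subject whose staircase cannot be
displayed.

## Estimators and tests

**Psychometric fitting.** Bernoulli maximum likelihood on the per-cell
binomial counts, bounded L-BFGS-B over τ ∈ [1, 30], β ∈ [0.5, 10] from a
grid of 15 start points (objective tolerance 1e-10; ties broken by higher
likelihood then smaller τ). All-correct/all-incorrect data and fits pinned
at a bound are flagged non-identifiable (`converged=False`) with a warning.
No lapse or guessing parameters: the curve has exactly the two reported
parameters. Bootstrap refits warm-start from the point fit with a single
start.

**PSE estimation.** Mean of a staircase's reversal eccentricities after
discarding the first two reversals; fewer than four reversals is an error
(the staircase never converged). A tail-mean alternative (mean of the last
35 trial eccentricities) is available via `estimate_pse(..., method=
"tail_mean")` for sensitivity analysis. Boundary clipping records the
clipped value and never counts as a reversal (a clipped move repeats the
previous direction).

**Bootstrap resampling.** Staircase uncertainty uses a *replay bootstrap*:
the observed choices at each visited eccentricity form an empirical pool,
and each resample re-runs the one-up one-down dynamics drawing choices from
the pool at the nearest visited eccentricity, then re-estimates the PSE
(tail-mean fallback if a replay yields under four reversals). This
preserves the sequential trial structure while resampling only observed
choices. Calibration uncertainty resamples trials within contrast ×
eccentricity cells (equivalently, binomial draws at the observed cell
rates) with a curve refit per resample. Percentile intervals throughout.

**Equivalence.** For each of the 12 subjective-indifference pairs, Δp is
the fitted true probability of the lower-contrast member minus the
higher-contrast member; intervals are Bonferroni-corrected for 12 tests at
overall level .05 (per-test size .05/12). The mean signed Δp across pairs
gets a two-tailed one-sample t-test (pairs treated as independent), and
each pair's eccentricity error is the PSE minus the eccentricity at which
the variable contrast truly matches the fixed target's probability.

**Transitivity.** Ordinary least squares of ln(PSE) on ln(fixed
eccentricity) over the four staircases of each directed mapping gives the
transform (intercept, slope); natural logarithms by contract (the slope,
and hence b, is base-invariant). Composition around the cycle gives
composite slope B = b_LM·b_MH·b_HL and intercept
A = a_HL + b_HL·(a_MH + b_MH·a_LM); the statistics are a = A and
b = B − 1, both exactly zero for transforms induced by any single curve
triple of the family (slopes telescope as β-ratios, intercepts cancel).
Bootstrap intervals at overall 95%, Bonferroni-corrected for the two
statistics (per-interval coverage 97.5%); the observer is flagged
intransitive if either interval excludes zero. Transforms are fitted to the
four PSEs, not to trial-level choices — the PSEs are the quantities the
log-linear law relates.

**Dominance.** An error is choosing the larger eccentricity at equal
contrast or the lower contrast at equal eccentricity. The error proportion
is modelled as Beta(errors + 1, n − errors + 1) — a uniform prior updated
by the observed counts — with a 95% equal-tailed interval.

**Expected gain.** Per decision trial the loss is
`(max(p_A, p_B) − p_chosen) · reward` with probabilities from the fitted
calibration curves (the analysis's only access to truth); the loss fraction
divides total loss by the ideal expected gain over the same trials. For a
deterministic optimal observer this is therefore a measure of calibration
estimation error (typically well under 1%), not of decision quality.

## What the simulator does and does not emulate

The generator reproduces the protocol's trial economy, the Bernoulli
structure of 2AFC responses, staircase/dominance interleaving, and choice
stochasticity through a single logistic noise parameter. It does not
emulate sequential dependencies (learning, fatigue, criterion drift),
lapses in the default rule, eccentricity-perception noise, fixation breaks,
or reaction times, and subjective-map distortions are test constructs, not
a psychological model of how miscalibration arises. Passing tests therefore
certify the analysis chain and its operating characteristics under clean
assumptions, not the behaviour of human observers.

## Numerical notes and limitations

- `predict`/`invert` are exact closed-form inverses; far past τ the curve
  saturates to the 0.5 floor in float64, so oracles (root finding,
  monotonicity checks) operate on the informative range.
- Equal log-likelihoods between optimiser starts are broken toward smaller
  τ; refits in bootstrap loops use the point estimate as a warm start.
- The replay bootstrap degenerates for a noiseless (deterministic)
  observer: all resamples reproduce the same trajectory, intervals collapse
  to a point, and any quantization bias in the point estimate (PSEs move on
  a 0.6° lattice) becomes "significant". The axiom tests presume stochastic
  choice; the deterministic observer is supported for oracle checks, not
  for bootstrap inference.
- PSEs near the 2°/12.2° boundaries are clipped, which attenuates fitted
  transform slopes for strongly distorted observers (the corkscrew
  observer's b ≈ 0.9–1.15 instead of exactly 1); detection is unaffected.
- Validation problem sizes: parameter recovery uses 100 simulated
  calibrations at the protocol's 540 trials/contrast; null calibration and
  power of the transitivity test use 20 observers at B = 500 (the scaled
  `fast` setting); the staircase oracle comparison uses 200 runs at a 0.02°
  grid-search resolution.
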