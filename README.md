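# visconjoint

Do observers know their own visual sensitivity? Performance in visual tasks
falls off steeply with retinal eccentricity and improves with target
contrast, and models of efficient visual search assume the visual system can
consult this sensitivity map when deciding where to look. `visconjoint`
implements a conjoint-measurement analysis of that question: it simulates a
two-task psychophysical protocol on configurable synthetic observers and
runs the statistical battery that scores their choices for **equivalence**
(do judgments match measured performance?), **transitivity** (are the
judgments self-consistent?) and **dominance** (is more contrast / less
eccentricity always preferred?), together with an expected-gain account of
what the failures cost.

The package is aimed at psychophysicists and decision scientists who want a
tested, seeded implementation of the full analysis chain — adaptive
staircases, psychometric fitting, bootstrap axiom tests — and a generative
observer model (including an intransitive, lexicographic-semiorder-style
preset) to study its operating characteristics.

## The model

Probability correct for a 2AFC target at eccentricity *e* (degrees) follows
a decreasing Quick–Weibull function with position τ and steepness β:

```
p(e) = 0.5 + 0.5 · 2^(−(e/τ)^β)
```

fit per contrast (low/medium/high) by maximum likelihood to 1620 calibration
trials (3 contrasts × 18 eccentricities, 2°–12.2°, × 30 repeats). In the
decision phase, 12 interleaved one-up one-down staircases (3 directed
contrast mappings × anchor levels p ∈ {0.6, 0.7, 0.8, 0.9}, 70 trials each)
estimate the eccentricity-contrast pairs the observer treats as equally
discriminable, alongside 90 + 90 dominance trials.

Within the Quick–Weibull family, the *equivalence transformation* between
equally discriminable eccentricities at two contrasts is linear on a log
scale,

```
ln e₂ = a₁₂ + b₁₂ · ln e₁ ,   with slope b₁₂ = β₁/β₂ ,
```

so composing the three mappings around the contrast cycle
low→med→high→low must return the identity. The composite intercept
`a` and composite slope minus one `b` are both zero for any self-consistent
observer; bootstrap confidence intervals for (a, b) — resampling staircase
choices within staircase and calibration trials within cell — give the
transitivity test. Equivalence is tested per pair via the signed true
probability difference Δp with Bonferroni-corrected bootstrap intervals (12
tests), dominance via beta-distributed error-rate intervals, and each
suboptimal choice is priced as `(max(p_A, p_B) − p_chosen) · reward`.

## Worked example

`python examples/transitivity_battery.py` runs the decision phase for a
self-consistent observer and for a "corkscrew" observer whose cross-contrast
mappings exaggerate eccentricity differences (composite slope 2), then
bootstraps the transitivity statistics:

```
veridical: a = +0.072 CI [-0.176, +0.914]  b = -0.036 CI [-0.534, +0.122]  intransitive=False
corkscrew: a = -1.621 CI [-2.066, -0.436]  b = +1.157 CI [+0.449, +1.450]  intransitive=True
```

For the veridical observer both intervals cover zero: composing its three
equivalence transforms returns (numerically) the identity. The corkscrew
observer's composite slope deviation b ≈ 1 (composite slope ≈ 2) is
significantly positive, flagging the intransitive spiral. The other
examples (`fit_sensitivity_curves.py`, `run_staircases.py`,
`full_experiment.py`) demonstrate curve fitting, the staircase/PSE oracle
comparison, and the full pipeline on a contrast-underestimating observer.

A thin CLI wraps the pipeline: `visconjoint run --seed 1 --out results/`
writes trial CSVs and a JSON report; `visconjoint cohort` runs several
seeds and reports cohort medians.

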