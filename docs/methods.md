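# Methods

## Scope and coordinate conventions

All orientations are expressed in degrees relative to each participant's
measured point of subjective equality (PSE), counterclockwise positive
("orange" side).  Orientation is 180°-periodic; internally every circular
computation runs in double-angle radians (z = 2θ), so a von Mises
concentration κ quoted anywhere in the package is in double-angle units
(κ = 1/σ_z² for narrow distributions; σ_θ[deg] ≈ 90/(π√κ)).  Probability
distributions over orientation are masses on a fixed grid of 720 points
(0.25° steps) spanning one period; every constructor and update renormalises
to machine precision.  User-facing files use plain degrees at six
significant digits.

## Session generator

A session is 2160 stimuli (300 ms presentation, 900 ms inter-stimulus
interval, plus a 1.5 s pause after each response) split into three equal
blocks.  Adaptor orientations are drawn per block: block i from
N(PSE, 3°); blocks ii–iii from a bimodal mixture with modes ±15° from the
PSE and 3° spread.  Group A keeps the mixture balanced in block ii; group B
weights the counterclockwise mode 3:1; group C keeps it balanced but
presents every clockwise adaptor at low contrast.  Response cues follow each
12-stimulus cycle's last stimulus, plus one position drawn uniformly from
the 11 earlier slots of the cycle (the random cue can never coincide with
the fixed one), giving 2 tests per 12 stimuli, i.e. 360 per session.  Tests
are substituted into the stream at cue positions — they are full stimuli and
feed the history of later trials.  Test orientations are exactly ±3° from
the PSE at 50% (high) or 8–10% (low) contrast; every 240-trial span contains
exactly 10 tests of each of the four types in randomised order.

Participant profiles replace an adaptive-staircase calibration phase by
direct sampling, since the downstream models consume only five numbers:
baseline midpoint c₀ ~ N(0°, 1°) (the residual error of the calibration),
logistic slopes k_high ~ logN(ln 1.0, 0.25) and k_low ~ logN(ln 0.4, 0.25)
per degree with k_high ≥ k_low enforced, reference-representation mean
μ_ref ~ N(0°, 1°) and concentration κ_ref ~ logN(ln 200, 0.3) (≈ 2° spread).
Three in eight participants receive a 10% rather than 8% low-contrast level.
These values emulate practised observers on this task; the generator does
not emulate lapses, attentional drift, response bias, session breaks, or
learning, so passing tests say nothing about those aspects of real data.

All randomness flows through `numpy.random.default_rng` generators seeded
explicitly; a cohort is reproduced bit-for-bit from a single seed.

## Linear history model

The model shifts a logistic psychometric function's midpoint by a weighted
history of signed differences between past stimuli and the midpoint that
held *at their own presentation time*.  The influence function is a sum of
three ramps per test-contrast level, each with an initial one-back weight w
(dimensionless; negative = repulsive) and an integer extinction lag m; a
separate multiplier 1/γ (γ > 0, dimensionless) down-weights low-contrast
past stimuli.  Free parameters: 3 × (w, m) × 2 + γ = 13.

Because the influence function and the k_norm = 2 ln 9 / k normalisation
both depend on the *judged* test's contrast, the "midpoint at time t" is
contrast-dependent.  The package tracks two causal midpoint trajectories per
session — one under the high-contrast influence function and slope, one
under the low — and evaluates each test on its own trajectory.  With empty
history both trajectories start at c₀, and once history ages past the
largest m the shift regresses to zero.

Numerics: the forward pass is jit-compiled; the shift is clamped to ±90°
(one period) because the linear recursion can diverge for aggressive
parameter proposals during fitting, and shifts beyond the period are
meaningless.  Response probabilities are clipped to [10⁻⁹, 1 − 10⁻⁹] in the
pooled negative log-likelihood.  Fitting uses bounded L-BFGS-B over the six
weights and log γ from multiple starts; the integer lags m are handled by
nested coordinate descent over a candidate grid, with ties broken toward
smaller m.  A fit can never return a point worse than its initialisation.

## Bayesian observer

Sixty von Mises channels tile the period with concentration κ_φ at maximum
contrast.  Response amplitude saturates with contrast as
c^e/(c50^e + c^e); the contrast-variant (CV) flavour applies the same
saturation form to the tuning concentration (constants w50, ε).  Both
saturations are rescaled by their value at c = 1 so that maximum contrast
reproduces the nominal amplitude-1, κ_φ-width tuning exactly; the
semi-saturation point then sits at half the (rescaled) large-contrast
asymptote.  Per stimulus, in order: gains recover toward 1 by
min(βΔt, 1) over the blank Δt = onset(t) − onset(t−1) − duration(t−1)
(recovery runs only between presentations); channels respond; the
likelihood is decoded as exp(ω_s Σ m_i n_i log φ_i) with ω_s = ω ·
duration/300 ms, normalised over the grid (all-zero drive yields a uniform
mass); the posterior is the renormalised product with the prior; for tests,
P("orange") is P(X > Y) + ½P(X = Y) for X ~ posterior, Y ~ the participant's
fixed reference distribution V(μ_ref, κ_ref), computed on the shared grid
linearised around μ_ref (the tie term keeps identical distributions at
exactly 0.5); gains then adapt by m_i ← m_i(1 − α n_i) (the current stimulus
is perceived with pre-update gains); finally the prior takes a convex step
of size τ toward the posterior.  The prior starts uniform and updates on
every stimulus, adaptor or test; the reference distribution never adapts.

Free parameters and defaults: α = 0.08 (gain loss per unit activation,
in [0,1)), β = 0.10 s⁻¹ (recovery), τ = 0.005 (prior integration per
presentation — hundreds of presentations to reshape the prior), ω = 15
(accumulation per 300 ms; at maximum-contrast drive this gives a
high-contrast likelihood spread of ≈ 1.9° and low-contrast ≈ 3.1° under the
V5 preset), and in the CV variant w50 = 0.09, ε = 2.3.  ω_s scaling linearly
with duration is the minimal assumption consistent with treating ω as
accumulated drive; it also lets high-contrast stimuli be shortened to match
a low-contrast stimulus's static likelihood exactly in the CI variant
(`equivalent_duration`), while adaptation — which has no duration term —
still sees them as high-contrast: duration and contrast are therefore not
interchangeable in the sequential predictions.

The V1/V2/V5 presets (κ_φ, c50, e) are synthetic placeholders with
physiologically plausible orderings (V1 narrowest tuning and highest c50;
V5 broadest and most contrast-sensitive); they are stand-ins, not
transcribed measurements, and nothing in the package's tests or results
depends on their values.

## An exact property of the decoded likelihood, and its consequences

Because the channels tile the period evenly and log φ_i is a sinusoid in z,
the decoded log-likelihood Σ w_i log φ_i is itself exactly a sinusoid: the
likelihood is always a von Mises distribution with mode
arg(Σ w_i e^{i z_i}) and concentration κ_φ ω_s |Σ w_i e^{i z_i}|.  Two
consequences are worth stating because they constrain what the model can
and cannot reproduce:

1. the likelihood-mode displacement caused by an asymmetric gain profile is
   *scale-invariant* in the response amplitude and *monotone increasing* in
   the test's tuning width — so in the CV variant a low-contrast (wide)
   test's likelihood is displaced at least as far as a high-contrast one,
   and in the CI variant exactly as far;
2. with a symmetric prior, the psychometric *crossing* (PSE) inherits the
   full likelihood displacement regardless of prior strength — the prior
   and decision stages attenuate the psychometric slope, not the crossing.

The package's tests therefore assert the repulsive sign and exact agreement
with the closed-form vector sum, the stronger prior pull on low-contrast
tests, the collapse of group-B block-ii counterclockwise-test responses
toward chance, and the presence of a high-contrast midpoint shift in group
C.  A suppression of the *low*-contrast group-C shift below the
high-contrast one is not attainable in this architecture (see Known
limitations) and the corresponding test documents that gap rather than
papering over it.

## Model comparison and recovery

AIC = 2k + 2·NLL and BIC = k ln n + 2·NLL with n the number of responses
(8640 at full cohort scale); nested CI/CV pairs are compared with a χ²
likelihood-ratio test on 2 degrees of freedom.  Variance explained is
reported as adjusted R² with R² the squared Pearson correlation between
predicted probabilities and binary responses (a convention, since binary-R²
definitions vary); a McFadden pseudo-R² is emitted alongside.

Recovery studies regenerate cohorts whose responses are simulated from a
known truth and refit from neutral starting points (zero weights / default
dynamics — never the truth).  Problem sizes are chosen to finish on a
single CPU: the linear-model γ recovery runs 10 replicates at the full
24-participant scale with the component timescales m held at the truth
(fitting the 7 continuous parameters); the observer α recovery refits α
alone on 3-participant cohorts across a 3-point α grid and checks rank
order.  Full joint fits (nested m search; all 6 observer parameters) are
supported through the same interfaces and exercised on small cohorts.

## Known limitations

* The likelihood-geometry result above: contrast modulates how *strongly*
  an adapted gain profile displaces a test's likelihood only through tuning
  width, and in the wrong direction to suppress low-contrast shifts.
  Reproducing a near-absent low-contrast aftereffect would require a
  different encoding stage (e.g. non-uniform channel placement, additive
  response baselines, or response-dependent decision noise), which this
  package deliberately does not add.
* The channel presets are placeholders; preset rankings (V1 vs V2 vs V5)
  carry no physiological meaning here.
* The generator does not model lapses, learning, breaks, or reaction-time
  variability; inter-trial gaps vary only through the fixed response pause.
* Per-participant (non-pooled) fits and bootstrap confidence intervals on
  components are out of scope.
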