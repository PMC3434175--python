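# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of the `cuefidelity` pipeline.

## Psychometric model and threshold definition

Forced-choice up/down categorisation is modelled with a Weibull function
`p(x) = A + (B − A)(1 − exp(−(x/x₀)^m))` on the absolute signal level
`x = |Xc|`, with the asymptotes fixed at chance (`A = 0.5`) and ceiling
(`B = 1.0`). `x₀` (level units, collective inches) is the scale: the curve
passes `0.5 + 0.5(1 − e⁻¹) ≈ 0.816` there. The reported threshold is the
level where the fitted curve crosses **81% correct**, solved in closed form;
both `x₀` and the 81% crossing are stored on the fit.

Fitting maximises the binomial log-likelihood of the per-level correct
counts. Least squares on proportions would also be defensible; maximum
likelihood was chosen because it weights levels by their trial counts and
behaves sensibly near the asymptotes. The optimiser is deterministic:
a 49×33 log-spaced grid over `(x₀, m)` followed by Nelder–Mead refinement in
log-parameters from the three best grid points. Tests verify the optimum
dominates a dense 200×200 grid on small tables.

Degenerate data are rejected rather than fitted: all-correct or
all-incorrect tables (unbounded likelihood), and chance-only tables, where
the likelihood is maximised only as `x₀ → ∞` (detected when the fitted scale
escapes to 100× the largest tested level — no finite threshold exists).
Levels with zero valid trials are dropped with a logged warning. Trials with
no response are excluded from all fits. Up/down pooling onto `|Xc|` is the
default, mirroring the use of direction-collapsed data once direction
effects have been ruled out by paired tests.

## Quick pooling

With unimodal thresholds `T_i` and a combined threshold `T`, the pooling
rule is `Σ (T/T_i)^k = 1`. For one subject, `k` is found by Brent root
finding on `u^k + v^k − 1` over `k ∈ [0.1, 64]` (the left side is strictly
decreasing when both normalised coordinates are below 1, so the root is
unique). The group fit minimises the sum of squared radial residuals
`((u^k + v^k)^{1/k} − 1)²`; this objective is symmetric in the two cues and
reduces exactly to the single-subject solution for one point. Whether a
group exponent should be fitted to pooled points or averaged over
per-subject exponents is genuinely open; the radial least-squares choice
treats every subject's deviation from the unit contour equally.

Fitted `k > 8` is reported as the independent-channels regime (a numeric
stand-in for `k → ∞`); otherwise the regime label is the nearest of
{1, 2, 4}. Subjects without facilitation (`T_am ≥ min(T_a, T_m)`) have no
finite `k`; strict mode raises, lenient mode returns `inf` or lets such
points pull the group fit upward.

## Observer mechanisms (synthetic data)

The forced-choice task has no public data set, so cohorts are simulated.
The mechanisms are chosen so that each canonical pooling regime is realised
*provably*, not approximately:

* **optimal_gaussian** — each channel senses `x + ε_i`,
  `ε_i ~ N(0, σ_i²)`; bimodally the estimates are combined with
  inverse-variance weights, so `1/σ_c² = 1/σ_a² + 1/σ_m²` and thresholds
  combine Euclidean-ly (`k = 2`).
* **linear_late_noise** — channel signals are summed with fixed gains
  `g_i = 1/σ_i` into one decision variable with a single late noise source
  (σ = 1); sensitivities add, giving `1/T_am = 1/T_a + 1/T_m` (`k = 1`).
  An early-noise summation model would itself be optimal and collapse onto
  `k = 2`, which is why the noise must enter after summation.
* **probability_summation** — each channel detects independently with
  Weibull probability `1 − exp(−(|x|/T_i)^m)` and reports the true sign when
  it detects; otherwise the observer guesses. The OR rule multiplies the
  miss probabilities, which for Weibull channels gives exactly `k = m`. The
  audio-wins tie-break is arbitrary and inert: detecting channels always
  agree on the sign.
* **single_channel** — one cue only; requesting the bimodal condition is a
  spec-mismatch error.

Channel noise defaults (`σ_a = 0.31`, `σ_m = 0.24`) put the unimodal 81%
thresholds near 0.27 and 0.21 collective inches (threshold ≈ 0.878 σ for a
Gaussian channel) — the magnitude regime of untrained observers on this
task. This is a calibration choice, not an inference. Cohorts draw
per-subject σ's log-normally around the base with multiplicative sd 0.15 by
default, a moderate between-subject spread. The session design tests ten
signed levels ±{0.1…0.5} in the three cue conditions; level 0 is accepted
for chance-floor calibration runs, in which a nominal direction is drawn at
random so correctness stays defined (and is exactly 50% in the long run).

Gaussian-CDF psychometrics are deliberately fitted with the Weibull model
(the analysis pipeline should not be told the generating family); the shape
mismatch is absorbed by the recovery tolerances. At 500 trials/level the
group pooling exponent recovered from optimal observers is distributed
around 2.07 ± 0.07 — the small upward shift is the convexity
(small-sample) bias of threshold ratios, not a property of the mechanism,
and shrinks with trial count.

## Heave model and cue channels

The vertical dynamics are `ẇ = Z_w·w + Z₀·Xc`, `ḣ = w`, with `Z₀ = 4.8`,
`Z_w = −0.1` ("hard") or `−0.5` ("easy"). The published schematic routes
acceleration to the motion platform and height to the visuals but prints no
equations; this first-order law is the standard single-axis heave
reconstruction consistent with that routing and the hard/easy damping
interpretation. Units: `Xc` in collective inches, heights in ft; the model
units of `Z₀` are left as configuration since acceleration is separately
calibrated in g in the cue channel.

Integration is fixed-step RK4 at `dt = 10 ms` with linear interpolation of
the control at half-steps; against the constant-input closed form the
velocity error is below 1e−11 relative. Non-uniform input grids and
non-negative damping are rejected.

Cue channels: the audio level is `87.5 + (3 / travel)·Xc` dB(A) with a full
collective travel of 3.0 in (±1.5), giving an 86–89 dB(A) excursion —
3 dB end to end; `static` mode holds the base level and `substitute` mode
applies the identical mapping (a carrier label only; no audio is rendered).
The platform channel is the model acceleration normalised by `Z₀`, scaled by
0.04 g per unit `Xc` (so a step to `|Xc|` peaks at exactly `0.04·|Xc|` g)
and delayed by 80 ms = 8 samples; off-grid delays are rounded to the nearest
sample with a logged warning. An optional first-order high-pass stub stands
in for a washout filter and is off by default.

Target paths sum six sinusoids with frequencies evenly spaced over
0.2–0.5 rad/s; amplitudes (uniform 0.5–1.5 ft) and phases are drawn once
from the seed, yielding excursions of a few ft — reproducible across calls
yet too complex to memorise.

## Synthetic pilots

The tracking task defines the environment, not the pilot, so the pilot is a
designed mechanism. Both closed-loop controllers command a trim feedforward
`−Z_w·ḣ_target/Z₀` (the steady collective the damping demands — pilots are
assumed to discover this within a run) plus a proportional correction on the
perceived height error; the visual height arrives with a 0.2 s delay and
`σ_h = 0.3` ft of noise (reduced 30% when the auditory error beep localises
the target). With that delay the proportional loop is oscillation-limited —
most severely in the lightly damped hard dynamics, which is what makes them
hard. The derivative term damps the perceived error rate, but only to the
extent a velocity cue exists: the platform supplies a direct velocity sense
(`σ_w = 0.05` ft/s, full gain `k_d`); a trained pilot (`audio_skill > 0`)
flying without the platform propagates a forward-model velocity from their
own commands via the turbine cue, recovering `audio_skill`-scaled damping;
with neither cue the term vanishes. This one mechanism reproduces the
qualitative pattern of the flying experiments by construction: the platform
and the easy dynamics reduce the error, the turbine is inert for untrained
pilots, and training transfers the turbine benefit. An `ideal_inverse`
controller applies the exact model inverse (no delay or noise) as a
perfect-tracking reference. Runs whose error leaves a ±200 ft envelope
raise a divergence error. Default gains `k_p = 0.08`, `k_d = 0.25` keep the
closed loop stable across both damping settings with errors in the
0.2–1.2 ft range.

## Tracking statistics

The run score is the median absolute height error (robust to excursions).
Main effects of a complete within-subject 2^k design are computed per
subject, then averaged; incomplete or unbalanced designs are rejected with
the missing cells listed, never imputed. The repeated-measures ANOVA tests
each two-level factor as `F = MS_factor / MS_(factor×subject)` with df
`(1, n_subjects − 1)`; for a single factor this is algebraically `t²` of the
paired test, which the suite verifies. A factor that is exactly inert with
no subject-by-factor variation (a 0/0 statistic) is reported as `F = 0`,
`p = 1`. Paired comparisons expose one- and two-sided alternatives
explicitly; identical inputs return `t = 0, p = 1` by convention, while a
nonzero constant difference (zero variance) is a degenerate-data error. No
multiple-testing correction is applied by default; a Holm adjustment is
available. The learning filter fits a least-squares line to the four
training-phase mean errors and includes a participant iff the fitted drop
from first to last phase is at least 0.15 ft (boundary inclusive).

## Problem sizes

The test suite and acceptance script use: 100,000 trials for the
chance-floor check; cohorts of 10 observers at 500 trials/level (2,000 for
probability summation, whose thresholds need more data at channel exponent
4); 50 seeds for regime-separation distributions; 1,000 replications for the
ANOVA type-I calibration; 200 replications for scale-recovery; and 60 s
tracking runs at `dt = 10 ms` with cohorts of 4–6 synthetic pilots. These
sizes give comfortable statistical resolution for every assertion while
keeping a full run to a few minutes.

## What the synthetic data do and do not show

Passing tests demonstrate that the pipeline is *correct*: thresholds sit at
81% by construction, the pooling fit identifies the generating integration
mechanism, the statistics have their nominal error rates, and the simulator
realises its printed calibrations. They do not validate the models
*against people*: real observers lapse, adapt, and weight cues
asymmetrically; real pilots learn within runs and produce autocorrelated,
non-Gaussian control noise; and real bimodal facilitation may mix regimes.
Human-subject headline statistics (group `t`/`F` values, the empirical group
pooling exponent, absolute training gains) depend on raw behavioural data
that are not publicly available and are therefore out of scope. Confidence
intervals on individual thresholds, lapse-rate parameters, adaptive
staircases, audio rendering, platform kinematics and washout design are
likewise out of scope.
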