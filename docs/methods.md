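# Methods

`ssinva` implements a headphone-delivered, virtual-acoustics dual-task test
of spatial hearing: in every trial a *reference* word and then a *target*
word are presented from adjacent virtual loudspeakers in continuous
multi-talker babble, and the listener reports (a) both words from a
four-alternative closed set and (b) whether the target moved left or right
of the reference.  The package covers the whole measurement chain — stimulus
synthesis and calibration, anechoic binaural rendering, adaptive threshold
estimation, balanced trial-list generation and session logging — plus a
simulated listener for end-to-end verification and the trial-level
mixed-effects logistic analysis of both outcomes.

## Test geometry and timeline

Seven virtual loudspeakers sit on the frontal horizontal arc at
−90°…+90° in 30° steps (negative = listener's left).  Babble plays
continuously from four fixed azimuths (±30°, ±60°).  Within a trial the
babble runs from 0 to 3.5 s, the reference word starts at 0.5 s and the
target word at 2.0 s; each word is ≈1 s long.  The twelve ordered pairs of
adjacent azimuths define the *mean location* (pair midpoint, one of ±15°,
±45°, ±75°) used as the spatial predictor of the localization model, and a
shift *direction* (right iff the target azimuth exceeds the reference).

## Stimuli

Real word recordings (a closed-set children's discrimination corpus) and
recorded 16-talker babble are not redistributable, so the default assets
are synthetic stand-ins that preserve what the pipeline depends on:

* **Word tokens** — 16 words in 4 phonetic-contrast groups (complex vowel,
  simple vowel, initial consonant, final consonant; 4 words each).  Each
  token is a 1-s harmonic "vowel" core with word-specific fundamental and
  two formant-like resonances, flanked by word-specific narrow-band noise
  bursts standing in for consonantal onsets/offsets.  The vowel steady
  state is annotated at 0.25–0.75 s by construction (for real recordings
  the annotation comes from a CSV sidecar; it is metadata, never
  auto-detected).  Tokens are deterministic in `(word_id, seed)` and
  mutually separable by matched-filter correlation, which gives the
  audio-driven simulated listener a clean ceiling.
* **Babble** — 16 independent streams of speech-spectrum-shaped Gaussian
  noise (first-order low-pass at 500 Hz) amplitude-modulated at syllabic
  rate (~4 Hz envelope).  The 16-stream sum is near-stationary: any 1-s
  window RMS is within ±1.5 dB of the global RMS, which is the property
  the level chain and SNR logic rely on.  It does not contain
  intelligible speech, informational masking, or the spectro-temporal
  dips of real babble, so absolute masked thresholds are not comparable
  to those measured with recorded babble.
* **HRIRs** — a spherical-head set on the 7-azimuth grid.  Interaural time
  differences follow the Woodworth model, ITD = (r/c)(θ + sin θ) with
  r = head circumference / 2π and c = 343 m/s; interaural level
  differences come from a broadband gain (±5 dB at 90°) plus a
  first-order high shelf above 2 kHz (±4 dB at 90°), both scaling with
  sin |azimuth| so the ILD is strictly monotone in lateral angle and the
  two ears are identical at 0°.  Real HRTF sets load from SOFA
  (SimpleFreeFieldHRIR) files; the SOFA counterclockwise azimuth
  convention is flipped on load and the native ITD of each measurement is
  estimated by cross-correlation and removed, so personalised delays can
  be substituted at render time.  No elevation, distance or pinna cues
  are modelled.

## Calibration

Word tokens are equalised so the RMS over each token's vowel steady-state
window is identical across all 16 words.  Digital levels map to SPL
through a single configurable reference (digital RMS 1.0 ↔ 100 dB SPL by
default; hardware calibration is out of scope).  The presentation levels
are fixed properties of the test: babble at 52 dB SPL throughout; word
level 52 dB SPL + SNR; calibration noise 20 dB above the word reference,
i.e. 72 dB SPL.  Babble scaling accounts for the number of sources under
an incoherent-summation convention — each of the four streams gets gain
target/(rms·√n) so their *sum* sits at the babble level; a per-source
alternative is switchable, since which of the two the original hardware
used is not documented.  SNR is defined at the source domain, before
spatialisation: one scalar per run, while the SNR at each eardrum varies
with azimuth by design (that variation is the better-ear effect the test
is sensitive to).

## Binaural rendering

Rendering is fully anechoic.  Every 12 ms the effective azimuth of each
source (world azimuth minus head yaw, wrapped to (−180°, 180°]) selects an
IR pair: grid IRs are stored time-aligned (zero ITD), linearly
interpolated between bracketing azimuths, and given a personalised
Woodworth delay computed from the listener's measured head circumference
(valid range 0.40–0.70 m).  Successive frames are joined by linearly
crossfading the framed input between the previous and current IR pairs —
exact when the head is static, click-free when it moves.  Azimuths beyond
±90° are folded onto the frontal mirror direction with a structured
warning, because the synthetic HRIRs carry no front/back cues.

The fractional interaural delay uses first-order (linear/Lagrange)
interpolation rather than a symmetric windowed-sinc kernel: a symmetric
kernel is acausal (its precursor ripples precede the true onset), which
would break the sample-accurate onset contract of the trial timeline; the
first-order interpolator is causal, artifact-free at these sub-millisecond
delays, and the standard choice in real-time binaural engines.  Its mild
high-frequency attenuation at non-integer delays is irrelevant at the
grid ITDs involved.  The default head track is static at 0° (participants
face front); arbitrary yaw tracks load from CSV for testing.

Rendered trials return the stereo mix plus speech-only and babble-only
stems; the mix equals the sample-wise stem sum by linearity, which the
simulated listener uses to compute per-ear SNRs.

## Adaptive threshold and session design

The speech reception threshold (SRT) is estimated with single words from
0° in the four-source babble: SNR starts at 0 dB and follows a 1-up/1-down
rule in 2-dB steps (correct → −2 dB, incorrect → +2 dB).  A reversal is
recorded at the SNR where the step direction changes sign (the first trial
defines no direction); the track stops at 8 reversals and the SRT is the
mean SNR of the last 6.  The 1-up/1-down rule converges to the 50% point
of the *response* psychometric function — for a 4AFC task with guess floor
1/4, that is the SNR where 1/4 + 3/4·ψ = 1/2.

The main task runs three SNR conditions (SRT, SRT+3, SRT+6 dB) in three
blocks of two runs; all 6 block-order permutations are used across 12
participants (each twice).  Each run is a fresh 96-trial list: 12 ordered
adjacent-azimuth pairs × 8 trials, with each word group appearing exactly
twice per pair and the trial's two words drawn from the group without
replacement (the reference and target word always differ — identical words
would make the discrimination contrast untestable).  A legacy mode appends
one extra random trial per run (97 × 6 = 582 presented trials per
session), reproducing a quirk of the original implementation; the extra
trial is flagged and excluded from balance accounting but kept in the
analysis.  A response is valid only if it consists of exactly two word
clicks and one direction click; invalid trials are dropped before
analysis.  Scoring is order-matched: the first click is compared with the
reference word and the second with the target (word order is a modelled
predictor, so clicks must map to positions).  Each valid trial contributes
one localization row and two word rows to the long-format observation
table.  All session randomness derives from one master seed via a
documented per-run splitting rule.

## Simulated listeners

The geometry-driven listener assigns correct-response probabilities
p = floor + (1 − floor)·logistic(η), with η a linear function of the
trial's factors (mean location, SNR condition, direction for
localization; azimuth, SNR, word group for words) plus a per-participant
Normal(0, τ) intercept; wrong word clicks fall uniformly on the three
within-group foils.  Floors are 1/4 (word) and 1/2 (direction) to mirror
the forced-choice structure, and are set to 0 when a simulation must
generate exactly from a logistic model (parameter recovery, type-I-error
studies).  Default coefficients follow the magnitudes the test typically
produces: an inverted-U over mean location (peak log-odds ≈ 1.0 near the
midline), a U over azimuth, a strong SNR effect for words (log-odds ≈ 1.9
at +6 dB) and a weak one for localization; the direction coefficient
ships at 0 because the observed rightward bias has no mechanistic account.
The audio-driven listener identifies words in the rendered mix by template
correlation among the four group candidates and judges direction from the
change in speech-stem interaural level difference between the two words;
it exercises the DSP chain rather than the statistics.

With guessing floors active, simulated accuracies are a compressed-logit
transform of η, so fitted log-odds are attenuated relative to the
generative coefficients; recovery checks therefore use floor-0 profiles.
Passing tests on these simulations show the machinery is correct, not
that human data will show the same effect sizes.

## Statistical models

Both outcomes are Bernoulli and modelled with logistic mixed models:
a participant random intercept for localization, plus an optional
correlated random slope over the SNR factor for word discrimination (two
slope variances and intercept-slope correlations, parameterised by a
log-Cholesky factor).  Fixed factors are treatment-coded against fixed
reference levels: mean location −75°, azimuth −90°, SNR = SRT, direction
left, group = complex vowels; the intercept is the reference cell.

Estimation maximises the marginal likelihood with the random effects
integrated out by a Laplace approximation — per-participant posterior
modes by Newton iterations (vectorised across participants in the
scalar-intercept case), curvature correction −½ log det(ΣH) — with BFGS
over the joint fixed-effect/variance parameters.  For scalar-intercept
models an adaptive Gauss–Hermite quadrature (default 15 nodes, centered
and scaled at each participant's mode) is available as a cross-check; the
two agree within 10⁻³ in log-odds on the models tested, and with the
variance pinned at zero the fit reproduces the ordinary logistic MLE to
10⁻⁴.  Fixed-effect covariance is the inverse observed information with
the variance components held at their estimates (the same convention as
the reference mixed-model software); Wald CIs and p-values follow.
Convergence is judged by the optimizer or, when BFGS halts on
finite-difference precision loss, by a flat-gradient check; quasi-
separation (|log-odds| > 15) raises a warning rather than failing.

Model ladders are compared by likelihood-ratio tests (χ² = 2Δll, df =
parameter-count difference).  Post hoc pairwise contrasts cover all level
pairs of a factor (15 for 6 mean locations, 3 for SNR, 1 for direction,
21 for 7 azimuths), with Bonferroni correction using that family size;
interaction follow-ups contrast group pairs within each SNR (family = all
18 reported pairs).  On the latent logistic scale the residual variance is
fixed at π²/3 ≈ 3.29, giving ICC = τ₀₀/(τ₀₀ + π²/3) and the Nakagawa
R²: marginal = var(Xβ)/(var(Xβ) + τ̄ + π²/3), conditional adds τ̄ to the
numerator, where τ̄ averages zᵢᵀΣzᵢ over the sample for random-slope
models.  Generalized VIFs (Fox–Monette determinant ratio, reported with
the 1/(2·df) scaling) screen the fixed design for collinearity.

## Problem sizes and numerical choices

Verification simulations use sizes chosen to give stable Monte-Carlo
estimates at modest cost: 200 staircases for SRT convergence (mean within
1 dB of the analytic 50% point), 200 six-participant cohorts for the LRT
type-I rate, 50 cohorts of 24 participants × 576 trials for fixed-effect
coverage, and 12-participant cohorts for the qualitative accuracy-shape
checks.  Audio unit tests render at 16 kHz (the timing, level and ITD
contracts are sample-rate-free; 44.1 kHz remains the production default).
Newton inner iterations stop at step < 10⁻⁹; equalization treats a
zero-energy steady state as an error naming the offending token; staircase
ties cannot occur (steps are exactly ±2 dB).  Degenerate inputs (empty
HRIR grids, off-grid azimuths, non-adjacent trial azimuths, malformed
block orders, non-binary outcomes, rank-deficient designs) are rejected
with explicit errors.

## Known limitations

Synthetic tokens and babble are acoustic surrogates: they support
relative and structural claims (balance, levels, convergence, model
recovery), not absolute performance levels of human listeners with real
recordings.  The renderer claims only its documented contract, not
equivalence with any particular commercial binaural engine; front/back
cones are folded, not modelled.  Profile likelihood CIs, Bayesian fits
and GEEs are out of scope, as are room acoustics, headphone equalisation
and live head-tracker I/O.
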