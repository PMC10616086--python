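# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `tonecortex`, in the spirit of the methods notes
that accompany simulation-heavy analysis packages.

## The command-response model of pitch

Vocal pitch during Mandarin tone production is modelled in the
log-frequency domain as a superposition of a speaker baseline and the
responses of two laryngeal control mechanisms:

    ln F0(t) = ln Fb + Σ_i Ap_i Gp(t − T0_i)
                     + Σ_j At_j [Gt(t − T1_j) − Gt(t − T2_j)]

with the phrase mechanism's impulse response `Gp(t) = α² t e^{−αt}` (unit
area) and the tone mechanism's step response
`Gt(t) = min[1 − (1 + βt) e^{−βt}, γ]`, both zero for `t < 0`.  A tone
command is a signed rectangular drive `(At, T1, T2)`: positive commands
raise pitch (cricothyroid lengthens the folds), negative commands lower it
(thyroarytenoid shortens them).  For isolated syllables the phrase
component is dropped (`P = 0`); phrase commands are available for sentence
material.

The four Mandarin tones map onto canonical command patterns: a long
positive command (high-level tone 1), an early negative plus a late
positive command (rising tone 2), a long negative command (low-dipping
tone 3), and an early positive plus a late negative command (falling
tone 4).  The template amplitudes/timings in `fujisaki.tone_template`
realise this qualitative structure with amplitudes of 0.3–0.6 and command
spans proportional to the voiced duration; the literature gives the
structure but not numeric values, so the magnitudes were chosen once to
produce natural-looking contours (~±4 semitone excursions at Fb ≈ 120 Hz).

**Mechanism constants.** α = 3 s⁻¹, β = 20 s⁻¹, γ = 0.9 — canonical values
from the Fujisaki-model literature.  They are held fixed during inverse
fitting; only the baseline, amplitudes and timings are free.  This keeps
the inverse problem well-posed.

**Inverse estimation** (`FujisakiEstimator`): residuals are evaluated in
ln-Hz over voiced samples only; unvoiced gaps are never interpolated into
the objective (interpolation is used only to build the initial guess).
The fit is bounded nonlinear least squares (trust-region reflective, with
analytic Jacobians; the step response's γ-clamp zeroes the derivative in
the clamped region).  Commands are parameterised as (At, T1, ΔT = T2 − T1)
with ΔT ≥ 20 ms so T1 < T2 holds by construction.  Initialisation comes
from the tone template when a label is available, otherwise from signed
extrema of high-passed ln F0; eight seeded random multistarts around the
initial point replace the manual corrections of interactive Fujisaki
editors, and the best-RMSE solution wins (stopping early only when a start
reaches an exact, zero-residual fit).  When the number of tone commands is
not specified, J ∈ {1, 2} is chosen by BIC with ties toward the smaller J.
Contours with fewer than 10 voiced samples are rejected.

## Synthetic study conditions

The generator (`synthetic_data`) emulates the tone-production task: words
of 0.4–0.6 s separated by 0.4–0.6 s gaps, three repetitions per cue, an
unvoiced consonant prefix of 0.05–0.12 s, 60 trials per tone and 64
electrodes by default.  Per-trial contours are synthesized from the tone
template of the trial's label with amplitude jitter (CV 0.15), timing
jitter (SD 20 ms), a per-trial baseline Fb ~ N(120, 10²) Hz, ln-domain
noise (SD 0.02) and 10% random unvoiced dropout.

Electrode roles are mixed 15% positive-tuned / 20% negative-tuned / 15%
onset-only / 50% noise, loosely mirroring the reported prevalence of
tone-discriminant and positively/negatively tuned sites in laryngeal motor
cortex.  A tuned electrode's drive is the half-wave-rectified positive (or
negative) part of the summed command track, shifted by the neural latency
(−80 ms: motor cortex leads the acoustics) and convolved with a Gaussian
response kernel (width 100 ms ≈ 2σ); onset electrodes fire at each
acoustic onset; all tracks get unit Gaussian noise and are z-scored per
block.  Per-electrode gains are drawn uniformly in [0.5, 1.5] × 1.5
z-units per command unit, so that recovery analyses have a graded ground
truth to rank against.

What the generator does **not** emulate: 1/f broadband structure and
autocorrelated noise, cross-electrode noise correlations, behavioural
errors, coarticulation, session drift, or any nonlinearity beyond the
rectified drive.  Passing tests therefore demonstrate correctness of the
analysis machinery under the planted model, not performance on real
electrocorticography.

## Preprocessing

High-gamma extraction averages the Hilbert envelopes of eight log-spaced
Gaussian bands with centers 70–150 Hz, applied in the frequency domain
with bandwidths chosen so adjacent bands cross at half maximum (the
centers are standard; the widths are a convention).  Envelopes are
polyphase-resampled to 100 Hz and z-scored per (electrode, block).  Line
noise is removed with zero-phase IIR notches (−3 dB width 2 Hz) at 50, 100
and 150 Hz.  Epoch windows are half-open `[t_min, t_max)`, so the
(−0.3, 0.2) s selection window holds exactly 50 samples at 100 Hz.

## Electrode selection

*Speech responsiveness*: the mean high-gamma timecourse over real speech
onsets (window −300..+100 ms) is compared with the mean ± 5 SD of 1000
windows at random alignment times; an electrode is responsive if ≥ 100 ms
(10 consecutive samples) of the real mean falls outside that band.  The SD
is across the 1000 single random windows, making the 5-SD rule very
conservative; the false-positive calibration in the test suite confirms a
familywise rate indistinguishable from zero on pure noise.  Random
alignment times are not excluded from real-speech periods by default (an
exclusion radius is available), so detection requires speech to be sparse
relative to the recording — the calibration uses 100 onsets in a long
recording for that reason.

*Tone discrimination*: per-timepoint one-way ANOVA across the four tones
over −300..+200 ms, Bonferroni-corrected for (total electrodes × 50
timepoints), requiring ≥ 10 consecutive significant samples.  The
Bonferroni denominator takes the *total* electrode count as an explicit
argument so subsetting can never silently relax the threshold.

## Encoding models

Per electrode, a temporal receptive field `y(t) = Σ_f Σ_τ β_f(τ)·x_f(t−τ) + ε`
is fitted by ridge regression over the feature blocks: intensity (1),
binned pitch height (10), binned pitch change (10), binary pitch (1),
syllable onset (1), non-laryngeal articulator flag (1), tone command (1),
tone category (4).  Pitch height is ln F0, speaker-normalised (z-scored
over voiced frames) before binning; bins are equal-width between the 2.5th
and 97.5th percentiles with out-of-range values in the extreme bins and
all-zero rows on unvoiced frames.  Pitch change across a voicing boundary
is undefined and yields an all-zero row rather than 0.

The default lag window is ±0.4 s in 10 ms steps — symmetric so neither
feed-forward nor feedback timing is presumed.  Data are split into
contiguous 80/10/10% train/validation/test chunks (contiguous to avoid
autocorrelation leakage), the penalty (8-point log grid 10⁻²…10⁵) is
chosen per electrode on the validation chunk with ties toward stronger
regularisation, and the procedure repeats five times; reported R² is the
mean squared held-out Pearson correlation.  All models over one dataset
share a single design matrix and per-chunk Gram matrices, so drop-one
reduced models are solved exactly on sub-blocks — unique ΔR² (full minus
reduced, same folds) costs one Cholesky per penalty rather than a new
regression pass.  Negative ΔR² values are retained.

Permutation significance shuffles whole-syllable feature trajectories
across syllable tokens (all blocks jointly, truncating or zero-padding to
the target span), recomputes ΔR², and reports
`p = (1 + #{null ≥ obs}) / (n_perm + 1)`.

The tone-command feature is the rectangular signed amplitude A(t) (the
smoothed response T(t) is available behind a flag).  Because the planted
pitch contour is itself generated from the commands, the pitch-feature and
tone-category blocks share most of the command variance; the *unique*
tone-command contribution in synthetic data is carried by trial-to-trial
command jitter and is accordingly small in absolute terms (ΔR² of order
10⁻³) while still ranking electrode gains correctly.

## Tuning curves

Tone commands are discretised into 12 bins spanning the middle
99-percentile range: edges are empirical quantiles at levels
`0.005 + 0.99·(i−1)/12`, i = 1..13 (a literal variant with levels
`(i−1)/12 + 0.005` clamped at 1.0 is available for comparison; its top
level overshoots 1, which is why the rescaled form is the default).
Samples outside the outer edges are excluded; a value exactly on an
interior edge goes to the higher bin.  Tuning uses voiced speech samples
only.  The polarity is the sign of the OLS slope of (bin index, bin mean);
per the binning convention the regressor is the index, not the raw
amplitude.

## Decoding

Vowel-aligned epochs (−0.3..0.2 s) are scanned with 50 ms windows (5
samples; the 100 ms variant reported in some figure legends is exposed via
a flag, the 50 ms methods value is the default) in 10 ms steps.  For each
of the 6 tone pairs, an L2-penalised logistic regression on the
concatenated (electrodes × 5 samples) features is evaluated with nested
CV: stratified 5-fold outer folds grouped by cue (the three repetitions of
a cue never straddle a fold boundary), stratified 10-fold inner CV
selecting λ from a 7-point grid 10⁻³…10³ with ties toward stronger
regularisation, features standardised within each outer training fold.
Chance is 0.5 by class balance.  Single-dataset significance permutes
labels per window, re-using the per-fold penalty chosen on the observed
labels, with Bonferroni correction over the windows tested; a t-test
across datasets is provided for the multi-dataset case.

## Tone-space PCA

Trial contours (ln Hz) are proportionally time-warped to 40 samples and
decomposed with full-rank PCA after removing the mean contour (the
decomposition is exact: X = LWᵀ + μ with column-orthonormal W).  The
reported dimensionality is the minimal number of components reaching 95%
cumulative explained variance; four noisy tone archetypes yield ≤ 4.

## Validation problem sizes

The test suite validates the pipeline at the following scales, chosen to
exercise every statistical property at desk scale: 400 contours for the
inverse-fit recovery; 500 noise electrodes / 100-electrode injections /
200 null datasets for selection calibration; the 64-electrode, 240-trial
planted dataset (seed 0) for encoding, tuning and decoding recovery, with
the encoding permutation run at 50 permutations, a ±0.2 s lag window and a
4-point penalty grid, and decoding calibration at 3 datasets × 150 label
permutations over the pre-signal windows.  The encoding and tuning
recovery tests use the planted command tracks as features, isolating those
modules from inverse-fit error (which is measured separately); the
acceptance script instead runs the full chain with fitted commands on a
fresh 60-trial-per-tone dataset, with the encoding partition evaluated at
a ±0.2 s lag window (the planted-command variant is reported alongside).

## Known limitations

* Template amplitudes are qualitative; absolute command amplitudes are not
  calibrated to any speaker population.
* The permutation null for unique ΔR² shuffles all feature blocks jointly;
  per-block shuffling would give feature-specific nulls at higher cost.
* The speech-responsiveness statistic is insensitive when speech occupies
  a large fraction of the recording (the permutation SD then contains the
  response itself); this mirrors the conservative design of the original
  procedure.
* Decoding significance in single-dataset mode re-uses the observed-label
  penalty for the permutation refits; a fully nested null would multiply
  cost by the inner-CV factor with negligible effect on the null mean.
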