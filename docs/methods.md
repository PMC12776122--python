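# Methods

`aperislope` implements a time-resolved analysis of aperiodic (1/f) EEG
activity around visual conflict (congruency) manipulations, together with a
ground-truth generator that makes every stage testable as a parameter-recovery
problem. This note documents the model, the estimator, the generator, the
numerical choices, and the known limits of each.

## The aperiodic model

Broadband EEG power falls with frequency approximately as a power law,

    P(f) ∝ f^(−x)   ⇔   log10 P = −x · log10 f + offset,

so in log-log coordinates the spectrum is a line whose slope is the negated
aperiodic exponent x and whose intercept is the broadband offset. Steeper
(more negative) slope ↔ larger x ↔ relatively more low-frequency power,
conventionally read as a shift toward cortical inhibition. The package
estimates this slope *per time point within single trials*, so that
stimulus-locked, sub-second changes in x — e.g., transient post-stimulus
steepening, or conflict-dependent steepening that differs by the previous
trial's congruency — can be tested directly.

## Instantaneous slope estimation

1. **One-cycle wavelet power.** Each epoch (trials × 56 channels × 1024
   samples at 512 Hz, −500…1500 ms) is convolved with untapered single-cycle
   cosine/sine pairs at 2.5, 5, 7.5, 15 and 25 Hz (kernel length
   `round(fs/f)` samples, phase 2πk/L, 'same' alignment). The squared
   quadrature sum gives an instantaneous power estimate per frequency and
   sample. One-cycle kernels maximize temporal resolution at the cost of
   frequency resolution (bandwidth ≈ 2f), which is acceptable because the
   target is broadband slope, not narrowband power.
2. **Normalization.** By default power is expressed as a spectral density
   (µV²/Hz) by dividing each wavelet's output by its white-noise-equivalent
   bandwidth 2·fs/L. This matters: one-cycle bandwidth grows ∝ f, so
   *amplitude*-normalized power (kernels scaled 2/L, unit sinusoid → power
   1) of a 1/f^x process falls as f^(1−x) and a fit on it estimates −(x−1),
   not −x. `wavelet_power(..., normalization="amplitude")` exposes the
   amplitude convention for line components; the slope pipeline always uses
   density.
3. **ERP subtraction.** Before decomposition, the phase-locked average of
   each participant × (previous × current congruency) cell is subtracted
   from its trials. ERP transients contribute broadband power and otherwise
   bias the aperiodic fit; subtraction removes the phase-locked part while
   leaving single-trial non-phase-locked content untouched (checked by
   variance conservation in tests).
4. **Log-log fit with a censored-power clamp.** At every trial × channel ×
   sample, log10 power is regressed on log10 frequency by OLS over the
   fit-masked frequencies — 2.5, 5 and 25 Hz; the 7.5–15 Hz points are
   excluded as alpha-adjacent. Single-trial instantaneous power is
   approximately exponentially distributed around the true spectrum; its
   left tail (momentary near-zero quadrature power) is information-free but
   produces extreme negative log values and hence spurious slope
   excursions. Each (trial, channel, frequency) power trace is therefore
   left-clamped at 5% of its own epoch-mean power before the log — a crude
   censored-regression treatment. The clamp is scale-equivariant, leaves
   constant-in-time power untouched (exact collinear inputs stay exact),
   and biases the slope by < 0.05 for smoothly varying exponents; it does
   bias strongly non-stationary epochs (e.g., a hard mid-epoch exponent
   step) toward flatter values, because the epoch mean then overstates the
   locally available power. An absolute floor of 1e-12 µV² guards log(0).
5. **Smoothing and censoring.** Slope time courses are smoothed with a
   centered 5-point moving average (shrinking windows at the edges), then
   any trial whose smoothed slope exceeds ±4 at any channel × sample is
   censored. The censor scan excludes 200 ms at each epoch edge, where
   'same'-mode convolution against zero padding makes estimates meaningless
   (those samples are discarded by the −300…1300 ms analysis crop anyway).
   Under the default generator this retains ≈ 80–95% of clean epochs,
   and censoring responds to genuinely implausible exponents.
6. **Condition averaging.** Retained trials are averaged per participant ×
   previous × current congruency cell into slope maps
   (participant × cell × channel × sample).

### Known estimator limits (measured, not hidden)

- **Steep spectra.** For x = 3 the 25 Hz kernel (20 samples ≈ 39 ms) picks
  up enough leakage from the large low-frequency power to inflate its
  density estimate by ≈ 0.4 dex; the mean fitted slope is ≈ −2.72 rather
  than −3 (Welch on the same realizations: −2.92). Recovery for
  x ∈ {1, 1.5, 2} is accurate to ≈ 0.02. This is an intrinsic resolution
  limit of untapered one-cycle kernels, reported as-is by the acceptance
  suite.
- **Alpha leakage.** The 7.5–15 Hz fit exclusion removes the directly
  alpha-contaminated grid points, but a 10 Hz oscillation still leaks into
  the 25 Hz estimate with power gain ≈ 0.29 (the 39-ms kernel cannot
  resolve 10 from 25 Hz). At the generator's default alpha level
  (oscillation amplitude 0.3× the broadband SD — oscillatory alpha power
  comparable to the aperiodic alpha-band floor, typical of eyes-open task
  EEG) the induced slope shift is ≈ 0.07; an unusually large alpha
  (amplitude ≳ the broadband SD) shifts the slope by 0.5 or more. The
  exclusion protects against moderate, not arbitrary, alpha.

## Trial exclusion and behavioral analysis

Accuracy analyses drop practice trials and the first trial of each block; RT
and EEG analyses additionally drop error trials, trials following an error,
and trials beyond ±2.5 SD of the participant's mean RT. The outlier bounds
are computed once per participant, pooled over blocks, on the trials that
survive the other rules (the rule is not iterated; whether the SD is taken
before or after post-error removal is not externally fixed — this package
computes it after, and the filter is idempotent under that choice).
Artifact rejection flags any epoch whose peak-to-peak voltage exceeds 150 µV
on any channel within any full 600-ms window stepped by 100 ms from epoch
start (trailing partial windows are not evaluated).

RT and accuracy are analyzed as per-participant cell means in a 2×2
within-subject ANOVA (previous × current congruency). For 2×2 designs every
effect is exactly the squared paired t on the corresponding contrast, with
df = (1, n−1); partial η² = F/(F + df_err); Cohen's d = t/√n. Huynh–Feldt ε
is implemented generally but equals 1 for two-level factors. Tests are
two-tailed at α = 0.05; p-values are reported uncorrected (a
Benjamini–Hochberg helper exists but is off by default). Follow-up simple
effects are gated on a significant interaction.

## Data reduction

Spatial PCA treats electrodes as variables and participant × condition ×
timepoint rows (inside the −300…1300 ms crop) as cases; temporal PCA treats
decimated timepoints (every 10th sample ≈ 51 Hz, so a 160-ms window holds
8–9 points) as variables and participant × condition × electrode rows as
cases. Extraction is on the covariance matrix, because regression-method
scores are defined as data × unstandardized loadings × inverse covariance;
eigenvalues are rescaled to correlation metric (sum = n_vars) only for the
Empirical Kaiser Criterion, whose serial reference values

    l_ref_j = max( (1+√(n_vars/n_cases))² · (n_vars − Σ_{i<j} λ_i) / (n_vars − j + 1), 1 )

determine how many components to rotate. Varimax (Kaiser-normalized,
SVD-based, verified against a pairwise-Jacobi oracle) is applied to the
retained unstandardized loadings; components are sign-fixed so the
largest-|loading| variable is positive, ordered by explained variance, and
finally filtered by the 1/x rule: a component carrying less than 1/x of the
*extracted solution's* variance (x = EKC count) is dropped. Measuring the
share against the solution rather than the raw total is the only convention
under which a single dominant source survives its own filter (against the
raw total, a lone component would need 100% of the variance, unreachable
with any noise). With near-equal shares the filter deliberately drops below-average
components — on stationary data it can retain nothing, which is the
documented degenerate outcome.

Spatial components are named by the scalp region (frontal / central /
occipital / left- / right-temporal) of their peak-|loading| electrode.
Temporal components are summarized by the FWHM of their loading curve
(linear interpolation to the half-maximum crossings nearest the peak; a
side that never crosses is bounded by the crop edge and flagged truncated).
The analysis windows are consecutive 160-ms spans anchored at stimulus
onset, kept only if fully inside the crop: [−160,0], (0,160], …,
(1120,1280] — the pre-stimulus window closed, post-stimulus windows
lower-exclusive. The 160-ms default matches the mean temporal-component
FWHM the package's own simulations produce (~155 ms at moderate sizes); the
width is a configuration parameter, not re-derived at run time.

Statistics on windowed scores: (a) baseline contrasts — paired t of each
post-stimulus window against [−160,0] on condition-averaged scores, per
component; no baseline subtraction is ever applied to the data themselves;
(b) per component × window 2×2 ANOVAs with gated follow-ups, as in the
behavioral analysis.

## The synthetic generator

Each participant's epochs are built as

    data(trial, ch, t) = Σ_g w_g(ch) · s_g(t; x_g(t, condition)) · A_bg
                         + w_occ(ch) · A_α sin(2π·10·t + φ_trial)
                         + ERP_cond(ch, t) + ε(ch, t)

with three independent background sources g ∈ {frontal, central, occipital}
weighted by Gaussian scalp maps (σ = 0.45 head radii) on a schematic 56-
channel BioSemi-style layout (frontal-pole row excluded). Colored noise is
synthesized exactly in the frequency domain (|A(f)| ∝ f^(−x/2), Gaussian
spectral coefficients, zero DC, unit variance); a time-varying exponent uses
overlap-add of 500-ms stationary segments with a 50% sqrt-Hann crossfade,
which keeps variance flat across seams but mildly decorrelates content at
periods comparable to the segment length — another reason recovery tests for
*constant* x use the exact single-shot path.

Defaults mirror the study design they emulate: 49 participants, 240 trials
per previous × current cell over 2 blocks (960 experimental trials plus 8
practice trials per block), 512 Hz, −500…1500 ms epochs, baseline exponent
1.5. Scale choices: background 10 µV, sensor noise 2 µV, alpha 3 µV
(occipitally weighted, random phase per trial), ERP ~5 µV with early
occipital, mid central-negative and late central-positive deflections (the
late one larger and later for incongruent trials); 2% of trials receive a
250 µV step-like artifact on one random channel so rejection has real work.
Participant random effects: RT offset SD 40 ms; per-region exponent offset
SD 0.15 (regional individual differences — this is what gives the spatial
PCA its three-factor covariance structure rather than one global factor).

Programmed dynamics (the ground truth downstream stages must recover):
stimulus-evoked steepening with staggered regional time courses — occipital
Δx = +0.35 over 0–350 ms, central +0.30 over 100–550 ms, frontal +0.25 over
200–800 ms (raised-cosine ramps of 100 ms) — plus a conflict effect,
frontal Δx = +0.15 on incongruent trials preceded by congruent trials
(100–500 ms). The conflict-only-after-congruent structure produces a
current-congruency main effect, a previous × current interaction, and the
congruency-sequence (CSE) follow-up pattern. Behavioral cells are drawn
from per-cell RT means (635/663/649/650 ms, residual SD 120 ms) and error
probabilities (2.4/3.8/2.6/2.8%), i.e., a ~15 ms congruency effect that is
present after congruent and absent after incongruent trials. Trial
sequences are balanced exactly by constructing a random Eulerian circuit on
the two-state congruency transition multigraph, so each previous × current
cell occurs exactly n_trials_per_cell times per participant.

What the generator does **not** emulate: ocular and muscle artifacts,
electrode drift, line noise, volume-conducted global fields beyond the
three regional sources, spectral knees, heavy-tailed RT distributions, and
any real stimulus content. Passing recovery tests therefore demonstrates
that the estimator and reduction machinery are correct and calibrated under
the stated statistical structure — not that real recordings satisfy that
structure.

## Simulation sizes

The defaults above are the emulated study's scale. The heavy end-to-end
recovery checks run at 49 participants with 10 trials per cell (42
experimental trials per participant) and 20 seeds, and the PCA-recovery
checks at 3 participants × 6 trials per cell over 50 seeds. The sizing
follows a power analysis of the conflict design: programming the conflict
shift only in the incongruent-after-congruent cell (the only way to obtain
the "simple effect present only after congruent trials" signature) makes
the current-congruency main effect half the size of the simple effect, and
10 trials per cell is the smallest count at which that half-size effect
clears per-window power ≈ 95% at n = 49, keeping the 20-seed sweep within
minutes on one core. The statistical-calibration checks use 10 000 null
draws at n = 49.

## Reproducibility

All randomness flows from `numpy.random.SeedSequence` children of a single
integer seed (behavior stream, one stream per participant, a dedicated
stream for participant-level random effects), so datasets are bit-identical
across runs and machines for a fixed configuration, and the pipeline
manifest records every stage parameter, the seed, per-participant retention
counts, and library versions.
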