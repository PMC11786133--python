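# Methods and design notes

## Band prescription

A DFCRS prescription is four frequency endpoints flanking the matched
tinnitus pitch *p*: lower band (p·2^(−g−1/3), p·2^(−g)), upper band
(p·2^(g), p·2^(g+1/3)), with guard gap g in octaves (default 0, bands
abutting the pitch). The constraints "below and above the pitch",
"surrounding" and "each 1/3 octave" determine this geometry uniquely up to
the guard gap; `guard_octaves` is exposed so a notch at the pitch itself can
be explored without changing the code. Pitch-matching psychophysics are out
of scope: the pitch is an input.

## The boost stage

"Dynamically increasing the intensity of both bands by 10 dB" is read as a
constant *relative* gain applied frame-wise, so the absolute boost follows
the music's instantaneous in-band content. Implementation: STFT
analysis/overlap-add with a Hann window of 2048 samples at 44.1 kHz (the
window length rescales with sample rate to keep ~46 ms duration, rounded to
a power of two), hop = window/4 (75 % overlap, COLA-exact reconstruction via
`scipy.signal.ShortTimeFFT`). The spectral gain mask is 10^(G/20) in-band
and 1 outside, with raised-cosine transitions of 1/24 octave *centered on
the band edges* (weight 0.5 at the edge). Centering the taper halves the
in-band average loss relative to an inside-the-band taper: broadband
material measures ≈9.9 dB of band-integrated gain instead of ≈9.4 dB, while
a tone at a band center measures 10.0 dB and tones more than 1/6 octave
outside are untouched well below 0.1 dB.

Numerical/degenerate-input choices:

* **Limiter.** A per-sample soft knee (tanh) engages only above
  10^(−1/20) ≈ 0.891 full scale (1 dB headroom) and asymptotes at 1.0, so
  it is exactly the identity on moderate-level material — verification
  fixtures are unaffected and measured band gain is not eroded.
* **Nyquist.** Processing refuses when sample_rate ≤ 2·f2_hi, naming the
  offending endpoint; resampling is explicit opt-in
  (`EngineConfig.allow_resample` / `--resample`), via polyphase resampling
  to the smallest standard rate above the requirement. No silent resampling.
* **Short inputs** are zero-padded to one analysis window and truncated
  back; empty audio is an error. Stereo is processed per channel with
  identical filters.
* **Gain measurement** (`measure_band_gain`) integrates Welch PSDs
  (nperseg ≤ 8192) over the band and reports 10·log10 of the power ratio;
  zero reference band power is an explicit undefined-gain error.

## Audiometry and eligibility

PTA is the arithmetic mean of air-conduction thresholds at 0.5/1/2/4 kHz;
all four frequencies are required, anything else present is ignored. The
worse ear is the ear with the larger PTA (ties give the same value either
way). Enrolment: age ≥ 18, worse-ear PTA ≤ 55 dB HL (the boundary itself is
eligible), and none of the exclusion diagnoses; the verdict lists every
failed rule. PTA is kept unrounded internally and formatted to two decimals
only for display.

## Instrument scoring

All six instruments are validated sums (THI 25×{0,2,4} → 0–100; HADS 14×0–3
with 7-item anxiety/depression subscales; AIS 8×0–3 → 0–24; FTQ 17×{0,1} →
0–17; TCS 13×0–4 → 0–52; VAS single 0–10). Missing items are an error by
default; opt-in prorating rescales the sum of answered items to the full
item count. The HADS anxiety-item positions are configuration, shipped with
the conventional alternating (odd-item) assignment — a convention of the
published instrument, not a claim about this trial's administration. THI
subscale assignment is not exposed by default (total only); users with the
standard functional/emotional/catastrophic mapping can compute subscales
from the raw items.

## Synthetic cohort generator

The generator produces cohorts with exactly the statistical structure the
analysis assumes, so every analysis stage is testable without access to
patient data (which was never deposited).

* **Design:** 107 DFCRS + 77 UM subjects, visits at days 0/30/60/90 (day
  coding chosen because the default slope −0.119/day × 90 days ≈ −10.7 THI
  points, the right order of magnitude for the observed median decline;
  per-month coding is not).
* **THI:** additive random-intercept Gaussian model; fixed-effect defaults
  are the fitted clinical estimates (intercept 56.13335, time −0.119/day,
  DFCRS −16.6469, plus the small nonsignificant gender/age/location/course
  effects). These clinical values are *simulator defaults*, not quantities
  the package claims to reproduce from data.
* **Variance components** default to sd_intercept = 8 and sd_resid = 4 THI
  points. These are deliberately modest: they keep every generated
  trajectory strictly inside the bounded 0–100 scale, so the mandated
  clipping is a no-op and the generator remains exactly the model the mixed
  model assumes — which is what makes unbiased parameter recovery a fair
  test of the fitting code. Real cohorts are more dispersed (baseline THI
  IQR ≈ 33–66 implies a between-subject SD nearer 20); with such spread the
  floor at 0 truncates late-visit scores of responders and biases a naive
  Gaussian fit, a fidelity/self-consistency trade-off the user can explore
  by raising the SDs.
* **Baseline covariates:** age truncated-normal (mean 47, SD 14, ≥18);
  gender ≈ 52 % male; location 42/5.5/52.5 % uni/in-head/bilateral; course
  and pitch log-normal around medians 10 months and 6350 Hz; severity
  grades 15/35/30/20 %; 30 % intermittent; daily listening hours log-normal
  around a 2.2 h/day median (the recommended dose was ≥ 2 h/day). Where the
  trial reports only medians/IQRs these shapes are the package's own
  choices.
* **Outcome:** 3-category logit (reference worsened) with linear predictors
  in daily hours and severity dummies; default slopes are the logs of the
  reported odds ratios (time: 13.07 relief, 64.78 disappeared; severity
  II–IV likewise). The two intercepts are *calibrated at generation time*
  by root finding (`scipy.optimize.fsolve`) on the drawn covariates so the
  expected marginal split matches 8/93/6 of 107 — a documented procedure,
  not a hidden constant; the solved intercepts are recorded in the cohort
  metadata. Because the time coefficients are positive and ordered, mean
  daily hours are ordered worsened < relief < disappeared by construction.
* **Secondary scales** are noisy monotone transforms of the same THI
  trajectory (shared latent severity), with slopes chosen so baseline
  medians land near the reported Table-level values. No joint model is
  claimed.
* **Note on baseline THI:** the additive model (no group×time interaction)
  with the clinical coefficients implies a DFCRS baseline mean near 39, not
  the observed 48 — the fitted group effect averages over all four visits.
  A generator matching both the observed baseline medians and the additive
  coefficients does not exist; this package prioritizes the additive model
  because parameter recovery of those coefficients is the generator's
  stated purpose.
* **Reproducibility:** a seed is mandatory; identical seeds give
  byte-identical CSVs; the seed and full configuration are recorded in the
  output metadata.

What passing tests on these cohorts do **not** show: robustness to
floor/ceiling effects, informative dropout, visit-time jitter,
non-Gaussian score distributions, or confounding from the nonrandomized
arm assignment — none of which the generator emulates.

## Analysis pipeline

* **Baseline tests:** chi-square for categoricals (with Yates continuity
  correction on 2×2 tables, matching R's `chisq.test` default); for
  continuous covariates a per-group Shapiro–Wilk gate at α = 0.05 chooses
  ANOVA (all groups normal) or Kruskal–Wallis. The gate is explicit and
  logged in the result rows; constant covariates return a flagged
  degenerate row rather than an error.
* **Mixed model:** `statsmodels` MixedLM, random intercept per subject,
  REML; reference levels UM/male/unilateral so improvement yields negative
  time and group estimates. Degrees of freedom use a containment-style
  rule (between terms: n_subjects − n_between_params; within terms:
  n_obs − n_subjects − n_within_params), flagged as
  `df_method="containment"`; a Satterthwaite approximation is not provided
  by the backend, and the df only affect p-values, not estimates. A zero
  random-intercept variance is flagged `singular`, not silenced.
* **Multinomial model:** `statsmodels` MNLogit on the DFCRS arm's
  3-category outcome, reference "worsened". Bidirectional stepwise search
  from the intercept-only model over the candidate covariates, scored by
  AICc by default (AIC/BIC selectable; the small event counts make the
  small-sample correction the sensible default). Selection only chooses the
  covariate set: refitting the selected set without selection reproduces
  the coefficients exactly. ORs use Wald 95 % intervals on the log scale
  (consistent with the wide asymmetric intervals such models print);
  quasi-separation (|coef| > 20) is flagged, with NaN/infinite intervals
  reported as such. Treatment time is modeled continuously in hours/day.
* **Contrasts:** paired two-tailed t tests over all six visit pairs, with
  listwise deletion per pair and per-pair n reported; all-zero differences
  return t = 0, p = 1 rather than NaN.
* **Proportions:** percentages rounded to one decimal; pooled categories
  supported (e.g. relief-or-disappeared).

## Problem sizes

The verification suite uses 1–5 s synthetic tones/noise at 44.1 kHz for
the DSP checks, 1000 random pitches for the band-geometry property, 40
probe tones for the gain profile, and 200 simulated cohorts of n = 184 for
the mixed-model parameter-recovery study; these sizes give Monte-Carlo
standard errors small enough to detect sub-point biases in the group
effect while keeping the whole suite to about a minute of CPU.

## Known limitations

* The exact clinical endpoint algorithm was never published beyond its
  existence; the symmetric log-frequency construction here is the unique
  reading of the published description, and `guard_octaves` covers the
  remaining freedom.
* WAV I/O reads PCM16/24/32 and float; writes PCM16 or float32 (24-bit
  inputs are written back as float32).
* The package does not implement notched (attenuating) music therapy,
  intermittent masking, coordinated-reset neuromodulation, real-time
  playback, or the clinical estimates themselves (no patient-level data
  exist to fit).
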