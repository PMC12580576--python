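# Methods

`mpiaf` simulates and analyses an individual-differences experiment that
asks whether a trait-like property of resting-state EEG — the individual
alpha frequency (IAF) — predicts the magnitude of eight motion-position
illusions (MPIs). Because the interesting quantities are all latent
person-level traits, the package is built around a synthetic cohort with
known ground truth: every estimator in the chain can be checked against
the values it is supposed to recover.

## The observer model

Each simulated observer carries:

* **true illusion magnitudes** for the eight tasks — flash-lag (FLE),
  luminance flash-lag (LUM-FLE), Fröhlich (FE), flash-drag (FD),
  flash-grab (FG), motion-induced position shift (MIPS), twinkle-goes
  (TG) and flash-jump (FJ). Units are the tasks' native ones: arc-length
  degrees of visual angle (dva) for the rotational tasks (FLE, FE, FG),
  plain dva for the translational tasks, % luminance contrast for
  LUM-FLE.
* **psychophysical response parameters**: a cumulative-normal
  psychometric slope `sigma` per task, a lapse rate in [0, 0.05], and a
  direction-independent response bias.
* **EEG spectral parameters**: a 1/f aperiodic background (offset,
  exponent, in log10 power coordinates) and a single Gaussian alpha peak
  (centre frequency = the observer's true IAF, height, width).

Magnitudes, alpha centre frequency and age are drawn jointly from a
multivariate Gaussian so that correlations can be planted and their
recovery tested; all other parameters are independent. Latent draws are
clipped to physical ranges (alpha CF to [8, 12.5] Hz, lapse to [0, 0.1]);
with the default marginals clipping is rare and its effect on planted
correlations negligible (verified: a planted 0.5 is realized as 0.499 at
n = 20 000).

Default marginals follow the magnitudes observed in the study population
(e.g. FLE 1.68 ± 2.14 dva, FG 4.42 ± 1.51 dva, alpha CF 10.34 ± 0.83 Hz,
age 25.6 ± 6.9 y). They are configuration, not claims: any mean/SD can
be overridden per run.

### What the EEG generator does and does not emulate

Epochs are synthesized by spectral shaping: complex Gaussian
coefficients scaled by the square root of the model's linear power
target, inverse-FFT'd to 60-s microvolt traces at 256 Hz, 19
parieto-occipital channels, five eyes-closed trials per observer. All
channels share the observer's spectral parameters up to a small fixed
per-channel jitter of the alpha CF (SD 0.05 Hz). The generator is
calibrated (signal variance equals the integral of the power target;
Welch log-PSD tracks the model within ~0.02 log10 units RMS after
averaging).

The default alpha peak height is 1.5 log10 units over the background
with a 0.8 Hz Gaussian SD — a strong, single eyes-closed peak. This is
the regime the source population showed (a clear alpha peak in every
participant), and it reproduces the characteristic ~0.15 Hz downward
bias of the fixed-band centre of gravity relative to the peak frequency.

Deliberately not modelled: eye/muscle/heart artifacts, non-stationarity,
channel topography, volume conduction, eyes-open data, multiple or
split alpha peaks. Passing recovery tests therefore demonstrates the
estimators' correctness under clean single-peak spectra, not their
robustness to artifactual real-world recordings (the artifact-rejection
steps of a real pipeline — ICA, channel interpolation — are out of
scope here because synthetic data never needs them).

## Behavioural simulation

Staircase tasks (FLE, LUM-FLE, FE, FD, TG) use 1-up/1-down adaptive
staircases with the published designs:

| task | staircases | trials | start | step schedule |
|------|-----------|--------|-------|---------------|
| FLE | 2 directions x 2 starts | 40 | ±28° polar | 4° → 2° after 3 reversals |
| LUM-FLE | 2 x 2 | 40 | 100% / 10% contrast | 5% fixed |
| FE | 2 x 2 | 40 | ±45° polar | 6/3/2/1° per reversal |
| FD | 2 x 2 | 52 | ±3.52 dva | 0.44 → 0.22 after 4 reversals |
| TG | 2 noise conditions x 2 x 2 | 40 | ±4.52 dva | 0.45 dva fixed |

A "+1" response (stimulus judged beyond the PSE) moves the value down by
the active step; a reversal is a change of response sign relative to the
immediately preceding response, and a scheduled step-size change applies
from the move that follows the threshold reversal. Staircases are
statistically independent given the observer, so interleaving is not
simulated. The TG illusion is modelled as present only on dynamic-noise
trials; static-noise staircases converge on the observer's bias alone,
so the dynamic-minus-static difference of half-difference magnitudes
recovers the planted value.

Adjustment tasks report an endpoint with Gaussian noise: MIPS (60
trials) and FJ (48 trials, 3 of them attention checks) report twice the
per-element shift — mirroring the halving in the corresponding
estimators — and FG (200 trials: 30 per inducer duration plus 20
no-target catch trials) reports a signed arc-length error. Observer
compliance (attention-check failure and invalid-response probabilities)
defaults to 0 and is configurable to exercise the exclusion rules.

## Magnitude estimation

Per staircase, the PSE is the mean presented value over the final 20
trials (FLE, LUM-FLE, FD) or final 10 (FE, TG). PSEs are averaged
within motion direction, and the magnitude is the half-difference
between opposing directions — biases cancel, and the halving keeps the
magnitude at its true scale. FLE/FE values are converted from polar
angle to arc dva at the task radii (12.15 and 10.5 dva).

Convergence requires each within-direction staircase pair (started above
vs. below the PSE) to agree within the task's threshold — 3.18 arc dva
(FLE), 30% contrast (LUM-FLE), 8.25 arc dva (FE), 3.5 dva on final
staircase values (FD), 1.48 dva (TG). Thresholds are exclusive: a
difference exactly at the bound converges. Additional rules: FE
observers pressing one key on ≥ 80% of trials in two or more staircases
are excluded; MIPS trials with an absolute reported offset ≥ 10 dva are
outliers; FJ drops per-trial effects beyond 3 SD of the observer's mean
and excludes observers failing all three attention checks; FG excludes
observers failing > 20% of catch trials or giving > 18 invalid
responses. For two-session observers the magnitudes of converged
sessions are averaged, falling back to the sole surviving session.

Every estimator is verified bit-for-bit against a brute-force,
explicit-loop recomputation in the test suite.

## IAF estimation

Recordings are band-passed 1–40 Hz (4th-order Butterworth, zero-phase),
downsampled to 256 Hz if needed, and trimmed to 60 s. PSDs use Welch's
method with 4-s Hamming windows at 50% overlap (0.25 Hz resolution;
the source algorithm does not publish its Welch segmentation, so these
values are fixed in `SpectralSettings` and reported with results).

* **PAF**: Savitzky–Golay smoothing (11 bins, order 5) of the log PSD
  over 7–13 Hz, then the frequency of the maximum — accepted only when
  the maximum is unique and interior (edge maxima mean a monotone
  spectrum; ties are ambiguous). Smoothing operates on log power.
* **COG**: power-weighted mean frequency over the fixed 7–13 Hz window
  on the smoothed *linear* power. The fixed window gives COG a
  systematic downward pull from the 1/f background (~0.15 Hz at default
  peak strength) — exactly the bias the parameterized measure corrects.
* **F_PAF**: per 60-s trial, the channel-averaged log spectrum over
  2–20 Hz is decomposed into an aperiodic line plus one Gaussian peak
  (robust line fit, flatten, Gaussian fit constrained to CF ∈ [7, 13]
  Hz and full width 0.5–12 Hz ⇒ Gaussian SD 0.25–6 Hz, joint
  refinement). Fits with R² < 0.6, or no candidate peak above 2 SD of
  the flattened spectrum, contribute no peak. Accepted trial CFs are
  averaged (an alternative reading — take the single largest-power peak
  across trials — would discard data and is not used).

Channel aggregation requires ≥ 9 of the 19 parieto-occipital channels
(≥ 2 of 3 for the O1/Oz/O2 subset); otherwise the measure is missing.

## Statistics

* **Spearman rho**: midranks + Pearson, p from the t approximation with
  n − 2 df (adequate in the n ≈ 60 regime this targets); pairwise-
  complete deletion with per-pair n recorded.
* **BCa bootstrap** (default B = 1000): paired row resampling, bias
  term from the strictly-less-than bootstrap fraction, acceleration
  from leave-one-observer-out jackknife skewness. Degenerate bootstrap
  distributions fall back to the percentile interval with a warning.
  Verified coverage at nominal 95%: 0.92–0.98 across 500 bivariate-
  normal replicates at n = 60.
* **Holm correction** over an explicit family size (55 for the full
  8 + 3 battery, 28 illusions-only); simulated family-wise error under
  a global null stays ≤ 0.07.
* **Age-partialled variant**: first-order partial correlation on ranks.
* **Disattenuation**: rho / sqrt(rel_x · rel_y), descriptive only;
  out-of-range values are flagged, not truncated. Reliabilities are
  config inputs (IAF defaults to 0.87, a published eyes-closed
  test-retest value).
* **Power analysis**: the exact sampling density of Pearson's r under
  bivariate normality (Gaussian hypergeometric form, evaluated in log
  space and integrated adaptively), with the null critical value from
  the t transform. This reproduces the a-priori calculation exactly
  (n = 59 for 90% power at rho = 0.37, one-tailed alpha 0.05; power
  0.910 at n = 61) and matches a 10^6-replicate Monte-Carlo oracle
  within 0.005. Inference in the battery uses Spearman while the power
  analysis targets Pearson's exact distribution — the same mismatch the
  original calculation makes, retained deliberately.

## Reproducibility and numerical choices

One master seed spawns fixed, named substreams (cohort, eeg, staircase,
bootstrap), so each stage is independently reproducible and identical
seeds yield bit-identical cohort tables, recordings and reports.
Recordings are written as 16-bit EDF (per-channel physical range set
from the data, round-tripped through the 8-character header fields so
readers reconstruct the same scale) with a JSON ground-truth sidecar;
quantization error is bounded by two digitization steps and covered by
a round trip through MNE's independent EDF reader.

Problem sizes in the shipped tests are the package's own choices:
parameter-recovery suites use 20–200 observers, 200 staircase runs per
task, 500 replicates for coverage/FWER simulations, and a 10^6-sample
power oracle — large enough that the checked tolerances (0.25 Hz MAE,
one final step, ±0.005 power, 0.92–0.98 coverage) are meaningful.

Known limitations: no eyes-open condition; no individualized alpha band
for COG; no psychometric-slope estimation (the measured studies did not
fit slopes either); adjustment-task noise is Gaussian on the endpoint
rather than arising from a process model; disattenuation can exceed 1
in small samples and is reported as such.
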