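# Methods

This note documents the model behind `hdieeg`, the parameter choices that
matter, the simulator's scope, and the numerical decisions made where the
design was genuinely open. It states no empirical result that the test
suite and `scripts/acceptance.py` do not themselves compute.

## Signal model and processing chain

The target signal is an 8-channel scalp EEG (prefrontal AFz/AF3/AF4/AF7/AF8
and parietal Pz/P3/P4, left-mastoid reference, 125 Hz), carrying
band-limited cortical oscillations on a 1/f background, contaminated by eye
blinks on the frontal row and by occasional non-physiological transients.
Processing order is: band-pass → notch → blink detection/correction →
1-s epoching → three-criterion rejection → per-epoch band power → indices.
Re-referencing is not performed; the mastoid reference of acquisition is
kept as-is.

### Filtering

* Band-pass: Butterworth, design order 5, 2–30 Hz, applied
  forward–backward (`sosfiltfilt`). Offline analysis permits zero-phase
  filtering; the quoted −3 dB points (2 and 30 Hz) are those of the
  single-pass design, and the effective magnitude response is its square.
* Notch: second-order IIR notch at 50 Hz with Q = 30 (≈1.7 Hz −3 dB
  width), also zero-phase. Only the center frequency is dictated by the
  method; Q = 30 is this package's choice — narrow enough to leave the
  26–30 Hz upper beta edge untouched at 125 Hz.

### Blink handling

Blink detection is a subject-adaptive statistical threshold rather than a
fixed microvolt bound: the detection channel (default AFz) is low-passed at
6 Hz, standardized by median/MAD (robust to the blinks themselves), and
samples with |z| > 4 are marked, dilated by 100 ms per side, with gaps
under 50 ms merged. All constants are configurable; the defaults give
≥80% recall on the simulator's 150 µV templates with essentially no false
events at the calibration noise level (verified in the test suite).

Correction is a multichannel Wiener filter: with `Ra` the channel
covariance over blink-marked samples and `Rc` over clean samples, the
artifact estimate for a sample vector `x` is `(Ra − Rc) Ra⁻¹ x`, which is
the MMSE estimate when artifact and brain signal are uncorrelated. The
estimate is subtracted inside marked intervals only, with a 50 ms linear
cross-fade at interval edges so the correction introduces no step; `Ra` is
diagonally loaded (`1e-6 · trace/N`) for invertibility and the rank is not
truncated. A second pass over already-corrected data changes blink-interval
energy by well under 10% of the original artifact energy (the filter
re-estimates to ≈0 once `Ra ≈ Rc`).

### Epoching and artifact rejection

Non-overlapping consecutive 1-s epochs; a trailing partial epoch is
discarded. Three per-channel criteria, OR-ed over channels (any-channel
contamination invalidates a field-power average over those channels):

| criterion | statistic | bound |
|---|---|---|
| threshold | max absolute sample | 80 µV |
| trend | OLS linear slope vs time | 20 µV/s |
| jump | max sample-to-sample difference | 25 µV |

All bounds are strict (equality is not flagged, per "exceeding"). "Trend"
is ordinary least squares per channel — the standard linear trend
estimator. Removed epochs leave gaps in the index series; nothing is
interpolated. Rejecting *every* epoch is an error, not an empty result.

## Spectral estimation

**IAF.** Welch spectrum of the eyes-open rest run (Hanning, 1-s windows =
1 Hz resolution, 50% overlap), averaged over the parietal channels (alpha
is posterior-dominant; the channel set is configurable). The IAF is the
largest strict local maximum in 8–13 Hz, refined by parabolic
interpolation of log-power over the three surrounding bins. A candidate
peak must rise 1.25× above the within-range median power; the factor sits
well above the ≈10% fluctuation scale of a one-minute Welch average, so a
structureless spectrum raises "no alpha peak" instead of silently
returning a default. Band anchors: theta [IAF−8, IAF−4), alpha
[IAF−2, IAF+2), beta [IAF+2, IAF+20); IAF ≤ 8 Hz is rejected because the
theta band would reach DC. The anchored theta (2–6 Hz at IAF 10) is
implemented as defined, not widened to a conventional 4–8 Hz theta.

**GFP.** Per epoch and channel the band-restricted mean-square amplitude
is computed spectrally: Hanning-taper, FFT, sum one-sided power over bins
in [low, high), normalize by `N·Σw²`. By Parseval this equals the
time-domain mean square of the band-limited signal while avoiding
per-epoch filter transients; a unit-amplitude in-band sinusoid yields
0.5 µV² within windowing tolerance. Half-open intervals keep the shared
alpha/beta edge (IAF+2) unambiguous. The regional GFP is the mean over the
region's channels (N = 5 frontal, N = 3 parietal).

## Indices and normalization

`workload = frontal-theta / parietal-alpha`, `attention = frontal-beta /
frontal-theta` (the inverse theta–beta ratio), `HDI = workload −
attention`, all per epoch. Denominators below 1e-12 µV² drop the epoch
with a log entry rather than producing infinities. HDI is z-scored against
the kept-epoch statistics of the same scenario's focused baseline run.
Indices are computed per epoch and only then aggregated to segments
(preserving the method's 1-s time resolution); whether to normalize
workload/attention separately is left to the caller — HDI normalization is
the default output.

## Synthetic data: what it emulates, what it does not

Each simulated channel is a sum of (a) per-(band, region) oscillations —
by default narrowband-filtered Gaussian noise (±1 Hz around the band
center: theta at IAF−6, alpha at the IAF, beta at IAF+11) so spectra
resemble EEG, with a pure-tone mode for closed-form tests; amplitudes are
sinusoid-equivalent (an entry A contributes ≈A²/2 µV² of band power) —
(b) 1/f Gaussian noise (exponent 1.0, 3 µV RMS), and (c) 400 ms
raised-cosine blinks at 150 µV on the AF row (10% on parietal sites) at
0.2 Hz. Channels within a region share each band's source, which is the
regional-synchrony idealization GFP summarizes. Default band amplitudes
(µV): frontal theta 4, parietal alpha 6, frontal beta 3, plus weaker
cross-region terms (frontal alpha 2, parietal theta 1.5, parietal beta 1).

Cohorts draw a per-subject IAF uniform in (8.6, 12.4) Hz, jitter
amplitudes lognormally (σ = 0.1), and scale band amplitudes per condition;
the default condition set encodes a graded secondary-task load — Focused
(×1), ACPT (theta ×1.1, beta ×0.95), Matrix (×1.25, ×0.9), SURT (×1.4,
×0.8) — plus a focused Baseline run for normalization. A behavioral
covariate generator attaches, e.g., a horizontal-gaze-SD proxy with a
prescribed within-subject correlation to any per-segment series.

Not emulated: volume conduction and realistic cross-channel mixing,
non-stationary artifact regimes, muscle/EMG contamination, saccadic
potentials, or driving dynamics. Passing tests therefore demonstrate that
the chain recovers what it assumes — calibrated band powers, blink
geometry, injected effects — not that it is robust to every failure mode
of real recordings.

## Validation design and problem sizes

The rejection bounds are recovered behaviorally by bisecting constructed
epochs (constant, ramp, step) against the flag predicates to 1e-3
precision; `scripts/acceptance.py` reports exactly these three bisections.
The cohort-level checks run the full chain at sizes chosen to keep the
suite at desk scale while leaving the conclusions comfortably powered: 200
subjects with 60-s segments for the effect-direction check, 100 + 100
replicate n = 25 cohorts with 12-s segments (blinks disabled, band schemes
taken from the cohort's ground-truth IAFs) for Friedman power and null
level, and 100 seeds × 8 subjects × 8 segments for repeated-measures
correlation recovery at ρ = 0.6.

## Statistics layer

Shapiro–Wilk on both samples gates Student's t (both p > α) versus
Mann–Whitney U; a Wilcoxon signed-rank alternative is available behind a
flag for paired designs, with Mann–Whitney kept as the named default.
Friedman's χ² comes from the standard rank statistic (an all-tied table is
defined as χ² = 0); the reported effect size is Kendall's
W = χ² / (n(k−1)), the rank-concordance analogue, clearly labeled as such.
Repeated-measures correlation follows the Bakdash–Marusich
subject-intercept ANCOVA (dof = N_obs − N_subjects − 1), delegated to
`pingouin` and cross-checked in the tests against an explicit
subject-dummy OLS; a closed-form within-subject-centered fallback covers
the two-subject edge pingouin declines. Post-hoc pairwise comparisons use
Wilcoxon with Bonferroni correction — a deliberate, conservative package
choice where no canonical procedure is dictated.

## Known limitations

* The MWF blink corrector is a faithful standard formulation, not a
  reconstruction of any specific published variant; its parameters (ridge,
  cross-fade) are package choices.
* EDF output is 16-bit; round-trips are exact only to the per-channel
  quantization step. The writer covers the plain EDF profile used here,
  not EDF+ annotations.
* IAF estimation fails loudly on alpha-free spectra by design; recordings
  from subjects with true low-alpha power need a manually supplied IAF
  (`--iaf` in the CLI).
* Segment aggregation assumes segment labels partition kept epochs; no
  overlap or weighting is supported.
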