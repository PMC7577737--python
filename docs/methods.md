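# Methods

## The wave statistic

A cortical travelling wave appears in a time × electrode map as an oblique
stripe: the oscillation's phase advances systematically along an ordered
spatial array.  `eegwaves` quantifies this by sliding a 1-s window (0.5 s
step) over the signals of one electrode axis (by default the five
posterior→anterior midline electrodes Oz, POz, Pz, Cz, FCz), stacking each
window into a 5 × fs map, and taking its two-dimensional Fourier transform.
Energy at (negative spatial frequency, positive temporal frequency)
corresponds to forward (FW, posterior→anterior) propagation; the mirrored
quadrant to backward (BW) propagation.  From each quadrant the maximum power
is extracted over bins with strictly nonzero spatial and temporal frequency —
a spatially uniform component is not a travelling wave and DC is not an
oscillation — restricted to the 1–45 Hz analysis band.

Raw quadrant maxima are meaningless in isolation: any temporally structured
signal produces some quadrant power.  The null is built by shuffling the
electrode order (default 100 uniform permutations, identity allowed, redrawn
per window from a per-window stream spawned off the master seed), which
destroys spatial organisation while preserving every channel's temporal
spectrum, and recomputing the same maxima.  The same permutation sequence
serves both directions of a window.  The net wave amount is

    W_dB = 10 · log10(W / W_ss),

where `W_ss` is the mean surrogate maximum; 0 dB means "no more directional
structure than chance", so the value is tested against zero.

### Numerical design

* **Exact symmetries.**  The spatial transform uses a phase convention
  centered on the array midpoint and a reversal-symmetric pairwise summation.
  Consequently reversing the electrode order swaps FW and BW quadrant power
  *bit-exactly*, and maps with identical rows give exactly 0 dB for any
  shuffle seed (surrogate maxima of identical rows are identical, and their
  mean is returned without summation round-off).  These are the two
  symmetries that catch orientation bugs — the most likely error in any
  implementation of a signed-quadrant statistic — so they are held to machine
  exactness, not tolerance.  The quadrant orientation itself is pinned by a
  unit test that generates a posterior→anterior plane wave and asserts it
  lands in the FW quadrant.
* **Surrogate means** are averaged after sorting (order-canonical) so
  exhaustive-permutation runs are bit-reproducible.  In the batch recording
  path the shuffled spectra are computed in single precision (relative error
  ~1e-7 on the mean, orders of magnitude below the shuffle Monte-Carlo
  error); the raw maxima and everything downstream stay double precision.
* **Windowing.**  Windows are neither detrended nor tapered; DC-line
  exclusion at the quadrant stage handles the mean.  Second-to-sample
  conversions that are not whole numbers are rejected rather than rounded.
  The Nyquist temporal bin is excluded (its propagation sign is undefined).
* **Ties** in a quadrant resolve to the lowest temporal, then lowest spatial
  frequency bin.
* **Filter.**  Preprocessing is a 4th-order Butterworth band-pass (1–45 Hz)
  applied forward-backward, then average reference.  Zero-phase filtering is
  essential: the statistic lives in cross-channel phase relations, and any
  phase-distorting filter would bias apparent direction.  An optional
  amplitude-threshold window rejection stands in for manual artifact
  screening.

## Frequency decomposition

Band membership uses half-open intervals δ=[1,4), θ=[4,8), α=[8,13),
β=[13,30] Hz, tiling the axis so every 1-Hz peak belongs to exactly one band
(the conventional ranges leave gaps; the δ floor is the 1 Hz filter corner
and window resolution).  `per_frequency_waves` repeats the quadrant/surrogate
construction per temporal-frequency column (maximising only over spatial
bins), and `peak_band_histogram` counts windows by the band of their quadrant
peak.

## Study-level statistics

Per-window dB values are averaged per minute bin (bin *b* covers window start
times `[60(b−1), 60b)` seconds from injection) and per 5-min pre/post block;
aggregation is the arithmetic mean of dB values, making windows
exchangeable.  Minute series get one-sample t-tests against zero with
Benjamini–Hochberg correction applied within each condition × direction
series (matching the per-panel multiple-testing family).  Block summaries
get one-sample tests per cell plus paired contrasts (drug vs placebo post,
post vs pre), each with a classical 95% t-interval and an optional JZS Bayes
factor (Cauchy scale 0.707, marginal likelihood by adaptive quadrature in
log space; cross-checked against an independent implementation).  The
reported intervals are frequentist; no Bayesian ANOVA is attempted.  FW–BW
coupling is the per-subject Pearson correlation between window-wise FW and
BW dB inside minutes 2–5 post-injection (and the pre block as a control),
tested against zero across subjects.  Rating analyses: (a) time-course
correlation of group-mean intensity with group-mean wave dB across post
minutes; (b) per-minute across-subject correlations, reported uncorrected
and BH-adjusted (at n≈13 none are expected to survive correction); (c)
per-VAS-item across-subject correlations with the mean wave amount over the
coupling window.  The power helper computes two-sided two-sample t-test
power under a noncentral t with `ncp = |μ₁−μ₂|/σ·√(n/2)` and `df = 2n−2`.

## The synthetic study

The generator emulates the statistical structure of a 13-subject,
two-session (placebo first) pharmaco-EEG experiment: eyes-closed rest at
1000 Hz, 32 channels, 5 min pre- and 20 min post-injection, a BW-dominant
alpha regime at baseline, and a drug session in which FW waves rise and BW
waves shrink (staying positive) while spectral weight moves from alpha
toward delta/theta.

* **Targets.**  Post-block group means default to FW +0.19 / BW +0.18 dB
  (drug) and FW −0.20 / BW +0.51 dB (placebo), with between-subject SDs
  0.29 / 0.25 — the design quantities of the power analysis.  The baseline
  regime reuses the placebo-post means (pre ≈ post under placebo).  These
  numbers are the *sample statistics* a 13-subject study reports, not
  population parameters, so the generator standardises its per-subject
  offset draws: every simulated study realises exactly the configured group
  mean and between-subject SD (between-study fluctuation of the sample mean
  is not part of the emulated design; at n=13 and SD 0.29 it would be
  ±0.08 dB and would occasionally flip the sign of a 0.19 dB group effect,
  conflating draw luck with pipeline error in recovery tests).  Baseline and
  drug-response offsets are independent, so the drug effect itself varies
  between subjects — necessary for any across-subject correlation with
  ratings to exist.
* **Kinetics.**  The drug effect ramps linearly to full strength over
  minutes 0–2, plateaus to minute 5, then decays exponentially with a 5-min
  half-life (half effect near minute 10).  Because the stated target is the
  post-*block* mean, per-minute targets are scaled so the block mean of the
  ramped series equals the target.
* **Calibration, not guessing.**  Within each minute the five midline
  channels carry, per band, two tones (at f and f−1 Hz) whose complex
  spatial profiles — forward and backward one- and two-cycle harmonics —
  are *solved* so that the exact quadrant/surrogate statistic (exhaustive
  120-permutation surrogates, computed analytically on the spatial profile)
  hits that minute's dB target pair to <0.02 dB.  Two independent spectral
  columns are required: with a single column the reachable (FW, BW) set has
  a frontier (strong FW dominance forces BW strongly negative), and
  per-subject draws routinely demand decoupled pairs.  Because every band's
  columns share the minute's profiles, band re-weighting (the spectral
  shift) provably leaves the dB values unchanged, and the peak-frequency
  histogram is controlled independently of the wave amounts.  Unreachable
  targets raise a calibration error rather than being approximated.
* **Coupling.**  A slow sinusoidal antiphase modulation (depth 0.3, period
  30 s) scales forward harmonics by (1+μ) and backward by (1−μ), producing
  the negative window-by-window FW–BW correlation; the calibration averages
  the statistic over the modulation cycle so block means still hit their
  targets.
* **Noise.**  All channels carry 1/f noise (spectrally shaped white
  Gaussian): 2 µV RMS on the midline (signal amplitude scale 20 µV), 10 µV
  on the background channels.  Noise pulls per-window dB slightly toward
  zero (a real property of noisy recordings); calibration accuracy is
  defined noise-free.
* **Ratings.**  Minute-wise intensity is a clipped affine map of the
  subject-minute FW drug effect to a 0–10 scale plus Gaussian noise; the 20
  VAS items are positively loaded noisy functions of the subject's mean
  post-block FW effect on a 0–100 scale.  Any bounded monotone map supports
  the correlation analyses; these choices are not claims about real rating
  scales.

**What the generator does not emulate:** volume conduction and sensor
geometry, eye/muscle/cardiac artifacts, non-stationary background rhythms,
wave packets with mixed spatial frequencies, or any biophysical forward
model.  Passing tests therefore demonstrate that the *pipeline* recovers the
statistical structure it assumes, at realistic effect sizes and sample
sizes — not that the method is robust to everything real EEG contains.

## Problem sizes used in tests

Validation runs use reduced recordings chosen as the smallest sizes at which
every targeted effect is identified: 13 simulated subjects with 2-min
pre/post blocks standing in for the 5-min blocks, 5 post-injection minutes
(covering the minute-2–5 coupling window), and 8 channels (the analysis
touches only the 5 midline channels; the remainder are inert 1/f
background).  The parameter-recovery suite repeats the full
generate-analyse cycle over 20 seeds and requires every qualitative effect
(FW above zero, BW decreased but positive, negative coupling, positive
intensity correlation) in at least 19 of them.

## Known limitations

* The quadrant maximum sees only the dominant wave per direction per window;
  simultaneous waves at different spatial frequencies compete.
* The five-electrode axis resolves spatial frequencies of only ±1/5 and
  ±2/5 cycles/electrode; no spatial interpolation is attempted.
* dB values are mildly attenuated toward zero by additive noise (Jensen
  bias of the log-ratio); group *contrasts* are affected much less.
* The JZS Bayes factor covers one-sample/paired designs only; repeated-
  measures Bayesian ANOVA is out of scope.
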