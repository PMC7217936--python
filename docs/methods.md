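# Methods

`phasermt` simulates and analyses a brain-state-dependent TMS experiment in
which the resting motor threshold (RMT) of both primary motor cortices is
estimated while stimuli are locked to the positive peak, the negative peak,
or a random phase of the sensorimotor mu-rhythm (8–13 Hz).  This note
documents the models, the numerical choices, and what the synthetic data do
and do not emulate.

## Real-time phase forecasting

The online algorithm operates on a Laplacian EEG derivation (centre
electrode minus the mean of its four neighbours; C3 or C4 centred).  For
each evaluation instant it:

1. takes a 500-ms sliding window ending "now" (5-kHz sampling);
2. bandpass-filters it 8–13 Hz with a linear-phase windowed-sinc FIR applied
   forward and backward (zero phase);
3. fits a Yule–Walker autoregressive model of order 30 to 372 ms of
   filtered data in the middle of the window;
4. extrapolates a 128-ms prediction from the fit-span end — the prediction
   is therefore centred on the window end, i.e. on "now";
5. reads the instantaneous phase at the prediction centre from the Hilbert
   analytic signal.  Convention: 0 rad = positive peak, ±π = negative peak
   (the condition names refer to the Laplacian EEG signal's extrema).

A trigger fires when the estimated phase matches the target within a
tolerance *and* the in-band power of the filtered fit span exceeds a gate
threshold (gate first, then phase).  For the random condition a target
phase is drawn uniformly, which makes the trigger-phase distribution
circularly uniform.

Numerical choices that matter:

- **Autocovariance estimator.** The AR fit uses the unbiased
  (divide-by-`n−k`) autocovariance.  The biased estimator's implicit taper
  drags the dominant pole radius to ≈0.993 per sample at 5 kHz, so a
  multi-cycle extrapolation decays ~10× by the segment centre and the
  forecast phase acquires a 10–30° bias.  A relative diagonal loading of
  1e-9 keeps the Toeplitz system solvable for noiseless sinusoids.
- **AR stage rate** (`RtConfig.ar_fs`, default 1 kHz).  The filtered fit
  span is decimated before the AR fit: an order-30 model at 5 kHz spans
  only 6 ms and cannot lock onto a ~10-Hz rhythm in noise; at 1 kHz it
  spans 30 ms.  Poles that land outside the unit circle are reflected
  inside (`stabilize_ar`) so extrapolations stay bounded.
- **FIR length** (default 145 ms ≈ 725 taps at 5 kHz).  Two errors trade
  off: a short filter's wide transition band leaks 1/f power into the
  filtered trace and costs several degrees of phase accuracy in noise,
  while a long filter's leading-edge distortion (the forward–backward
  kernel extends `numtaps−1` samples each way, but no future samples exist
  beyond the window end) reaches into the fit span and biases the
  noiseless forecast.  145 ms keeps the noiseless trigger error under
  5° while staying within a few degrees of the sharpest usable design in
  noise.
- **Power gate** default: the 75th percentile of sliding in-band power over
  a resting recording (`power_gate_threshold`); the evaluation stride is
  1 ms and the phase tolerance is the phase step one stride implies at the
  band centre (≈3.8°).

Accuracy under the study conditions (measured by the package's own tests):
noiseless 10-Hz rhythm, trigger-phase error < 5°; at the 5-dB mu-band SNR
inclusion floor, the median absolute trigger-phase error is ≈40–45°
(per-recording medians fluctuate between roughly 35° and 60°).  This is
the causal information limit of the architecture at that SNR rather than
an implementation artifact: an acausal Hilbert transform of the ideally
filtered trace does no better than ≈50° on the same recordings, oracle
experiments that grant the filter future samples reach ≈25° only by
violating causality, and causal approximations of those sharper filters
degrade accuracy because their padding re-injects the estimator's own
error.  Published real-time mu-phase systems report comparable errors
(≈50–60° SD) for subjects near their SNR inclusion floor.

## Synthetic recordings

The mu source is a fixed-frequency carrier with exactly known phase
φ(t) = 2πf·t + φ₀, multiplied by a slow lognormal envelope (log-SD 0.6,
~0.5-Hz bandwidth) that emulates the waxing and waning of real rhythms.
Because the envelope is far below the band, the analytic phase of the
component equals the carrier phase (Bedrosian's condition), so ground truth
is exact.  Each channel receives independent 1/f^α noise (spectral shaping
of white noise, α = 1 by default); the source projects at gain 1 onto the
Laplacian centre and 0.25 onto its neighbours, so the Laplacian enhances
it.  When a target SNR is requested, the source amplitude is calibrated
against the same Welch/1-f-fit estimator the SNR measurement uses, with the
noise PSD and the mu–noise cross-spectrum at the peak bin solved for
explicitly; calibrated recordings land within ±1 dB of the target.

A constant-amplitude sinusoid was deliberately rejected: for the same
*measured* spectral-peak SNR it carries far less band power than a real,
finite-bandwidth rhythm (all its power sits in one Welch bin), producing
in-band time-domain SNRs around −7 dB at a nominal 5 dB and making phase
estimation unrealistically hard.  The envelope restores the realistic
relation between measured SNR and band power and gives the power gate its
physiological role (triggering during strong-rhythm epochs).

What the generator does **not** emulate: volume conduction and realistic
head geometry, eye-blink/cardiac artifacts, frequency drift of the rhythm,
and non-stationarity of the 1/f background.  Tests passing on this
synthetic data therefore validate the algorithmic chain, not robustness to
real-world artifacts.

## MEP responder and threshold tracking

The probability that a stimulus at intensity *x* (%MSO) evokes an MEP above
50 µV peak-to-peak is Φ((x − µ)/σ), a cumulative Gaussian with threshold µ
(the true RMT of the condition) and spread σ (default 2 %MSO).  Drawn
amplitudes are lognormal about the 50-µV criterion with the log-location
tied to the Φ-quantile, so the exceedance probability is exact by
construction; the lognormal shape itself is a modelling convention (MEP
amplitude distributions near threshold are not otherwise constrained
here).

RMT estimation evaluates the Bernoulli likelihood of the per-trial
exceedance outcomes on a (threshold, spread) grid — 0–100 %MSO at
0.1 %MSO by 16 log-spaced spreads over 0.5–10 %MSO — marginalises over the
spread with a uniform prior, and normalises to a density over intensity.
The RMT estimate is the density's mode (ties resolve to the lowest
intensity, matching the threshold's definition as a minimum).
P(RMT_pos > RMT_neg) integrates the product of the two condition densities
over the triangular half of the joint grid; diagonal mass splits evenly,
which makes P(A>B) + P(B>A) = 1 exact.

Threshold tracking is maximum-a-posteriori: each next intensity is the
current posterior mode of its condition, rounded to the 0.1-%MSO
stimulator resolution, starting from 50 %MSO.  The three conditions track
independently, interleaved in pseudorandomised blocks of three with one
stimulus per condition per block and ≥2-s interstimulus intervals;
100 stimuli per condition is the session default.  With σ = 2 the tracker
recovers the threshold within ±1 %MSO in well over 90% of sessions.

## Offline preprocessing

EEG: epochs around each pulse are baseline-corrected by the mean of the
600 ms immediately preceding it; trials whose baseline peak exceeds a
threshold are discarded.  EMG, in fixed order: 5-Hz second-order
Butterworth high-pass (forward–backward) on the continuous record;
epoching; −200–0 ms baseline correction; linear interpolation of the TMS
artifact between the samples at 0 and 10 ms; 49–51-Hz second-order
Butterworth notch (forward–backward); a fifth-order polynomial fitted to
the baseline samples and subtracted across the whole epoch; second
baseline correction.  Epochs span ±1 s so the high-Q notch's edge
transients stay clear of the analysis windows.  MEP amplitude is max−min
in 15–45 ms.

The per-subject rejection thresholds are, in the emulated protocol, set by
eye.  The programmatic surrogate is median + k·MAD (k = 5) of the
per-trial peak absolute baseline amplitude — per-trial peaks rather than
pooled samples, because the rejection rule itself compares peaks, and a
threshold a few MADs above the pooled distribution would reject a large
fraction of clean trials purely through the maximum statistic.  With the
generator's default contamination (≈16% of trials get an EMG
pre-innervation burst, ≈1% an EEG baseline artifact), the chain discards
≈17% of trials, ≈1% of them by the EEG criterion.

Spectral features: resting mu-band SNR is the Welch PSD (Hann, 2-s
segments, 50% overlap) peak over 8–13 Hz above a 1/f background fitted by
linear least squares of log-power on log-frequency over 1–45 Hz excluding
the mu band, in dB.  Pre-stimulus mu power follows a five-step chain:
2-s epoch, 0–15-ms artifact interpolation, 200-Hz anti-alias filter and
decimation to 500 Hz, Burg AR spectrum (order 26; statsmodels' Burg
recursion; the AR transfer function is evaluated on a 1-Hz grid over
1–45 Hz) of the −150–0-ms window, and summation of the 1/f-subtracted
residual over 8–13 Hz (residuals clipped at zero before summing).

## Cohort model and statistics

Per-subject phase-dependency is PHASE = (RMT_pos − RMT_neg)/RMT_rand.  The
cohort generator draws (PHASE_dom, PHASE_nondom) from a bivariate normal —
defaults: means 0.022/0.025, SDs 0.025/0.029, correlation 0.45, n = 51 —
and baseline excitability RMT_rand from interhemispherically correlated
normals (means 54.85/55.85 %MSO, SD 8, correlation 0.8).  The ground-truth
random-phase threshold is the midpoint of the peak thresholds (a random
phase averages over the cycle), so neg/pos thresholds follow exactly from
(PHASE, RMT_rand).  Resting SNR and mu peak frequency are drawn per
hemisphere around shared per-subject values, giving realistic
interhemispheric differences for the exploratory analyses.

Statistics follow the emulated protocol: Friedman tests (average ranks,
standard tie correction; a fully tied matrix reports χ²=0, p=1) per
hemisphere across the three conditions; pairwise Wilcoxon signed-rank
tests with Pratt zero-handling, reported as Z with significance at the
rounded Bonferroni criterion p < 0.017 (strict, rather than 0.05/3 exactly); interhemispheric Wilcoxon
tests per condition; a two-tailed paired t-test on PHASE with Cohen's d
and the default JZS Bayes factor (Cauchy prior scale √2/2, adaptive
quadrature over the g-mixture); Pearson correlations; prevalence counts of
RMT_neg < RMT_pos (strict inequalities; ties do not count); and an
exploratory similar/dissimilar split — dissimilar iff P(RMT_pos > RMT_neg)
straddles 0.5 across hemispheres, a probability of exactly 0.5 counting to
the ≥0.5 side — compared by Mann–Whitney U.  Wilcoxon and Mann–Whitney
p-values are exact for n ≤ 25 without ties and tie-corrected normal
approximations otherwise; Shapiro–Wilk at α = 0.05 routes between
parametric and non-parametric branches.

## Orchestration and problem sizes

`run_study` simulates every subject (dominant hemisphere first, as in the
emulated protocol) at one of two depths: `tracking` (responder/tracker
loop only; the default, exact with respect to the psychometric model) or
`signal` (full EEG/EMG synthesis, trigger placement, offline
preprocessing, and RMT fits from measured MEP amplitudes; meant for small
validation cohorts).  Everything derives deterministically from one master
seed via spawned child seeds; rerunning a configuration reproduces the
output tables byte for byte.

The test suite and the acceptance script keep Monte-Carlo problem sizes
moderate by design: 100-replicate tracking studies, a 51-subject cohort
for correlation recovery, 12-subject null cohorts for the Friedman
false-positive rate (the test's level does not depend on cohort size), and
a few hundred real-time triggers per accuracy measurement.  These sizes
put sampling error well below the margins being tested while keeping a
full run in the minutes range.

## Known limitations

- The threshold-tracking rule ("next intensity = posterior mode") is one
  reasonable reading of adaptive threshold tracking; mean- or
  quantile-based trackers would differ in early-trial behaviour.
- The spread σ is marginalised with a uniform prior on a log-spaced grid;
  profiling or fixing σ would sharpen the posterior slightly.
- The real-time loop's evaluation rate and phase tolerance in the original
  hardware are not public; the 1-ms stride and stride-implied tolerance
  are declared defaults.
- Whether the fifth-order EMG detrend polynomial should be subtracted from
  the baseline only or the whole epoch is ambiguous in the emulated
  protocol; it is subtracted from the whole epoch here.
- Signal-level cohort simulation at full size (51 subjects × 2 hemispheres
  × 300 real-time-detected triggers) is computationally heavy; the
  statistical results in the default pipeline come from the tracking-level
  simulation, with the signal level validated on small runs.
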