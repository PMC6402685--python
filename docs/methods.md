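# Methods

## Stimulus codes

Two 31-bit binary code families at 90 bits/s (one period = 31/90 s ≈
0.344 s; bit 1 = light, bit 0 = dark).

**m-sequence.** Generated by a 5-stage Fibonacci LFSR.  The feedback
polynomial is not part of the protocol specification, so the package
defaults to x⁵ + x² + 1 with an all-ones seed for reproducibility; any
primitive order-5 polynomial yields a sequence with the same period-31,
16/15 balance and two-valued {1, −1/31} circular autocorrelation, which
the test suite checks by brute force rather than against fixed bits.
Non-primitive taps are detected at generation time (the register fails
to return to its seed after 2⁵−1 steps) and reported with a warning.

**Chaotic code.** The logistic map x(i+1) = A·x(i)(1−x(i)) is iterated
17 times from x(0) = 0.015 with A = 3.882 (chaotic regime).  Each
iterate emits C(n) = 0 if x > 0.5 else 1, immediately followed by its
one's complement C(n+1) = 1 − C(n); the 34 raw bits are truncated to 31.
The complement pairing forces every even-length prefix to be exactly
balanced and concentrates spectral energy near the Nyquist frequency of
the bit train — the property that makes the code less visually
fatiguing.  Two conventions are worth noting: some descriptions of the
map use x(0) = 0.15; both values are supported and 0.015 (the value tied
to the generation algorithm) is the default.  A threshold tie x = 0.5
exactly takes the "else" branch (bit 1); it is a measure-zero event.

**Lagged targets.** Target i is the base code circularly delayed by
(i−1)·8 bits (0.0889 s at 90 bits/s, conventionally printed as
0.088 s).  With a 31-bit code the shifts 0, 8, 16, 24 are distinct
modulo the period, so the four targets are mutually separable through
the code autocorrelation.

**Correlation convention.** Bits are mapped 0 → −1, 1 → +1 before
correlating (a raw 0/1 option exists); values are normalized by the
zero-lag autocorrelation, so an autocorrelation is 1 at lag 0.  The
amplitude spectrum is the one-sided transform of one 0/1 code period
sampled at the bit rate with a rectangular window; band energies
partition the one-sided power into [0, 10), [10, 30] and (30, 45] Hz
and sum to the mean squared bit value (Parseval).

## Synthetic EEG

The simulator reproduces the statistical structure the decoders rely
on, not biophysical detail.  For each trial, the attended target's ±1
bit train (18 code repetitions, zero-order-hold sampled at the
simulation rate) is linearly convolved with an evoked-impulse kernel and
truncated to the trial length, so the first epoch carries an onset
transient as real EEG would; a circular steady-state mode is available
for exact oracle checks.  Channels share the kernel shape and differ by
positive gains (1.0, 0.85, 0.8, 0.55 for Oz, O1, O2, Pz) — a spatial
rank-1 model that keeps the decoders analyzable; per-channel kernel
shapes are available as an option.

**Kernel.** A causal sum of damped sinusoids with unit energy; the
defaults — (14 Hz, τ 25 ms, latency 20 ms), (28 Hz, τ 35 ms, 50 ms),
(9 Hz, τ 60 ms, 85 ms), 0.25 s long — are fast occipital transients
(P1/N1-like) followed by a slower late wave.  The short decay times keep
the kernel autocorrelation low beyond ~80 ms, so that responses to codes
8 bits apart remain separable; this mirrors the sharply peaked response
cross-correlations that make lag decoding possible on real data.  A
seed jitters component frequencies and latencies by ~5% to create
distinct simulated subjects.

**Noise and SNR.** Background noise is an equal-power mixture of white
and 1/f-amplitude (pink) noise, independent across the 4 channels.
`snr_db` fixes the evoked-signal to noise power ratio over the
stimulation samples of the recording (broadband, before filtering); the
signal is rescaled to achieve it exactly, so the realized SNR matches by
construction.  The default of −5 dB is the study condition used in the
acceptance checks; `+inf` disables noise and `−inf` disables the signal
(chance-level control).

**Protocol timing.** 10 trials per target, 18 epochs per trial (6.2 s of
stimulation), 2 s breaks after each trial; triggers mark trial onsets.
The default simulation rate is 600 Hz rather than the 4800 Hz of the
original acquisition — decoders operate on epoch shapes, not absolute
rate.  600 Hz is not an integer multiple of 90 bits/s, so epoch
boundaries drift by fractional samples (a warning says so); tests that
assert sample-exact lag structure run at 540 Hz, where one bit is
exactly 6 samples.  Session length is 10·(6.2 + 2) = 82 s; the
"90 s per session" sometimes quoted for this protocol is not asserted
anywhere, and break placement is configurable.

**What the simulator does not emulate:** eye-blink/EMG artifacts,
volume conduction and realistic spatial covariance, inter-session
fatigue drift, or nonlinear cortical responses.  Passing tests show the
pipeline recovers structure it imposes — they do not certify performance
on real recordings.

**VAS tables.** Per-subject fatigue scores for the 8 codes (M1–M4,
Ch1–Ch4) are generated as family mean + shared subject latent +
family-level residual + per-code jitter, clipped to [0, 10].  The latent
variance is set to corr·sd₁·sd₂ so the two per-subject family averages
have the requested standard deviations (defaults 2.6207, 2.1981), means
(5.8152, 4.9076) and within-subject correlation (0.8).  This is the
simplest generative structure consistent with a paired design, not a
model of any subject population; clipping pulls the realized moments
slightly toward the middle of the scale.

## Preprocessing

Trials are cut at triggers first (length 18·n samples,
n = round(fs·31/90)), then band-pass filtered and detrended per trial
segment, then reshaped into 18 consecutive epochs — matching the order
of operations of the recording protocol.  The filter is a zero-phase
(forward–backward) Butterworth band-pass, 2–40 Hz; "order 8" is read as
the order of the band-pass transfer function, i.e. scipy's
`butter(4, ..., btype="bandpass")`, applied with `sosfiltfilt`.
Detrending removes each channel's best-fit line.  Epoch boundaries are
cumulative sample counts from the trial onset (no per-epoch rounding),
so concatenating the epochs reconstructs the segment bit-exactly; a
segment one sample short from rounding is padded by repeating its last
sample.

## Decoders

**CCA template matching.** Templates T_i are the element-wise mean of
each target's training epochs, built per target separately (no circular
shifting of a single calibration template).  For a test trial the first
r epochs are averaged into s (channels × samples), and for each target
the canonical correlations between s and T_i are computed with channels
as variables: rows are centered, the auto-covariance blocks are
regularized by λ = 1e−8 times their mean diagonal, and the coefficients
are the singular values of the whitened cross-covariance (all m of
them, descending).  The feature is the arithmetic mean of the m
coefficients — an option uses only the leading one, which is
considerably more robust when the spatial signal is rank-1 — and the
predicted target is the argmax (ties resolve to the lowest index, with a
logged warning).  Zero-variance inputs raise instead of returning a
silent argmax.

**Spatiotemporal LCMV beamforming.** Activation patterns a_i are the
per-target mean training epochs with channels concatenated (length
m·n).  Σ is the sample covariance of *all* targets' concatenated
training epochs jointly.  Because m·n (e.g. 4·207 = 828) typically
exceeds the number of training epochs (≤ 648), Σ is shrunk toward its
diagonal, Σ ← (1−γ)Σ + γ·diag(Σ) with γ = 0.05 by default; γ = 0 on
rank-deficient data raises with advice to increase it.  Weights follow
the closed form w_i = Σ⁻¹a_i / (a_iᵀΣ⁻¹a_i), which satisfies the
unit-gain constraint a_iᵀw_i = 1 at any shrinkage.  A test trial's
averaged, concatenated epochs s score y_i = s·w_i; argmax identifies
the target.

## Evaluation

10-fold cross-validation over trials: each fold holds out one trial per
target, trains on the other nine, and tests at every averaged-epoch
count r = 1..18 (temporal prefix of the trial, matching online use);
fold accuracies are averaged.  "Subjects" for simulated statistics are
independent seeded simulation runs (20 by default).  The decoder
comparison applies the Wilcoxon signed-rank test across subjects at each
r, reporting the normal-approximation Z (negative when the second
decoder is better) and a stimulation-time column in the conventional
printed form — multiples of 0.344 s truncated to 2 decimals, so 18
epochs print as 6.19 s although the exact duration is 6.2 s.

Statistical conventions: Wilcoxon drops zero differences (Wilcoxon's
original rule) and uses exact enumeration for small tie-free samples;
the paired t flags zero-variance differences (p = 1 for identical
samples, infinite t for a constant shift) rather than emitting NaN;
the one-way repeated-measures ANOVA applies the Greenhouse–Geisser
epsilon (via pingouin, cross-checked against explicit sums of squares);
post hoc pairwise paired t tests over the 6 pairs of 4 conditions are
judged at the Bonferroni level α = 0.008.

## Problem sizes and determinism

Simulation-based checks use one session per target (40 trials total per
run) at 600 Hz, with 20 runs for the accuracy criterion, 8 runs (320
trials) for the chance-level control, 3 runs per SNR for the
monotonicity check over {−15, −10, −5, 0} dB, and 500 replicates for
the power of the paired fatigue contrast at n = 44 subjects.  Every
random quantity derives from explicit integer seeds; a global pipeline
seed fans out to per-stage substreams (all below 2³¹) so stages can be
re-run in isolation, and identical configs produce byte-identical
outputs.

## Known limitations

The m-sequence family decodes a few points below the chaotic family
under CCA in this simulator: its response energy concentrates on
harmonics of the 0.344 s period whose phases nearly realign under an
8-bit shift, so lagged m-sequence responses are intrinsically more
correlated through a smooth kernel.  The mean-of-all-coefficients CCA
feature is diluted by noise-driven trailing coefficients whenever the
spatial signal is rank-1; the leading-coefficient option does not have
this weakness.  EDF export is not provided (recordings use an HDF5
container; EDF import is available through MNE when installed).
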