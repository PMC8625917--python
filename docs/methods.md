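# Methods

## Signal model and scope

The package processes single-lead ECG of preterm infants sampled at 250 or
500 Hz.  The useful cardiac band is roughly 0.6–40 Hz; disturbances are
sub-1 Hz baseline drift from infant movement and electrode slippage, 50/60 Hz
mains pickup, and broadband sensor noise.  The clinical events of interest
are rhythm-level: bradycardia (rate < 100 bpm, i.e. RR intervals > 0.6 s,
sustained for at least two beats in the strict clinical definition) and
tachycardia (> 140 bpm, RR < 0.43 s).  Morphology-level diagnosis (ST
analysis, ectopic classification) is out of scope.

## The stationary wavelet transform

All processing shares one operator: the undecimated à trous transform with
the orthonormal db8 filter pair (taps from PyWavelets).  Analysis at level
*i* is circular correlation with the filters upsampled by 2^(i−1); synthesis
is circular convolution with the same taps, averaging the redundant
low-/high-pass branches.  Because |H(ω)|² + |G(ω)|² = 2 for orthonormal
filters, the round trip is exact (observed ≈ 1e−15) for **any** signal
length — no power-of-two padding — and the periodic transform is exactly
circular-shift invariant and linear.

Boundary handling is a genuine free choice; nothing in the problem fixes it.

* `periodic` (default): wraps the signal.  Chosen as default because shift
  invariance and linearity are then exact and testable.
* `symmetric`: reflects the signal into a margin covering the deepest
  filter support, runs the periodic transform on the extension, and exposes
  the central *n* samples of each coefficient array.  The margins stay on
  the coefficient object, which keeps reconstruction of an unmodified
  decomposition exact.  A cropped undecimated transform is information-
  expanding, so *no* scheme can make reconstruction of arbitrarily edited
  length-*n* symmetric-mode coefficients exact at the boundaries; edits
  made through the public views propagate to the stored interiors and the
  margins keep their analysis values, which is the behaviour a boundary-
  padded denoiser wants.

Level *i* details are labelled with the ideal dyadic band
[fs/2^(i+1), fs/2^i]; the filters are not brick-walls, so the labels guide
interpretation (e.g. at 500 Hz, five levels put the approximation below
7.8125 Hz and d5 between 7.8125 and 15.625 Hz) rather than guarantee
band-limits.

## Preprocessing

**Baseline removal** reconstructs from cA₅ alone (five levels regardless of
sampling rate; at 250 Hz the approximation band is ≈ 0–3.9 Hz, at 500 Hz
≈ 0–7.8 Hz) and subtracts.  `corrected + baseline` reproduces the input to
machine precision, and the operation is idempotent to first order.

**Denoising** soft-thresholds each detail level with
T = sample standard deviation (ddof = 1) of that level's coefficients.
A variance has squared-amplitude units and cannot be compared against a
coefficient, so the threshold is the square root of the mean-centred sum of
squares over n−1 — the dimensionally consistent reading.  The mean is taken
per level.  Properties that follow and are tested: scale covariance
(thresholds scale with the data), energy never increases, determinism.

The threshold is deliberately *relative*: it adapts to each infant and each
noise level, but on a very clean signal it is dominated by the QRS detail
energy itself and then shrinks real peaks (≈ 35 % peak-amplitude loss on
the clean synthetic waveform).  Detection is unaffected — the 70 % rule is
also relative — but reconstruction fidelity of the denoised waveform is
intentionally traded for noise robustness.  This is why denoising gain is
measured against noisy inputs, not clean ones.

**SNR improvement** is defined as
10·log10(P(original−clean)/P(processed−clean)) against a known clean
reference; zero when processing does nothing, capped at ±300 dB instead of
infinities.  Real recordings have no clean reference; a high-band
(> 40 Hz) power-ratio estimate is provided and clearly flagged as an
estimate.  The *noisy recording condition* used by tests and the
acceptance script is: clean synthetic ECG + 0.15 mV drift at 0.25 Hz
+ 0.05 mV mains at 50 Hz + white noise whose power sets the quoted input
SNR (0–10 dB).  Drift and mains are fixed recording artifacts — a NICU
chest lead always has them — and the improvement measure counts all three
as noise, since the chain's first step is drift removal.  Under this
condition the chain gains ≈ 4–6.5 dB across the input-SNR range (the
acceptance script recomputes this), sitting inside the single-digit-dB
range such chains achieve clinically.

## R-peak detection

Personalization means no fixed voltage threshold: the reference peak is the
largest amplitude seen since record start, established during a 2 s warm-up
(at least one heartbeat at neonatal rates) during which no peaks are
emitted.  Candidates are strict local maxima (plateaus resolve to their
left edge), must reach 70 % of the current reference, and must be ≥ 0.2 s
after the last accepted peak.  The refractory default suppresses
double-detection on T-waves and still admits 200 bpm (RR 0.3 s).  Across
blocks the reference decays by 0.99 per block before being max-merged with
the new block's running maximum, so it tracks slow amplitude drift without
ratcheting upward after one movement artifact.  Positive R-polarity is
assumed; an `invert` flag handles inverted leads.

## Rhythm logic

RR intervals come from consecutive peak times; the relative measure
2(RR_k−RR_{k−1})/(RR_k+RR_{k−1}) is algebraically confined to (−2, 2) and
flags irregularity outside ±20 %.  Bradycardia fires on a single interval
strictly above 0.6 s (one event per maximal run, the run's intervals stored
with the event); a two-beat confirmation mode implements the stricter
clinical definition.  Tachycardia requires at least two consecutive
intervals strictly below 0.43 s: the 140 bpm limit converts to
60/140 ≈ 0.4286 s, rounded to 0.43, and "intervals too *short*" is the only
reading consistent with a rate *above* 140 bpm.  Note that a healthy
150 bpm neonate (RR = 0.40 s) sits above the 140 bpm limit, so tachycardia
alerts on such rhythm are correct behaviour of the rule, not false alarms;
bradycardia alarms are the specific endpoint tests quantify.

HRV metrics are reported in ms: RMSSD (root mean square of successive RR
differences), SDNN (sample std of RR), SDANN (sample std of per-window mean
RR, default 5 s windows).  Metrics whose preconditions fail are NaN, never
zero.  Windowed RMSSD/SDNN every 2 s or 5 s supports trend monitoring.

## Compression

Sparsity comes from the denoiser: raw SWT coefficients of a real ECG are
never exactly zero, so the encoder decomposes, soft-thresholds the details
(adaptive thresholds by default, overridable), then quantizes survivors
per level with a uniform mid-rise min–max quantizer (error ≤ half a step,
verified).  The default bit accounting is fully explicit: payload codes at
`bits` each, a 1-bit-per-coefficient position bitmap per detail level, and
a 64-bit (two float32) min/max header per level; input bits = n × ADC
resolution (16 by default).  Under this accounting an undecimated
transform (6n coefficients for n samples at 5 levels) yields CR > 1 only
for sparse blocks — smooth/polynomial blocks reach ≈ 1.05–1.2, noisy ECG
blocks fall below 1.  Published CR figures for this scheme family
(roughly 1.7–7.4) are only reachable when side information is not counted;
the accounting terms are therefore switchable, and the acceptance script
reports both the full and the payload-only figures rather than promising
any published value.  Entropy coding and rate–distortion optimization are
out of scope.

The byte container is `NEC1` magic, version byte, then
`<u32 n, u8 levels, u8 bits, u8 input_bit_depth>`, a length-prefixed
wavelet name, per detail level `<f32 min, f32 max, u32 count>` + packed
bitmap + codes (1 byte each for bits ≤ 8, 2 bytes otherwise), and the same
header + codes for the approximation.  Decoding validates that bitmap
population equals payload count per level.

## Block streaming

Blocks of 1000 samples (4 s at 250 Hz, 2 s at 500 Hz) are the processing
unit everywhere: input delivered in arbitrary chunks is re-buffered to the
configured block size, and whole-record processing uses the identical
state machine, so streamed and offline runs are bit-identical — verified on
100 random records.  Carried state: the detector's reference amplitude,
refractory clock and the last two boundary samples (so a maximum on the
boundary still sees both neighbours), plus open alarm runs (a bradycardia
run spanning a block boundary stays one event).  A short final block is
processed with as many levels as its length allows and logged.  A
boundary-spanning plateau of exactly equal samples would resolve per-block;
with any noise this is measure-zero and it is not handled specially.
Per-block processing time is well under the block duration on one CPU
(asserted generously in the tests as a soft real-time contract).

## Synthetic data

The generator stands in for clinical recordings in all tests.  Beat times
follow a piecewise-constant rate profile (default 150 bpm) with
bradycardia episodes spliced in exactly (each episode contributes its
requested RR values to the ground truth); beats snap to the sample grid so
truth indices are exact.  The QRS is a Ricker (Gaussian second-derivative)
pulse, width 40 ms with σ = width/5, putting its spectral energy in the
5–40 Hz band like a real neonatal QRS; optional small Gaussian P/T waves
are off by default.  Baseline wander (< 1 Hz sine), mains pickup and white
noise are added on top of the clean beat train, so ground-truth peak times
never depend on the noise draw.  One seeded generator drives everything;
the same spec and seed reproduce the waveform bit-for-bit.

What it does **not** model: respiration coupling, autonomic heart-rate
variability, ectopic beats, electrode-pop artifacts, morphology changes.
Passing tests therefore demonstrate the algorithm logic and its noise
robustness under these idealized conditions, not clinical performance.

## Problem sizes and numerical choices

Tests use 10 s–10 min synthetic records; detector performance is measured
on five seeded 10-minute records (≈ 7 400 beats), denoising gain on twenty
20 s records spanning 0–10 dB input SNR, and streaming equivalence on one
hundred 15–25 s records at 250/500 Hz.  Reconstruction exactness is
asserted at 1e−8 (observed ≈ 1e−15); oracle comparisons (thresholds, HRV)
at 1e−12/1e−9; peak matching within ±2 samples.  Degenerate inputs raise
explicit errors (zero-energy spectra, < 2 coefficients for a threshold,
too-short signals) or return empty results where the contract asks for
them (flat signal → no peaks, < 2 peaks → empty RR series).

## Known limitations

* The adaptive threshold over-shrinks very clean signals (see above).
* WFDB support covers text headers, format-16/212 signals and MIT-format
  annotations — the subset this pipeline touches — not the full
  specification.
* The reference-peak decay constant (0.99/block) is a pragmatic tracking
  choice; pathologically alternating amplitudes could defeat it.
* Tachycardia and irregularity flags are rule-based screens, not
  classifiers; they are meant to call a clinician, not to diagnose.
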