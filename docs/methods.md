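# Methods

This note documents the models, procedures, parameter defaults and design
choices behind `laparosound`, and what the synthetic-data results do and do
not show.

## Channel characterization

**MLS measurement.** A maximum length sequence of order *n* is a ±1
pseudo-random sequence of period P = 2ⁿ − 1 produced by a linear-feedback
shift register with primitive feedback taps (a per-order table of standard
primitive polynomials is embedded; user-supplied taps are validated through
the flat-spectrum property |X(k)|² = P + 1 off DC, which only a true MLS
satisfies). The default order is 15 (P = 32767), covering channel decays up
to 0.68 s at 48 kHz; the period must exceed the channel's decay time.

The excitation stream repeats the sequence; the first recorded period is
discarded (channel settling) and the remaining periods — default 4 — are
averaged before deconvolution. Since no measurement hardware is in the loop,
"measurement" means applying a known FIR channel to the repeated stream by
linear convolution, optionally with additive white noise (the validation
suite uses −30 dB relative to signal RMS, matching a realistic measurement
noise floor).

**Deconvolution.** The IR estimate divides the averaged recording's spectrum
by the excitation's, bin by bin: Ĥ = Y·conj(X)/|X|². For an MLS this is
numerically benign (|X|² = P + 1 at every non-DC bin) and is equivalent to
the classical circular cross-correlation scaled by 1/(P + 1), except that it
also treats the DC bin exactly; the practical consequence is that an
identity channel returns a unit impulse to machine precision rather than
with an O(1/P) bias. Noiseless FIR channels shorter than one period are
recovered exactly; with −30 dB noise and 4-period averaging the relative L2
error is ≈ 1 %.

**Transfer functions.** H(ω) is the FFT of the zero-padded IR
(n_fft = next power of two ≥ 2× the IR length; one-sided grid excluding DC,
with the DC bin retained internally so the inverse transform round-trips).
The relative transfer function is ΔH(ω) = 20·log₁₀(|H_proto|/|H_ref|);
bins where |H_ref| < 1e-8 of its maximum are masked (NaN) rather than
fabricated, and are excluded from band averages.

**Fractional-octave smoothing.** "Savitzky–Golay with 1/6-octave relative
bandwidth" is made precise on a log-frequency axis: the dB curve is
resampled to 48 points/octave, filtered with window = round(bandwidth × 48)
forced odd (9 points for 1/6 octave) and polynomial order 2, and
interpolated back. Constants and log-frequency-linear ramps pass through
exactly; on an FFT-style linear grid, per-bin noise RMS is roughly halved.
Smoothing operates on dB magnitude only — the quantity displayed and
summarized — not on the complex spectrum.

**Band summaries** are arithmetic means of ΔH over bins in a band, reported
by default over 100 Hz–7.5 kHz (the classification front end's high-pass
corner to its mel upper edge). Note that on a linear grid this weights high
frequencies more than a log-spaced average would; for the flat dual-channel
profile the two coincide.

## Synthetic data

**Tissue sounds.** Each non-idle class is band-limited Gaussian noise
(4th-order Butterworth bandpass) around a class center frequency, amplitude
modulated by a Poisson train of exponentially decaying bursts, over a pink
broadband noise floor — a "crackle plus hiss" caricature of electrosurgical
sound. Idle is pink noise alone at a lower level. Defaults: centers
600/1500/3000/5000 Hz (liver/muscle/fat/fascia), bandwidths 400–1000 Hz,
burst rates 9–13 Hz with 30–50 ms decays, burst RMS −25 dBFS over a −45 dBFS
floor, idle at −50 dBFS; tissue durations uniform in 0.76–5.17 s, idle up to
a 20 s desk-scale cap (the much longer idle pauses of real recordings are a
config option; the balancing logic is unaffected by the cap). Everything is
deterministic given the per-file seed.

The centers are spaced to remain distinguishable after 64-band mel pooling.
The generator is *not* a physical model of plasma acoustics or abdominal
reverberation; what passing tests show is that the pipeline's mechanics —
front end, balancing, splitting, training, channel adaptation — behave
correctly on data with the assumed statistical structure, not that any
particular accuracy would be obtained on real surgical audio. Published
absolute accuracies are therefore not reproduction targets.

**Adapter channels.** A channel profile is a list of (frequency, gain dB)
breakpoints, interpolated linearly in log-frequency and held constant
outside the outermost anchors. The four defaults: reference (flat 0 dB),
dual-channel insert (flat −9.4 dB), Luer-Lock (flat to 200 Hz, then rolling
off to −55 dB at 1 kHz), silicone tube (flat to 300 Hz, −40 dB at 1 kHz,
10–20 dB above the Luer-Lock in the 300–1000 Hz region). IRs are realized
as 1024-tap minimum-phase FIRs at 48 kHz via the real-cepstrum method
(log-magnitude → cepstrum → causal fold → exponentiate); minimum phase
avoids pre-ringing, as a physical acoustic path would. Each designed IR is
verified against its breakpoints to ±2 dB at construction. The tube's 1 kHz
attenuation is accepted at ≤ −35 dB: the measured figure it emulates is a
read-off ("about −40 dB"), not a hard specification.

## Classification pipeline

**Front end.** Mono conversion by channel averaging; polyphase resampling
(Kaiser β = 5) to 16 kHz; 100 Hz 4th-order Butterworth high-pass applied
forward-backward (zero phase, preserving burst timing); segmentation into
0.98 s windows with 75 % overlap (hop 0.245 s) — signals shorter than one
window are zero-padded to exactly one, and for longer signals the trailing
remainder is dropped (padding is defined only for sub-window signals);
per window, 25 ms Hann frames with 10 ms hop and no centering give exactly
(15680 − 400)/160 + 1 = 96 frames, pooled through 64 HTK-mel peak-1
triangular filters over 125–7500 Hz on the magnitude spectrum, then
log(mel + 0.001). The offset keeps silence finite at log(0.001).
Magnitude-vs-power and the log offset follow the common audio-event
front-end convention; all constants are configurable.

**Dataset assembly.** The idle class's accumulated duration is capped at
the largest non-idle class total (seeded shuffle, greedy accumulation —
deterministic and idempotent). Splits are 80:10:10 at *recording* level,
stratified by class (≥ 3 recordings per class required), so overlapping
windows from one recording can never straddle splits; validation and test
get at least one recording per class.

**Model.** A compact CNN (~10k parameters): three 3×3 stride-2 convolution
blocks (8/16/32 channels, ReLU), mean-pooling over the *time* axis only,
and a linear softmax head. Pooling only over time is deliberate: with a
shallow network, global pooling over both axes would discard mel-band
position, which is exactly where the class information lives. The
implementation (convolutions, backprop, Adam and RMSprop) is pure
numpy/BLAS, dependency-free and deterministic for a fixed seed; the
architecture is pluggable so a larger pretrained backbone with the same
96×64 input geometry can be dropped in.

**Training.** Inputs are standardized by the training set's global
mean/std. Minibatch cross-entropy with ADAM or RMSprop; default 30 epochs
with early stopping (patience 10); the returned weights are those of the
epoch with minimum validation loss. The grid search covers
{ADAM, RMSprop} × {1e-3, 1e-4, 1e-5} × {64, 128, 256} exhaustively, selects
each cell by validation loss, and picks the winning cell by test accuracy —
mirroring the original protocol, with the optimistic bias flagged in the
report and a validation-based selection available (`select_by="val"`).

**Fine-tuning.** All weights remain trainable; the base model's input
normalization is inherited (re-normalizing on convolved data would absorb
part of the channel effect that fine-tuning is meant to learn); selection is
again by best validation loss; the adapter identity is recorded as
provenance, and train/validation sets from different channels are rejected.

**Channel simulation.** Convolution output (length M + N − 1) is trimmed to
the input length M, keeping leading alignment, so convolved datasets are
drop-in replacements (same durations, window counts, labels). Convolved
signals are not renormalized — relative level is part of the channel
effect — except for a clipping guard (peak scaled to 0.99, gain recorded in
the manifest). IRs are polyphase-resampled when sampling rates differ;
convolution runs at the audio's native rate.

**Metrics.** mAcc is overall (micro) accuracy; mAP/mAR are macro precision/
recall; F1 = 2·mAP·mAR/(mAP + mAR). These definitions are the ones
consistent with the harmonic-mean relation verifiable on the published
result tables (eight of nine fine-tuned rows agree to ≤ 1e-4; one row is
internally inconsistent beyond rounding and is flagged as such in
`laparosound.published`). Classes absent from both labels and predictions
are excluded from macro means; an undefined per-class precision counts as 0
with a warning. A macro-accuracy variant is available behind a flag.
Display rounding is 4 decimal places.

## The channel-shift experiment

`run_channel_shift_experiment` (defaults: seed 42, n_per_class 40, tube
channel, RMSprop 1e-3, batch 128, 30 epochs) synthesizes the dataset,
balances and splits it, trains the base model on clean patches, evaluates
it on clean and tube-convolved test sets, fine-tunes on tube-convolved
train/validation sets, and re-evaluates. At these problem sizes (~1900
patches; a few minutes on one CPU) the base model collapses under the tube
channel while fine-tuning recovers essentially the whole gap — the
qualitative degradation-and-recovery pattern of the real measurements. The
recovery is near-total here because the synthetic classes' in-band
signal-to-floor ratio is invariant under LTI filtering; real recordings add
ambient noise *after* the adapter, which caps recovery — one reason
absolute accuracies are out of scope.

## Numerical notes and limitations

- All generators take explicit integer seeds; fixed seeds reproduce
  byte-identical audio and identical training trajectories.
- IR design uses an 8192-point FFT grid; profiles requesting gain > 0 dB are
  rejected as unrealizable for a passive acoustic path.
- The linear-grid band average weights octaves unevenly (see above).
- WAV I/O is 32-bit float; integer PCM inputs are scaled to full scale.
- The tissue-sound generator makes no claim of acoustic realism; transfer
  of any accuracy figure to real electrosurgical audio is untested here.
- Time-varying or nonlinear channels, additive ambient-noise mixing, and
  phase/group-delay analysis are out of scope.
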