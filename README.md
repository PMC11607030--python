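# laparosound

Tissue-specific sounds produced during electrosurgery (diathermy) carry
information a machine-listening system can use in the operating room — but a
microphone cannot simply be dropped into an insufflated abdomen. Acoustic
adapters mounted on a laparoscopic trocar (a dual-channel insert, a Luer-Lock
microphone adapter, a silicone tube) make the sound accessible, at the price
of an acoustic channel that attenuates and colors it. `laparosound`
implements the complete analysis chain for studying that problem:

- **Channel characterization.** Maximum-length-sequence (MLS) excitation and
  impulse-response (IR) estimation by circular deconvolution; transfer
  functions H(ω) from IRs; the *relative transfer function*

  ΔH(ω) = 20·log₁₀(|H_adapter(ω)| / |H_ref(ω)|)  [dB],

  with 1/6-octave Savitzky–Golay smoothing and band averages.
- **Channel simulation.** Recording through an adapter is modeled as linear
  convolution y[n] = (f ∗ g)[n] of the direct recording f with the adapter
  IR g, at single-file and dataset scale.
- **Classification.** A 96×64 log-mel front end (mono 16 kHz, 100 Hz
  high-pass, 0.98 s windows with 75 % overlap, 25 ms/10 ms STFT, 64 HTK-mel
  bands over 125–7500 Hz), idle-class balancing, recording-level 80:10:10
  splits, and a compact CNN with ADAM/RMSprop grid search
  ({1e-3, 1e-4, 1e-5} × {64, 128, 256}), best-validation-loss model
  selection, and full fine-tuning on channel-convolved training sets.
- **Synthetic data.** Since no recorded dataset is distributed, a generator
  produces five spectrally separable classes (liver, muscle, fat, fascia,
  idle) and minimum-phase adapter IRs matching the measured channel profiles
  (near-flat ≈ −9.4 dB; roll-offs from 200 Hz and 300 Hz, the latter
  reaching ≈ −40 dB at 1 kHz).

It is a library first — `import laparosound` and the scripts in `examples/`
are the intended interface — with a thin `laparosound` CLI for the
shell-friendly steps (`synth`, `synth-ir`, `measure-ir`, `tf`, `convolve`,
`preprocess`).

## Worked example

```python
import numpy as np
from laparosound import (default_channel_profiles, synth_adapter_ir,
                         tf_from_ir, relative_tf, smooth_fractional_octave,
                         band_average, run_channel_shift_experiment)

profiles = default_channel_profiles()
h_ref = tf_from_ir(synth_adapter_ir(profiles["reference"]))
rtf = smooth_fractional_octave(
    relative_tf(tf_from_ir(synth_adapter_ir(profiles["tube"])), h_ref))
print(round(band_average(rtf, 100, 7500), 1),
      round(rtf.delta_db[np.argmin(abs(rtf.freqs_hz - 1000))], 1))
# -43.1 -39.9   -> tube channel: -43.1 dB band average, -39.9 dB at 1 kHz

res = run_channel_shift_experiment(seed=42, n_per_class=40)
print(f"{res.macc_clean:.4f} {res.macc_shifted:.4f} {res.macc_finetuned:.4f}")
# 1.0000 0.2297 1.0000
```

The last line is the package's central finding on its synthetic data: a
classifier trained on reference-channel audio scores mAcc 1.00 on its own
test set, collapses to 0.23 when the test set is convolved with the strongly
attenuating tube channel, and returns to 1.00 after fine-tuning on a
tube-convolved training set — the qualitative degradation-and-recovery
pattern reported for real adapter measurements.

Each script in `examples/` demonstrates one capability (dataset synthesis,
simulated MLS measurement, relative TFs, channel simulation, the experiment
above, and the metric arithmetic of the published result tables).

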