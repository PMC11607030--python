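"""Simulated MLS measurement of an adapter channel.

A maximum length sequence (period 2^12 - 1) is played through the synthetic
silicone-tube channel; the impulse response is recovered by circular
deconvolution, averaging 4 periods after discarding the first for settling.
"""

import numpy as np

from laparosound import default_channel_profiles, measure_ir, synth_adapter_ir

true_ir = synth_adapter_ir(default_channel_profiles()["tube"])
est = measure_ir(true_ir, order=12, n_periods=5, noise_db=-30, seed=0)

n = len(true_ir)
err = np.linalg.norm(est.samples[:n] - true_ir.samples) / np.linalg.norm(true_ir.samples)
print(f"MLS order 12 (period 4095), {est.meta['periods_averaged']} periods averaged")
print(f"relative L2 error of the recovered IR: {err:.4f}")
print("With a -30 dB noise floor the estimate stays within a few percent of "
      "the designed channel; noiseless recovery is exact to float precision.")
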