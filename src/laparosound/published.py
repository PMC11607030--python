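"""Previously reported adapter-study classification metrics.

These are the published evaluation numbers for a diathermy-sound classifier
measured through three trocar adapter prototypes (dual-channel insert,
Luer-Lock adapter, silicone tube) under different trocar sizes, with and
without an instrument inserted.  They serve as reference values for the
metric arithmetic in :mod:`laparosound.metrics`: the F1 column must follow
from the mAP/mAR columns by the harmonic mean, and the dispersion summary of
the original (non-fine-tuned) model across convolved test sets must follow
from the mAcc column.

One row ("Tube 13 mm w/o I", flagged ``f1_consistent = False``) prints an F1
of 0.9148 while the harmonic mean of its printed mAP (0.9118) and mAR
(0.9261) is 0.9189 — a 4.1e-3 discrepancy beyond rounding of the source
table; every other row agrees to better than 1e-4.
"""

from __future__ import annotations

import pandas as pd

#: Headline metrics of the reference-microphone model on its own test set.
HEADLINE = {"mAcc": 0.966, "mAP": 0.943, "mAR": 0.968, "f1": 0.955}

#: Per-test-set results: mAcc of the original (reference-trained) model on
#: each adapter-convolved test set, and mAcc/mAP/mAR/F1 of the model
#: fine-tuned for that adapter.  "w/ I" = instrument inserted.
ADAPTER_RESULTS = pd.DataFrame(
    [
        # test set,               orig mAcc, ft mAcc, ft mAP, ft mAR, ft F1
        ("Dual channel",            0.9097, 0.8952, 0.8804, 0.9271, 0.9032),
        ("Luer-Lock 11 mm w/o I",   0.5939, 0.9598, 0.9590, 0.9494, 0.9542),
        ("Luer-Lock 11 mm w/ I",    0.4061, 0.9314, 0.9290, 0.9348, 0.9319),
        ("Luer-Lock 13 mm w/o I",   0.6941, 0.9420, 0.9224, 0.9207, 0.9216),
        ("Luer-Lock 13 mm w/ I",    0.5900, 0.9123, 0.8789, 0.9321, 0.9047),
        ("Tube 11 mm w/o I",        0.6236, 0.8134, 0.8299, 0.8496, 0.8397),
        ("Tube 11 mm w/ I",         0.5682, 0.8504, 0.9020, 0.8936, 0.8978),
        ("Tube 13 mm w/o I",        0.5728, 0.9268, 0.9118, 0.9261, 0.9148),
        ("Tube 13 mm w/ I",         0.6282, 0.7416, 0.7888, 0.7594, 0.7738),
    ],
    columns=["test_set", "orig_mAcc", "ft_mAcc", "ft_mAP", "ft_mAR", "ft_f1"],
).assign(f1_consistent=[True, True, True, True, True, True, True, False, True])

#: mAcc of the reference model on the unconvolved (reference-mic) test set.
REFERENCE_TESTSET_MACC = 0.9657

#: Reported cross-test-set summary of the original model: mean and sample
#: standard deviation of the nine orig_mAcc values above.
ORIG_MODEL_SUMMARY = {"mean": 0.6207, "std": 0.1331}

#: Reported average attenuation (dB) of the dual-channel insert relative to
#: the reference microphone.
DUAL_CHANNEL_AVG_ATTENUATION_DB = 9.4
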