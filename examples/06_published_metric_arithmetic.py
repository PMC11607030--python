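"""Verify the arithmetic of the published adapter-study result tables.

The F1 column of the fine-tuned models must equal the harmonic mean of the
printed macro precision (mAP) and macro recall (mAR); the reported
0.6207 +/- 0.1331 summary must equal the mean and sample std of the nine
original-model accuracies.
"""

from laparosound import f1_from_pr, summarize_across_testsets
from laparosound.published import ADAPTER_RESULTS, HEADLINE

f1 = f1_from_pr(HEADLINE["mAP"], HEADLINE["mAR"])
print(f"headline: F1(mAP={HEADLINE['mAP']}, mAR={HEADLINE['mAR']}) = {f1:.3f} "
      f"(printed {HEADLINE['f1']})\n")

for row in ADAPTER_RESULTS.itertuples():
    f1 = f1_from_pr(row.ft_mAP, row.ft_mAR)
    flag = "" if row.f1_consistent else "   <- printed F1 inconsistent with its own mAP/mAR"
    print(f"{row.test_set:24s} computed {f1:.4f}  printed {row.ft_f1:.4f}{flag}")

mean, std = summarize_across_testsets(ADAPTER_RESULTS["orig_mAcc"])
print(f"\noriginal model across convolved test sets: {mean:.4f} +/- {std:.4f}")
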