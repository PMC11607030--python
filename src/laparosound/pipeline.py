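"""End-to-end experiment drivers built from the library modules.

The central experiment reproduces the channel-shift finding: a classifier
trained on reference-microphone audio degrades when tested on audio
convolved with a strongly attenuating adapter channel (the silicone tube),
and fine-tuning on a convolved training set recovers most of that loss.
Everything is generated in memory from the synthetic dataset module; audio
is processed one recording at a time so memory stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import ImpulseResponse
from .channel import convolve
from .classifier import HyperParams, ModelSpec, TrainedModel, fine_tune, train
from .data import PatchData, SplitSpec, assemble_patches, balance_idle, split
from .preprocess import patches_from_audio
from .synth import (CLASS_NAMES, default_channel_profiles, default_tissue_specs,
                    synth_adapter_ir, synth_tissue_sound)

TISSUE_CLASSES = tuple(c for c in CLASS_NAMES)


def synth_manifest(n_per_class: int, seed: int,
                   specs: dict | None = None) -> pd.DataFrame:
    """In-memory dataset plan: one row per recording with its duration and seed."""
    specs = specs if specs is not None else default_tissue_specs()
    rows = []
    for ci, (cls, spec) in enumerate(sorted(specs.items())):
        dur_rng = np.random.default_rng((seed * 1009 + ci) % 2**31)
        lo, hi = spec.duration_range_s
        durations = dur_rng.uniform(lo, hi, size=n_per_class)
        for i, dur in enumerate(durations):
            file_seed = (seed * 100_003 + ci * 1013 + i) % 2**31
            rows.append({"path": f"{cls}_{i:03d}", "class": cls,
                         "duration_s": float(dur), "seed": file_seed})
    return pd.DataFrame(rows)


def patches_for_manifest(manifest: pd.DataFrame, specs: dict,
                         ir: ImpulseResponse | None = None) -> PatchData:
    """Synthesize, (optionally) convolve, and preprocess every recording."""
    sets = []
    for rec in manifest.to_dict("records"):
        spec = specs[rec["class"]]
        sig = synth_tissue_sound(spec, rec["duration_s"], rec["seed"])
        sig.source_id = rec["path"]
        if ir is not None:
            sig = convolve(sig, ir)
        sets.append(patches_from_audio(sig))
    return assemble_patches(sets, TISSUE_CLASSES,
                            channel=ir.label if ir is not None else "reference")


@dataclass
class ChannelShiftResult:
    """Outcome of the channel-shift / fine-tuning experiment."""

    base_model: TrainedModel
    finetuned_model: TrainedModel
    macc_clean: float          # base model on unconvolved test set
    macc_shifted: float        # base model on tube-convolved test set
    macc_finetuned: float      # fine-tuned model on tube-convolved test set
    n_test_patches: int = 0

    @property
    def gap(self) -> float:
        return self.macc_clean - self.macc_shifted

    @property
    def gap_recovered_fraction(self) -> float:
        if self.gap <= 0:
            return float("nan")
        return (self.macc_finetuned - self.macc_shifted) / self.gap


def run_channel_shift_experiment(seed: int = 42, n_per_class: int = 40,
                                 channel: str = "tube",
                                 hp: HyperParams | None = None,
                                 spec: ModelSpec = ModelSpec()
                                 ) -> ChannelShiftResult:
    """Train on reference audio, test under an adapter channel, fine-tune.

    Steps: synthesize the default five-class dataset, balance the idle
    class, split 80:10:10 at recording level, train the compact CNN on clean
    patches, evaluate on the clean and channel-convolved test sets, then
    fine-tune on the convolved training/validation sets and re-evaluate.
    """
    specs = default_tissue_specs()
    manifest = synth_manifest(n_per_class, seed, specs)
    manifest = balance_idle(manifest, seed=seed)
    tr_m, va_m, te_m = split(manifest, SplitSpec(seed=seed))

    ir = synth_adapter_ir(default_channel_profiles()[channel])
    clean = {name: patches_for_manifest(m, specs)
             for name, m in (("train", tr_m), ("val", va_m), ("test", te_m))}
    shifted = {name: patches_for_manifest(m, specs, ir=ir)
               for name, m in (("train", tr_m), ("val", va_m), ("test", te_m))}

    if hp is None:
        hp = HyperParams(optimizer="RMSprop", learning_rate=1e-3,
                         batch_size=128, epochs=30, seed=seed)
    base = train(clean["train"], clean["val"], hp, spec)
    macc_clean = base.evaluate(clean["test"]).mAcc
    macc_shifted = base.evaluate(shifted["test"]).mAcc

    ft = fine_tune(base, shifted["train"], shifted["val"], hp, channel=channel)
    macc_ft = ft.evaluate(shifted["test"]).mAcc

    return ChannelShiftResult(base_model=base, finetuned_model=ft,
                              macc_clean=macc_clean, macc_shifted=macc_shifted,
                              macc_finetuned=macc_ft,
                              n_test_patches=len(clean["test"]))
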