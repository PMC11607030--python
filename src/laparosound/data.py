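"""Dataset assembly: idle balancing, recording-level splitting, patch sets.

Idle segments (pauses between diathermy events) are much longer than the
tissue samples, so the idle class is balanced by capping its accumulated
duration at the maximum accumulated duration of any other class.  Splits are
made at recording level, stratified by class, so that overlapping windows
cut from one recording can never leak across train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MelPatchSet


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split configuration (default 80:10:10)."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")


def balance_idle(manifest: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Cap the idle class's total duration at the largest non-idle class total.

    Idle rows are shuffled with the given seed and accumulated greedily until
    adding the next file would exceed the cap.  Non-idle rows pass through
    untouched; the operation is idempotent.
    """
    is_idle = manifest["class"] == "idle"
    non_idle = manifest[~is_idle]
    if non_idle.empty:
        raise ValueError("manifest needs at least one non-idle class")
    idle = manifest[is_idle]
    if idle.empty:
        return manifest.copy()

    cap = non_idle.groupby("class")["duration_s"].sum().max()
    if idle["duration_s"].sum() <= cap:
        return manifest.copy()

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(idle))
    keep, total = [], 0.0
    for pos in order:
        dur = float(idle.iloc[pos]["duration_s"])
        if total + dur > cap:
            continue  # greedy: skip files that would overshoot, try smaller ones
        keep.append(idle.index[pos])
        total += dur
    kept = manifest.loc[sorted(set(keep) | set(non_idle.index))]
    return kept.reset_index(drop=True)


def split(manifest: pd.DataFrame, spec: SplitSpec
          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition recordings into train/val/test manifests.

    Stratified by class: within each class the recordings are shuffled with
    the split seed, then sliced so per-class proportions match the ratios to
    within one recording (validation and test get at least one recording
    each).  Every recording lands in exactly one split.
    """
    rng = np.random.default_rng(spec.seed)
    parts: dict[str, list[pd.DataFrame]] = {"train": [], "val": [], "test": []}

    groups = manifest.groupby("class") if spec.stratified else [(None, manifest)]
    for cls, grp in groups:
        n = len(grp)
        if spec.stratified and n < 3:
            raise ValueError(
                f"class {cls!r} has only {n} recordings; stratified split needs >= 3")
        order = rng.permutation(n)
        n_val = max(1, int(round(spec.ratios[1] * n)))
        n_test = max(1, int(round(spec.ratios[2] * n)))
        if n_val + n_test >= n:
            n_val = n_test = 1
        test_idx = order[:n_test]
        val_idx = order[n_test:n_test + n_val]
        train_idx = order[n_test + n_val:]
        parts["test"].append(grp.iloc[test_idx])
        parts["val"].append(grp.iloc[val_idx])
        parts["train"].append(grp.iloc[train_idx])

    out = []
    for name in ("train", "val", "test"):
        df = pd.concat(parts[name]).reset_index(drop=True)
        df = df.assign(split=name)
        out.append(df)
    return tuple(out)


@dataclass
class PatchData:
    """Flat patch-level training array assembled from many recordings."""

    x: np.ndarray          # (N, 96, 64)
    y: np.ndarray          # (N,) integer class indices
    source_ids: np.ndarray  # (N,) originating recording per patch
    classes: tuple[str, ...]
    channel: str = "reference"  # acoustic channel the patches passed through

    def __len__(self) -> int:
        return int(self.x.shape[0])


def assemble_patches(patch_sets: list[MelPatchSet], classes: tuple[str, ...],
                     channel: str = "reference") -> PatchData:
    """Stack per-recording patch sets into one labeled array."""
    xs, ys, sids = [], [], []
    cls_index = {c: i for i, c in enumerate(classes)}
    for ps in patch_sets:
        if ps.label not in cls_index:
            raise ValueError(f"label {ps.label!r} not in class set {classes}")
        xs.append(ps.patches.astype(np.float32))
        ys.append(np.full(ps.k, cls_index[ps.label], dtype=np.int64))
        sids.append(np.full(ps.k, ps.source_id, dtype=object))
    return PatchData(x=np.concatenate(xs), y=np.concatenate(ys),
                     source_ids=np.concatenate(sids), classes=tuple(classes),
                     channel=channel)
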