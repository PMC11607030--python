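"""Channel simulation: convolve audio with an adapter impulse response.

A recording made through an adapter is modeled as the linear convolution of
the directly recorded signal f (length M) with the adapter's impulse
response g (length N):

    y[n] = (f * g)[n] = sum_j f[j] g[n - j],   n = 0 .. M + N - 2.

The dataset writer trims the output back to M samples (keeping the leading
alignment) so that durations, window counts and labels of a convolved
dataset line up with the unconvolved pipeline, making the convolved sets
drop-in replacements for the originals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, resample_poly

from .audio import AudioSignal, ImpulseResponse, read_wav, write_wav

#: Peak magnitude above which convolved output is rescaled before writing.
CLIP_GUARD_PEAK = 0.99


def _resample_ir(ir: ImpulseResponse, fs: int) -> ImpulseResponse:
    from math import gcd

    g = gcd(int(fs), int(ir.fs))
    up, down = int(fs) // g, int(ir.fs) // g
    samples = resample_poly(ir.samples, up, down)
    return ImpulseResponse(samples=samples, fs=fs, source=ir.source,
                           label=ir.label, meta=dict(ir.meta))


def convolve(signal: AudioSignal, ir: ImpulseResponse, trim: bool = True,
             allow_resample: bool = True) -> AudioSignal:
    """Apply an adapter channel to a signal by linear convolution.

    ``trim`` keeps the first M samples of the M+N-1 convolution output.
    When sampling rates differ the IR is polyphase-resampled to the audio's
    rate first (``allow_resample=False`` rejects the mismatch instead).
    """
    if len(ir) == 0:
        raise ValueError("impulse response is empty")
    if ir.fs != signal.fs:
        if not allow_resample:
            raise ValueError(
                f"sampling rate mismatch: signal {signal.fs} Hz vs IR {ir.fs} Hz")
        ir = _resample_ir(ir, signal.fs)
    x = signal.samples
    if x.ndim != 1:
        raise ValueError("convolve expects single-channel audio")
    y = fftconvolve(x, ir.samples)
    if trim:
        y = y[: x.size]
    return AudioSignal(samples=y, fs=signal.fs, label=signal.label,
                       source_id=signal.source_id)


def clip_guard(signal: AudioSignal, peak: float = CLIP_GUARD_PEAK
               ) -> tuple[AudioSignal, float]:
    """Scale down to ``peak`` if the waveform would clip; returns (signal, gain)."""
    m = float(np.max(np.abs(signal.samples)))
    if m <= 1.0:
        return signal, 1.0
    gain = peak / m
    return signal.with_samples(signal.samples * gain), gain


def convolve_dataset(manifest: pd.DataFrame, ir: ImpulseResponse,
                     in_dir: str | Path, out_dir: str | Path,
                     trim: bool = True) -> pd.DataFrame:
    """Convolve every file of a dataset with one adapter IR.

    Returns a new manifest with the same rows plus provenance columns
    ``ir_name`` and ``applied_gain``.  Any unreadable input aborts the run —
    no partial silent success.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    missing = [str(in_dir / p) for p in manifest["path"]
               if not (in_dir / p).exists()]
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} dataset file(s) unreadable, e.g. {missing[0]}")

    rows = []
    for rec in manifest.to_dict("records"):
        sig = read_wav(in_dir / rec["path"], label=rec.get("class"))
        out = convolve(sig, ir, trim=trim)
        out, gain = clip_guard(out)
        write_wav(out_dir / rec["path"], out)
        row = dict(rec)
        row["ir_name"] = ir.label
        row["applied_gain"] = gain
        rows.append(row)
    out_manifest = pd.DataFrame(rows)
    out_manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_manifest
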