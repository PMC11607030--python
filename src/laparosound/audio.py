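"""Core audio containers and WAV I/O.

Waveforms are kept as 1-D float64 arrays in ``[-1, 1]`` full-scale convention
(dBFS levels refer to an RMS of 1.0). Files are written as 32-bit float WAV so
no quantization enters the round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioSignal:
    """Single-channel sampled waveform with label metadata.

    Parameters
    ----------
    samples : ndarray
        Waveform, shape ``(M,)`` (mono) or ``(M, C)`` (multi-channel).
    fs : int
        Sampling rate in Hz.
    label : str or None
        Class label (``liver``, ``muscle``, ``fat``, ``fascia``, ``idle``).
    source_id : str
        Identifier of the originating recording; propagated through the
        pipeline so that windows cut from one recording can never straddle a
        train/test split.
    """

    samples: np.ndarray
    fs: int
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("AudioSignal requires at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples: np.ndarray, fs: int | None = None) -> "AudioSignal":
        """Copy of this signal with new samples (metadata preserved)."""
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)


@dataclass
class ImpulseResponse:
    """Finite impulse response ``h[n]`` of a linear time-invariant channel."""

    samples: np.ndarray
    fs: int
    source: str = "synthetic"  # "measured" | "synthetic"
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("ImpulseResponse must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ImpulseResponse samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.source not in ("measured", "synthetic"):
            raise ValueError(f"unknown IR source {self.source!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def energy(self) -> float:
        return float(np.sum(self.samples**2))


def read_wav(path: str | Path, label: str | None = None,
             source_id: str | None = None) -> AudioSignal:
    path = Path(path)
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":  # integer PCM -> full-scale float
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioSignal(samples=data, fs=int(fs), label=label,
                       source_id=source_id if source_id is not None else path.stem)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(signal.fs), signal.samples.astype(np.float32))


def write_ir(path: str | Path, ir: ImpulseResponse) -> None:
    """IR as single-channel float WAV plus a JSON sidecar with metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(ir.fs), ir.samples.astype(np.float32))
    sidecar = {
        "name": ir.label,
        "fs": int(ir.fs),
        "length": len(ir),
        "source": ir.source,
        **{k: v for k, v in ir.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_ir(path: str | Path) -> ImpulseResponse:
    path = Path(path)
    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim > 1:
        data = data[:, 0]
    meta: dict = {}
    label = path.stem
    source = "synthetic"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.pop("name", label) or label
        source = meta.pop("source", source)
        meta.pop("fs", None)
        meta.pop("length", None)
    return ImpulseResponse(samples=data, fs=int(fs), source=source,
                           label=label, meta=meta)
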