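"""Audio-to-spectrogram front end.

Every recording, whatever its native rate or channel count, is reduced to a
stack of 96x64 log-mel patches through five steps:

1. conversion to mono and polyphase resampling to 16 kHz,
2. a 100 Hz high-pass (4th-order Butterworth, applied forward-backward so
   transient timing is preserved),
3. zero-padding of signals shorter than one 0.98 s window,
4. segmentation into 0.98 s windows with 75 % overlap (0.245 s hop); for
   signals longer than one window the trailing remainder is dropped,
5. a log-scaled mel spectrogram per window: 25 ms Hann frames with a 10 ms
   hop (96 frames per window, no centering), 64 HTK-mel triangular bands
   spanning 125-7500 Hz on the magnitude spectrum, log(mel + 0.001).

A signal of K windows therefore yields a (K, 96, 64) patch stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal

TARGET_FS = 16_000
WINDOW_S = 0.98
OVERLAP = 0.75
HIGHPASS_HZ = 100.0

STFT_WIN = 400   # 25 ms at 16 kHz
STFT_HOP = 160   # 10 ms at 16 kHz
N_FFT = 512
N_MELS = 64
MEL_FMIN = 125.0
MEL_FMAX = 7500.0
LOG_OFFSET = 0.001

WINDOW_SAMPLES = int(round(WINDOW_S * TARGET_FS))          # 15680
HOP_SAMPLES = int(round(WINDOW_S * (1 - OVERLAP) * TARGET_FS))  # 3920
FRAMES_PER_PATCH = (WINDOW_SAMPLES - STFT_WIN) // STFT_HOP + 1  # 96


@dataclass
class MelPatchSet:
    """Stack of log-mel patches cut from one source recording."""

    patches: np.ndarray  # (K, 96, 64)
    label: str | None
    source_id: str

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 3 or self.patches.shape[1:] != (FRAMES_PER_PATCH, N_MELS):
            raise ValueError(
                f"patches must have shape (K, {FRAMES_PER_PATCH}, {N_MELS}), "
                f"got {self.patches.shape}")
        if self.patches.shape[0] < 1:
            raise ValueError("patch set must contain at least one patch")
        if not np.all(np.isfinite(self.patches)):
            raise ValueError("patches must be finite")

    @property
    def k(self) -> int:
        return int(self.patches.shape[0])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, patches=self.patches.astype(np.float32))
        meta = {"source_id": self.source_id, "label": self.label, "K": self.k}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "MelPatchSet":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(patches=data["patches"], label=meta["label"],
                   source_id=meta["source_id"])


def standardize(audio: AudioSignal, target_fs: int = TARGET_FS) -> AudioSignal:
    """Mono 16 kHz homogenization; multi-channel inputs are averaged."""
    x = audio.samples
    if x.ndim == 2:
        x = x.mean(axis=1)
    if audio.fs != target_fs:
        from math import gcd

        g = gcd(int(target_fs), int(audio.fs))
        x = sps.resample_poly(x, int(target_fs) // g, int(audio.fs) // g,
                              window=("kaiser", 5.0))
    if x.size == 0:
        raise ValueError("audio is empty after standardization")
    return AudioSignal(samples=x, fs=target_fs, label=audio.label,
                       source_id=audio.source_id)


def highpass(audio: AudioSignal, fc: float = HIGHPASS_HZ) -> AudioSignal:
    """Zero-phase 4th-order Butterworth high-pass at ``fc``."""
    if fc >= audio.fs / 2:
        raise ValueError(f"cutoff {fc} Hz at or above Nyquist ({audio.fs / 2} Hz)")
    sos = sps.butter(4, fc, btype="highpass", fs=audio.fs, output="sos")
    padlen = min(3 * (2 * 4 + 1), audio.n_samples - 1)
    y = sps.sosfiltfilt(sos, audio.samples, padlen=padlen)
    return audio.with_samples(y)


def n_windows(n_samples: int, win: int = WINDOW_SAMPLES,
              hop: int = HOP_SAMPLES) -> int:
    """Number of analysis windows for a signal of ``n_samples`` samples."""
    if n_samples < win:
        return 1  # zero-padded to one full window
    return (n_samples - win) // hop + 1


def segment(audio: AudioSignal, win_s: float = WINDOW_S,
            overlap: float = OVERLAP) -> list[np.ndarray]:
    """Cut a standardized signal into overlapping fixed-length windows.

    Signals shorter than one window are zero-padded at the end; for longer
    signals the trailing remainder that cannot fill a window is dropped.
    """
    win = int(round(win_s * audio.fs))
    hop = int(round(win_s * (1 - overlap) * audio.fs))
    x = audio.samples
    if x.size < win:
        return [np.pad(x, (0, win - x.size))]
    count = (x.size - win) // hop + 1
    return [x[i * hop: i * hop + win] for i in range(count)]


def mel_filterbank(n_mels: int = N_MELS, n_fft: int = N_FFT, fs: int = TARGET_FS,
                   fmin: float = MEL_FMIN, fmax: float = MEL_FMAX) -> np.ndarray:
    """HTK-mel triangular filterbank (peak-1 triangles), shape (n_mels, n_fft//2+1)."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)

    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    fb = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, c, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (fft_freqs - lo) / (c - lo)
        down = (hi - fft_freqs) / (hi - c)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_band_centers(n_mels: int = N_MELS, fmin: float = MEL_FMIN,
                     fmax: float = MEL_FMAX) -> np.ndarray:
    """Center frequencies (Hz) of the mel bands."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)

    edges = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(edges[1:-1])


_MEL_FB_CACHE: dict[tuple, np.ndarray] = {}


def logmel(window: np.ndarray) -> np.ndarray:
    """Log-mel patch of one 0.98 s window; shape (96, 64)."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 1 or window.size != WINDOW_SAMPLES:
        raise ValueError(
            f"window must be exactly {WINDOW_SAMPLES} samples "
            f"({WINDOW_S} s at {TARGET_FS} Hz), got {window.shape}")
    # frames without centering: first frame starts at sample 0
    idx = np.arange(STFT_WIN)[None, :] + STFT_HOP * np.arange(FRAMES_PER_PATCH)[:, None]
    frames = window[idx] * sps.get_window("hann", STFT_WIN, fftbins=True)
    mag = np.abs(np.fft.rfft(frames, N_FFT, axis=1))
    key = (N_MELS, N_FFT, TARGET_FS, MEL_FMIN, MEL_FMAX)
    if key not in _MEL_FB_CACHE:
        _MEL_FB_CACHE[key] = mel_filterbank(*key)
    mel = mag @ _MEL_FB_CACHE[key].T
    return np.log(mel + LOG_OFFSET)


def patches_from_audio(audio: AudioSignal) -> MelPatchSet:
    """Full front end: standardize -> high-pass -> segment -> log-mel stack."""
    std = standardize(audio)
    filt = highpass(std)
    windows = segment(filt)
    patches = np.stack([logmel(w) for w in windows])
    return MelPatchSet(patches=patches, label=audio.label,
                       source_id=audio.source_id)
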