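"""Synthetic diathermy-like audio and synthetic adapter channels.

No recorded operating-room dataset ships with this package.  This module
generates a labeled stand-in with the statistical structure the analysis
assumes: short tissue-dependent electrosurgical bursts (liver, muscle, fat,
fascia) over a broadband noise floor, long quiet ``idle`` segments, and
adapter channels described by piecewise frequency responses that are turned
into minimum-phase FIR impulse responses.

The tissue model is deliberately simple — band-limited noise around a
class-specific center frequency, amplitude-modulated by a Poisson train of
exponentially decaying bursts ("crackle plus hiss") — and is not claimed to
be physically accurate electrosurgical acoustics.  Its job is to give the
downstream spectrogram classifier five spectrally separable classes whose
relative in-band structure survives linear channel filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio import AudioSignal, ImpulseResponse, write_wav

CLASS_NAMES = ("liver", "muscle", "fat", "fascia", "idle")

#: Default sampling rate of synthesized material, matching a typical
#: measurement-chain rate; the classification front-end later resamples
#: to 16 kHz.
DEFAULT_FS = 48_000

#: Desk-scale cap on idle-segment duration (seconds).  Real idle pauses can
#: run to minutes; the cap keeps synthetic datasets small while leaving the
#: idle-balancing logic fully exercised.
DEFAULT_IDLE_MAX_S = 20.0

#: Duration range of non-idle samples (seconds).
TISSUE_DURATION_RANGE = (0.76, 5.17)


@dataclass(frozen=True)
class TissueSoundSpec:
    """Spectral/temporal recipe for one sound class.

    ``center_freq_hz``/``bandwidth_hz`` place the band-limited burst noise;
    ``burst_rate_hz`` and ``burst_decay_s`` shape the Poisson activation
    envelope; ``noise_floor_db`` is the RMS (dBFS) of the broadband floor.
    The idle class is floor only (``burst_rate_hz = 0``).
    """

    class_name: str
    center_freq_hz: float
    bandwidth_hz: float
    burst_rate_hz: float
    burst_decay_s: float
    noise_floor_db: float
    duration_range_s: tuple[float, float]
    level_db: float = -25.0  # target RMS of the burst component, dBFS

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        if self.class_name == "idle":
            if self.burst_rate_hz != 0:
                raise ValueError("idle class must have burst_rate_hz = 0")
        else:
            if self.center_freq_hz <= 0 or self.bandwidth_hz <= 0:
                raise ValueError("center_freq_hz and bandwidth_hz must be positive")
            if self.center_freq_hz + self.bandwidth_hz / 2 >= 8000:
                raise ValueError("band must stay below the 8 kHz mel upper edge")
        if self.burst_rate_hz < 0 or self.burst_decay_s <= 0:
            raise ValueError("invalid burst parameters")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError(f"invalid duration range {self.duration_range_s}")


def default_tissue_specs(idle_max_s: float = DEFAULT_IDLE_MAX_S) -> dict[str, TissueSoundSpec]:
    """Default five-class spec set.

    Centers (liver 600, muscle 1500, fat 3000, fascia 5000 Hz) are spaced so
    the classes remain distinguishable after 64-band mel pooling.
    """
    mk = TissueSoundSpec
    return {
        "liver": mk("liver", 600.0, 400.0, 9.0, 0.05, -45.0, TISSUE_DURATION_RANGE),
        "muscle": mk("muscle", 1500.0, 600.0, 11.0, 0.04, -45.0, TISSUE_DURATION_RANGE),
        "fat": mk("fat", 3000.0, 800.0, 13.0, 0.03, -45.0, TISSUE_DURATION_RANGE),
        "fascia": mk("fascia", 5000.0, 1000.0, 9.0, 0.04, -45.0, TISSUE_DURATION_RANGE),
        "idle": mk("idle", 0.0, 0.0, 0.0, 1.0, -50.0, (2.0, idle_max_s)),
    }


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / np.sqrt(np.mean(out**2))


def synth_tissue_sound(spec: TissueSoundSpec, duration_s: float, seed: int,
                       fs: int = DEFAULT_FS) -> AudioSignal:
    """Generate one labeled sound sample.

    Deterministic for fixed ``(spec, duration_s, seed)``.  ``duration_s``
    must lie inside ``spec.duration_range_s``.
    """
    lo, hi = spec.duration_range_s
    if not (lo <= duration_s <= hi):
        raise ValueError(
            f"duration {duration_s} s outside the {spec.class_name!r} range [{lo}, {hi}] s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    floor = _pink_noise(n, rng) * 10 ** (spec.noise_floor_db / 20)

    if spec.class_name == "idle" or spec.burst_rate_hz == 0:
        x = floor
    else:
        f_lo = spec.center_freq_hz - spec.bandwidth_hz / 2
        f_hi = spec.center_freq_hz + spec.bandwidth_hz / 2
        sos = sps.butter(2, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
        band = sps.sosfilt(sos, rng.standard_normal(n))

        n_bursts = rng.poisson(spec.burst_rate_hz * duration_s)
        onsets = rng.uniform(0.0, duration_s, size=max(n_bursts, 1))
        t = np.arange(n) / fs
        env = np.zeros(n)
        for t0 in onsets:
            tail = t >= t0
            env[tail] += np.exp(-(t[tail] - t0) / spec.burst_decay_s)
        burst = band * env
        burst *= 10 ** (spec.level_db / 20) / np.sqrt(np.mean(burst**2))
        x = burst + floor

    return AudioSignal(samples=x, fs=fs, label=spec.class_name,
                       source_id=f"{spec.class_name}-seed{seed}")


@dataclass(frozen=True)
class ChannelProfile:
    """Piecewise magnitude-response description of an adapter channel.

    ``breakpoints`` are ``(freq_hz, gain_db)`` anchors; the gain between
    anchors is interpolated linearly on a log-frequency axis and held
    constant beyond the outermost anchors.
    """

    name: str
    breakpoints: tuple[tuple[float, float], ...]
    ir_length_samples: int = 1024
    phase: str = "minimum"

    def __post_init__(self) -> None:
        freqs = [f for f, _ in self.breakpoints]
        gains = [g for _, g in self.breakpoints]
        if len(freqs) < 1 or any(f <= 0 for f in freqs):
            raise ValueError("breakpoints need at least one positive frequency")
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ValueError("breakpoint frequencies must be strictly increasing")
        if not np.all(np.isfinite(gains)):
            raise ValueError("breakpoint gains must be finite")
        if self.ir_length_samples < 64:
            raise ValueError("ir_length_samples must be >= 64")
        if self.phase not in ("minimum", "linear"):
            raise ValueError(f"unknown phase type {self.phase!r}")

    def gain_db_at(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Designed gain (dB) at arbitrary frequencies (log-f interpolation)."""
        f = np.asarray(self.breakpoints, dtype=float)[:, 0]
        g = np.asarray(self.breakpoints, dtype=float)[:, 1]
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        safe = np.maximum(freqs_hz, 1e-6)
        return np.interp(np.log10(safe), np.log10(f), g)


def default_channel_profiles() -> dict[str, ChannelProfile]:
    """The four channels the study compares.

    - ``reference``: the bare reference microphone, flat 0 dB.
    - ``dual_channel``: near-flat with ~9.4 dB average attenuation.
    - ``luer_lock``: roll-off starting at 200 Hz, 10-20 dB below the tube
      in the 300 Hz - 1 kHz region.
    - ``tube``: roll-off starting at 300 Hz, reaching about -40 dB at 1 kHz.
    """
    return {
        "reference": ChannelProfile("reference", ((10.0, 0.0), (22_000.0, 0.0))),
        "dual_channel": ChannelProfile(
            "dual_channel", ((10.0, -9.4), (22_000.0, -9.4))),
        "luer_lock": ChannelProfile(
            "luer_lock",
            ((10.0, 0.0), (200.0, 0.0), (400.0, -18.0), (1000.0, -55.0),
             (7500.0, -60.0), (22_000.0, -60.0))),
        "tube": ChannelProfile(
            "tube",
            ((10.0, 0.0), (300.0, 0.0), (500.0, -15.0), (1000.0, -40.0),
             (7500.0, -50.0), (22_000.0, -50.0))),
    }


def _minimum_phase_fir(mag: np.ndarray, n_taps: int, n_fft: int) -> np.ndarray:
    """Minimum-phase FIR from a one-sided magnitude target (real cepstrum fold)."""
    log_mag = np.log(np.maximum(mag, 1e-12))
    cep = np.fft.irfft(log_mag, n_fft)
    # fold anti-causal quefrencies onto causal ones
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1:n_fft // 2] = 2 * cep[1:n_fft // 2]
    fold[n_fft // 2] = cep[n_fft // 2]
    h_min = np.fft.irfft(np.exp(np.fft.rfft(fold, n_fft)), n_fft)
    return h_min[:n_taps]


def synth_adapter_ir(profile: ChannelProfile, fs: int = DEFAULT_FS) -> ImpulseResponse:
    """Design an FIR impulse response realizing a channel profile.

    The breakpoint gains are interpolated on a log-frequency axis onto a
    dense FFT grid and converted to a causal FIR; minimum phase (the
    default) avoids pre-ringing, as a physical acoustic path would.
    """
    if fs < 16_000:
        raise ValueError("fs must be >= 16 kHz")
    if any(g > 0 for _, g in profile.breakpoints):
        raise ValueError("profile gains above 0 dB are not realizable here")
    n_taps = profile.ir_length_samples
    n_fft = max(8192, 4 * n_taps)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    mag = 10 ** (profile.gain_db_at(freqs) / 20)

    if profile.phase == "minimum":
        h = _minimum_phase_fir(mag, n_taps, n_fft)
    else:  # linear phase via windowed ifft, peak centered
        h_full = np.fft.irfft(mag, n_fft)
        h = np.roll(h_full, n_taps // 2)[:n_taps] * np.hanning(n_taps)

    ir = ImpulseResponse(samples=h, fs=fs, source="synthetic", label=profile.name,
                         meta={"breakpoints": [list(bp) for bp in profile.breakpoints],
                               "phase": profile.phase})
    _check_ir_against_profile(ir, profile, tol_db=2.0)
    return ir


def _check_ir_against_profile(ir: ImpulseResponse, profile: ChannelProfile,
                              tol_db: float) -> None:
    """Verify the realized magnitude matches every breakpoint within tol."""
    freqs = np.array([f for f, _ in profile.breakpoints if f < ir.fs / 2])
    gains = profile.gain_db_at(freqs)
    _, resp = sps.freqz(ir.samples, worN=freqs, fs=ir.fs)
    got = 20 * np.log10(np.maximum(np.abs(resp), 1e-12))
    err = np.max(np.abs(got - gains))
    if err > tol_db:
        raise ValueError(
            f"IR design for {profile.name!r} misses breakpoints by {err:.2f} dB")


def make_dataset(out_dir: str | Path, n_per_class: int, seed: int,
                 specs: dict[str, TissueSoundSpec] | None = None,
                 fs: int = DEFAULT_FS) -> pd.DataFrame:
    """Write a labeled WAV dataset plus a CSV manifest.

    Per-file seeds are derived deterministically from ``seed``; calling twice
    with the same arguments reproduces identical manifests and identical
    audio bytes.  Returns the manifest (columns: path, class, duration_s,
    seed) with paths relative to ``out_dir``.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    specs = specs if specs is not None else default_tissue_specs()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc

    rows = []
    for ci, (cls, spec) in enumerate(sorted(specs.items())):
        dur_rng = np.random.default_rng((seed * 1009 + ci) % 2**31)
        lo, hi = spec.duration_range_s
        durations = dur_rng.uniform(lo, hi, size=n_per_class)
        for i, dur in enumerate(durations):
            file_seed = (seed * 100_003 + ci * 1013 + i) % 2**31
            sig = synth_tissue_sound(spec, float(dur), file_seed, fs=fs)
            rel = f"{cls}_{i:03d}.wav"
            try:
                write_wav(out_dir / rel, sig)
            except OSError as exc:
                raise OSError(f"failed writing {out_dir / rel}: {exc}") from exc
            rows.append({"path": rel, "class": cls,
                         "duration_s": round(float(dur), 6), "seed": file_seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
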