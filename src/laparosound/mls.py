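"""Maximum-length-sequence (MLS) excitation and impulse-response estimation.

An MLS is a ±1 pseudo-random sequence of period ``2^order - 1`` generated by
a linear-feedback shift register with primitive feedback taps.  Its circular
autocorrelation is ``period`` at lag 0 and exactly -1 everywhere else, which
makes a channel's impulse response recoverable from a recording of the MLS
played through it: circular cross-correlation of excitation and recording,
normalized per frequency bin, inverts the excitation exactly.

The "measurement" here replaces a loudspeaker/microphone loop by applying a
known FIR channel to the repeated MLS stream, optionally with additive white
noise — the only measurement path at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, max_len_seq

from .audio import AudioSignal, ImpulseResponse

# Feedback tap positions of a primitive polynomial per register length
# (taps as used by scipy.signal.max_len_seq: x^order + sum x^tap + 1).
_PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (1,), 3: (2,), 4: (3,), 5: (3,), 6: (5,), 7: (6,),
    8: (7, 6, 1), 9: (5,), 10: (7,), 11: (9,), 12: (11, 10, 4),
    13: (12, 11, 8), 14: (13, 12, 2), 15: (14,), 16: (15, 13, 4),
    17: (14,), 18: (11,), 19: (18, 17, 14), 20: (17,),
}

DEFAULT_ORDER = 15  # period 32767: covers IRs up to 0.68 s at 48 kHz


@dataclass(frozen=True)
class MlsSequence:
    """One period of a maximum length sequence, ±1 valued."""

    order: int
    samples: np.ndarray  # shape (period,), values in {-1, +1}
    taps: tuple[int, ...]

    @property
    def period(self) -> int:
        return 2**self.order - 1

    def repeated(self, n_periods: int) -> np.ndarray:
        return np.tile(self.samples, n_periods)


def generate_mls(order: int, taps: tuple[int, ...] | None = None) -> MlsSequence:
    """Generate one MLS period; rejects tap sets that are not primitive.

    Non-primitive taps produce a shorter-period register cycle, detected via
    the flat-spectrum property (|FFT|^2 = period + 1 off DC) that only a
    true MLS satisfies.
    """
    if not (2 <= order <= 20):
        raise ValueError(f"order must be in [2, 20], got {order}")
    use_taps = tuple(taps) if taps is not None else _PRIMITIVE_TAPS[order]
    bits, _ = max_len_seq(order, taps=list(use_taps))
    seq = 2.0 * bits - 1.0
    period = 2**order - 1
    power = np.abs(np.fft.rfft(seq)) ** 2
    if not np.allclose(power[1:], period + 1, atol=1e-6 * period):
        raise ValueError(
            f"taps {use_taps} are not a primitive polynomial for order {order}: "
            "sequence period falls short of 2^order - 1")
    return MlsSequence(order=order, samples=seq, taps=use_taps)


def circular_autocorrelation(mls: MlsSequence) -> np.ndarray:
    """Circular autocorrelation over one period (period at lag 0, -1 off-lag)."""
    spec = np.fft.rfft(mls.samples)
    return np.round(np.fft.irfft(spec * np.conj(spec), mls.period)).astype(np.int64)


def excitation_stream(mls: MlsSequence, n_periods: int = 5,
                      fs: int = 48_000) -> AudioSignal:
    """The playable excitation: ``n_periods`` MLS repetitions."""
    return AudioSignal(samples=mls.repeated(n_periods), fs=fs,
                       source_id=f"mls-order{mls.order}")


def simulate_measurement(mls: MlsSequence, channel: ImpulseResponse,
                         n_periods: int = 5, noise_db: float | None = None,
                         seed: int = 0) -> AudioSignal:
    """Play the repeated MLS through a known FIR channel (linear convolution).

    ``noise_db`` adds white noise at the given level relative to the RMS of
    the convolved signal (e.g. -30 for a -30 dB noise floor).
    """
    stream = mls.repeated(n_periods)
    rec = fftconvolve(stream, channel.samples)[: stream.size]
    if noise_db is not None:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(rec.size)
        noise *= 10 ** (noise_db / 20) * np.sqrt(np.mean(rec**2))
        rec = rec + noise
    return AudioSignal(samples=rec, fs=channel.fs,
                       source_id=f"measurement-{channel.label}")


def estimate_ir(excitation: MlsSequence, recording: AudioSignal,
                discard_first_period: bool | None = None) -> ImpulseResponse:
    """Recover the channel impulse response from a recorded MLS response.

    The recording is cut into full MLS periods; when more than one period is
    available the first is discarded (channel settling) and the rest are
    averaged before deconvolution.  Deconvolution divides the recording's
    spectrum by the excitation's bin-by-bin, which for an MLS is numerically
    benign (flat magnitude off DC) and makes an identity channel return an
    exact unit impulse.
    """
    period = excitation.period
    rec = np.asarray(recording.samples, dtype=np.float64)
    if rec.ndim != 1:
        raise ValueError("recording must be single-channel")
    if rec.size < period:
        raise ValueError(
            f"recording ({rec.size} samples) shorter than one MLS period ({period})")

    n_full = rec.size // period
    if discard_first_period is None:
        discard_first_period = n_full >= 2
    frames = rec[: n_full * period].reshape(n_full, period)
    if discard_first_period and n_full >= 2:
        frames = frames[1:]
    avg = frames.mean(axis=0)

    if not np.any(avg):
        warnings.warn("recording is silent; returning an all-zero impulse response",
                      stacklevel=2)
        return ImpulseResponse(samples=np.zeros(period), fs=recording.fs,
                               source="measured", label=recording.source_id)

    x_spec = np.fft.rfft(excitation.samples)
    y_spec = np.fft.rfft(avg)
    h_spec = y_spec * np.conj(x_spec) / np.maximum(np.abs(x_spec) ** 2, 1e-30)
    h = np.fft.irfft(h_spec, period)
    return ImpulseResponse(samples=h, fs=recording.fs, source="measured",
                           label=recording.source_id,
                           meta={"order": excitation.order,
                                 "periods_averaged": int(frames.shape[0])})


def measure_ir(channel: ImpulseResponse, order: int = DEFAULT_ORDER,
               n_periods: int = 5, noise_db: float | None = None,
               seed: int = 0) -> ImpulseResponse:
    """End-to-end simulated measurement: MLS -> channel -> deconvolution."""
    mls = generate_mls(order)
    rec = simulate_measurement(mls, channel, n_periods=n_periods,
                               noise_db=noise_db, seed=seed)
    est = estimate_ir(mls, rec)
    est.label = channel.label
    return est
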