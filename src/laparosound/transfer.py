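"""Transfer functions, relative transfer functions, and fractional-octave smoothing.

The transfer function of an LTI channel is the Fourier transform of its
impulse response.  Adapters are compared to the bare reference microphone
through the relative transfer function

    dH(f) = 20 * log10( |H_adapter(f)| / |H_reference(f)| )   [dB],

optionally smoothed with a Savitzky-Golay filter of 1/6-octave relative
bandwidth (applied on a log-frequency axis, where "relative bandwidth" is
well defined) and summarized by band averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .audio import ImpulseResponse

#: Fraction of the reference peak magnitude below which bins are masked
#: (excluded, not fabricated) in the relative TF.
REFERENCE_FLOOR = 1e-8

#: Log-frequency resampling density for fractional-octave smoothing.
POINTS_PER_OCTAVE = 48

#: Default analysis band: high-pass corner of the classification front-end
#: up to the mel upper edge.
ANALYSIS_BAND_HZ = (100.0, 7500.0)


@dataclass
class TransferFunction:
    """One-sided complex spectrum of an impulse response (DC excluded)."""

    freqs_hz: np.ndarray
    values: np.ndarray
    fs: int
    n_fft: int
    _dc: complex = 0.0  # kept so the IR round-trips exactly

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.freqs_hz.shape != self.values.shape:
            raise ValueError("freqs and values must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    def magnitude_db(self) -> np.ndarray:
        return 20 * np.log10(np.maximum(np.abs(self.values), 1e-300))


@dataclass
class RelativeTF:
    """dB-valued relative transfer function on a frequency grid.

    Bins where the reference magnitude falls below the configured floor are
    NaN (masked) and are excluded from band averages.
    """

    freqs_hz: np.ndarray
    delta_db: np.ndarray
    smoothed: bool = False
    bandwidth_octaves: float = 0.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.delta_db = np.asarray(self.delta_db, dtype=np.float64)
        if self.freqs_hz.shape != self.delta_db.shape:
            raise ValueError("freqs and delta_db must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def tf_from_ir(ir: ImpulseResponse, n_fft: int | None = None) -> TransferFunction:
    """Fourier transform of a (zero-padded) impulse response.

    ``n_fft`` defaults to the next power of two >= twice the IR length; it
    must not truncate the IR.
    """
    n = len(ir)
    if n_fft is None:
        n_fft = 1 << int(np.ceil(np.log2(max(2 * n, 2))))
    if n_fft < n:
        raise ValueError(f"n_fft={n_fft} shorter than IR length {n}")
    spec = np.fft.rfft(ir.samples, n_fft)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / ir.fs)
    return TransferFunction(freqs_hz=freqs[1:], values=spec[1:], fs=ir.fs,
                            n_fft=n_fft, _dc=complex(spec[0]))


def ir_from_tf(tf: TransferFunction) -> np.ndarray:
    """Inverse transform back to the zero-padded impulse response."""
    full = np.concatenate(([tf._dc], tf.values))
    return np.fft.irfft(full, tf.n_fft)


def relative_tf(h_proto: TransferFunction, h_ref: TransferFunction,
                floor: float = REFERENCE_FLOOR) -> RelativeTF:
    """Relative transfer function of an adapter against the reference."""
    if h_proto.freqs_hz.shape != h_ref.freqs_hz.shape or \
            not np.allclose(h_proto.freqs_hz, h_ref.freqs_hz):
        raise ValueError("transfer functions are on different frequency grids")
    ref_mag = np.abs(h_ref.values)
    proto_mag = np.abs(h_proto.values)
    mask = ref_mag < floor * ref_mag.max()
    delta = np.full(ref_mag.shape, np.nan)
    ok = ~mask
    delta[ok] = 20 * np.log10(np.maximum(proto_mag[ok], 1e-300) / ref_mag[ok])
    return RelativeTF(freqs_hz=h_proto.freqs_hz.copy(), delta_db=delta)


def smooth_fractional_octave(rtf: RelativeTF, bandwidth_oct: float = 1 / 6,
                             polyorder: int = 2) -> RelativeTF:
    """Fractional-octave Savitzky-Golay smoothing of a dB curve.

    The curve is resampled onto a log-spaced grid (48 points/octave), the
    filter window is the odd point count spanning ``bandwidth_oct``, and the
    result is interpolated back onto the original grid.  Constants and
    log-frequency-linear ramps pass through unchanged.
    """
    if rtf.smoothed:
        raise ValueError("relative TF is already smoothed")
    if bandwidth_oct <= 0:
        raise ValueError("bandwidth_oct must be positive")

    finite = np.isfinite(rtf.delta_db)
    f = rtf.freqs_hz[finite]
    y = rtf.delta_db[finite]
    if f.size < 3:
        raise ValueError("too few unmasked points to smooth")
    log_f = np.log2(f)
    n_oct = log_f[-1] - log_f[0]
    n_pts = max(int(np.ceil(n_oct * POINTS_PER_OCTAVE)) + 1, 3)
    grid = np.linspace(log_f[0], log_f[-1], n_pts)
    y_log = np.interp(grid, log_f, y)

    window = int(round(bandwidth_oct * POINTS_PER_OCTAVE)) | 1  # force odd
    window = max(window, polyorder + 1 + ((polyorder + 1) % 2 == 0))
    if window % 2 == 0:
        window += 1
    if window > n_pts:
        raise ValueError(
            f"grid has {n_pts} points, fewer than the smoothing window {window}")
    y_smooth = savgol_filter(y_log, window_length=window, polyorder=polyorder,
                             mode="interp")
    out = np.full(rtf.delta_db.shape, np.nan)
    out[finite] = np.interp(log_f, grid, y_smooth)
    return RelativeTF(freqs_hz=rtf.freqs_hz.copy(), delta_db=out,
                      smoothed=True, bandwidth_octaves=bandwidth_oct)


def band_average(rtf: RelativeTF, f_lo: float, f_hi: float) -> float:
    """Arithmetic mean of the relative TF (dB) over ``[f_lo, f_hi]``."""
    if f_lo >= f_hi:
        raise ValueError("f_lo must be below f_hi")
    sel = (rtf.freqs_hz >= f_lo) & (rtf.freqs_hz <= f_hi) & np.isfinite(rtf.delta_db)
    if not np.any(sel):
        raise ValueError(f"no unmasked bins in [{f_lo}, {f_hi}] Hz")
    return float(np.mean(rtf.delta_db[sel]))


def export_csv(path, freqs_hz: np.ndarray, values: np.ndarray,
               value_name: str = "value") -> None:
    import pandas as pd

    pd.DataFrame({"freq_hz": freqs_hz, value_name: values}).to_csv(path, index=False)
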