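"""Respiratory-rate estimation by spectral peak recognition.

Respiration is the dominant oscillation in the vital signal (typically
0.25-0.5 Hz for resting adults), so the respiratory rate is read off the
largest peak of the signal's power spectrum.  The default search band,
0.1-0.7 Hz (6-42 breaths/min), encloses the physiologic range; the
periodogram is Hann-windowed and zero-padded to a <= 0.01 Hz grid, and
the located maximum is refined by parabolic interpolation so the estimate
is not quantized to the FFT grid.

The rate is reported once per recording (the measurement protocol is a
1-minute epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VitalSignal
from .exceptions import InsufficientDataError, InvalidArgumentError
from .spectral import hann_periodogram, parabolic_refine

DEFAULT_RESP_BAND_HZ = (0.1, 0.7)
DEFAULT_ZERO_PAD_FACTOR = 4


@dataclass
class RespirationResult:
    """Respiratory-rate estimate with the spectrum it came from."""

    rr_bpm: float
    peak_freq_hz: float
    freqs_hz: np.ndarray
    power: np.ndarray


def estimate_rr(
    signal: VitalSignal,
    band_hz: tuple[float, float] = DEFAULT_RESP_BAND_HZ,
    zero_pad_factor: int = DEFAULT_ZERO_PAD_FACTOR,
) -> RespirationResult:
    """Estimate breaths/min from the largest spectral peak inside ``band_hz``.

    Requires at least two cycles of the slowest admissible breath
    (``duration >= 2 / band_hz[0]``).
    """
    low, high = band_hz
    if not 0 < low < high:
        raise InvalidArgumentError(f"band must satisfy 0 < low < high, got ({low}, {high})")
    if high >= signal.frame_rate_hz / 2:
        raise InvalidArgumentError(
            f"band upper edge {high} Hz must be below Nyquist "
            f"({signal.frame_rate_hz / 2:.1f} Hz)"
        )
    min_duration = 2.0 / low
    if signal.duration_s < min_duration:
        raise InsufficientDataError(
            f"signal of {signal.duration_s:.1f} s is shorter than the "
            f"{min_duration:.1f} s (two slowest-breath cycles) needed for band ({low}, {high}) Hz"
        )
    freqs, power = hann_periodogram(
        signal.values, signal.frame_rate_hz, zero_pad_factor=zero_pad_factor
    )
    mask = (freqs >= low) & (freqs <= high)
    idx = np.flatnonzero(mask)
    i_peak = idx[np.argmax(power[idx])]
    delta = parabolic_refine(power, int(i_peak))
    df = freqs[1] - freqs[0]
    peak_freq = float(freqs[i_peak] + delta * df)
    peak_freq = float(np.clip(peak_freq, low, high))
    return RespirationResult(
        rr_bpm=60.0 * peak_freq, peak_freq_hz=peak_freq, freqs_hz=freqs, power=power
    )
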