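"""Shared spectral helpers: Hann periodogram, parabolic peak refinement,
and the respiratory-vs-pulse band power ratio used both to calibrate the
simulator and to characterise measured vital signals."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .exceptions import InvalidArgumentError

RESP_BAND_HZ = (0.1, 0.6)
PULSE_BAND_HZ = (0.7, 3.0)


def hann_periodogram(
    x: np.ndarray, fs: float, min_resolution_hz: float = 0.01, zero_pad_factor: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed periodogram of a mean-subtracted signal.

    The FFT length is zero-padded so the frequency grid spacing is at most
    ``min_resolution_hz`` (and at least ``zero_pad_factor`` times the signal
    length), which keeps peak frequencies from being quantized by a coarse
    grid on short records.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InvalidArgumentError("periodogram needs at least 2 samples")
    if zero_pad_factor < 1:
        raise InvalidArgumentError("zero_pad_factor must be >= 1")
    nfft = next_fast_len(
        max(x.size * int(zero_pad_factor), int(np.ceil(fs / min_resolution_hz)))
    )
    freqs, power = sps.periodogram(
        x - x.mean(), fs=fs, window="hann", nfft=nfft, detrend=False
    )
    return freqs, power


def parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample refinement of a local maximum at index ``i``.

    Fits a parabola through ``y[i-1], y[i], y[i+1]`` and returns the
    fractional offset of the vertex in [-0.5, 0.5]; 0 at the edges or for
    degenerate (flat) neighbourhoods.
    """
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return 0.0
    delta = 0.5 * (a - c) / denom
    return float(np.clip(delta, -0.5, 0.5))


def band_peak_power(freqs: np.ndarray, power: np.ndarray, band_hz: tuple[float, float]) -> float:
    """Maximum periodogram power inside a frequency band."""
    low, high = band_hz
    mask = (freqs >= low) & (freqs <= high)
    if not np.any(mask):
        raise InvalidArgumentError(f"band {band_hz} contains no frequency-grid points")
    return float(power[mask].max())


def band_power_ratio_db(
    x: np.ndarray,
    fs: float,
    resp_band_hz: tuple[float, float] = RESP_BAND_HZ,
    pulse_band_hz: tuple[float, float] = PULSE_BAND_HZ,
) -> float:
    """dB excess of the respiratory-band spectral peak over the pulse-band peak.

    This mirrors how the prominence of respiration over carotid pulsation
    is read off a power-density spectrum: the ratio of the tallest peak in
    the respiratory band (default 0.1-0.6 Hz) to the tallest peak in the
    pulse band (default 0.7-3.0 Hz).
    """
    freqs, power = hann_periodogram(x, fs)
    p_resp = band_peak_power(freqs, power, resp_band_hz)
    p_pulse = band_peak_power(freqs, power, pulse_band_hz)
    if p_pulse <= 0 or p_resp <= 0:
        raise InvalidArgumentError("band peak power is zero; ratio undefined")
    return 10.0 * float(np.log10(p_resp / p_pulse))
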