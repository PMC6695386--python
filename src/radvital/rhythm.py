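"""Rhythm classification via the peak-frequency track and MaxΔfrq.

In atrial fibrillation the interbeat interval varies randomly from beat
to beat, so the dominant frequency of the carotid-pulse waveform wanders
over time, while in normal sinus rhythm it stays put.  The detector
tracks the frequency of peak spectral intensity in short sliding windows
and summarizes its excursion over an analysis epoch:

    MaxΔfrq = max(track) - min(track)   within a 17-s epoch,

taking the maximum over sliding epochs on longer recordings.  A recording
is labelled PeAF when MaxΔfrq >= 0.57 Hz (the boundary goes to PeAF,
preserving sensitivity).

The track is built from 3-s analysis segments hopped at 1/20 s, so each
of the 20 estimates per second summarizes 3 s of signal; an alternative
"smoothed" mode computes near-instantaneous (1-s segment) estimates at
the same hop and applies a 3-s moving average to the frequency sequence.
Segment spectra are zero-padded to a <= 0.05 Hz grid so track steps, not
grid coarseness, dominate MaxΔfrq.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq

from .exceptions import InsufficientDataError, InvalidArgumentError

DEFAULT_THRESHOLD_HZ = 0.57


@dataclass
class SpectrogramConfig:
    """Peak-frequency-track parameters.

    ``estimate_rate_hz`` estimates per second (default 20), averaged over
    ``avg_window_s``-long segments (default 3 s), searched within
    ``analysis_band_hz`` (default 0.7-3.0 Hz, the pulse band), summarized
    over ``epoch_s``-long spans (default 17 s).
    """

    estimate_rate_hz: float = 20.0
    avg_window_s: float = 3.0
    epoch_s: float = 17.0
    analysis_band_hz: tuple[float, float] = (0.7, 3.0)
    freq_resolution_hz: float = 0.05
    epoch_hop_s: float = 1.0
    track_mode: Literal["segment", "smoothed"] = "segment"

    def validate(self, frame_rate_hz: float) -> None:
        if self.estimate_rate_hz <= 0 or self.estimate_rate_hz > frame_rate_hz:
            raise InvalidArgumentError(
                f"estimate_rate_hz must be in (0, frame_rate] = (0, {frame_rate_hz}]"
            )
        if not 0 < self.avg_window_s < self.epoch_s:
            raise InvalidArgumentError("must satisfy 0 < avg_window_s < epoch_s")
        low, high = self.analysis_band_hz
        if not 0 < low < high < frame_rate_hz / 2:
            raise InvalidArgumentError(
                f"analysis band ({low}, {high}) must lie in (0, Nyquist)"
            )


@dataclass
class PeakFrequencyTrack:
    """Timestamps and smoothed peak frequencies of the pulse spectrogram."""

    times_s: np.ndarray
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.times_s.size != self.freqs_hz.size:
            raise InvalidArgumentError("times_s and freqs_hz must have equal lengths")


@dataclass
class RhythmResult:
    """MaxΔfrq statistic and the NSR/PeAF decision it implies."""

    max_dfrq_hz: float
    label: Literal["NSR", "PeAF"]
    threshold_hz: float = DEFAULT_THRESHOLD_HZ


def _segment_peak_freqs(
    waveform: np.ndarray,
    frame_rate_hz: float,
    nperseg: int,
    hop: int,
    band: tuple[float, float],
    freq_resolution_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment argmax frequencies of Hann-windowed power spectra."""
    starts = np.arange(0, waveform.size - nperseg + 1, hop)
    window = np.hanning(nperseg)
    nfft = next_fast_len(max(nperseg, int(np.ceil(frame_rate_hz / freq_resolution_hz))))
    freqs = rfftfreq(nfft, d=1.0 / frame_rate_hz)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise InvalidArgumentError(f"analysis band {band} contains no frequency-grid points")
    band_freqs = freqs[mask]
    segments = np.lib.stride_tricks.sliding_window_view(waveform, nperseg)[starts]
    spectra = np.abs(rfft(segments * window, n=nfft, axis=1)) ** 2
    peak_freqs = band_freqs[np.argmax(spectra[:, mask], axis=1)]
    times = (starts + nperseg / 2.0) / frame_rate_hz
    return times, peak_freqs


def compute_peak_track(
    waveform: np.ndarray,
    frame_rate_hz: float,
    config: SpectrogramConfig | None = None,
) -> PeakFrequencyTrack:
    """Track the frequency of peak spectral intensity over the recording.

    Requires at least one full epoch of signal (``epoch_s`` seconds).
    """
    config = config if config is not None else SpectrogramConfig()
    config.validate(frame_rate_hz)
    waveform = np.asarray(waveform, dtype=float).ravel()
    n_epoch = int(round(config.epoch_s * frame_rate_hz))
    if waveform.size < n_epoch:
        raise InsufficientDataError(
            f"waveform of {waveform.size / frame_rate_hz:.1f} s is shorter than "
            f"the {config.epoch_s:.1f} s analysis epoch"
        )
    hop = max(int(round(frame_rate_hz / config.estimate_rate_hz)), 1)
    if config.track_mode == "segment":
        nperseg = int(round(config.avg_window_s * frame_rate_hz))
        times, freqs = _segment_peak_freqs(
            waveform, frame_rate_hz, nperseg, hop,
            config.analysis_band_hz, config.freq_resolution_hz,
        )
    else:
        # near-instantaneous 1-s estimates, then a 3-s moving average of
        # the frequency sequence
        nperseg = int(round(1.0 * frame_rate_hz))
        times, freqs = _segment_peak_freqs(
            waveform, frame_rate_hz, nperseg, hop,
            config.analysis_band_hz, config.freq_resolution_hz,
        )
        n_avg = max(int(round(config.avg_window_s * config.estimate_rate_hz)), 1)
        kernel = np.ones(n_avg) / n_avg
        freqs = np.convolve(freqs, kernel, mode="same")
    return PeakFrequencyTrack(times_s=times, freqs_hz=freqs)


def max_frequency_variation(
    track: PeakFrequencyTrack,
    epoch_s: float = 17.0,
    epoch_hop_s: float = 1.0,
) -> float:
    """MaxΔfrq: peak-to-peak excursion of the track within one epoch.

    For tracks spanning more than one epoch, 17-s epochs slide at
    ``epoch_hop_s`` and the maximum excursion over epochs is returned.
    """
    if track.freqs_hz.size == 0:
        raise InvalidArgumentError("peak-frequency track is empty")
    t = track.times_s
    f = track.freqs_hz
    span = t[-1] - t[0]
    if span <= epoch_s:
        return float(f.max() - f.min())
    best = 0.0
    start = t[0]
    while start <= t[-1] - epoch_s:
        mask = (t >= start) & (t <= start + epoch_s)
        if np.any(mask):
            best = max(best, float(f[mask].max() - f[mask].min()))
        start += epoch_hop_s
    return best


def classify_rhythm(
    max_dfrq_hz: float, threshold_hz: float = DEFAULT_THRESHOLD_HZ
) -> RhythmResult:
    """Label PeAF iff MaxΔfrq >= threshold (boundary assigned to PeAF)."""
    if max_dfrq_hz < 0:
        raise InvalidArgumentError(f"max_dfrq_hz must be >= 0, got {max_dfrq_hz}")
    label = "PeAF" if max_dfrq_hz >= threshold_hz else "NSR"
    return RhythmResult(max_dfrq_hz=float(max_dfrq_hz), label=label, threshold_hz=threshold_hz)
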