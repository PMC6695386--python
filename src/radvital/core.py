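"""Core in-memory containers shared across the pipeline.

An IR-UWB radar recording is a 2-D *frame matrix*: slow time (successive
transmitted frames, sampling motion over seconds) along axis 0 and fast
time (range bins, sampling distance) along axis 1.  The device modelled
here quantizes 1 m of range into 156 bins (~6.4 mm pitch).  After clutter
removal and target localization the pipeline works on the *vital signal*:
the slow-time series at the target range bin, which carries respiratory
and carotid-pulse displacement components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

DEFAULT_BIN_PITCH_M = 1.0 / 156.0


@dataclass
class RadarFrameMatrix:
    """Slow-time x range-bin sample grid with acquisition metadata.

    Parameters
    ----------
    samples
        2-D array, shape ``(n_frames, n_bins)``, in raw signal units.
    frame_rate_hz
        Slow-time frame rate (frames per second).
    bin_pitch_m
        Fast-time bin spacing in meters (default 1/156).
    """

    samples: np.ndarray
    frame_rate_hz: float
    bin_pitch_m: float = DEFAULT_BIN_PITCH_M

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidArgumentError(
                f"frame matrix must be 2-D (frames x bins), got ndim={self.samples.ndim}"
            )
        if not self.frame_rate_hz > 0:
            raise InvalidArgumentError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if not self.bin_pitch_m > 0:
            raise InvalidArgumentError(f"bin_pitch_m must be > 0, got {self.bin_pitch_m}")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_bins(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        """Slow-time stamps of each frame, starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def bin_distances(self) -> np.ndarray:
        """Range of each bin center in meters (0-based bins at ``b * bin_pitch_m``)."""
        return np.arange(self.n_bins) * self.bin_pitch_m


@dataclass
class VitalSignal:
    """Slow-time series at the target range bin (respiration + pulse + noise)."""

    values: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.frame_rate_hz > 0:
            raise InvalidArgumentError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.frame_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate_hz


@dataclass
class TargetLocation:
    """Range bin selected by maximal slow-time variability."""

    bin_index: int
    distance_m: float
    sd_profile: np.ndarray = field(repr=False)


@dataclass
class BeatSeries:
    """Detected carotid-pulse peak times and the interbeat intervals between them.

    The interbeat interval (IBI) is the radar surrogate for the ECG R-R
    interval: ``ibis_s[i] = peak_times_s[i + 1] - peak_times_s[i]``.
    """

    peak_times_s: np.ndarray
    ibis_s: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float).ravel()
        self.ibis_s = np.asarray(self.ibis_s, dtype=float).ravel()
        if self.peak_times_s.size and np.any(np.diff(self.peak_times_s) <= 0):
            raise InvalidArgumentError("peak times must be strictly increasing")
        if self.ibis_s.size != max(self.peak_times_s.size - 1, 0):
            raise InvalidArgumentError("len(ibis_s) must equal len(peak_times_s) - 1")

    @classmethod
    def from_peak_times(cls, peak_times_s: np.ndarray) -> "BeatSeries":
        peak_times_s = np.asarray(peak_times_s, dtype=float).ravel()
        return cls(peak_times_s=peak_times_s, ibis_s=np.diff(peak_times_s))

    @property
    def n_beats(self) -> int:
        return self.peak_times_s.size
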