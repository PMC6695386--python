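"""Carotid-pulse isolation, beat detection, and pulse-rate / IBI measurement.

The vital signal is band-pass filtered to strip the (much stronger)
respiratory component below and thermal noise above the pulse band, then
lightly smoothed; local maxima of the resulting carotid waveform mark the
systolic phases, and interbeat intervals (IBIs, the R-R surrogate) are
the differences between successive peak times.

Filtering is zero-phase (forward-backward Butterworth) so peak times are
not biased by group delay — essential because IBIs are compared against
reference beat times.  Defaults: pass band 0.7-3.0 Hz (above the
respiratory band, admitting 42-180 bpm fundamentals), order 4, 3-point
moving-average smoothing, 0.3 s refractory period (200 bpm ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BeatSeries, VitalSignal
from .exceptions import InsufficientBeatsError, InvalidArgumentError
from .spectral import parabolic_refine

DEFAULT_REFRACTORY_S = 0.3
DEFAULT_PROMINENCE_FACTOR = 1.0
DEFAULT_MATCH_TOL_S = 0.3


@dataclass
class FilterSpec:
    """Band-pass + smoothing parameters for pulse isolation."""

    hp_cutoff_hz: float = 0.7
    lp_cutoff_hz: float = 3.0
    order: int = 4
    smoothing_points: int = 3

    def validate(self, frame_rate_hz: float) -> None:
        nyq = frame_rate_hz / 2.0
        if not 0 < self.hp_cutoff_hz < self.lp_cutoff_hz:
            raise InvalidArgumentError(
                f"cutoffs must satisfy 0 < hp < lp, got ({self.hp_cutoff_hz}, {self.lp_cutoff_hz})"
            )
        if self.lp_cutoff_hz >= nyq:
            raise InvalidArgumentError(
                f"lp_cutoff_hz {self.lp_cutoff_hz} must be below Nyquist ({nyq:.1f} Hz)"
            )
        if self.order < 1:
            raise InvalidArgumentError("filter order must be >= 1")
        if self.smoothing_points < 1 or self.smoothing_points % 2 == 0:
            raise InvalidArgumentError("smoothing_points must be odd and >= 1")


@dataclass
class PulseResult:
    """Pulse rate and mean interbeat interval, with the beat series."""

    pr_bpm: float
    mean_ibi_s: float
    beats: BeatSeries


def isolate_pulse(signal: VitalSignal, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase band-pass + centered moving average; length-preserving."""
    spec = spec if spec is not None else FilterSpec()
    spec.validate(signal.frame_rate_hz)
    sos = sps.butter(
        spec.order,
        [spec.hp_cutoff_hz, spec.lp_cutoff_hz],
        btype="bandpass",
        fs=signal.frame_rate_hz,
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, signal.values)
    if spec.smoothing_points > 1:
        kernel = np.ones(spec.smoothing_points) / spec.smoothing_points
        filtered = np.convolve(filtered, kernel, mode="same")
    return filtered


def detect_beats(
    waveform: np.ndarray,
    frame_rate_hz: float,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
) -> BeatSeries:
    """Locate carotid-pulse peaks in a band-passed waveform.

    Peaks must have prominence >= ``prominence_factor`` times the median
    absolute amplitude and be at least ``refractory_s`` apart (the larger
    peak wins a conflict).  Peak times are refined to sub-sample
    resolution by parabolic interpolation.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if not refractory_s > 0:
        raise InvalidArgumentError("refractory_s must be > 0")
    if not frame_rate_hz > 0:
        raise InvalidArgumentError("frame_rate_hz must be > 0")
    if waveform.size == 0 or not np.any(waveform):
        raise InsufficientBeatsError("waveform has no amplitude; no beats detectable")
    scale = float(np.median(np.abs(waveform)))
    threshold = prominence_factor * scale
    distance = max(int(round(refractory_s * frame_rate_hz)), 1)
    peaks, _ = sps.find_peaks(
        waveform, distance=distance, prominence=threshold if threshold > 0 else None
    )
    if peaks.size < 2:
        raise InsufficientBeatsError(
            f"only {peaks.size} pulse peak(s) found; need at least 2 for an interval"
        )
    times = np.array(
        [(p + parabolic_refine(waveform, int(p))) / frame_rate_hz for p in peaks]
    )
    return BeatSeries.from_peak_times(times)


def compute_pr(beats: BeatSeries) -> PulseResult:
    """Pulse rate = 60 / mean interbeat interval."""
    if beats.ibis_s.size < 1:
        raise InsufficientBeatsError("need at least 2 peaks (1 interval) to compute a pulse rate")
    mean_ibi = float(np.mean(beats.ibis_s))
    return PulseResult(pr_bpm=60.0 / mean_ibi, mean_ibi_s=mean_ibi, beats=beats)


def match_beat_times(
    detected_s: np.ndarray, reference_s: np.ndarray, tol_s: float = DEFAULT_MATCH_TOL_S
) -> list[tuple[int, int]]:
    """Pair detected peaks with reference beats by nearest time within ``tol_s``.

    Greedy one-to-one matching in order of increasing time difference;
    unmatched detections count as false detections in validation.
    Returns (detected_index, reference_index) pairs sorted by detection.
    """
    detected_s = np.asarray(detected_s, dtype=float)
    reference_s = np.asarray(reference_s, dtype=float)
    if detected_s.size == 0 or reference_s.size == 0:
        return []
    diffs = np.abs(detected_s[:, None] - reference_s[None, :])
    order = np.argsort(diffs, axis=None)
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), reference_s.size)
        if diffs[i, j] > tol_s:
            break
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return sorted(pairs)


def matched_ibi_errors(
    detected: BeatSeries, reference_times_s: np.ndarray, tol_s: float = DEFAULT_MATCH_TOL_S
) -> np.ndarray:
    """Absolute IBI errors over consecutively matched beat pairs.

    Only intervals whose two endpoints match two *consecutive* reference
    beats contribute, so missed or spurious detections do not pollute the
    interval comparison.
    """
    pairs = dict(match_beat_times(detected.peak_times_s, reference_times_s, tol_s))
    ref = np.asarray(reference_times_s, dtype=float)
    errors = []
    for k in range(detected.n_beats - 1):
        j0, j1 = pairs.get(k), pairs.get(k + 1)
        if j0 is None or j1 is None or j1 != j0 + 1:
            continue
        errors.append(abs(detected.ibis_s[k] - (ref[j1] - ref[j0])))
    return np.asarray(errors)
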