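"""Statsmodels-style facade: a model built from a frame matrix whose
``fit()`` runs the full processing chain and returns a results object.

The chain is: clutter removal -> SD-based target localization -> vital
signal extraction -> respiratory-rate FFT estimation -> carotid pulse
band-pass + beat detection -> peak-frequency track and MaxΔfrq rhythm
classification.  The results object carries all estimates, the resolved
configuration that produced them, and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import __version__ as _version
from .core import BeatSeries, RadarFrameMatrix, TargetLocation, VitalSignal
from .exceptions import InsufficientDataError, RadVitalError
from .preprocess import (
    DEFAULT_CLUTTER_ALPHA,
    DEFAULT_SEARCH_WINDOW_M,
    extract_vital_signal,
    locate_target,
    remove_clutter,
)
from .pulse import (
    DEFAULT_PROMINENCE_FACTOR,
    DEFAULT_REFRACTORY_S,
    FilterSpec,
    compute_pr,
    detect_beats,
    isolate_pulse,
)
from .respiration import DEFAULT_RESP_BAND_HZ, DEFAULT_ZERO_PAD_FACTOR, estimate_rr
from .rhythm import (
    DEFAULT_THRESHOLD_HZ,
    SpectrogramConfig,
    classify_rhythm,
    compute_peak_track,
    max_frequency_variation,
)

#: flat configuration namespace with the package defaults; keys mirror the
#: per-stage parameter names
DEFAULT_CONFIG: dict[str, Any] = {
    "clutter.alpha": DEFAULT_CLUTTER_ALPHA,
    "target.window_m": list(DEFAULT_SEARCH_WINDOW_M),
    "respiration.band_hz": list(DEFAULT_RESP_BAND_HZ),
    "respiration.zero_pad_factor": DEFAULT_ZERO_PAD_FACTOR,
    "pulse.hp_cutoff_hz": 0.7,
    "pulse.lp_cutoff_hz": 3.0,
    "pulse.order": 4,
    "pulse.smoothing_points": 3,
    "pulse.refractory_s": DEFAULT_REFRACTORY_S,
    "pulse.prominence_factor": DEFAULT_PROMINENCE_FACTOR,
    "rhythm.estimate_rate_hz": 20.0,
    "rhythm.avg_window_s": 3.0,
    "rhythm.epoch_s": 17.0,
    "rhythm.band_hz": [0.7, 3.0],
    "rhythm.threshold_hz": DEFAULT_THRESHOLD_HZ,
    "rhythm.track_mode": "segment",
}


def resolve_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Defaults overlaid with user overrides; unknown keys rejected."""
    config = dict(DEFAULT_CONFIG)
    if overrides:
        unknown = set(overrides) - set(config)
        if unknown:
            raise RadVitalError(f"unknown config keys: {sorted(unknown)}")
        config.update(overrides)
    return config


class _StageError(RadVitalError):
    """Wraps a stage failure with the stage name for diagnostics."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.error = error
        super().__init__(f"stage '{stage}': {error}")


@dataclass
class CarotidVitalResults:
    """Estimates produced by :meth:`CarotidVitalModel.fit`."""

    rr_bpm: float
    pr_bpm: float
    mean_ibi_s: float
    ibis_s: np.ndarray
    max_dfrq_hz: float
    rhythm_label: str
    target: TargetLocation
    beats: BeatSeries
    vital_signal: VitalSignal = field(repr=False)
    pulse_waveform: np.ndarray = field(repr=False)
    config: dict[str, Any] = field(repr=False, default_factory=dict)
    version: str = _version

    def summary(self) -> str:
        lines = [
            "Carotid radar vital-sign analysis",
            "=" * 46,
            f"{'Target range bin':<30}{self.target.bin_index:>10d}",
            f"{'Target distance (m)':<30}{self.target.distance_m:>10.3f}",
            f"{'Respiratory rate (breaths/min)':<30}{self.rr_bpm:>10.1f}",
            f"{'Pulse rate (beats/min)':<30}{self.pr_bpm:>10.1f}",
            f"{'Mean interbeat interval (s)':<30}{self.mean_ibi_s:>10.3f}",
            f"{'Detected beats':<30}{self.beats.n_beats:>10d}",
            f"{'MaxΔfrq (Hz)':<30}{self.max_dfrq_hz:>10.2f}",
            f"{'Rhythm':<30}{self.rhythm_label:>10}",
            "=" * 46,
            f"threshold {self.config.get('rhythm.threshold_hz', DEFAULT_THRESHOLD_HZ)} Hz; "
            f"PeAF iff MaxΔfrq >= threshold",
        ]
        return "\n".join(lines)


class CarotidVitalModel:
    """Vital-sign estimation model over an IR-UWB radar frame matrix.

    Parameters
    ----------
    frames
        Raw (clutter-containing) slow-time x range-bin recording.
    config
        Flat overrides of :data:`DEFAULT_CONFIG` keys
        (e.g. ``{"clutter.alpha": 0.995}``).
    """

    def __init__(self, frames: RadarFrameMatrix, config: dict[str, Any] | None = None):
        self.frames = frames
        self.config = resolve_config(config)

    @classmethod
    def from_recording(cls, path, config: dict[str, Any] | None = None) -> "CarotidVitalModel":
        """Build the model from a CSV + JSON sidecar recording on disk."""
        from .io import read_recording

        return cls(read_recording(path), config=config)

    def fit(self) -> CarotidVitalResults:
        """Run the full chain and return the results object.

        Raises :class:`radvital.exceptions.InsufficientDataError` (with
        the failing stage named) when the recording is shorter than the
        rhythm analysis epoch.
        """
        cfg = self.config
        epoch_s = float(cfg["rhythm.epoch_s"])
        if self.frames.duration_s < epoch_s:
            raise InsufficientDataError(
                f"stage 'rhythm': recording of {self.frames.duration_s:.1f} s is "
                f"shorter than the {epoch_s:.1f} s analysis epoch"
            )

        def run(stage, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except RadVitalError as exc:
                raise type(exc)(f"stage '{stage}': {exc}") from exc

        clean = run("clutter", remove_clutter, self.frames, alpha=float(cfg["clutter.alpha"]))
        target = run("target", locate_target, clean, tuple(cfg["target.window_m"]))
        vital = run("vital", extract_vital_signal, clean, target)
        resp = run(
            "respiration",
            estimate_rr,
            vital,
            band_hz=tuple(cfg["respiration.band_hz"]),
            zero_pad_factor=int(cfg["respiration.zero_pad_factor"]),
        )
        spec = FilterSpec(
            hp_cutoff_hz=float(cfg["pulse.hp_cutoff_hz"]),
            lp_cutoff_hz=float(cfg["pulse.lp_cutoff_hz"]),
            order=int(cfg["pulse.order"]),
            smoothing_points=int(cfg["pulse.smoothing_points"]),
        )
        waveform = run("pulse", isolate_pulse, vital, spec)
        beats = run(
            "beats",
            detect_beats,
            waveform,
            vital.frame_rate_hz,
            refractory_s=float(cfg["pulse.refractory_s"]),
            prominence_factor=float(cfg["pulse.prominence_factor"]),
        )
        pr = compute_pr(beats)
        sg_config = SpectrogramConfig(
            estimate_rate_hz=float(cfg["rhythm.estimate_rate_hz"]),
            avg_window_s=float(cfg["rhythm.avg_window_s"]),
            epoch_s=epoch_s,
            analysis_band_hz=tuple(cfg["rhythm.band_hz"]),
            track_mode=cfg["rhythm.track_mode"],
        )
        track = run("rhythm", compute_peak_track, waveform, vital.frame_rate_hz, sg_config)
        max_dfrq = max_frequency_variation(track, epoch_s=epoch_s)
        rhythm = classify_rhythm(max_dfrq, threshold_hz=float(cfg["rhythm.threshold_hz"]))

        return CarotidVitalResults(
            rr_bpm=resp.rr_bpm,
            pr_bpm=pr.pr_bpm,
            mean_ibi_s=pr.mean_ibi_s,
            ibis_s=beats.ibis_s,
            max_dfrq_hz=rhythm.max_dfrq_hz,
            rhythm_label=rhythm.label,
            target=target,
            beats=beats,
            vital_signal=vital,
            pulse_waveform=waveform,
            config=dict(cfg),
        )
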