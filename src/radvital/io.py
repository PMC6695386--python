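"""On-disk formats, configuration files, and the end-to-end pipeline report.

A recording is a CSV matrix (rows = slow-time frames, columns = range
bins, no header) plus a JSON sidecar of the same stem holding the
acquisition metadata (``frame_rate_hz``, ``bin_pitch_m``, ``n_bins`` and,
for simulated recordings, the seed and physiologic profile).  Ground
truth is a one-column beat-time CSV plus a JSON summary.  The analysis
report is JSON with a stable key order and the fully resolved
configuration echoed for auditability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .core import RadarFrameMatrix
from .exceptions import FormatError, InvalidArgumentError
from .model import CarotidVitalModel, CarotidVitalResults, resolve_config
from .simulate import GroundTruth

REQUIRED_SIDECAR_KEYS = ("frame_rate_hz", "bin_pitch_m", "n_bins")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(
    frames: RadarFrameMatrix, path: str | Path, metadata: dict[str, Any] | None = None
) -> Path:
    """Write the frame matrix as CSV + JSON sidecar; returns the CSV path.

    Floats are serialized with 17 significant digits so a read-back
    reproduces the matrix bit for bit.
    """
    csv_path = Path(path).with_suffix(".csv")
    np.savetxt(csv_path, frames.samples, delimiter=",", fmt="%.17g")
    sidecar = {
        "frame_rate_hz": frames.frame_rate_hz,
        "bin_pitch_m": frames.bin_pitch_m,
        "n_bins": frames.n_bins,
    }
    if metadata:
        sidecar.update(metadata)
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return csv_path


def read_recording(path: str | Path) -> RadarFrameMatrix:
    """Read a CSV + JSON sidecar recording, validating shape and schema."""
    csv_path = Path(path)
    if csv_path.suffix != ".csv":
        csv_path = csv_path.with_suffix(".csv")
    sidecar_path = _sidecar_path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"recording CSV not found: {csv_path}")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    for key in REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise FormatError(f"sidecar {sidecar_path} is missing required key '{key}'")

    n_bins = int(sidecar["n_bins"])
    rows: list[np.ndarray] = []
    with open(csv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != n_bins:
                raise FormatError(
                    f"{csv_path}: row {lineno} has {len(fields)} columns, expected {n_bins}"
                )
            try:
                rows.append(np.array(fields, dtype=float))
            except ValueError as exc:
                raise FormatError(f"{csv_path}: row {lineno}: {exc}") from exc
    if not rows:
        raise FormatError(f"{csv_path}: no data rows")
    return RadarFrameMatrix(
        samples=np.vstack(rows),
        frame_rate_hz=float(sidecar["frame_rate_hz"]),
        bin_pitch_m=float(sidecar["bin_pitch_m"]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Beat-time CSV (one time per row) + JSON summary; returns the CSV path."""
    csv_path = Path(path).with_suffix(".csv")
    np.savetxt(csv_path, truth.beat_times_s, delimiter=",", fmt="%.17g",
               header="beat_time_s", comments="")
    summary = {
        "rhythm": truth.rhythm,
        "true_rr_bpm": truth.true_rr_bpm,
        "n_beats": int(truth.beat_times_s.size),
        "mean_ibi_s": float(np.mean(truth.ibis_s)) if truth.beat_times_s.size > 1 else None,
    }
    _sidecar_path(csv_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
    return csv_path


def read_beat_times(path: str | Path) -> np.ndarray:
    """Read a one-column beat-time CSV (optional header)."""
    times = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                times.append(float(line.split(",")[0]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(f"{path}: row {lineno} is not a number") from None
    return np.asarray(times)


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a flat ``key = value`` config file (one namespace, # comments).

    Values are parsed as JSON where possible (numbers, lists, strings);
    bare words fall back to strings.
    """
    config: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: line {lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        try:
            config[key] = json.loads(raw)
        except json.JSONDecodeError:
            config[key] = raw
    return config


@dataclass
class AnalysisReport:
    """Serializable end-to-end pipeline output."""

    rr_bpm: float
    pr_bpm: float
    mean_ibi_s: float
    ibis_s: list[float]
    max_dfrq_hz: float
    rhythm_label: str
    target_bin: int
    target_distance_m: float
    config_echo: dict[str, Any] = field(default_factory=dict)
    version: str = ""

    @classmethod
    def from_results(cls, results: CarotidVitalResults) -> "AnalysisReport":
        return cls(
            rr_bpm=float(results.rr_bpm),
            pr_bpm=float(results.pr_bpm),
            mean_ibi_s=float(results.mean_ibi_s),
            ibis_s=[float(x) for x in results.ibis_s],
            max_dfrq_hz=float(results.max_dfrq_hz),
            rhythm_label=results.rhythm_label,
            target_bin=int(results.target.bin_index),
            target_distance_m=float(results.target.distance_m),
            config_echo=dict(results.config),
            version=results.version,
        )

    def to_json(self) -> str:
        """Stable-key-order JSON (byte-identical for identical analyses)."""
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_pipeline(frames: RadarFrameMatrix, config: dict[str, Any] | None = None) -> AnalysisReport:
    """Chain preprocess -> respiration -> carotid pulse -> rhythm into a report.

    Thin wrapper over :class:`radvital.model.CarotidVitalModel`; the
    report embeds the fully resolved configuration.
    """
    results = CarotidVitalModel(frames, config=config).fit()
    return AnalysisReport.from_results(results)
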