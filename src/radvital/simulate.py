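"""Synthetic IR-UWB radar recordings with exported ground truth.

The simulator emulates a 60-s recording of a stationary subject whose neck
is ~0.5 m from the radar.  The neck surface displacement is the sum of a
respiratory oscillation (a sinusoid at the breathing frequency, the
dominant component) and a per-beat carotid pulsation (a raised-cosine
upstroke followed by an exponential relaxation, ~6.3 dB weaker in spectral
peak power).  The displacement modulates the fast-time position of a
Gaussian-derivative echo template inside a static clutter background with
additive thermal noise.  Optional motion events inject large broadband
transients, reproducing the wild fluctuations a moving subject causes.

Beat timing follows the rhythm model:

* NSR (normal sinus rhythm): interbeat intervals i.i.d. Normal with mean
  ``60 / hr_bpm`` and a small jitter SD, truncated to > 0.25 s.
* PeAF (persistent atrial fibrillation): intervals i.i.d. lognormal with
  the same mean and a large coefficient of variation — the
  "irregularly irregular" rhythm that drives the MaxΔfrq statistic.

Everything is driven by one seeded generator: a fixed seed reproduces the
recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .core import DEFAULT_BIN_PITCH_M, RadarFrameMatrix
from .exceptions import InvalidArgumentError
from .spectral import PULSE_BAND_HZ, RESP_BAND_HZ, band_peak_power, hann_periodogram

Rhythm = Literal["NSR", "PeAF"]

#: minimum physiologic interbeat interval (240 bpm ceiling) used to
#: truncate the NSR interval distribution
MIN_IBI_S = 0.25

#: carotid per-beat template shape: raised-cosine upstroke then exponential decay
UPSTROKE_S = 0.12
DECAY_TAU_S = 0.25


@dataclass
class SimConfig:
    """Acquisition geometry and noise of the simulated radar.

    Defaults model the experimental setup: 156 range bins per meter, the
    subject's neck at 0.50 m, 60-s recordings.  The 200 Hz frame rate
    resolves interbeat intervals to 5 ms.  ``echo_amplitude`` sets the
    target echo scale; ``noise_sd`` the per-sample thermal noise
    (default 5e-4, ~34 dB below the respiratory echo excursion).
    """

    frame_rate_hz: float = 200.0
    bin_pitch_m: float = DEFAULT_BIN_PITCH_M
    n_bins: int = 156
    duration_s: float = 60.0
    subject_distance_m: float = 0.50
    noise_sd: float = 5e-4
    clutter_profile: np.ndarray | None = None
    pulse_width_m: float = 0.04
    echo_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise InvalidArgumentError("frame_rate_hz must be > 0")
        if self.n_bins < 2:
            raise InvalidArgumentError("n_bins must be >= 2")
        if not 0 < self.subject_distance_m < self.n_bins * self.bin_pitch_m:
            raise InvalidArgumentError(
                "subject_distance_m must lie inside the unambiguous range "
                f"(0, {self.n_bins * self.bin_pitch_m:.3f}) m"
            )
        if not self.duration_s > 0:
            raise InvalidArgumentError("duration_s must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not self.pulse_width_m > 0:
            raise InvalidArgumentError("pulse_width_m must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class PhysioProfile:
    """Physiology of the simulated subject.

    ``hr_bpm`` defaults per rhythm (NSR 69, PeAF 80 — the group means of
    the population being emulated); ``power_ratio_db`` is the target
    respiratory-to-pulse spectral peak-power ratio the displacement trace
    is calibrated to (6.3 dB).
    """

    rhythm: Rhythm = "NSR"
    hr_bpm: float | None = None
    rr_bpm: float = 18.0
    nsr_jitter_sd_s: float = 0.03
    peaf_rr_cv: float = 0.24
    resp_amp_mm: float = 1.0
    pulse_amp_mm: float = 0.15
    power_ratio_db: float | None = 6.3
    motion_events: Sequence[tuple[float, float, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rhythm not in ("NSR", "PeAF"):
            raise InvalidArgumentError(f"rhythm must be 'NSR' or 'PeAF', got {self.rhythm!r}")
        if self.hr_bpm is None:
            self.hr_bpm = 69.0 if self.rhythm == "NSR" else 80.0
        if not 30 <= self.hr_bpm <= 220:
            raise InvalidArgumentError(f"hr_bpm must be in [30, 220], got {self.hr_bpm}")
        if not 6 <= self.rr_bpm <= 42:
            raise InvalidArgumentError(f"rr_bpm must be in [6, 42], got {self.rr_bpm}")
        if self.resp_amp_mm < 0 or self.pulse_amp_mm < 0:
            raise InvalidArgumentError("displacement amplitudes must be >= 0")
        if self.nsr_jitter_sd_s < 0:
            raise InvalidArgumentError("nsr_jitter_sd_s must be >= 0")
        mean_ibi = 60.0 / self.hr_bpm
        if self.rhythm == "PeAF" and self.peaf_rr_cv <= self.nsr_jitter_sd_s / mean_ibi:
            raise InvalidArgumentError(
                "peaf_rr_cv must exceed the NSR-level jitter CV "
                f"({self.nsr_jitter_sd_s / mean_ibi:.3f})"
            )


@dataclass
class GroundTruth:
    """Simulator-emitted truth for parameter-recovery tests."""

    beat_times_s: np.ndarray
    true_rr_bpm: float
    displacement_trace_mm: np.ndarray
    rhythm: Rhythm

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise InvalidArgumentError("ground-truth beat times must be strictly increasing")

    @property
    def ibis_s(self) -> np.ndarray:
        return np.diff(self.beat_times_s)


def generate_beat_times(
    profile: PhysioProfile, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw beat onset times on [0, duration_s) under the profile's rhythm model.

    The first beat is at t = 0; intervals are drawn i.i.d. from the
    rhythm's interval law and accumulated until the recording ends.
    """
    if not duration_s > 0:
        raise InvalidArgumentError("duration_s must be > 0")
    mean_ibi = 60.0 / profile.hr_bpm
    times = [0.0]
    while times[-1] < duration_s:
        if profile.rhythm == "NSR":
            ibi = rng.normal(mean_ibi, profile.nsr_jitter_sd_s)
            while ibi <= MIN_IBI_S:  # truncated normal via rejection
                ibi = rng.normal(mean_ibi, profile.nsr_jitter_sd_s)
        else:
            cv = profile.peaf_rr_cv
            sigma2 = np.log1p(cv * cv)
            mu = np.log(mean_ibi) - sigma2 / 2.0
            ibi = float(rng.lognormal(mu, np.sqrt(sigma2)))
        times.append(times[-1] + ibi)
    return np.asarray(times[:-1] if times[-1] >= duration_s else times)


def carotid_template(t_rel: np.ndarray) -> np.ndarray:
    """Unit-amplitude per-beat carotid wall displacement.

    Raised-cosine upstroke over ``UPSTROKE_S`` seconds followed by an
    exponential relaxation with time constant ``DECAY_TAU_S``; zero before
    the beat onset.  Peak value 1 at ``t_rel == UPSTROKE_S``.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t_rel)
    up = (t_rel >= 0) & (t_rel < UPSTROKE_S)
    out[up] = 0.5 * (1.0 - np.cos(np.pi * t_rel[up] / UPSTROKE_S))
    down = t_rel >= UPSTROKE_S
    out[down] = np.exp(-(t_rel[down] - UPSTROKE_S) / DECAY_TAU_S)
    return out


def _pulse_component(beat_times: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Superpose unit carotid templates anchored at each beat time."""
    trace = np.zeros_like(t_grid, dtype=float)
    # each template is negligible after ~2 s; only touch that span
    span = UPSTROKE_S + 8.0 * DECAY_TAU_S
    dt = t_grid[1] - t_grid[0] if t_grid.size > 1 else 1.0
    n_span = int(np.ceil(span / dt)) + 2
    for bt in np.atleast_1d(beat_times):
        i0 = int(np.searchsorted(t_grid, bt))
        i1 = min(i0 + n_span, t_grid.size)
        if i0 >= t_grid.size:
            continue
        trace[i0:i1] += carotid_template(t_grid[i0:i1] - bt)
    return trace


def displacement_trace(
    profile: PhysioProfile, beat_times: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Neck-surface displacement (mm) on the frame-time grid.

    Sum of the respiratory sinusoid and the carotid pulse train.  When
    ``profile.power_ratio_db`` is set, the pulse amplitude is rescaled so
    that the respiratory-band spectral peak exceeds the pulse-band peak by
    exactly that many dB (measured on this trace with a Hann periodogram);
    ``pulse_amp_mm`` then serves as the nominal starting amplitude.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise InvalidArgumentError("t_grid must be non-empty")
    f_resp = profile.rr_bpm / 60.0
    resp = profile.resp_amp_mm * np.sin(2.0 * np.pi * f_resp * t_grid)
    pulse = profile.pulse_amp_mm * _pulse_component(np.asarray(beat_times, float), t_grid)
    if (
        profile.power_ratio_db is not None
        and profile.resp_amp_mm > 0
        and profile.pulse_amp_mm > 0
        and np.any(pulse != 0)
        and t_grid.size > 3
    ):
        fs = 1.0 / (t_grid[1] - t_grid[0])
        fr, pr_ = hann_periodogram(resp, fs)
        fp, pp = hann_periodogram(pulse, fs)
        p_resp = band_peak_power(fr, pr_, RESP_BAND_HZ)
        p_pulse = band_peak_power(fp, pp, PULSE_BAND_HZ)
        if p_resp > 0 and p_pulse > 0:
            target = p_resp / 10.0 ** (profile.power_ratio_db / 10.0)
            pulse *= np.sqrt(target / p_pulse)
    return resp + pulse


def synthesize_frames(
    config: SimConfig,
    displacement_mm: np.ndarray,
    motion_events: Sequence[tuple[float, float, float]] = (),
    rng: np.random.Generator | None = None,
) -> RadarFrameMatrix:
    """Render the frame matrix for a given neck-displacement trace.

    Frame ``k``, bin ``b`` is::

        clutter[b] + G * g((b*pitch - d - disp_k) / w) + N(0, noise_sd)

    with ``g(u) = -u * exp(-u**2 / 2)`` a Gaussian first-derivative echo
    template, ``d`` the nominal subject distance and ``w`` the spatial
    pulse width.  Motion events ``(time_s, duration_s, amplitude)`` add a
    Gaussian-windowed broadband transient spread over bins near the target.
    """
    displacement_mm = np.asarray(displacement_mm, dtype=float).ravel()
    n_frames = config.n_frames
    if displacement_mm.size != n_frames:
        raise InvalidArgumentError(
            f"displacement length {displacement_mm.size} != frame count {n_frames}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    bin_pos = np.arange(config.n_bins) * config.bin_pitch_m
    if config.clutter_profile is not None:
        clutter = np.asarray(config.clutter_profile, dtype=float)
        if clutter.shape != (config.n_bins,):
            raise InvalidArgumentError("clutter_profile must have length n_bins")
    else:
        # smooth static background: a few broad reflectors, deterministic per seed
        clutter_rng = np.random.default_rng(config.seed + 1_000_003)
        clutter = np.zeros(config.n_bins)
        for _ in range(5):
            center = clutter_rng.uniform(0, config.n_bins * config.bin_pitch_m)
            width = clutter_rng.uniform(0.02, 0.15)
            amp = clutter_rng.normal(0, 0.5)
            clutter += amp * np.exp(-0.5 * ((bin_pos - center) / width) ** 2)

    u = (
        bin_pos[None, :]
        - config.subject_distance_m
        - displacement_mm[:, None] / 1000.0
    ) / config.pulse_width_m
    echo = config.echo_amplitude * (-u) * np.exp(-0.5 * u * u)

    samples = clutter[None, :] + echo
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)

    if motion_events:
        t = config.frame_times()
        spatial = np.exp(
            -0.5 * ((bin_pos - config.subject_distance_m) / (5.0 * config.pulse_width_m)) ** 2
        )
        for time_s, dur_s, amp in motion_events:
            if dur_s <= 0:
                raise InvalidArgumentError("motion event duration must be > 0")
            window = np.exp(-0.5 * ((t - time_s) / (dur_s / 4.0)) ** 2)
            wobble = np.sin(2.0 * np.pi * 2.0 * (t - time_s)) * window
            samples = samples + amp * wobble[:, None] * spatial[None, :]

    return RadarFrameMatrix(
        samples=samples, frame_rate_hz=config.frame_rate_hz, bin_pitch_m=config.bin_pitch_m
    )


def simulate_recording(
    config: SimConfig | None = None, profile: PhysioProfile | None = None
) -> tuple[RadarFrameMatrix, GroundTruth]:
    """Generate one seeded recording plus its ground truth.

    Deterministic for a fixed ``config.seed``: beat timing, thermal noise
    and the clutter background all derive from it.
    """
    config = config if config is not None else SimConfig()
    profile = profile if profile is not None else PhysioProfile()
    rng = np.random.default_rng(config.seed)
    beat_times = generate_beat_times(profile, config.duration_s, rng)
    t_grid = config.frame_times()
    disp = displacement_trace(profile, beat_times, t_grid)
    frames = synthesize_frames(config, disp, profile.motion_events, rng=rng)
    truth = GroundTruth(
        beat_times_s=beat_times,
        true_rr_bpm=profile.rr_bpm,
        displacement_trace_mm=disp,
        rhythm=profile.rhythm,
    )
    return frames, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, seed=int(seed))
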