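# Methods

## Signal model

The radar observes the neck surface at range `d ≈ 0.50 m`. Its
displacement (in mm) is modelled as

    s(t) = A_r sin(2π f_r t) + A_p Σ_j h(t − t_j)

where `f_r` is the breathing frequency, `t_j` the beat onset times and
`h` a per-beat carotid template: a raised-cosine upstroke of 0.12 s
(systolic ejection) followed by an exponential relaxation with a 0.25 s
time constant (diastolic recoil). Any unimodal template with a single
dominant peak would serve; this one is smooth, causal, and its spectrum
is dominated by the beat-rate fundamental, which is what the rhythm
tracker relies on. The template functions are exposed
(`radvital.simulate.carotid_template`) for substitution.

Beat timing:

* **NSR** — intervals i.i.d. `Normal(60/HR, σ_j)` truncated to
  > 0.25 s, default `σ_j = 0.03 s`. Resting sinus rhythm has a few
  percent beat-to-beat variability; 0.03 s on a 0.87 s interval is
  CV ≈ 3.5%.
* **PeAF** — intervals i.i.d. lognormal with mean `60/HR` and
  CV 0.24. Atrial fibrillation intervals are irregular with no serial
  structure at this timescale; the lognormal keeps them positive and
  right-skewed. CV 0.24 places the default simulated MaxΔfrq
  (≈1.2–1.4 Hz) inside the interquartile range reported for PeAF
  patients measured this way.

Default rates: HR 69 bpm (NSR) / 80 bpm (PeAF) — the group means of the
populations the simulator emulates — and RR 18 breaths/min.

## Power calibration

On a power-density spectrum of the measured vital signal, respiration is
the most prominent peak and the carotid pulse the second, ~6.3 dB below
it. The simulator enforces this: after generating the respiratory and
pulse displacement components it rescales the pulse train so the ratio
of the tallest Hann-periodogram peak in 0.1–0.6 Hz to the tallest in
0.7–3.0 Hz equals `power_ratio_db` (default 6.3 dB) exactly on the
displacement trace. Because displacements (~1 mm) are small against the
echo pulse width (40 mm), the echo response is effectively linear in
displacement and the ratio survives synthesis, clutter removal and
bin extraction to within a fraction of a dB; the residual error comes
from thermal noise and the slight spectral overlap of the components.

## Echo synthesis

Frame `k`, bin `b` is

    clutter[b] + G g((b·Δ − d − s_k/1000) / w) + ε,  ε ~ N(0, σ_n)

with `g(u) = −u e^{−u²/2}` a Gaussian first-derivative template
(`w = 0.04 m`), `Δ = 1/156 m` the bin pitch, and a smooth static clutter
profile built from a few broad reflectors. The default noise SD
(`5e-4` with `G = 1`) puts the respiratory echo excursion ~34 dB above
per-sample noise — a strong, stationary-subject recording. Motion
events `(time, duration, amplitude)` add a Gaussian-windowed 2 Hz
oscillation spread over ±5 pulse widths around the target, reproducing
the broadband fluctuation a body movement causes. All randomness
derives from a single seeded `numpy` generator, so recordings are
bit-reproducible.

## Clutter filter choice

The one-pole loopback filter `c_k = α c_{k−1} + (1−α) x_k`, `y = x − c`
is the standard IR-UWB background subtractor; its high-pass transfer
function is `H(z) = α(1 − z⁻¹)/(1 − α z⁻¹)`. The corner frequency is
`≈ f_s(1−α)/2π`. At a 200 Hz frame rate, α = 0.97 corners at ~0.95 Hz
and attenuates the respiratory band by 7–11 dB relative to the pulse
band — it would distort the very power relation the pipeline (and the
target localizer) depends on. The default is therefore **α = 0.999**
(corner ≈ 0.032 Hz): static clutter is still cancelled exactly from the
first frame (`c_0 = x_0`) and tracked with a 5 s time constant, while
differential attenuation across 0.2–3 Hz stays below 0.05 dB.
`clutter_filter_gain()` exposes the analytic response for choosing α
against other frame rates.

## Target localization

Performed after clutter removal (breathing motion then dominates the
per-bin slow-time SD). The search window defaults to 0.3–0.8 m around
the 0.5 m setup; ties resolve to the nearer bin. Bin centers are at
`b·Δ` with 0-based indices, so the 0.50 m subject maps to bin 78. A
single bin is extracted, with no neighbor averaging — one target, one
location.

## Respiratory rate

Hann periodogram of the mean-subtracted vital signal, zero-padded to a
≤ 0.01 Hz grid, argmax within 0.1–0.7 Hz (6–42 breaths/min, enclosing
the 0.25–0.5 Hz band observed in resting adults), refined by parabolic
interpolation of the peak and its neighbours. One estimate per
recording, matching the 1-minute measurement epoch; the estimator needs
at least two cycles of the slowest admissible breath (20 s at the
default band floor).

## Pulse isolation and beat detection

Band-pass corners 0.7/3.0 Hz: above the respiratory band and its
vicinity, below 0.7 Hz; 3.0 Hz admits fundamentals up to 180 bpm.
Filtering is forward-backward (zero-phase) so peak times carry no
group-delay bias — a constant physiological offset between carotid
upstroke and the ECG R wave cancels in interval differences, but a
frequency-dependent delay would not. The 3-point moving average matches
the light smoothing applied before peak reading. Peaks need prominence
≥ 1.0 × median |waveform| and ≥ 0.3 s spacing (200 bpm refractory
ceiling); the larger peak wins conflicts, and times are refined
parabolically to sub-sample (≪ 5 ms) resolution.

Validation pairing: detected peaks match reference beats by greedy
nearest-time assignment within 0.3 s, one-to-one; only intervals whose
endpoints match *consecutive* reference beats enter the IBI-error
statistics, so missed beats do not contaminate interval comparisons.

## Rhythm statistic

The phrase "20 estimates per second averaged over a 3-second window" is
realized as 3-s analysis segments hopped every 50 ms — each plotted
frequency is then genuinely a 3-s summary. The alternative reading
(1-s instantaneous estimates, 3-s moving average of the frequency
sequence) is available as `track_mode="smoothed"`, default off.
Segment spectra are zero-padded to a 0.05 Hz grid so the NSR track's
residual wobble (±1–2 grid steps, ≈0.1 Hz) sits far below the 0.57 Hz
decision threshold; MaxΔfrq is max − min of the track within a 17-s
epoch, sliding at 1 s across longer recordings with the maximum taken —
the statistic an online monitor would raise an alarm on. Exactly
0.57 Hz classifies as PeAF: the boundary goes to the sensitive side.

## Agreement statistics

ICC defaults to the one-way random-effects single-rater form
ICC(1,1) = (MSB − MSW)/(MSB + MSW) for two raters, with the standard
F-bound 95% CI; a two-way consistency variant (ICC(3,1)) is available
via `variant="consistency"`. Bland–Altman uses the 1.96 multiplier on
the (n−1) sample SD of differences. ROC thresholds are the midpoints
between consecutive distinct scores (plus outer sentinels), AUC is the
Mann–Whitney rank statistic with ties counted half, and Youden ties
resolve to the lower threshold. Kappa's CI uses the large-sample
standard error `sqrt(p_o(1−p_o)/n)/(1−p_e)` with the upper bound capped
at 1.000. Degenerate inputs (zero variance, one-class labels, empty
margins, p_e = 1) raise `UndefinedStatisticError` rather than returning
NaN.

## What the simulator does and does not show

The generator reproduces the statistical structure the pipeline
assumes: a dominant respiratory oscillation, a calibrated ~6.3 dB-weaker
pulse component, static clutter, thermal noise, rhythm-dependent beat
irregularity, and optional motion transients. It does **not** model
electromagnetic propagation, antenna patterns, multipath, variable
pulse morphology, respiratory sinus arrhythmia, premature beats, or
slow posture drift. Passing recovery tests on simulated data therefore
demonstrates the correctness and calibration of the processing chain
under its stated assumptions — not clinical performance, which requires
real recordings against ECG.

## Problem sizes and numerical choices

Tests and the acceptance script use 60-s recordings at 200 Hz × 156
bins (20-s recordings where only localization or I/O is exercised), 10
seeds for power-calibration averages, 20 seeded runs per recovery
property, and 20 + 20 subjects for the rhythm-separation check — sizes
at which the Monte-Carlo error of each property is comfortably below
its acceptance margin. Recordings round-trip through CSV with 17
significant digits, preserving bits. All float comparisons in the
pipeline are exact-arithmetic or tolerance-free by construction;
stochastic assertions state their tolerance next to the moment
calculation that justifies it.
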