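"""Seeded synthetic walking / running / jumping accelerometry.

The study protocol this emulates has each participant wear a triaxial
sensor (100 Hz, +/-16 g) and perform repeated short trials: 9 walking,
6 running and 22 jumping bouts. The generator reproduces the signal
structure the downstream feature set relies on, not biomechanics:

* the vertical (y) axis carries a +1 g gravity offset plus an impact
  train — half-sine pulses (duty 20% of the cycle) at the participant's
  cadence for walking and running, running additionally with brief low-g
  flight phases between impacts;
* jumping cycles contain a near-0-g free-fall interval (the flight) and a
  sparse high-amplitude landing spike, which makes running and jumping
  partially confusable, as real data are;
* horizontal axes carry correlated lower-amplitude oscillation; white
  Gaussian noise is added to all axes;
* placement scales impact amplitude (ankle > hip > lower back);
* per-participant multiplicative lognormal effects on cadence and
  amplitude create between-subject variability.

One global seed determines everything; each participant's random stream is
derived with ``SeedSequence(seed, spawn_key=(participant_index,))`` so a
single participant can be regenerated without simulating the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    ACTIVITIES,
    PLACEMENTS,
    ActivitySegment,
    TriaxialRecording,
    write_recording,
    write_segments,
)

#: Impact-amplitude scaling by sensor placement; distal placements see
#: larger accelerations than waist-level ones.
PLACEMENT_AMPLITUDE: dict[str, float] = {"ankle": 1.0, "hip": 0.7, "lower_back": 0.6}

#: Fraction of a gait cycle occupied by the impact pulse.
IMPACT_DUTY: float = 0.2

#: Fraction of a jump cycle occupied by the landing spike.
LANDING_DUTY: float = 0.08


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol and signal-model parameters.

    All amplitudes are in g; cadences and rates in Hz. Ranges are sampled
    uniformly per trial; participant effects are multiplicative lognormal
    draws (sigma ``participant_sigma``) applied to cadence and amplitude.
    """

    n_participants: int = 48
    fs: float = 100.0
    placement: str = "hip"
    walking_step_frequency_hz: tuple[float, float] = (1.5, 2.2)
    walking_peak_amplitude_g: tuple[float, float] = (0.3, 0.8)
    running_step_frequency_hz: tuple[float, float] = (2.4, 3.2)
    running_peak_amplitude_g: tuple[float, float] = (1.5, 3.5)
    jumping_peak_amplitude_g: tuple[float, float] = (3.0, 7.0)
    jump_rate_hz: tuple[float, float] = (0.8, 1.6)
    flight_fraction: tuple[float, float] = (0.2, 0.4)
    participant_sigma: float = 0.1
    noise_sd_g: float = 0.05
    segment_seconds: dict[str, float] = field(
        default_factory=lambda: {"walking": 4.0, "running": 2.0, "jumping": 3.0}
    )
    trials: dict[str, int] = field(
        default_factory=lambda: {"walking": 9, "running": 6, "jumping": 22}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        for name in (
            "walking_step_frequency_hz",
            "walking_peak_amplitude_g",
            "running_step_frequency_hz",
            "running_peak_amplitude_g",
            "jumping_peak_amplitude_g",
            "jump_rate_hz",
            "flight_fraction",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} range must satisfy 0 <= low <= high, got ({lo}, {hi})")
        ff_lo, ff_hi = self.flight_fraction
        if ff_hi >= 1 - LANDING_DUTY:
            raise ValueError("flight_fraction must leave room for the landing spike")
        if self.participant_sigma < 0 or self.noise_sd_g < 0:
            raise ValueError("participant_sigma and noise_sd_g must be non-negative")
        for activity in ACTIVITIES:
            if self.segment_seconds.get(activity, 0) <= 0:
                raise ValueError(f"segment_seconds[{activity!r}] must be positive")
            if self.trials.get(activity, -1) < 0:
                raise ValueError(f"trials[{activity!r}] must be non-negative")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _half_sine_pulse(phase: np.ndarray, duty: float) -> np.ndarray:
    """Half-sine impact pulse over the first ``duty`` fraction of the cycle."""
    pulse = np.zeros_like(phase)
    active = phase < duty
    pulse[active] = np.sin(np.pi * phase[active] / duty)
    return pulse


def _gait_trial(
    rng: np.random.Generator,
    n: int,
    fs: float,
    cadence: float,
    amplitude: float,
    running: bool,
) -> np.ndarray:
    """One walking or running bout: impact train on y, oscillation on x/z."""
    t = np.arange(n) / fs
    phase0 = float(rng.uniform(0, 1))
    phase = (t * cadence + phase0) % 1.0
    y = 1.0 + amplitude * _half_sine_pulse(phase, IMPACT_DUTY)
    if running:
        # Brief aerial phase mid-cycle: vertical acceleration dips toward 0 g.
        # Depth scales (saturating) with impact amplitude so a zero-amplitude
        # bout degenerates to quiet stance.
        dip_phase = (phase - 0.5) % 1.0
        y -= 0.7 * min(1.0, amplitude) * _half_sine_pulse(dip_phase, 0.15)
    x = 0.35 * amplitude * np.sin(2 * np.pi * (t * cadence + phase0))
    z = 0.25 * amplitude * np.sin(2 * np.pi * (t * cadence + phase0) + 0.8)
    return np.column_stack([x, y, z])


def _jump_trial(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate: float,
    amplitude: float,
    flight_fraction: float,
) -> np.ndarray:
    """One jumping bout: free-fall flight then a high-amplitude landing spike."""
    t = np.arange(n) / fs
    phase0 = float(rng.uniform(0, 1))
    phase = (t * rate + phase0) % 1.0
    flight_start = 0.4
    in_flight = (phase >= flight_start) & (phase < flight_start + flight_fraction)
    landing_phase = (phase - (flight_start + flight_fraction)) % 1.0
    landing = amplitude * _half_sine_pulse(landing_phase, LANDING_DUTY)
    y = 1.0 + landing
    y[in_flight] = 0.0  # sensor in free fall reads ~0 g on every axis
    x = 0.3 * landing * np.sin(2 * np.pi * landing_phase / LANDING_DUTY + 0.3)
    z = 0.2 * landing * np.sin(2 * np.pi * landing_phase / LANDING_DUTY + 1.1)
    x[in_flight] = 0.0
    z[in_flight] = 0.0
    return np.column_stack([x, y, z])


def simulate_participant(
    config: SimulationConfig, participant_index: int
) -> tuple[TriaxialRecording, list[ActivitySegment]]:
    """Simulate one participant's full trial protocol.

    Returns one concatenated recording (walking trials, then running, then
    jumping, back to back) together with its labeled segments. The same
    (config, participant_index) pair always yields bit-identical output.
    """
    config.validate()
    if not 0 <= participant_index < max(config.n_participants, 1):
        raise ValueError(
            f"participant_index {participant_index} out of range "
            f"[0, {config.n_participants})"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(participant_index,))
    )
    sigma = config.participant_sigma
    cadence_mult = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
    amplitude_mult = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
    placement_scale = PLACEMENT_AMPLITUDE[config.placement]

    participant_id = f"P{participant_index:02d}"
    recording_id = f"{participant_id}_{config.placement}"
    chunks: list[np.ndarray] = []
    segments: list[ActivitySegment] = []
    cursor = 0
    for activity in ACTIVITIES:
        n = round(config.fs * config.segment_seconds[activity])
        for _ in range(config.trials[activity]):
            if activity == "walking":
                cadence = _uniform(rng, config.walking_step_frequency_hz) * cadence_mult
                amp = _uniform(rng, config.walking_peak_amplitude_g)
                chunk = _gait_trial(
                    rng, n, config.fs, cadence, amp * amplitude_mult * placement_scale, False
                )
            elif activity == "running":
                cadence = _uniform(rng, config.running_step_frequency_hz) * cadence_mult
                amp = _uniform(rng, config.running_peak_amplitude_g)
                chunk = _gait_trial(
                    rng, n, config.fs, cadence, amp * amplitude_mult * placement_scale, True
                )
            else:
                rate = _uniform(rng, config.jump_rate_hz) * cadence_mult
                amp = _uniform(rng, config.jumping_peak_amplitude_g)
                flight = _uniform(rng, config.flight_fraction)
                chunk = _jump_trial(
                    rng, n, config.fs, rate, amp * amplitude_mult * placement_scale, flight
                )
            if config.noise_sd_g > 0:
                chunk = chunk + rng.normal(0.0, config.noise_sd_g, chunk.shape)
            chunks.append(chunk)
            segments.append(
                ActivitySegment(
                    recording_id=recording_id,
                    label=activity,
                    start=cursor,
                    end=cursor + n,
                )
            )
            cursor += n
    samples = np.concatenate(chunks, axis=0) if chunks else np.zeros((1, 3))
    recording = TriaxialRecording(
        recording_id=recording_id,
        participant_id=participant_id,
        placement=config.placement,
        fs=config.fs,
        samples=np.clip(samples, -16.0, 16.0),
    )
    return recording, segments


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[TriaxialRecording], list[ActivitySegment]]:
    """Simulate the full cohort: one recording per participant.

    Per-participant random streams are independent given the global seed;
    the segment layout (trial counts and durations) depends only on the
    config, never on the random draws.
    """
    config.validate()
    recordings: list[TriaxialRecording] = []
    segments: list[ActivitySegment] = []
    for index in range(config.n_participants):
        recording, recording_segments = simulate_participant(config, index)
        recordings.append(recording)
        segments.extend(recording_segments)
    return recordings, segments


def write_dataset(
    recordings: list[TriaxialRecording],
    segments: list[ActivitySegment],
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> None:
    """Write recording CSVs, a labels CSV, and the config snapshot (YAML)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for recording in recordings:
        write_recording(recording, out_dir / f"{recording.recording_id}.csv")
    write_segments(segments, out_dir / "labels.csv")
    if config is not None:
        snapshot = dataclasses.asdict(config)
        (out_dir / "simulation_config.yaml").write_text(yaml.safe_dump(snapshot))
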