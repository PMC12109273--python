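"""Lissajous target and cursor-perturbation trajectories.

The pursuit task shows a target ring moving along an invisible Lissajous
curve (x and y are sinusoids at different frequencies) while the cursor
is additionally displaced by a second, smaller Lissajous curve.  Both
curves are deterministic, so the analysis can regress them out of the
cursor path.  Screen coordinates are abstract continuous units centred
at zero; only relative error is ever analysed, so no pixel mapping is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LissajousSpec",
    "Trajectory",
    "TrialTimeline",
    "TARGET_FREQ_X",
    "TARGET_FREQ_Y",
    "PERTURBATION_FREQ_X",
    "PERTURBATION_FREQ_Y",
    "lissajous",
    "make_target_trajectory",
    "make_perturbation_trajectory",
    "write_trajectory",
]

TARGET_FREQ_X = 0.075
TARGET_FREQ_Y = 0.1
PERTURBATION_FREQ_X = 0.14
PERTURBATION_FREQ_Y = 0.21

#: Perturbation amplitude as a fraction of the (unit) target amplitude.
DEFAULT_PERTURBATION_RATIO = 0.25


@dataclass(frozen=True)
class LissajousSpec:
    """x(t)=amp_x·sin(2π·freq_x·t+phase_x), y likewise."""

    freq_x: float
    freq_y: float
    amp_x: float = 1.0
    amp_y: float = 1.0
    phase_x: float = 0.0
    phase_y: float = 0.0

    def __post_init__(self) -> None:
        if self.freq_x <= 0 or self.freq_y <= 0:
            raise ValueError("Lissajous frequencies must be positive")
        if self.amp_x < 0 or self.amp_y < 0:
            raise ValueError("Lissajous amplitudes must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """A sampled 2-D path at a fixed rate."""

    x: np.ndarray
    y: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class TrialTimeline:
    """One trial: 45 s of tracking sampled at 60 Hz, then a 15 s break."""

    trial_duration: float = 45.0
    break_duration: float = 15.0
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.break_duration < 0:
            raise ValueError("break_duration must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))


def lissajous(spec: LissajousSpec, duration: float, sample_rate: float) -> Trajectory:
    """Sample a Lissajous curve at t = k / sample_rate, k = 0..N-1."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = spec.amp_x * np.sin(2 * np.pi * spec.freq_x * t + spec.phase_x)
    y = spec.amp_y * np.sin(2 * np.pi * spec.freq_y * t + spec.phase_y)
    return Trajectory(x, y, sample_rate)


def make_target_trajectory(timeline: TrialTimeline, amplitude: float = 1.0) -> Trajectory:
    """Target ring path: 0.075 Hz on x, 0.1 Hz on y, zero phases."""
    spec = LissajousSpec(TARGET_FREQ_X, TARGET_FREQ_Y, amp_x=amplitude, amp_y=amplitude)
    return lissajous(spec, timeline.trial_duration, timeline.sample_rate)


def make_perturbation_trajectory(
    timeline: TrialTimeline, amplitude: float = DEFAULT_PERTURBATION_RATIO
) -> Trajectory:
    """Cursor-perturbation path: 0.14 Hz on x, 0.21 Hz on y, smaller amplitude."""
    spec = LissajousSpec(
        PERTURBATION_FREQ_X, PERTURBATION_FREQ_Y, amp_x=amplitude, amp_y=amplitude
    )
    return lissajous(spec, timeline.trial_duration, timeline.sample_rate)


def write_trajectory(traj: Trajectory, path) -> None:
    """Delimited text: time_s, x, y."""
    data = np.column_stack([traj.time, traj.x, traj.y])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header="time_s,x,y", comments="")
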