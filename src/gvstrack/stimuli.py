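"""Amplitude-modulated galvanic vestibular stimulation (GVS) waveforms.

A GVS condition is a low-amplitude current delivered through mastoid
electrodes (two-pole montage) or mastoid-plus-temple electrodes
(three-pole montage).  Each active stimulus is an amplitude-modulated
(AM) signal written as an envelope/carrier frequency pair in Hz; the
bank holds eight such pairs (GVS1..GVS8) plus a zero-current sham.
Per-participant current amplitude is set to 90% of the sensory
perception threshold located by an ascending staircase, independently
for the two montages, so that delivered stimuli stay subthreshold.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Configuration",
    "StimulusSpec",
    "Waveform",
    "AliasingWarning",
    "StaircaseNonConvergenceError",
    "BANK_FREQUENCIES",
    "BANK_LABELS",
    "SHAM_LABEL",
    "bank_order_key",
    "make_stimulus_bank",
    "synthesize_am_stimulus",
    "staircase_threshold",
    "optimal_amplitude",
    "bank_to_json",
    "bank_from_json",
    "write_waveform",
]


class Configuration(str, enum.Enum):
    """Electrode montage: mastoids only, or mastoids plus temples."""

    TWO_POLE = "two_pole"
    THREE_POLE = "three_pole"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Envelope/carrier frequency pairs (Hz) of the AM stimulus bank.
BANK_FREQUENCIES: dict[str, tuple[float, float]] = {
    "GVS1": (10.0, 30.0),
    "GVS2": (10.0, 60.0),
    "GVS3": (20.0, 60.0),
    "GVS4": (20.0, 110.0),
    "GVS5": (30.0, 75.0),
    "GVS6": (50.0, 110.0),
    "GVS7": (70.0, 145.0),
    "GVS8": (30.0, 110.0),
}

BANK_LABELS: tuple[str, ...] = tuple(BANK_FREQUENCIES)
SHAM_LABEL = "SHAM"

#: Deterministic synthesis rate; >= 2x the highest carrier (145 Hz).
DEFAULT_SAMPLE_RATE = 600.0

_CONFIG_ORDER = {Configuration.TWO_POLE: 0, Configuration.THREE_POLE: 1}


class AliasingWarning(UserWarning):
    """Synthesis sample rate is below the Nyquist rate of the carrier."""


class StaircaseNonConvergenceError(RuntimeError):
    """Ascending staircase exhausted its step budget without perception."""


def _as_configuration(configuration: Configuration | str) -> Configuration:
    if isinstance(configuration, Configuration):
        return configuration
    return Configuration(configuration)


def bank_order_key(label: str, configuration: Configuration | str) -> tuple[int, int]:
    """Deterministic ordering: bank order GVS1..GVS8, then two-pole first.

    Used as the tie-break everywhere a single (stimulus, configuration)
    pair must be picked from candidates with equal error.
    """
    configuration = _as_configuration(configuration)
    try:
        stim_rank = BANK_LABELS.index(label)
    except ValueError:
        stim_rank = len(BANK_LABELS)  # sham and unknown labels sort last
    return (stim_rank, _CONFIG_ORDER[configuration])


@dataclass(frozen=True)
class StimulusSpec:
    """One GVS condition: an AM waveform recipe bound to a montage."""

    label: str
    envelope_freq: float
    carrier_freq: float
    amplitude: float
    configuration: Configuration
    is_sham: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "configuration", _as_configuration(self.configuration))
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0 mA, got {self.amplitude}")
        if self.is_sham:
            if self.amplitude != 0:
                raise ValueError("sham stimulus must have zero amplitude")
        else:
            if not self.envelope_freq < self.carrier_freq:
                raise ValueError(
                    "envelope frequency must be below carrier frequency, got "
                    f"{self.envelope_freq} >= {self.carrier_freq} Hz"
                )

    def with_amplitude(self, amplitude: float) -> "StimulusSpec":
        """Copy of this spec at a different current amplitude (sham stays 0)."""
        if self.is_sham:
            return self
        return replace(self, amplitude=amplitude)


@dataclass(frozen=True)
class Waveform:
    """A sampled current time series (mA) at a fixed rate."""

    samples: np.ndarray
    sample_rate: float
    duration: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        expected = int(round(self.duration * self.sample_rate))
        if samples.shape != (expected,):
            raise ValueError(
                f"expected {expected} samples for {self.duration} s at "
                f"{self.sample_rate} Hz, got {samples.shape}"
            )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def make_stimulus_bank(
    configuration: Configuration | str, amplitude: float = 1.0
) -> list[StimulusSpec]:
    """The nine conditions of one montage: GVS1..GVS8 plus sham, in bank order.

    ``amplitude`` is the per-participant subthreshold current (mA) applied
    to every active stimulus; the sham member is always zero current.
    """
    configuration = _as_configuration(configuration)
    bank = [
        StimulusSpec(
            label=label,
            envelope_freq=env,
            carrier_freq=car,
            amplitude=amplitude,
            configuration=configuration,
        )
        for label, (env, car) in BANK_FREQUENCIES.items()
    ]
    bank.append(
        StimulusSpec(
            label=SHAM_LABEL,
            envelope_freq=0.0,
            carrier_freq=0.0,
            amplitude=0.0,
            configuration=configuration,
            is_sham=True,
        )
    )
    return bank


def synthesize_am_stimulus(
    spec: StimulusSpec,
    duration: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    modulation_depth: float = 1.0,
) -> Waveform:
    """Sample the AM current s(t) = A·((1−m) + m·sin(2πf_e t))·sin(2πf_c t).

    The default modulation depth m=1 gives the suppressed-carrier product
    of sines, whose spectrum concentrates at the carrier ± envelope
    sidebands.  Sham specs yield all-zero samples.  A rate below twice the
    carrier frequency aliases the waveform; synthesis still proceeds (the
    historical acquisition rate of 60 Hz is representable) but an
    :class:`AliasingWarning` is emitted.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    if not 0 < modulation_depth <= 1:
        raise ValueError(f"modulation depth must be in (0, 1], got {modulation_depth}")
    n = int(round(duration * sample_rate))
    if spec.is_sham:
        return Waveform(np.zeros(n), sample_rate, duration)
    if sample_rate < 2 * spec.carrier_freq:
        warnings.warn(
            f"sample rate {sample_rate} Hz is below the Nyquist rate of the "
            f"{spec.carrier_freq} Hz carrier; the synthesised waveform is aliased",
            AliasingWarning,
            stacklevel=2,
        )
    t = np.arange(n) / sample_rate
    m = modulation_depth
    envelope = (1.0 - m) + m * np.sin(2 * np.pi * spec.envelope_freq * t)
    samples = spec.amplitude * envelope * np.sin(2 * np.pi * spec.carrier_freq * t)
    return Waveform(samples, sample_rate, duration)


def staircase_threshold(
    perception: Callable[[float], bool],
    base: float = 0.1,
    step: float = 0.1,
    max_steps: int = 100,
) -> float:
    """Sensory threshold by a single ascending staircase run.

    Currents base, base+step, base+2·step, ... are presented until
    ``perception`` first reports True; that current is the threshold.
    ``perception`` must be monotone (never True-then-False as current rises).
    """
    if base <= 0:
        raise ValueError(f"base current must be positive, got {base}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    for k in range(max_steps):
        current = base + k * step
        if perception(current):
            return current
    raise StaircaseNonConvergenceError(
        f"no perception after {max_steps} steps (last current "
        f"{base + (max_steps - 1) * step:g} mA)"
    )


def optimal_amplitude(threshold: float) -> float:
    """Subthreshold stimulation amplitude: 90% of the perception threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return 0.9 * threshold


# -- serialisation ---------------------------------------------------------


def bank_to_json(bank: Sequence[StimulusSpec]) -> str:
    records = [
        {
            "label": s.label,
            "envelope_freq": s.envelope_freq,
            "carrier_freq": s.carrier_freq,
            "amplitude": s.amplitude,
            "configuration": s.configuration.value,
            "is_sham": s.is_sham,
        }
        for s in bank
    ]
    return json.dumps(records, indent=2)


def bank_from_json(text: str) -> list[StimulusSpec]:
    return [StimulusSpec(**record) for record in json.loads(text)]


def write_waveform(wave: Waveform, path) -> None:
    """Two-column delimited text: time_s, current_mA."""
    data = np.column_stack([wave.time, wave.samples])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header="time_s,current_mA", comments="")
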