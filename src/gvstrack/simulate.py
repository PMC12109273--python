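"""Synthetic tracking cohorts with planted stimulus effects.

Stands in for a recorded cohort: each simulated participant tracks the
target with a gain, a visuomotor lag, and band-limited Gaussian motor
noise whose standard deviation is scaled per (stimulus, montage) by an
effect map.  The stimulus waveform itself never enters the cursor
equation — stimuli act purely through their noise multiplier, because
the downstream analysis measures effects on error magnitude, not a
transduction model.  The multiplier map (after per-participant
heterogeneity) is retained as planted ground truth so recovery of the
individualised stimulus can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import scipy.signal

from .stimuli import (
    BANK_LABELS,
    SHAM_LABEL,
    Configuration,
    StimulusSpec,
    bank_order_key,
    make_stimulus_bank,
)
from .trajectory import (
    DEFAULT_PERTURBATION_RATIO,
    Trajectory,
    TrialTimeline,
    make_perturbation_trajectory,
    make_target_trajectory,
)

__all__ = [
    "ParticipantModel",
    "EffectMap",
    "SimConfig",
    "TrialRecord",
    "SimulatedCohort",
    "simulate_trial",
    "simulate_cohort",
    "planted_optimum",
]

EffectKey = tuple[str, Configuration]


@dataclass(frozen=True)
class ParticipantModel:
    """One simulated participant's tracking behaviour.

    gain
        Multiplicative cursor response to the target (unitless, > 0).
    lag
        Visuomotor delay in seconds, applied as a sample shift with the
        leading edge held at the first target value.
    base_noise_sd
        Motor-noise standard deviation (screen units) under a unit
        effect multiplier.
    noise_bandwidth
        Low-pass cut-off (Hz) of the motor noise.
    """

    participant_id: str
    gain: float = 1.0
    lag: float = 0.0
    base_noise_sd: float = 0.1
    noise_bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.base_noise_sd < 0:
            raise ValueError("base_noise_sd must be non-negative")
        if self.noise_bandwidth <= 0:
            raise ValueError("noise_bandwidth must be positive")


def _as_key(label: str, configuration: Configuration | str) -> EffectKey:
    return (label, Configuration(configuration))


@dataclass(frozen=True)
class EffectMap:
    """Noise multiplier per (stimulus label, montage); sham is the reference."""

    multipliers: Mapping[EffectKey, float]

    def __post_init__(self) -> None:
        normalised = {
            _as_key(label, cfg): float(m) for (label, cfg), m in self.multipliers.items()
        }
        if any(m <= 0 for m in normalised.values()):
            raise ValueError("all effect multipliers must be positive")
        object.__setattr__(self, "multipliers", normalised)

    def multiplier(self, label: str, configuration: Configuration | str) -> float:
        key = _as_key(label, configuration)
        if key not in self.multipliers:
            raise KeyError(
                f"no effect multiplier for stimulus {label!r} in "
                f"{Configuration(configuration).value} configuration"
            )
        return self.multipliers[key]

    @classmethod
    def uniform(cls, value: float = 1.0, labels: Iterable[str] | None = None) -> "EffectMap":
        labels = tuple(labels) if labels is not None else BANK_LABELS + (SHAM_LABEL,)
        return cls({(lab, cfg): value for lab in labels for cfg in Configuration})

    def with_planted(
        self, label: str, configuration: Configuration | str, value: float
    ) -> "EffectMap":
        """Copy with one (stimulus, montage) multiplier replaced."""
        updated = dict(self.multipliers)
        updated[_as_key(label, configuration)] = float(value)
        return EffectMap(updated)

    def perturbed(self, rng: np.random.Generator, sd: float) -> "EffectMap":
        """Lognormal per-entry jitter of the non-sham multipliers.

        Models between-participant heterogeneity of stimulus response, so
        simulated participants can have different individualised stimuli.
        The sham reference level is left untouched.
        """
        if sd < 0:
            raise ValueError("heterogeneity sd must be non-negative")
        updated = {}
        for (label, cfg), m in self.multipliers.items():
            if sd > 0 and label != SHAM_LABEL:
                m = m * float(np.exp(rng.normal(0.0, sd)))
            updated[(label, cfg)] = m
        return EffectMap(updated)


@dataclass(frozen=True)
class TrialRecord:
    """One 45 s trial: identifiers plus aligned target, perturbation, cursor."""

    participant_id: str
    configuration: Configuration
    stimulus_label: str
    target: Trajectory
    perturbation: Trajectory
    cursor: Trajectory
    trial_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "configuration", Configuration(self.configuration))
        n = self.target.n_samples
        fs = self.target.sample_rate
        for traj in (self.perturbation, self.cursor):
            if traj.n_samples != n or traj.sample_rate != fs:
                raise ValueError("target, perturbation and cursor must be aligned")


@dataclass
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the source study design: 10 analysed participants,
    two montages, 8 AM stimuli plus sham (two sham trials per montage),
    45 s trials at 60 Hz.  Participant gains, lags and noise levels are
    drawn once per participant from the distributions parameterised
    below, each participant on an independent random substream.
    """

    n_participants: int = 10
    timeline: TrialTimeline = field(default_factory=TrialTimeline)
    effect_map: EffectMap = field(default_factory=EffectMap.uniform)
    participant_heterogeneity_sd: float = 0.15
    seed: int = 0
    n_sham_trials: int = 2
    gain_sd: float = 0.05           # lognormal sd around gain 1
    lag_range: tuple[float, float] = (0.1, 0.3)  # s, uniform visuomotor delay
    base_noise_sd: float = 0.1      # screen units, vs unit target amplitude
    noise_sd_cv: float = 0.2        # lognormal sd of per-participant noise level
    noise_bandwidth: float = 2.0    # Hz
    target_amplitude: float = 1.0
    perturbation_amplitude: float = DEFAULT_PERTURBATION_RATIO
    participant_effect_maps: list[EffectMap] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_sham_trials < 1:
            raise ValueError("n_sham_trials must be >= 1")
        if self.participant_effect_maps is not None and len(
            self.participant_effect_maps
        ) != self.n_participants:
            raise ValueError("need one participant_effect_map per participant")


@dataclass
class SimulatedCohort:
    """Simulated trials plus the planted ground truth that generated them."""

    trials: list[TrialRecord]
    ground_truth: dict
    config: SimConfig


def _lowpass_noise(
    rng: np.random.Generator, n: int, sd: float, bandwidth: float, sample_rate: float
) -> np.ndarray:
    """Band-limited Gaussian noise with stationary SD equal to ``sd``.

    White Gaussian noise through a first-order IIR low-pass at the given
    cut-off, scaled by the filter's theoretical stationary gain so the
    output SD matches ``sd`` in expectation.  A 2 s burn-in is discarded
    in place of steady-state initialisation.
    """
    if sd == 0:
        return np.zeros(n)
    a = float(np.exp(-2 * np.pi * bandwidth / sample_rate))
    burn = int(round(2 * sample_rate))
    white = rng.standard_normal(n + burn)
    filtered = scipy.signal.lfilter([1 - a], [1.0, -a], white)[burn:]
    stationary_sd = (1 - a) / np.sqrt(1 - a * a)
    return sd / stationary_sd * filtered


def _lagged(values: np.ndarray, lag_samples: int) -> np.ndarray:
    if lag_samples <= 0:
        return values
    out = np.empty_like(values)
    out[:lag_samples] = values[0]
    out[lag_samples:] = values[: values.size - lag_samples]
    return out


def simulate_trial(
    model: ParticipantModel,
    spec: StimulusSpec,
    effect: EffectMap,
    timeline: TrialTimeline,
    rng: np.random.Generator,
    target: Trajectory | None = None,
    perturbation: Trajectory | None = None,
    trial_index: int = 0,
) -> TrialRecord:
    """One simulated trial: cursor = gain·target(t−lag) + perturbation + noise.

    The noise term is zero-mean band-limited Gaussian with SD
    ``base_noise_sd × multiplier(stimulus, configuration)``.  Passing
    precomputed ``target``/``perturbation`` trajectories avoids
    regenerating the deterministic curves for every trial of a cohort.
    """
    multiplier = effect.multiplier(spec.label, spec.configuration)
    if target is None:
        target = make_target_trajectory(timeline)
    if perturbation is None:
        perturbation = make_perturbation_trajectory(timeline)
    fs = timeline.sample_rate
    n = timeline.n_samples
    lag_samples = int(round(model.lag * fs))
    sd = model.base_noise_sd * multiplier
    cursor_x = (
        model.gain * _lagged(target.x, lag_samples)
        + perturbation.x
        + _lowpass_noise(rng, n, sd, model.noise_bandwidth, fs)
    )
    cursor_y = (
        model.gain * _lagged(target.y, lag_samples)
        + perturbation.y
        + _lowpass_noise(rng, n, sd, model.noise_bandwidth, fs)
    )
    return TrialRecord(
        participant_id=model.participant_id,
        configuration=spec.configuration,
        stimulus_label=spec.label,
        target=target,
        perturbation=perturbation,
        cursor=Trajectory(cursor_x, cursor_y, fs),
        trial_index=trial_index,
    )


def _draw_participant(
    config: SimConfig, participant_id: str, rng: np.random.Generator
) -> ParticipantModel:
    gain = float(np.exp(rng.normal(0.0, config.gain_sd)))
    lag = float(rng.uniform(*config.lag_range))
    noise_sd = config.base_noise_sd * float(np.exp(rng.normal(0.0, config.noise_sd_cv)))
    return ParticipantModel(
        participant_id=participant_id,
        gain=gain,
        lag=lag,
        base_noise_sd=noise_sd,
        noise_bandwidth=config.noise_bandwidth,
    )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate the full crossover design for every participant.

    Every participant performs, in both montages, one trial per active
    stimulus and ``n_sham_trials`` sham trials.  Each participant draws
    from an independent substream of ``config.seed``, so adding
    participants never perturbs earlier participants' data.  The
    returned ground truth records each participant's realised effect
    multipliers (after heterogeneity) and behavioural parameters.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    target = make_target_trajectory(config.timeline, config.target_amplitude)
    perturbation = make_perturbation_trajectory(
        config.timeline, config.perturbation_amplitude
    )
    trials: list[TrialRecord] = []
    participants_truth = []
    for p in range(config.n_participants):
        rng = np.random.default_rng(streams[p])
        participant_id = f"P{p + 1:02d}"
        model = _draw_participant(config, participant_id, rng)
        if config.participant_effect_maps is not None:
            effect = config.participant_effect_maps[p]
        else:
            effect = config.effect_map.perturbed(rng, config.participant_heterogeneity_sd)
        for configuration in Configuration:
            bank = make_stimulus_bank(configuration)
            for spec in bank:
                n_reps = config.n_sham_trials if spec.is_sham else 1
                for rep in range(n_reps):
                    trials.append(
                        simulate_trial(
                            model,
                            spec,
                            effect,
                            config.timeline,
                            rng,
                            target=target,
                            perturbation=perturbation,
                            trial_index=rep,
                        )
                    )
        opt_label, opt_cfg = planted_optimum(effect)
        participants_truth.append(
            {
                "participant_id": participant_id,
                "gain": model.gain,
                "lag": model.lag,
                "base_noise_sd": model.base_noise_sd,
                "multipliers": {
                    f"{label}|{cfg.value}": m
                    for (label, cfg), m in sorted(
                        effect.multipliers.items(),
                        key=lambda kv: bank_order_key(kv[0][0], kv[0][1]),
                    )
                },
                "planted_optimum": f"{opt_label}|{opt_cfg.value}",
            }
        )
    ground_truth = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_sham_trials": config.n_sham_trials,
        "participants": participants_truth,
    }
    return SimulatedCohort(trials=trials, ground_truth=ground_truth, config=config)


def planted_optimum(effect: EffectMap) -> EffectKey:
    """The non-sham (stimulus, montage) with the smallest planted multiplier.

    Ties broken by bank order then two-pole first, matching the
    individualised-selection tie-break so recovery scoring is exact.
    """
    candidates = [
        (m, bank_order_key(label, cfg), (label, cfg))
        for (label, cfg), m in effect.multipliers.items()
        if label != SHAM_LABEL
    ]
    if not candidates:
        raise ValueError("effect map has no non-sham entries")
    return min(candidates)[2]
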