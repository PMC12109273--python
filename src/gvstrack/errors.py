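"""Tracking-error time course and sub-trial means.

The tracking error of a trial is defined through regression residuals:
the deterministic Lissajous curves (target and cursor perturbation) and
their Hilbert quadratures are linearly regressed out of the cursor x
and y positions, per axis.  Including each curve together with its
quadrature spans every phase-shifted copy of that sinusoid, so the
residual is insensitive to the participant's (constant) visuomotor lag
and response gain.  The pointwise residual magnitude

    ErrR(i) = sqrt(ErrX(i)^2 + ErrY(i)^2)

is the error time course; it is segmented into consecutive sub-trials
of one quarter of the target's y-period (2.5 s for the 0.1 Hz default)
and averaged within each segment.  Sub-trial means are the unit of all
downstream comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .simulate import TrialRecord
from .trajectory import TARGET_FREQ_Y

__all__ = [
    "ResidualSeries",
    "SubTrialErrors",
    "hilbert_quadrature",
    "regress_out",
    "error_timecourse",
    "segment_subtrials",
    "TrialProcessor",
    "process_trial",
    "subtrial_long_table",
]

logger = logging.getLogger(__name__)

RegressorSet = Literal["target+perturbation", "target"]


@dataclass(frozen=True)
class ResidualSeries:
    """Per-axis regression residuals of one trial's cursor path."""

    err_x: np.ndarray
    err_y: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        err_x = np.asarray(self.err_x, dtype=float)
        err_y = np.asarray(self.err_y, dtype=float)
        if err_x.shape != err_y.shape:
            raise ValueError("err_x and err_y must have equal length")
        object.__setattr__(self, "err_x", err_x)
        object.__setattr__(self, "err_y", err_y)


@dataclass(frozen=True)
class SubTrialErrors:
    """Mean error per consecutive sub-trial segment of one trial."""

    means: np.ndarray
    segment_length_s: float
    n_subtrials: int

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if means.size != self.n_subtrials:
            raise ValueError("means length must equal n_subtrials")
        if np.any(means < 0):
            raise ValueError("sub-trial mean errors must be non-negative")
        object.__setattr__(self, "means", means)

    @property
    def mean(self) -> float:
        """Trial-level mean error (average of the sub-trial means)."""
        return float(self.means.mean())


def hilbert_quadrature(signal: Sequence[float]) -> np.ndarray:
    """Quadrature component (imaginary part of the analytic signal).

    Computed with the discrete analytic-signal construction over the full
    input, which maps cos -> sin exactly for frequencies on the DFT grid
    and up to small edge leakage otherwise.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("signal must be a 1-D sequence of length >= 4")
    return np.imag(scipy.signal.hilbert(x))


def _drop_collinear(design: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Drop linearly dependent columns right-to-left until full rank."""
    kept = list(range(design.shape[1]))
    x = design
    rank = np.linalg.matrix_rank(x)
    while rank < len(kept):
        for j in range(len(kept) - 1, 0, -1):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                logger.warning(
                    "design matrix is rank deficient; dropping collinear column %d",
                    kept[j],
                )
                x = reduced
                kept.pop(j)
                break
        else:  # pragma: no cover - defensive; intercept alone is full rank
            break
        rank = np.linalg.matrix_rank(x)
    return x, kept


def regress_out(
    cursor_axis: Sequence[float], regressors: Iterable[Sequence[float]]
) -> np.ndarray:
    """Ordinary-least-squares residuals of one cursor axis on its regressors.

    An intercept column is always included, so residuals are mean-free.
    Collinear regressor columns are dropped right-to-left with a logged
    warning rather than failing.
    """
    y = np.asarray(cursor_axis, dtype=float)
    columns = [np.ones_like(y)]
    for reg in regressors:
        reg = np.asarray(reg, dtype=float)
        if reg.shape != y.shape:
            raise ValueError("regressors must match the cursor axis length")
        columns.append(reg)
    design = np.column_stack(columns)
    design, _ = _drop_collinear(design)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def error_timecourse(res: ResidualSeries) -> np.ndarray:
    """Pointwise Euclidean magnitude of the x/y residuals."""
    return np.hypot(res.err_x, res.err_y)


def segment_subtrials(
    err_r: Sequence[float], sample_rate: float, target_y_freq: float = TARGET_FREQ_Y
) -> SubTrialErrors:
    """Average the error time course over quarter-period sub-trials.

    The segment length is one quarter of the target's y-axis period;
    consecutive non-overlapping segments start at sample 0 and a trailing
    partial segment is discarded.
    """
    if target_y_freq <= 0:
        raise ValueError("target_y_freq must be positive")
    err = np.asarray(err_r, dtype=float)
    segment_length_s = (1.0 / target_y_freq) / 4.0
    seg_samples = int(round(segment_length_s * sample_rate))
    if seg_samples < 1:
        raise ValueError("segment shorter than one sample")
    n_subtrials = err.size // seg_samples
    if n_subtrials < 1:
        raise ValueError(
            f"error time course ({err.size} samples) is shorter than one "
            f"{segment_length_s:g} s sub-trial ({seg_samples} samples)"
        )
    trimmed = err[: n_subtrials * seg_samples]
    means = trimmed.reshape(n_subtrials, seg_samples).mean(axis=1)
    return SubTrialErrors(means, segment_length_s, n_subtrials)


class TrialProcessor:
    """Cursor trials -> sub-trial mean errors, with design-matrix caching.

    The per-axis regression design depends only on the deterministic
    target/perturbation curves, which are shared across the trials of a
    cohort; the least-squares projector for each distinct design is
    computed once and reused.

    Parameters
    ----------
    regressor_set
        ``"target+perturbation"`` (default) regresses out both Lissajous
        curves and their quadratures; ``"target"`` is the narrower
        reading that removes only the target curve.
    target_y_freq
        Target y frequency (Hz) defining the sub-trial length.
    """

    def __init__(
        self,
        regressor_set: RegressorSet = "target+perturbation",
        target_y_freq: float = TARGET_FREQ_Y,
    ) -> None:
        if regressor_set not in ("target+perturbation", "target"):
            raise ValueError(f"unknown regressor set {regressor_set!r}")
        self.regressor_set = regressor_set
        self.target_y_freq = target_y_freq
        self._projectors: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    def _axis_projector(
        self, target_axis: np.ndarray, pert_axis: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        key = target_axis.tobytes() + pert_axis.tobytes() + self.regressor_set.encode()
        cached = self._projectors.get(key)
        if cached is not None:
            return cached
        columns = [np.ones_like(target_axis), target_axis, hilbert_quadrature(target_axis)]
        if self.regressor_set == "target+perturbation":
            columns += [pert_axis, hilbert_quadrature(pert_axis)]
        design = np.column_stack(columns)
        design, _ = _drop_collinear(design)
        pinv = np.linalg.pinv(design)
        self._projectors[key] = (design, pinv)
        return design, pinv

    def residuals(self, trial: TrialRecord) -> ResidualSeries:
        out = []
        for axis in ("x", "y"):
            cursor = getattr(trial.cursor, axis)
            design, pinv = self._axis_projector(
                getattr(trial.target, axis), getattr(trial.perturbation, axis)
            )
            out.append(cursor - design @ (pinv @ cursor))
        return ResidualSeries(out[0], out[1], trial.cursor.sample_rate)

    def subtrial_errors(self, trial: TrialRecord) -> SubTrialErrors:
        err_r = error_timecourse(self.residuals(trial))
        return segment_subtrials(err_r, trial.cursor.sample_rate, self.target_y_freq)


def process_trial(
    trial: TrialRecord,
    regressor_set: RegressorSet = "target+perturbation",
    target_y_freq: float = TARGET_FREQ_Y,
) -> SubTrialErrors:
    """One-shot convenience wrapper around :class:`TrialProcessor`."""
    return TrialProcessor(regressor_set, target_y_freq).subtrial_errors(trial)


def subtrial_long_table(
    trials: Iterable[TrialRecord],
    regressor_set: RegressorSet = "target+perturbation",
    target_y_freq: float = TARGET_FREQ_Y,
) -> pd.DataFrame:
    """Long-format sub-trial table for a collection of trials.

    Columns: participant_id, configuration, stimulus_label, trial_index,
    subtrial_index, mean_err — the substrate for the metrics table and
    the mixed-effects comparisons.
    """
    processor = TrialProcessor(regressor_set, target_y_freq)
    rows = []
    for trial in trials:
        sub = processor.subtrial_errors(trial)
        for j, value in enumerate(sub.means):
            rows.append(
                (
                    trial.participant_id,
                    trial.configuration.value,
                    trial.stimulus_label,
                    trial.trial_index,
                    j,
                    value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "configuration",
            "stimulus_label",
            "trial_index",
            "subtrial_index",
            "mean_err",
        ],
    )
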