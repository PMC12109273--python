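"""Condition-level comparison metrics.

Aggregates sub-trial errors into the crossover comparisons: the
montage difference ΔErr, the individualised (minimum-error) stimulus,
and the two percentage performance-improvement measures

    PI_GVS = 100 · (ErrR_SHAM − ErrR_GVS) / ErrR_GVS
    PI_Ind = 100 · (ErrR_GVS − ErrR_Ind) / ErrR_Ind

where condition errors entering the PI measures are, by default,
averaged across the two-pole and three-pole montages, while the
individualised error is the single-montage minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SubTrialErrors
from .stimuli import BANK_LABELS, SHAM_LABEL, Configuration, bank_order_key

__all__ = [
    "IndividualisedChoice",
    "build_metrics_table",
    "config_averaged_means",
    "delta_err",
    "delta_err_table",
    "select_individualised",
    "pi_over_sham",
    "pi_individualised",
    "improvement_table",
    "best_overall",
]

#: Columns of a metrics table: one row per (participant, stimulus, montage).
METRICS_COLUMNS = (
    "participant_id",
    "stimulus_label",
    "configuration",
    "mean_err",
    "subtrial_means",
)


@dataclass(frozen=True)
class IndividualisedChoice:
    """A participant's minimum-error (stimulus, montage) pair."""

    participant_id: str
    stimulus_label: str
    configuration: Configuration
    mean_err: float


def build_metrics_table(long_table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean errors from a long sub-trial table.

    Repeated trials of the same condition (the sham trials) are averaged
    sub-trial-wise first, so each (participant, stimulus, montage) holds
    one sub-trial mean vector and one overall mean.
    """
    required = {"participant_id", "configuration", "stimulus_label", "subtrial_index", "mean_err"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    pooled = (
        long_table.groupby(
            ["participant_id", "stimulus_label", "configuration", "subtrial_index"],
            sort=False,
        )["mean_err"]
        .mean()
        .reset_index()
    )
    rows = []
    for (pid, label, cfg), group in pooled.groupby(
        ["participant_id", "stimulus_label", "configuration"], sort=False
    ):
        means = group.sort_values("subtrial_index")["mean_err"].to_numpy()
        rows.append((pid, label, cfg, float(means.mean()), means))
    rows.sort(key=lambda r: (r[0], bank_order_key(r[1], r[2])))
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))


def config_averaged_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, stimulus) mean error averaged across montages."""
    return (
        table.groupby(["participant_id", "stimulus_label"], sort=False)["mean_err"]
        .mean()
        .reset_index()
    )


def delta_err(two_pole: SubTrialErrors, three_pole: SubTrialErrors) -> float:
    """Mean over paired sub-trials of (two-pole − three-pole) error.

    Negative values mean lower error (better tracking) with the two-pole
    montage.
    """
    if two_pole.n_subtrials != three_pole.n_subtrials:
        raise ValueError(
            f"sub-trial counts differ: {two_pole.n_subtrials} vs {three_pole.n_subtrials}"
        )
    return float(np.mean(two_pole.means - three_pole.means))


def delta_err_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, stimulus) montage difference of sub-trial errors."""
    rows = []
    for (pid, label), group in table.groupby(
        ["participant_id", "stimulus_label"], sort=False
    ):
        by_cfg = {cfg: grp for cfg, grp in group.groupby("configuration")}
        if len(by_cfg) != 2:
            continue
        two = np.asarray(by_cfg[Configuration.TWO_POLE.value]["subtrial_means"].iloc[0])
        three = np.asarray(by_cfg[Configuration.THREE_POLE.value]["subtrial_means"].iloc[0])
        diff = two - three
        rows.append(
            (pid, label, float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(diff.size)))
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "stimulus_label", "delta_err", "se"]
    )


def select_individualised(table: pd.DataFrame, participant_id: str) -> IndividualisedChoice:
    """The participant's least-error non-sham (stimulus, montage) pair.

    Exact ties are broken by bank order (GVS1..GVS8) then two-pole first.
    """
    rows = table[
        (table["participant_id"] == participant_id)
        & (table["stimulus_label"] != SHAM_LABEL)
    ]
    if rows.empty:
        raise KeyError(f"no non-sham rows for participant {participant_id!r}")
    best = min(
        rows.itertuples(index=False),
        key=lambda r: (r.mean_err, bank_order_key(r.stimulus_label, r.configuration)),
    )
    return IndividualisedChoice(
        participant_id=participant_id,
        stimulus_label=best.stimulus_label,
        configuration=Configuration(best.configuration),
        mean_err=float(best.mean_err),
    )


def pi_over_sham(err_sham: float, err_gvs: float) -> float:
    """Percentage improvement of a stimulus over sham."""
    if err_gvs <= 0:
        raise ValueError(f"err_gvs must be positive, got {err_gvs}")
    return 100.0 * (err_sham - err_gvs) / err_gvs


def pi_individualised(err_gvs: float, err_ind: float) -> float:
    """Percentage improvement of the individualised stimulus over another."""
    if err_ind <= 0:
        raise ValueError(f"err_ind must be positive, got {err_ind}")
    return 100.0 * (err_gvs - err_ind) / err_ind


def improvement_table(
    table: pd.DataFrame, individualised_config_average: bool = False
) -> pd.DataFrame:
    """Per-stimulus improvement report (one row per bank stimulus plus sham).

    For each stimulus, ``pi_over_sham_pct`` compares its
    montage-averaged error with the montage-averaged sham error, and
    ``pi_individualised_pct`` compares it with the participant's
    individualised error; both are averaged across participants.  By
    default the individualised error is the single-montage minimum;
    ``individualised_config_average`` instead averages the chosen
    stimulus across both montages.
    """
    averaged = config_averaged_means(table)
    by_participant = {
        pid: grp.set_index("stimulus_label")["mean_err"]
        for pid, grp in averaged.groupby("participant_id", sort=False)
    }
    ind_err = {}
    for pid in by_participant:
        choice = select_individualised(table, pid)
        if individualised_config_average:
            ind_err[pid] = float(by_participant[pid][choice.stimulus_label])
        else:
            ind_err[pid] = choice.mean_err
    rows = []
    for label in BANK_LABELS + (SHAM_LABEL,):
        over_sham, with_ind = [], []
        for pid, errs in by_participant.items():
            if label not in errs.index or SHAM_LABEL not in errs.index:
                continue
            over_sham.append(pi_over_sham(errs[SHAM_LABEL], errs[label]))
            with_ind.append(pi_individualised(errs[label], ind_err[pid]))
        if over_sham:
            rows.append(
                (label, float(np.mean(with_ind)), float(np.mean(over_sham)))
            )
    return pd.DataFrame(
        rows,
        columns=["stimulus_label", "pi_individualised_pct", "pi_over_sham_pct"],
    )


def best_overall(improvements: pd.DataFrame) -> str:
    """The non-sham stimulus with the largest improvement over sham."""
    active = improvements[improvements["stimulus_label"] != SHAM_LABEL]
    if active.empty:
        raise ValueError("improvement table has no non-sham rows")
    return str(active.loc[active["pi_over_sham_pct"].idxmax(), "stimulus_label"])
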