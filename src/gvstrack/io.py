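"""Trial-table I/O, run configuration, and the end-to-end pipeline.

Trial data travel as one long-format CSV (one row per time sample) with
the columns

    participant, configuration, stimulus, t,
    target_x, target_y, pert_x, pert_y, cursor_x, cursor_y

plus an optional ``trial`` column distinguishing repeated trials of the
same condition (the sham repeats).  Floats are serialised with 17
significant digits so numeric content round-trips bit-exactly.  A run
is described by a YAML config holding either a simulation block or an
input path, and every output file carries the run-manifest hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import RegressorSet, subtrial_long_table
from .metrics import (
    best_overall,
    build_metrics_table,
    config_averaged_means,
    delta_err_table,
    improvement_table,
    select_individualised,
)
from .simulate import SimConfig, SimulatedCohort, TrialRecord, simulate_cohort
from .stimuli import BANK_LABELS, SHAM_LABEL, Configuration
from .stats import TestResult, bh_fdr, lme_config_contrast, wilcoxon_paired
from .trajectory import TARGET_FREQ_Y, Trajectory, TrialTimeline

__all__ = [
    "ParseError",
    "ConfigError",
    "RunConfig",
    "ReportBundle",
    "read_trials",
    "write_trials",
    "run_pipeline",
    "write_bundle",
]

REQUIRED_COLUMNS = (
    "participant",
    "configuration",
    "stimulus",
    "t",
    "target_x",
    "target_y",
    "pert_x",
    "pert_y",
    "cursor_x",
    "cursor_y",
)

FLOAT_FORMAT = "%.17g"
TIME_TOLERANCE_S = 1e-6


class ParseError(ValueError):
    """A trial table violated the documented CSV contract."""


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


def write_trials(trials: list[TrialRecord], path: str | Path, manifest_hash: str | None = None) -> None:
    """Write trials as the documented long-format CSV (plus ``trial``)."""
    frames = []
    for trial in trials:
        n = trial.target.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "participant": trial.participant_id,
                    "configuration": trial.configuration.value,
                    "stimulus": trial.stimulus_label,
                    "trial": trial.trial_index,
                    "t": trial.target.time,
                    "target_x": trial.target.x,
                    "target_y": trial.target.y,
                    "pert_x": trial.perturbation.x,
                    "pert_y": trial.perturbation.y,
                    "cursor_x": trial.cursor.x,
                    "cursor_y": trial.cursor.y,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    _write_csv(table, path, manifest_hash)


def _write_csv(df: pd.DataFrame, path: str | Path, manifest_hash: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if manifest_hash is not None:
            fh.write(f"# manifest={manifest_hash}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a long-format trial CSV back into TrialRecords.

    Groups rows by (participant, configuration, stimulus, trial); infers
    the sample rate from the time column and validates that it is
    constant within each trial to 1e-6 s.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column {missing[0]!r} in {path}")
    if "trial" not in df.columns:
        df["trial"] = 0
    trials = []
    for (pid, cfg, stim, rep), group in df.groupby(
        ["participant", "configuration", "stimulus", "trial"], sort=False
    ):
        t = group["t"].to_numpy(dtype=float)
        if t.size < 2:
            raise ParseError(
                f"trial ({pid}, {cfg}, {stim}, {rep}) has fewer than 2 samples"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(group.index[np.argmax(dt <= 0) + 1])
            raise ParseError(
                f"non-monotone time at row {row} of trial ({pid}, {cfg}, {stim}, {rep})"
            )
        if np.max(np.abs(dt - dt[0])) > TIME_TOLERANCE_S:
            raise ParseError(
                f"non-constant sampling interval in trial ({pid}, {cfg}, {stim}, {rep})"
            )
        fs = 1.0 / float(dt[0])
        trials.append(
            TrialRecord(
                participant_id=str(pid),
                configuration=Configuration(cfg),
                stimulus_label=str(stim),
                target=Trajectory(group["target_x"].to_numpy(), group["target_y"].to_numpy(), fs),
                perturbation=Trajectory(group["pert_x"].to_numpy(), group["pert_y"].to_numpy(), fs),
                cursor=Trajectory(group["cursor_x"].to_numpy(), group["cursor_y"].to_numpy(), fs),
                trial_index=int(rep),
            )
        )
    lengths = {
        (tr.participant_id, tr.configuration.value, tr.stimulus_label): tr.target.n_samples
        for tr in trials
    }
    if len(set(lengths.values())) > 1:
        raise ParseError(
            f"ragged trial groups: sample counts differ across trials ({sorted(set(lengths.values()))})"
        )
    return trials


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one data source.

    Either ``simulation`` (a :class:`SimConfig`) or ``input_path`` must
    be set.  ``regressor_set`` switches the error pipeline between the
    full target+perturbation design and the target-only reading.
    """

    seed: int = 0
    output_dir: str = "gvstrack_out"
    simulation: SimConfig | None = None
    input_path: str | None = None
    regressor_set: RegressorSet = "target+perturbation"
    target_y_freq: float = TARGET_FREQ_Y
    bootstrap_resamples: int = 1000

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ConfigError(
                "exactly one of 'simulation' and 'input_path' must be set"
            )
        if self.regressor_set not in ("target+perturbation", "target"):
            raise ConfigError(f"unknown regressor_set {self.regressor_set!r}")
        if self.bootstrap_resamples < 1:
            raise ConfigError("bootstrap_resamples must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        known = {
            "seed", "output_dir", "simulation", "input_path",
            "regressor_set", "target_y_freq", "bootstrap_resamples",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.get("simulation")
        if sim is not None:
            if not isinstance(sim, dict):
                raise ConfigError("'simulation' must be a mapping")
            sim = dict(sim)
            timeline = sim.pop("timeline", None)
            try:
                if timeline is not None:
                    sim["timeline"] = TrialTimeline(**timeline)
                sim.setdefault("seed", raw.get("seed", 0))
                sim = SimConfig(**sim)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid simulation block: {exc}") from exc
        kwargs = {k: v for k, v in raw.items() if k in known and k != "simulation"}
        return cls(simulation=sim, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "input_path": self.input_path,
            "regressor_set": self.regressor_set,
            "target_y_freq": self.target_y_freq,
            "bootstrap_resamples": self.bootstrap_resamples,
        }
        if self.simulation is not None:
            sim = asdict(self.simulation)
            sim["timeline"] = asdict(self.simulation.timeline)
            sim["effect_map"] = {
                f"{label}|{cfg.value}": m
                for (label, cfg), m in sorted(self.simulation.effect_map.multipliers.items())
            }
            if self.simulation.participant_effect_maps is not None:
                sim["participant_effect_maps"] = [
                    {f"{label}|{cfg.value}": m for (label, cfg), m in sorted(em.multipliers.items())}
                    for em in self.simulation.participant_effect_maps
                ]
            out["simulation"] = sim
        return out


def _manifest(config: RunConfig) -> dict[str, Any]:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "gvstrack_version": __version__,
    }


# -- the pipeline ----------------------------------------------------------


@dataclass
class ReportBundle:
    """All tables one run produces, plus its reproducibility manifest."""

    subtrial_table: pd.DataFrame
    metrics_table: pd.DataFrame
    config_averaged: pd.DataFrame
    delta_table: pd.DataFrame
    choices: pd.DataFrame
    improvement: pd.DataFrame
    stats_results: pd.DataFrame
    manifest: dict
    ground_truth: dict | None = None

    @property
    def best_overall_stimulus(self) -> str:
        return best_overall(self.improvement)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return decorate


def _stats_table(long_table: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Overall and per-stimulus montage contrasts plus sham-vs-individualised."""
    results: list[tuple[str, str, TestResult]] = []
    overall = lme_config_contrast(long_table)
    results.append(("lme_config_contrast", "all", overall))
    per_stim: list[tuple[str, TestResult]] = []
    for label in BANK_LABELS:
        if label in set(long_table["stimulus_label"]):
            per_stim.append((label, lme_config_contrast(long_table, stimulus=label)))
    if per_stim:
        adjusted = bh_fdr([r.p_value for _, r in per_stim])
        per_stim = [(lab, r.adjusted(float(q))) for (lab, r), q in zip(per_stim, adjusted)]
        results.extend(("lme_config_contrast", lab, r) for lab, r in per_stim)
    averaged = config_averaged_means(metrics)
    sham, ind = [], []
    for pid, errs in averaged.groupby("participant_id", sort=False):
        errs = errs.set_index("stimulus_label")["mean_err"]
        if SHAM_LABEL in errs.index:
            sham.append(float(errs[SHAM_LABEL]))
            ind.append(select_individualised(metrics, pid).mean_err)
    if len(sham) >= 5:
        results.append(
            ("wilcoxon_sham_vs_individualised", "all", wilcoxon_paired(sham, ind))
        )
    return pd.DataFrame(
        [
            (test, scope, r.estimate, r.p_value, r.p_adjusted, r.test_name)
            for test, scope, r in results
        ],
        columns=["test", "scope", "estimate", "p_value", "p_adjusted", "test_name"],
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis: data -> sub-trial errors -> metrics -> stats.

    With a simulation block the cohort is generated from the config seed;
    with an input path the trial CSV is read instead.  Output is a
    :class:`ReportBundle`; :func:`write_bundle` serialises it.
    """
    ground_truth = None
    if config.simulation is not None:
        cohort = _stage("simulate")(simulate_cohort)(config.simulation)
        trials, ground_truth = cohort.trials, cohort.ground_truth
    else:
        trials = _stage("read_trials")(read_trials)(config.input_path)

    long_table = _stage("error_pipeline")(subtrial_long_table)(
        trials, config.regressor_set, config.target_y_freq
    )
    metrics = _stage("metrics_table")(build_metrics_table)(long_table)
    averaged = _stage("config_average")(config_averaged_means)(metrics)
    delta = _stage("delta_err")(delta_err_table)(metrics)
    non_sham = metrics[metrics["stimulus_label"] != SHAM_LABEL]
    has_sham = SHAM_LABEL in set(metrics["stimulus_label"])
    choice_cols = ["participant_id", "stimulus_label", "configuration", "mean_err"]
    if non_sham.empty:
        choices = pd.DataFrame(columns=choice_cols)
    else:
        select = _stage("individualised_selection")(select_individualised)
        choices = pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "stimulus_label": c.stimulus_label,
                    "configuration": c.configuration.value,
                    "mean_err": c.mean_err,
                }
                for pid in metrics["participant_id"].unique()
                for c in [select(metrics, pid)]
            ],
            columns=choice_cols,
        )
    if has_sham and not non_sham.empty:
        improvement = _stage("improvement_report")(improvement_table)(metrics)
    else:
        # sham-only (or gvs-only) inputs still yield a well-formed report
        rows = [
            (label, float("nan"), 0.0 if label == SHAM_LABEL else float("nan"))
            for label in metrics["stimulus_label"].unique()
        ]
        improvement = pd.DataFrame(
            rows, columns=["stimulus_label", "pi_individualised_pct", "pi_over_sham_pct"]
        )
    both_configs = set(long_table["configuration"]) == {c.value for c in Configuration}
    if both_configs and long_table["participant_id"].nunique() >= 2 and not non_sham.empty:
        stats_results = _stage("stats")(_stats_table)(long_table, metrics)
    else:
        stats_results = pd.DataFrame(
            columns=["test", "scope", "estimate", "p_value", "p_adjusted", "test_name"]
        )
    return ReportBundle(
        subtrial_table=long_table,
        metrics_table=metrics,
        config_averaged=averaged,
        delta_table=delta,
        choices=choices,
        improvement=improvement,
        stats_results=stats_results,
        manifest=_manifest(config),
        ground_truth=ground_truth,
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Serialise a report bundle: CSV tables plus JSON sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle.manifest["config_sha256"]
    _write_csv(bundle.subtrial_table, outdir / "subtrial_errors.csv", h)
    metrics = bundle.metrics_table.drop(columns=["subtrial_means"])
    _write_csv(metrics, outdir / "metrics.csv", h)
    _write_csv(bundle.config_averaged, outdir / "metrics_config_averaged.csv", h)
    _write_csv(bundle.delta_table, outdir / "delta_err.csv", h)
    _write_csv(bundle.choices, outdir / "individualised_choices.csv", h)
    _write_csv(bundle.improvement, outdir / "improvement_report.csv", h)
    _write_csv(bundle.stats_results, outdir / "stats_results.csv", h)
    with open(outdir / "improvement_report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "manifest": bundle.manifest,
                "best_overall_stimulus": bundle.best_overall_stimulus
                if (bundle.improvement["stimulus_label"] != SHAM_LABEL).any()
                else None,
                "rows": bundle.improvement.to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    with open(outdir / "stats_results.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "manifest": bundle.manifest,
                "rows": bundle.stats_results.where(
                    bundle.stats_results.notna(), None
                ).to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2)
    if bundle.ground_truth is not None:
        with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump({"manifest": bundle.manifest, **bundle.ground_truth}, fh, indent=2)
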