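"""Statistical comparisons on sub-trial error tables.

Sub-trial means from the same trial are not independent, so the
two-pole vs three-pole comparison uses a linear mixed-effects model
with random intercepts for participant and for sub-trial index
(crossed), estimated by REML; the fixed montage effect is tested with
the large-sample normal approximation.  The sham vs individualised
comparison is a paired Wilcoxon signed-rank test (exact null
distribution for small samples), and families of p-values are adjusted
with the Benjamini–Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .stimuli import Configuration

__all__ = [
    "TestResult",
    "lme_config_contrast",
    "wilcoxon_paired",
    "bh_fdr",
    "median_se_bootstrap",
]

logger = logging.getLogger(__name__)

#: Exact signed-rank null distribution is used up to this sample size.
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: effect estimate, p, and optional adjusted p."""

    estimate: float
    p_value: float
    test_name: str
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value out of range: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")

    def adjusted(self, p_adjusted: float) -> "TestResult":
        return TestResult(self.estimate, self.p_value, self.test_name, p_adjusted)


def _prepare_lme_frame(table: pd.DataFrame, stimulus: str | None) -> pd.DataFrame:
    required = {"participant_id", "configuration", "stimulus_label", "subtrial_index", "mean_err"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long error table is missing columns: {sorted(missing)}")
    df = table if stimulus is None else table[table["stimulus_label"] == stimulus]
    df = df.copy()
    present = set(df["configuration"])
    expected = {c.value for c in Configuration}
    if present != expected:
        raise ValueError(
            f"both montages must be present in scope, got {sorted(present)}"
        )
    df["config_three_pole"] = (
        df["configuration"] == Configuration.THREE_POLE.value
    ).astype(float)
    df["_group"] = 1
    return df


def lme_config_contrast(table: pd.DataFrame, stimulus: str | None = None) -> TestResult:
    """Mixed-effects contrast of the three-pole vs two-pole montage.

    ``stimulus=None`` uses every stimulus in the table (the overall
    montage comparison); a stimulus label restricts the scope to that
    stimulus.  A positive estimate means larger error in the three-pole
    montage (two-pole is the baseline).  The participant random
    intercept is dropped automatically when the scope contains a single
    participant, where only sub-trials repeat.  If the crossed-effects
    fit fails to converge, the model falls back to a subject-only
    random intercept with a logged warning.
    """
    df = _prepare_lme_frame(table, stimulus)
    n_participants = df["participant_id"].nunique()
    if stimulus is None and n_participants < 2:
        raise ValueError("the all-stimuli contrast needs at least 2 participants")

    vc = {"subtrial": "0 + C(subtrial_index)"}
    if n_participants > 1:
        vc["participant"] = "0 + C(participant_id)"
    name = f"lme_config_contrast[{stimulus or 'all'}]"
    try:
        with warnings.catch_warnings():
            # boundary estimates (a variance component at 0) are legitimate
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.filterwarnings(
                "ignore", message="Random effects covariance is singular"
            )
            model = smf.mixedlm(
                "mean_err ~ config_three_pole",
                df,
                groups="_group",
                re_formula="0",
                vc_formula=vc,
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
        if not np.isfinite(fit.bse["config_three_pole"]) or not np.isfinite(
            fit.params["config_three_pole"]
        ):
            raise np.linalg.LinAlgError("non-finite fixed-effect estimate")
    except (np.linalg.LinAlgError, ValueError) as exc:
        if n_participants < 2:
            raise
        logger.warning(
            "crossed random-effects fit failed (%s); falling back to a "
            "subject-only random intercept",
            exc,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = smf.mixedlm("mean_err ~ config_three_pole", df, groups="participant_id")
            fit = model.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
        name += "+subject_only_fallback"
    estimate = float(fit.params["config_three_pole"])
    p = float(fit.pvalues["config_three_pole"])
    return TestResult(estimate=estimate, p_value=min(max(p, 0.0), 1.0), test_name=name)


def wilcoxon_paired(
    sham_means: Sequence[float], ind_means: Sequence[float]
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test, sham vs individualised.

    Pairs are matched by participant; zero differences are dropped; the
    exact null distribution is used for n <= 25 pairs and the normal
    approximation with continuity correction above.  The estimate is the
    median paired reduction (sham − individualised; positive means the
    individualised stimulus lowered error).
    """
    sham = np.asarray(sham_means, dtype=float)
    ind = np.asarray(ind_means, dtype=float)
    if sham.shape != ind.shape or sham.ndim != 1:
        raise ValueError("inputs must be 1-D and paired by participant")
    if sham.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = sham - ind
    estimate = float(np.median(diffs))
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p set to 1", UserWarning)
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank")
    nonzero = diffs[diffs != 0]
    method = "exact" if nonzero.size <= WILCOXON_EXACT_MAX_N else "approx"
    try:
        res = scipy.stats.wilcoxon(
            sham, ind, zero_method="wilcox", alternative="two-sided",
            correction=(method == "approx"), method=method,
        )
    except ValueError:
        # exact method rejects tied ranks; the approximation handles them
        res = scipy.stats.wilcoxon(
            sham, ind, zero_method="wilcox", alternative="two-sided",
            correction=True, method="approx",
        )
    return TestResult(estimate, float(res.pvalue), "wilcoxon_signed_rank")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_se_bootstrap(
    values: Sequence[float], n_resamples: int = 1000, seed: int = 0
) -> float:
    """Bootstrap standard error of the median (seeded, 1000 resamples)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    medians = np.median(x[idx], axis=1)
    return float(medians.std(ddof=1))
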