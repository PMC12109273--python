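"""Crossover metrics: ΔErr, individualised selection, improvement percentages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gvstrack.errors import SubTrialErrors
from gvstrack.metrics import (
    best_overall,
    build_metrics_table,
    config_averaged_means,
    delta_err,
    delta_err_table,
    improvement_table,
    pi_individualised,
    pi_over_sham,
    select_individualised,
)
from gvstrack.stimuli import BANK_LABELS, SHAM_LABEL, Configuration


def _sub(means):
    means = np.asarray(means, dtype=float)
    return SubTrialErrors(means, 2.5, means.size)


def _table(rows):
    """rows: (participant, stimulus, configuration, mean_err)"""
    return pd.DataFrame(
        [
            (pid, stim, cfg, err, np.full(18, err))
            for pid, stim, cfg, err in rows
        ],
        columns=["participant_id", "stimulus_label", "configuration", "mean_err", "subtrial_means"],
    )


class TestDeltaErr:
    def test_constant_difference(self):
        assert delta_err(_sub(np.ones(18)), _sub(np.full(18, 1.5))) == pytest.approx(-0.5)

    def test_identical_inputs_give_zero(self):
        assert delta_err(_sub([1.0, 2.0]), _sub([1.0, 2.0])) == 0.0

    def test_paired_arithmetic(self):
        assert delta_err(_sub([1.0, 3.0]), _sub([2.0, 2.0])) == pytest.approx(0.0)

    def test_mismatched_subtrial_counts_rejected(self):
        with pytest.raises(ValueError):
            delta_err(_sub([1.0, 2.0]), _sub([1.0, 2.0, 3.0]))

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=18))
    def test_antisymmetry(self, values):
        a = _sub(values)
        b = _sub(list(reversed(values)))
        assert delta_err(a, b) == pytest.approx(-delta_err(b, a))


class TestSelectIndividualised:
    def test_returns_the_planted_minimum(self):
        rows = [("P01", lab, cfg.value, 1.0) for lab in BANK_LABELS for cfg in Configuration]
        rows = [r if not (r[1] == "GVS3" and r[2] == "two_pole") else (r[0], r[1], r[2], 0.4) for r in rows]
        choice = select_individualised(_table(rows), "P01")
        assert (choice.stimulus_label, choice.configuration) == ("GVS3", Configuration.TWO_POLE)

    def test_exact_tie_breaks_by_bank_order_then_two_pole(self):
        rows = [
            ("P01", "GVS2", "three_pole", 0.5),
            ("P01", "GVS1", "two_pole", 0.5),
            ("P01", "GVS1", "three_pole", 0.5),
            ("P01", SHAM_LABEL, "two_pole", 0.1),  # sham excluded even if smaller
        ]
        choice = select_individualised(_table(rows), "P01")
        assert (choice.stimulus_label, choice.configuration) == ("GVS1", Configuration.TWO_POLE)

    def test_montage_split_of_choices_matches_planted_structure(self):
        # 7 of 10 planted minima in the three-pole montage
        rows = []
        for p in range(10):
            pid = f"P{p + 1:02d}"
            cfg_min = "three_pole" if p < 7 else "two_pole"
            for lab in BANK_LABELS:
                for cfg in ("two_pole", "three_pole"):
                    err = 0.3 if (lab == "GVS5" and cfg == cfg_min) else 1.0
                    rows.append((pid, lab, cfg, err))
        table = _table(rows)
        chosen = [select_individualised(table, f"P{p + 1:02d}").configuration for p in range(10)]
        assert sum(c == Configuration.THREE_POLE for c in chosen) == 7

    def test_unknown_participant_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            select_individualised(_table([("P01", "GVS1", "two_pole", 1.0)]), "P99")


class TestImprovementPercentages:
    @pytest.mark.parametrize(
        "sham,gvs,expected", [(1.25, 1.0, 25.0), (1.0, 1.0, 0.0), (1.0, 2.0, -50.0)]
    )
    def test_pi_over_sham(self, sham, gvs, expected):
        assert pi_over_sham(sham, gvs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "gvs,ind,expected", [(1.24, 1.0, 24.0), (0.7, 0.7, 0.0)]
    )
    def test_pi_individualised(self, gvs, ind, expected):
        assert pi_individualised(gvs, ind) == pytest.approx(expected)

    def test_non_positive_denominators_rejected(self):
        with pytest.raises(ValueError):
            pi_over_sham(1.0, 0.0)
        with pytest.raises(ValueError):
            pi_individualised(1.0, -0.5)

    @given(st.floats(0.05, 5.0), st.floats(0.05, 5.0), st.floats(0.05, 5.0))
    def test_pi_individualised_strictly_decreasing_in_denominator(self, gvs, a, b):
        lo, hi = sorted((a, b))
        if lo < hi:
            assert pi_individualised(gvs, lo) > pi_individualised(gvs, hi)


class TestTables:
    def test_build_metrics_table_averages_repeated_sham_trials(self):
        long = pd.DataFrame(
            {
                "participant_id": ["P01"] * 4,
                "configuration": ["two_pole"] * 4,
                "stimulus_label": [SHAM_LABEL] * 4,
                "trial_index": [0, 0, 1, 1],
                "subtrial_index": [0, 1, 0, 1],
                "mean_err": [1.0, 2.0, 3.0, 4.0],
            }
        )
        table = build_metrics_table(long)
        assert len(table) == 1
        np.testing.assert_allclose(table["subtrial_means"].iloc[0], [2.0, 3.0])
        assert table["mean_err"].iloc[0] == pytest.approx(2.5)

    def test_config_averaged_means(self):
        table = _table(
            [("P01", "GVS1", "two_pole", 1.0), ("P01", "GVS1", "three_pole", 3.0)]
        )
        avg = config_averaged_means(table)
        assert avg["mean_err"].iloc[0] == pytest.approx(2.0)

    def test_delta_err_table_sign_convention(self):
        table = _table(
            [("P01", "GVS1", "two_pole", 1.0), ("P01", "GVS1", "three_pole", 1.5)]
        )
        delta = delta_err_table(table)
        assert delta["delta_err"].iloc[0] == pytest.approx(-0.5)  # two-pole better

    def test_improvement_table_structure_and_sham_row(self):
        rows = []
        for lab in BANK_LABELS + (SHAM_LABEL,):
            for cfg in ("two_pole", "three_pole"):
                err = 0.8 if lab == "GVS8" else 1.0
                rows.append(("P01", lab, cfg, err))
                rows.append(("P02", lab, cfg, err * 1.1))
        table = _table(rows)
        imp = improvement_table(table)
        assert list(imp["stimulus_label"]) == list(BANK_LABELS) + [SHAM_LABEL]
        sham_row = imp[imp["stimulus_label"] == SHAM_LABEL].iloc[0]
        assert sham_row["pi_over_sham_pct"] == pytest.approx(0.0)
        assert best_overall(imp) == "GVS8"
        gvs8 = imp[imp["stimulus_label"] == "GVS8"].iloc[0]
        assert gvs8["pi_over_sham_pct"] == pytest.approx(25.0)
        assert gvs8["pi_individualised_pct"] == pytest.approx(0.0)
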