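"""Hilbert quadrature, residualisation, error time course, sub-trials."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gvstrack.errors import (
    ResidualSeries,
    TrialProcessor,
    error_timecourse,
    hilbert_quadrature,
    process_trial,
    regress_out,
    segment_subtrials,
    subtrial_long_table,
)
from gvstrack.simulate import EffectMap, ParticipantModel, simulate_trial
from gvstrack.stimuli import Configuration, make_stimulus_bank
from gvstrack.trajectory import Trajectory, TrialTimeline, make_target_trajectory


def _normal_equations_residuals(y, regressors):
    """Independent oracle: explicit (X'X)^-1 X'y with an intercept."""
    X = np.column_stack([np.ones_like(y)] + list(regressors))
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


class TestHilbertQuadrature:
    @pytest.mark.parametrize("freq,n_periods", [(2.0, 8), (5.0, 25)])
    def test_cosine_maps_to_sine(self, freq, n_periods):
        fs = 60.0
        n = int(n_periods / freq * fs)
        t = np.arange(n) / fs
        quad = hilbert_quadrature(np.cos(2 * np.pi * freq * t))
        expected = np.sin(2 * np.pi * freq * t)
        assert np.max(np.abs(quad[2:-2] - expected[2:-2])) <= 1e-6

    def test_zero_and_constant_inputs_have_no_quadrature(self):
        assert np.all(hilbert_quadrature(np.zeros(64)) == 0)
        np.testing.assert_allclose(hilbert_quadrature(np.full(64, 3.7)), 0.0, atol=1e-12)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            hilbert_quadrature(np.ones(3))


class TestRegressOut:
    def test_exact_linear_combination_leaves_zero_residuals(self, timeline):
        target = make_target_trajectory(timeline)
        lx, hx = target.x, hilbert_quadrature(target.x)
        cursor = 2.0 * lx + 3.0 * hx + 5.0
        res = regress_out(cursor, [lx, hx])
        assert np.max(np.abs(res)) <= 1e-8 * np.max(np.abs(cursor))

    def test_matches_normal_equations_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(100, 500))
            k = int(rng.integers(1, 6))
            regs = [rng.standard_normal(n) for _ in range(k)]
            y = rng.standard_normal(n)
            res = regress_out(y, regs)
            expected = _normal_equations_residuals(y, regs)
            assert np.max(np.abs(res - expected)) <= 1e-8 * max(1.0, np.abs(expected).max())

    def test_orthogonal_noise_passes_through(self, rng):
        n = 2700
        reg = np.sin(2 * np.pi * 0.1 * np.arange(n) / 60.0)
        noise = rng.standard_normal(n)
        res = regress_out(noise, [reg])
        corr = np.corrcoef(res, noise)[0, 1]
        assert corr >= 0.999

    def test_collinear_columns_are_dropped_not_fatal(self, rng, caplog):
        n = 200
        a = rng.standard_normal(n)
        y = rng.standard_normal(n)
        with caplog.at_level("WARNING"):
            res = regress_out(y, [a, 2.0 * a])
        assert "collinear" in caplog.text
        np.testing.assert_allclose(res, _normal_equations_residuals(y, [a]), atol=1e-10)

    def test_residuals_are_orthogonal_to_every_regressor(self, rng):
        n = 600
        regs = [rng.standard_normal(n) for _ in range(3)]
        res = regress_out(rng.standard_normal(n), regs)
        for reg in regs + [np.ones(n)]:
            inner = abs(np.dot(res, reg))
            assert inner <= 1e-6 * np.linalg.norm(res) * np.linalg.norm(reg)


class TestErrorTimecourse:
    def test_three_four_five(self):
        res = ResidualSeries(np.array([3.0, 0.0, 1.0]), np.array([4.0, 0.0, 1.0]), 60.0)
        np.testing.assert_allclose(error_timecourse(res), [5.0, 0.0, np.sqrt(2)])


class TestSegmentSubtrials:
    def test_default_trial_gives_18_subtrials_of_150_samples(self):
        sub = segment_subtrials(np.ones(2700), sample_rate=60.0, target_y_freq=0.1)
        assert sub.segment_length_s == pytest.approx(2.5)
        assert sub.n_subtrials == 18
        np.testing.assert_allclose(sub.means, 1.0)

    def test_trailing_partial_segment_is_discarded(self):
        sub = segment_subtrials(np.ones(2760), sample_rate=60.0, target_y_freq=0.1)
        assert sub.n_subtrials == 18

    def test_shorter_than_one_segment_rejected(self):
        with pytest.raises(ValueError):
            segment_subtrials(np.ones(100), sample_rate=60.0, target_y_freq=0.1)

    @given(st.floats(min_value=0.01, max_value=10.0))
    def test_constant_error_gives_constant_means(self, c):
        sub = segment_subtrials(np.full(2700, c), 60.0, 0.1)
        np.testing.assert_allclose(sub.means, c)


class TestPipeline:
    def _trial(self, rng, timeline=None, **model_kwargs):
        timeline = timeline or TrialTimeline()
        model = ParticipantModel("P01", **model_kwargs)
        spec = make_stimulus_bank(Configuration.TWO_POLE)[0]
        return simulate_trial(model, spec, EffectMap.uniform(), timeline, rng)

    def test_scale_equivariance_of_subtrial_means(self, rng, timeline):
        trial = self._trial(rng, timeline, base_noise_sd=0.1, lag=0.2)
        k = 3.0
        scaled = type(trial)(
            participant_id=trial.participant_id,
            configuration=trial.configuration,
            stimulus_label=trial.stimulus_label,
            target=Trajectory(k * trial.target.x, k * trial.target.y, 60.0),
            perturbation=Trajectory(k * trial.perturbation.x, k * trial.perturbation.y, 60.0),
            cursor=Trajectory(k * trial.cursor.x, k * trial.cursor.y, 60.0),
        )
        np.testing.assert_allclose(
            process_trial(scaled).means, k * process_trial(trial).means, rtol=1e-9
        )

    def test_lag_is_suppressed_by_quadrature_regressors(self, rng, timeline):
        # a time shift is a phase shift, spanned by {curve, quadrature} up to
        # the spectral leakage of non-integer-period curves and the held edge
        trial = self._trial(rng, timeline, base_noise_sd=0.0, lag=0.2)
        with_quadrature = process_trial(trial).mean
        no_quadrature = np.mean(
            np.hypot(
                regress_out(trial.cursor.x, [trial.target.x, trial.perturbation.x]),
                regress_out(trial.cursor.y, [trial.target.y, trial.perturbation.y]),
            )
        )
        assert with_quadrature < 0.05  # vs unit target amplitude
        assert with_quadrature < 0.3 * no_quadrature

    def test_target_only_regressor_switch_leaves_perturbation_in_error(self, rng, timeline):
        trial = self._trial(rng, timeline, base_noise_sd=0.0, lag=0.0)
        full = process_trial(trial, regressor_set="target+perturbation")
        narrow = process_trial(trial, regressor_set="target")
        assert np.all(full.means <= 1e-8)
        assert narrow.mean > 0.01  # the perturbation Lissajous remains

    def test_long_table_shape_and_keys(self, small_cohort):
        table = subtrial_long_table(small_cohort.trials)
        assert len(table) == len(small_cohort.trials) * 18
        assert table["subtrial_index"].max() == 17
        keys = table[["participant_id", "configuration", "stimulus_label", "trial_index", "subtrial_index"]]
        assert not keys.duplicated().any()

    def test_processor_cache_matches_uncached_path(self, rng, timeline):
        trial = self._trial(rng, timeline, base_noise_sd=0.1)
        proc = TrialProcessor()
        a = proc.subtrial_errors(trial)
        b = proc.subtrial_errors(trial)  # cached projector second time
        res = proc.residuals(trial)
        manual_x = regress_out(
            trial.cursor.x,
            [
                trial.target.x,
                hilbert_quadrature(trial.target.x),
                trial.perturbation.x,
                hilbert_quadrature(trial.perturbation.x),
            ],
        )
        np.testing.assert_allclose(a.means, b.means)
        np.testing.assert_allclose(res.err_x, manual_x, atol=1e-10)
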