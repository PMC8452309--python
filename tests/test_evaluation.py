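import numpy as np
import pytest

from qcmfit.evaluation import (
    bootstrap_ci,
    glm_model,
    leave_runs_out_cv,
    leave_session_out_cv,
    predict_response_at_stimulus,
    qcm_model,
    residual_by_direction,
    robust_fit,
)
from qcmfit.qcm import (
    EllipseParams,
    NakaRushtonParams,
    QCMParams,
    equivalent_contrast,
    naka_rushton,
    qcm_crf,
    qcm_predict_bold,
)
from qcmfit.stimulus_design import ChromaticStimulus
from qcmfit.synthetic import DEFAULT_TRUTH


class TestLeaveRunsOutCV:
    def test_folds_partition_and_determinism(self, noiseless_data, hrf):
        models = {"glm": glm_model(hrf)}
        a = leave_runs_out_cv(models, noiseless_data, seed=5)
        b = leave_runs_out_cv(models, noiseless_data, seed=5)
        assert a.folds == b.folds
        held_1 = [f[0] for f in a.folds]
        held_2 = [f[1] for f in a.folds]
        n = len(noiseless_data[0])
        assert sorted(held_1) == sorted(held_2) == list(range(n))

    def test_noiseless_cv_r2_is_one(self, noiseless_data, hrf):
        models = {"qcm": qcm_model(hrf, seed=0), "glm": glm_model(hrf)}
        cv = leave_runs_out_cv(models, noiseless_data, seed=0)
        assert cv.mean_r2["qcm"] == pytest.approx(1.0, abs=1e-6)
        assert cv.mean_r2["glm"] == pytest.approx(1.0, abs=1e-6)

    def test_failing_model_recorded_and_skipped(self, noiseless_data, hrf):
        def broken(designs, series):
            raise RuntimeError("no convergence")

        with pytest.warns(UserWarning, match="failed on fold"):
            cv = leave_runs_out_cv(
                {"broken": broken, "glm": glm_model(hrf)},
                noiseless_data, seed=1,
            )
        assert np.isnan(cv.mean_r2["broken"])
        assert len(cv.per_fold_r2["glm"]) == len(noiseless_data[0])

    def test_unequal_sessions_rejected(self, noiseless_data, hrf):
        with pytest.raises(ValueError, match="equally many"):
            leave_runs_out_cv({}, (noiseless_data[0], noiseless_data[1][:1]))


class TestLeaveSessionOutCV:
    def test_predictions_match_generating_crfs(self, noiseless_data, hrf):
        out = leave_session_out_cv(noiseless_data, hrf, seed=0)
        for held_idx, preds in out["predicted"].items():
            for (direction, contrast), value in preds.items():
                expected = qcm_crf(DEFAULT_TRUTH, direction, [contrast])[0]
                assert value == pytest.approx(expected, abs=2e-3)

    def test_circular_truth_generalizes_perfectly(self, small_sessions, hrf):
        truth = QCMParams(
            ellipse=EllipseParams(0.0, 1.0),
            nr=NakaRushtonParams(2.0, 1.0, 1.5, 0.0),
        )
        data = tuple(
            [(run, qcm_predict_bold(run, truth, hrf)) for run in session.runs]
            for session in small_sessions
        )
        out = leave_session_out_cv(data, hrf, seed=0)
        for preds in out["predicted"].values():
            for (direction, contrast), value in preds.items():
                expected = qcm_crf(truth, direction, [contrast])[0]
                assert value == pytest.approx(expected, abs=2e-3)

    def test_shared_directions_rejected(self, noiseless_data):
        from qcmfit.hemodynamics import canonical_hrf

        with pytest.raises(ValueError, match="disjoint"):
            leave_session_out_cv(
                (noiseless_data[0], noiseless_data[0]), canonical_hrf(0.8)
            )


class TestBootstrapCI:
    @staticmethod
    def mean_stat(sessions):
        return float(np.mean([np.mean(r) for s in sessions for r in s]))

    def test_zero_noise_zero_width(self):
        runs = [[np.full(10, 1.5)] * 4, [np.full(10, 1.5)] * 4]
        ci = bootstrap_ci(self.mean_stat, runs, n_iter=50, seed=0)
        assert ci.width == 0.0
        assert ci.estimate == pytest.approx(1.5)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        runs = [[rng.normal(size=20) for _ in range(5)] for _ in range(2)]
        a = bootstrap_ci(self.mean_stat, runs, n_iter=100, seed=7)
        b = bootstrap_ci(self.mean_stat, runs, n_iter=100, seed=7)
        assert (a.low, a.high) == (b.low, b.high)

    def test_width_shrinks_with_run_count(self):
        rng = np.random.default_rng(1)
        widths = {}
        for n_runs in (5, 20):
            runs = [[rng.normal(size=10) for _ in range(n_runs)]
                    for _ in range(2)]
            widths[n_runs] = bootstrap_ci(
                self.mean_stat, runs, n_iter=200, seed=2
            ).width
        assert widths[20] < widths[5]

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_ci(self.mean_stat, [[np.zeros(5)]], n_iter=10)


class TestResidualByDirection:
    def test_perfect_model_zero_residuals(self, small_runs, noiseless_series, hrf):
        res = residual_by_direction(
            noiseless_series, noiseless_series, small_runs
        )
        assert set(res) == {-45.0, -22.5, 0.0, 22.5, 45.0, 67.5, 90.0, 112.5}
        for v in res.values():
            assert v == 0.0

    def test_constant_bias_appears_everywhere(self, small_runs, noiseless_series):
        res = residual_by_direction(
            noiseless_series, noiseless_series + 0.25, small_runs
        )
        for v in res.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_direction_specific_misfit_isolated(self, small_runs, noiseless_series, hrf):
        corrupted = noiseless_series.copy()
        offset = 0
        for run in small_runs:
            for b in run.stimulus_blocks:
                if b.stimulus.direction_deg == 90.0:
                    onset = int(round(b.onset_s / run.tr_s))
                    corrupted[offset + onset + 4: offset + onset + 14] += 1.0
            offset += run.n_timepoints
        res = residual_by_direction(noiseless_series, corrupted, small_runs)
        assert res[90.0] == pytest.approx(1.0, abs=1e-9)
        for d, v in res.items():
            if d != 90.0:
                assert abs(v) < 0.05


class TestRobustFit:
    def test_table_arithmetic_minor_axis_ratio(self):
        x = np.linspace(0, 20, 40)
        y = 0.163 + (-1.19e-3) * x
        fit = robust_fit(x, y)
        assert fit.slope == pytest.approx(-1.19e-3, rel=1e-6)
        assert fit.delta_0_20 == pytest.approx(0.0238, abs=1e-6)

    def test_table_arithmetic_angle(self):
        x = np.linspace(0, 20, 40)
        y = 39.5 + 0.496 * x
        fit = robust_fit(x, y)
        assert fit.delta_0_20 == pytest.approx(9.92, abs=1e-6)

    def test_exact_line_equals_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 20, 30)
        y = 1.2 + 0.4 * x
        fit = robust_fit(x, y)
        assert fit.slope == pytest.approx(0.4, abs=1e-10)
        assert fit.offset == pytest.approx(1.2, abs=1e-9)

    def test_outlier_downweighted(self):
        x = np.linspace(0, 20, 50)
        y = 1.0 + 0.1 * x
        y_out = y.copy()
        y_out[25] += 50.0
        robust = robust_fit(x, y_out)
        ols_slope = np.polyfit(x, y_out, 1)[0]
        assert abs(robust.slope - 0.1) < abs(ols_slope - 0.1)
        assert robust.weights[25] < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            robust_fit([1, 2], [1, 2])
        with pytest.raises(ValueError, match="identical"):
            robust_fit([2, 2, 2], [1, 2, 3])


class TestPredictResponseAtStimulus:
    def test_identical_params_constant_response(self):
        params = [DEFAULT_TRUTH] * 10
        out = predict_response_at_stimulus(params, ChromaticStimulus(-45.0, 0.06))
        assert np.ptp(out) == 0.0

    def test_equivalent_stimuli_on_shared_contour(self):
        """At ellipse (45 deg, 0.2), the 6% L-M stimulus and the 30% L+M
        stimulus share equivalent contrast 0.30 and thus response."""
        ell = EllipseParams(45.0, 0.2)
        e_lm = equivalent_contrast(ChromaticStimulus(-45.0, 0.06), ell)
        e_lum = equivalent_contrast(ChromaticStimulus(45.0, 0.30), ell)
        assert e_lm == pytest.approx(0.30, rel=1e-12)
        assert e_lum == pytest.approx(0.30, rel=1e-12)
        params = [QCMParams(ellipse=ell, nr=DEFAULT_TRUTH.nr)]
        r1 = predict_response_at_stimulus(params, ChromaticStimulus(-45.0, 0.06))
        r2 = predict_response_at_stimulus(params, ChromaticStimulus(45.0, 0.30))
        np.testing.assert_allclose(r1, r2)

    def test_ratio_gradient_moves_lm_not_lum(self):
        """An eccentricity gradient in the minor-axis ratio changes the
        L-M (minor-axis) response but not the L+M (major-axis) response."""
        nr = DEFAULT_TRUTH.nr
        ratios = np.linspace(0.1, 0.4, 15)
        params = [
            QCMParams(ellipse=EllipseParams(45.0, r), nr=nr) for r in ratios
        ]
        lm = predict_response_at_stimulus(params, ChromaticStimulus(-45.0, 0.06))
        lum = predict_response_at_stimulus(params, ChromaticStimulus(45.0, 0.30))
        assert np.ptp(lm) > 0.05
        assert np.ptp(lum) < 1e-12

    def test_undefined_vertices_skipped_as_nan(self):
        params = [DEFAULT_TRUTH, None, DEFAULT_TRUTH]
        out = predict_response_at_stimulus(params, ChromaticStimulus(0.0, 0.1))
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()
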