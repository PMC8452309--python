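import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from qcmfit.hemodynamics import HRFKernel
from qcmfit.qcm import (
    EllipseParams,
    NakaRushtonParams,
    QCMParams,
    equivalent_contrast,
    fit_qcm,
    fit_qcm_locked,
    isoresponse_contour,
    naka_rushton,
    qcm_crf,
    qcm_neural_timecourse,
    qcm_predict_bold,
    quadratic_matrix,
)
from qcmfit.stimulus_design import (
    ChromaticStimulus,
    ConeContrastVector,
    build_design_matrix,
    cone_contrast_from_direction,
    default_ladders,
    generate_run_design,
)
from qcmfit.synthetic import DEFAULT_TRUTH


def contour_radius(ellipse: EllipseParams, direction_deg: float) -> float:
    """Independent geometric oracle: distance from the origin to the
    normalized contour along a chromatic direction, found by root-finding
    on the parametric ellipse (no quadratic form involved)."""
    phi = math.radians(ellipse.angle_deg)
    r = ellipse.minor_axis_ratio
    u = np.array([math.cos(math.radians(direction_deg)),
                  math.sin(math.radians(direction_deg))])

    def point(t):
        major, minor = math.cos(t), r * math.sin(t)
        return np.array([
            math.cos(phi) * major - math.sin(phi) * minor,
            math.sin(phi) * major + math.cos(phi) * minor,
        ])

    def cross(t):  # zero when the contour point is parallel to u
        p = point(t)
        return p[0] * u[1] - p[1] * u[0]

    grid = np.linspace(0, 2 * math.pi, 721)
    vals = [cross(t) for t in grid]
    for a, b, fa, fb in zip(grid, grid[1:], vals, vals[1:]):
        if fa == 0 or fa * fb < 0:
            t0 = a if fa == 0 else brentq(cross, a, b, xtol=1e-15)
            p = point(t0)
            if p @ u > 0:  # the intersection on the stimulus side
                return float(np.linalg.norm(p))
    raise AssertionError("no contour intersection found")


class TestQuadraticMatrix:
    def test_circle_is_identity(self):
        Q = quadratic_matrix(EllipseParams(angle_deg=37.0, minor_axis_ratio=1.0)).Q
        np.testing.assert_allclose(Q, np.eye(2), atol=1e-12)

    def test_axis_aligned(self):
        Q = quadratic_matrix(EllipseParams(angle_deg=0.0, minor_axis_ratio=0.5)).Q
        np.testing.assert_allclose(Q, np.diag([1.0, 4.0]), atol=1e-12)

    def test_180_degree_symmetry(self):
        a = quadratic_matrix(EllipseParams(23.0, 0.3)).Q
        b = quadratic_matrix(EllipseParams(203.0, 0.3)).Q
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_eigenvalues(self):
        Q = quadratic_matrix(EllipseParams(angle_deg=66.0, minor_axis_ratio=0.25)).Q
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(Q)), [1.0, 16.0], atol=1e-9
        )

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            EllipseParams(angle_deg=0.0, minor_axis_ratio=0.0)


class TestEquivalentContrast:
    def test_minor_axis_stimulus(self):
        ell = EllipseParams(45.0, 0.2)
        e = equivalent_contrast(ChromaticStimulus(-45.0, 0.12), ell)
        assert e == pytest.approx(0.60, rel=1e-12)

    def test_major_axis_stimulus(self):
        ell = EllipseParams(45.0, 0.2)
        e = equivalent_contrast(ChromaticStimulus(45.0, 0.60), ell)
        assert e == pytest.approx(0.60, rel=1e-12)

    def test_circle_returns_vector_length(self):
        ell = EllipseParams(120.0, 1.0)
        for d in (-90.0, 13.0, 45.0):
            assert equivalent_contrast(
                ChromaticStimulus(d, 0.37), ell
            ) == pytest.approx(0.37, rel=1e-12)

    def test_out_of_plane_rejected(self):
        with pytest.raises(ValueError, match="LM plane"):
            equivalent_contrast(ConeContrastVector(0.1, 0.1, 0.05),
                                EllipseParams(45.0, 0.2))

    @settings(max_examples=80, derandomize=True)
    @given(
        angle=st.floats(0.0, 179.9),
        ratio=st.floats(0.05, 1.0),
        direction=st.floats(-180.0, 179.9),
        contrast=st.floats(0.0, 1.0),
        k=st.floats(0.0, 3.0),
    )
    def test_homogeneity_and_symmetry(self, angle, ratio, direction, contrast, k):
        ell = EllipseParams(angle, ratio)
        stim = cone_contrast_from_direction(ChromaticStimulus(direction, contrast))
        v = np.array([stim.L, stim.M])
        e = equivalent_contrast(v, ell)
        assert equivalent_contrast(k * v, ell) == pytest.approx(k * e, abs=1e-12)
        assert equivalent_contrast(-v, ell) == pytest.approx(e, abs=1e-12)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 45.0, 112.5, 170.0])
    @pytest.mark.parametrize("ratio", [0.1, 0.2, 0.5, 1.0])
    def test_brute_force_contour_oracle(self, angle, ratio):
        """e(c) must equal ||c|| / (contour radius along c's direction):
        scaling the unit contour until it passes through the stimulus."""
        ell = EllipseParams(angle, ratio)
        for direction in (-45.0, 0.0, 22.5, 67.5, 90.0, 155.0):
            c = 0.31
            expected = c / contour_radius(ell, direction)
            e = equivalent_contrast(ChromaticStimulus(direction, c), ell)
            assert e == pytest.approx(expected, abs=1e-9)


class TestNakaRushton:
    nr = NakaRushtonParams(amplitude=1.4, semi_saturation=0.3, exponent=2.1,
                           offset=0.15)

    def test_zero_contrast_gives_offset(self):
        assert naka_rushton(0.0, self.nr) == pytest.approx(self.nr.offset)

    def test_semi_saturation_definition(self):
        assert naka_rushton(self.nr.semi_saturation, self.nr) == pytest.approx(
            self.nr.offset + self.nr.amplitude / 2
        )

    def test_asymptote(self):
        assert naka_rushton(1e9, self.nr) == pytest.approx(
            self.nr.offset + self.nr.amplitude, rel=1e-6
        )

    def test_monotone(self):
        e = np.linspace(0, 2, 200)
        out = naka_rushton(e, self.nr)
        assert np.all(np.diff(out) >= 0)

    def test_negative_contrast_rejected(self):
        with pytest.raises(ValueError):
            naka_rushton(-0.1, self.nr)


@pytest.fixture(scope="module")
def run():
    dirs = (-45.0, 0.0, 45.0, 90.0)
    return generate_run_design(dirs, default_ladders(dirs), seed=21)


class TestForwardModel:
    def test_all_background_constant(self):
        from qcmfit.stimulus_design import Block, RunDesign

        run = RunDesign(blocks=tuple(
            Block(onset_s=12.0 * i, stimulus=None) for i in range(4)
        ))
        neural = qcm_neural_timecourse(run, DEFAULT_TRUTH)
        assert np.all(neural == DEFAULT_TRUTH.nr.offset)

    def test_isoresponse_blocks_equal_amplitude(self, run):
        # two stimuli on the same contour by construction
        params = QCMParams(
            ellipse=EllipseParams(45.0, 0.2),
            nr=NakaRushtonParams(2.0, 1.0, 1.5, 0.1),
        )
        e1 = equivalent_contrast(ChromaticStimulus(-45.0, 0.12), params.ellipse)
        e2 = equivalent_contrast(ChromaticStimulus(45.0, 0.60), params.ellipse)
        assert e1 == pytest.approx(e2)
        assert naka_rushton(e1, params.nr) == pytest.approx(
            naka_rushton(e2, params.nr)
        )

    def test_impulse_hrf_returns_neural(self, run):
        impulse = HRFKernel(values=np.array([1.0]), tr_s=run.tr_s)
        neural = qcm_neural_timecourse(run, DEFAULT_TRUTH)
        np.testing.assert_allclose(
            qcm_predict_bold(run, DEFAULT_TRUTH, impulse), neural
        )

    def test_linear_equivalence_with_design_matrix(self, run, hrf):
        """With zero offset the QCM prediction is exactly the stimulus
        design-matrix columns weighted by the per-condition responses."""
        params = DEFAULT_TRUTH  # offset 0
        dm = build_design_matrix(run, hrf)
        betas = np.zeros(len(dm.column_labels))
        for j, lab in enumerate(dm.column_labels[:-1]):
            from qcmfit.stimulus_design import parse_condition_label

            d, c = parse_condition_label(lab)
            e = equivalent_contrast(ChromaticStimulus(d, c), params.ellipse)
            betas[j] = naka_rushton(e, params.nr)
        np.testing.assert_allclose(
            qcm_predict_bold(run, params, hrf), dm.values @ betas, atol=1e-10
        )

    def test_tr_mismatch_rejected(self, run):
        from qcmfit.hemodynamics import canonical_hrf

        with pytest.raises(ValueError, match="TR"):
            qcm_predict_bold(run, DEFAULT_TRUTH, canonical_hrf(0.4))


class TestCRFAndContour:
    params = QCMParams(
        ellipse=EllipseParams(45.0, 0.2),
        nr=NakaRushtonParams(2.0, 1.0, 1.5, 0.3),
    )

    def test_zero_contrast_zero_response(self):
        assert qcm_crf(self.params, -45.0, [0.0])[0] == pytest.approx(0.0)

    def test_monotone_in_contrast(self):
        crf = qcm_crf(self.params, 22.5, np.linspace(0, 0.6, 50))
        assert np.all(np.diff(crf) >= 0)

    def test_bipolar_symmetry(self):
        contrasts = [0.0075, 0.015, 0.03, 0.06, 0.12]
        np.testing.assert_allclose(
            qcm_crf(self.params, -45.0, contrasts),
            qcm_crf(self.params, 135.0, contrasts),
        )

    def test_contour_points_have_unit_equivalent_contrast(self):
        ell = EllipseParams(67.5, 0.35)
        pts = isoresponse_contour(ell, n_points=64)
        for p in pts:
            assert equivalent_contrast(p, ell) == pytest.approx(1.0, abs=1e-12)

    def test_contour_axis_lengths(self):
        ell = EllipseParams(45.0, 0.2)
        pts = isoresponse_contour(ell, n_points=720)
        angles = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
        norms = np.linalg.norm(pts, axis=1)
        at_major = np.argmin(np.abs(angles - 45.0))
        at_minor = np.argmin(np.abs(angles + 45.0))
        assert norms[at_major] == pytest.approx(1.0, abs=1e-3)
        assert norms[at_minor] == pytest.approx(0.2, abs=1e-3)

    def test_unit_circle_when_ratio_one(self):
        pts = isoresponse_contour(EllipseParams(0.0, 1.0), n_points=16)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0)


class TestFitting:
    def test_noiseless_recovery(self, small_runs, noiseless_series, hrf):
        fit = fit_qcm(noiseless_series, small_runs, hrf, seed=0)
        truth = DEFAULT_TRUTH.as_vector()
        recovered = fit.params.as_vector()
        # offset is compared absolutely (truth is 0)
        np.testing.assert_allclose(recovered[:5], truth[:5], rtol=1e-3)
        assert abs(recovered[5] - truth[5]) < 1e-3
        assert fit.r2 > 0.999999
        assert fit.n_free_params == 6

    def test_locked_at_truth_matches_unlocked(self, small_runs, noiseless_series, hrf):
        locked = fit_qcm_locked(noiseless_series, small_runs, hrf,
                                locked_angle_deg=45.0, seed=0)
        assert locked.n_free_params == 5
        assert locked.params.ellipse.angle_deg == 45.0
        np.testing.assert_allclose(
            locked.params.as_vector()[1:5], DEFAULT_TRUTH.as_vector()[1:5],
            rtol=1e-3,
        )

    def test_degenerate_constant_series_flagged(self, small_runs, hrf):
        n = sum(r.n_timepoints for r in small_runs)
        fit = fit_qcm(np.full(n, 3.7), small_runs, hrf)
        assert fit.degenerate
        assert fit.params is None

    def test_angle_unidentifiable_at_ratio_one(self, small_runs, hrf):
        truth = QCMParams(
            ellipse=EllipseParams(10.0, 1.0),
            nr=NakaRushtonParams(2.0, 0.5, 1.5, 0.0),
        )
        series = qcm_predict_bold(list(small_runs), truth, hrf)
        fit = fit_qcm(series, small_runs, hrf, seed=0)
        assert fit.angle_undefined
        assert fit.to_json_dict()["params"]["angle_deg"] is None

    def test_length_mismatch_rejected(self, small_runs, hrf):
        with pytest.raises(ValueError, match="length"):
            fit_qcm(np.zeros(10), small_runs, hrf)
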