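import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filmdose.calibration import (
    CalibrationModel,
    CalibrationPoint,
    DoseQuantity,
    ModelForm,
    fit_calibration,
    invert_dose,
    load_calibration,
    model_from_dict,
    model_to_dict,
    predict_response,
    save_calibration,
)
from filmdose.errors import (
    CalibrationIOError,
    ExtrapolationWarning,
    FitError,
    SaturationError,
)
from filmdose.response import ResponseKind
from filmdose.synthetic import generate_calibration_set, xrqa2_truth

DOSES = np.linspace(0.0, 10.0, 10)


def noiseless_points(b=0.2, c=0.1):
    return [
        CalibrationPoint(x, c * x / (1 + b * x), 0.0) for x in DOSES
    ]


class TestFit:
    def test_constrained_fit_recovers_noiseless_truth(self):
        model = fit_calibration(noiseless_points(), ModelForm.CONSTRAINED)
        assert model.b == pytest.approx(0.2, abs=1e-6)
        assert model.c == pytest.approx(0.1, abs=1e-6)
        assert model.valid_dose_range == (0.0, 10.0)

    def test_general_fit_on_zero_intercept_data(self):
        # a is consistent with zero but far worse determined than b and c
        points, _ = generate_calibration_set(
            doses=DOSES, sigma_y=3e-4, seed=42
        )
        general = fit_calibration(points, ModelForm.GENERAL)
        constrained = fit_calibration(points, ModelForm.CONSTRAINED)
        rel = general.relative_uncertainties
        assert abs(general.a) < 3 * general.parameter_sigmas["a"]
        assert rel["a"] > rel["b"]
        assert rel["a"] > rel["c"]
        # b and c barely move between the two forms
        sig_g, sig_c = general.parameter_sigmas, constrained.parameter_sigmas
        for p in ("b", "c"):
            tol = np.hypot(sig_g[p], sig_c[p])
            assert abs(getattr(general, p) - getattr(constrained, p)) <= tol

    def test_single_repeated_dose_is_degenerate(self):
        points = [CalibrationPoint(5.0, 0.25, 0.0)] * 6
        with pytest.raises(FitError):
            fit_calibration(points, ModelForm.CONSTRAINED)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_calibration(noiseless_points()[:3], ModelForm.GENERAL)

    def test_mixed_zero_and_positive_sigmas_rejected(self):
        points = noiseless_points()
        points[0] = CalibrationPoint(points[0].dose, points[0].response, 1e-4)
        with pytest.raises(FitError):
            fit_calibration(points, ModelForm.CONSTRAINED)

    def test_weight_scale_invariance(self):
        points, _ = generate_calibration_set(doses=DOSES, sigma_y=3e-4, seed=3)
        scaled = [
            CalibrationPoint(p.dose, p.response, 3.0 * p.sigma_y) for p in points
        ]
        m1 = fit_calibration(points, ModelForm.CONSTRAINED)
        m2 = fit_calibration(scaled, ModelForm.CONSTRAINED)
        assert m2.b == pytest.approx(m1.b, rel=1e-9)
        assert m2.c == pytest.approx(m1.c, rel=1e-9)
        np.testing.assert_allclose(m2.covariance, 9.0 * m1.covariance, rtol=1e-8)

    def test_parameter_recovery_under_one_percent_noise(self):
        # median relative error on b and c stays below 5% over 200 datasets
        rng = np.random.default_rng(2024)
        truth = xrqa2_truth()
        doses = np.linspace(1.0, 10.0, 10)
        errs_b, errs_c = [], []
        for _ in range(200):
            y_true = truth.c * doses / (1 + truth.b * doses)
            points, _ = generate_calibration_set(
                doses=doses, truth=truth, sigma_y=0.01 * y_true, rng=rng
            )
            model = fit_calibration(points, ModelForm.CONSTRAINED)
            errs_b.append(abs(model.b - truth.b) / truth.b)
            errs_c.append(abs(model.c - truth.c) / truth.c)
        assert np.median(errs_b) < 0.05
        assert np.median(errs_c) < 0.05


class TestPredictInvert:
    def test_zero_dose_anchor(self, example_model):
        assert predict_response(example_model, 0.0) == 0.0

    def test_rational_value(self, example_model):
        assert predict_response(example_model, 1.0) == pytest.approx(
            0.1 / 1.2, abs=1e-12
        )

    def test_linear_limit_as_b_vanishes(self, example_model):
        m = CalibrationModel(
            form=ModelForm.CONSTRAINED, a=0.0, b=1e-12, c=0.1,
            covariance=np.zeros((2, 2)),
            response_kind=ResponseKind.NET_DELTA_R,
            dose_quantity=DoseQuantity.AIR_KERMA_IN_AIR,
            valid_dose_range=(0.0, 10.0),
        )
        assert predict_response(m, 4.0) == pytest.approx(0.4, rel=1e-9)

    def test_extrapolation_warns_not_raises(self, example_model):
        with pytest.warns(ExtrapolationWarning):
            predict_response(example_model, 20.0)

    def test_invert_is_exact_algebraic_inverse(self, example_model):
        rng = np.random.default_rng(1)
        for x in rng.uniform(0.0, 10.0, 100):
            y = predict_response(example_model, x)
            assert abs(invert_dose(example_model, y) - x) < 1e-10

    def test_invert_arithmetic_example(self, example_model):
        assert invert_dose(example_model, 0.1 / 1.2) == pytest.approx(1.0, abs=1e-12)

    def test_saturation_at_asymptote(self, example_model):
        with pytest.raises(SaturationError):
            invert_dose(example_model, example_model.c / example_model.b)


@settings(derandomize=True, max_examples=50)
@given(
    b=st.floats(1e-4, 1.0),
    c=st.floats(1e-4, 1.0),
    x1=st.floats(0.0, 10.0),
    dx=st.floats(1e-6, 5.0),
)
def test_constrained_model_strictly_increasing(b, c, x1, dx):
    m = CalibrationModel(
        form=ModelForm.CONSTRAINED, a=0.0, b=b, c=c,
        covariance=np.zeros((2, 2)),
        response_kind=ResponseKind.NET_DELTA_R,
        dose_quantity=DoseQuantity.AIR_KERMA_IN_AIR,
        valid_dose_range=(0.0, 20.0),
    )
    assert predict_response(m, x1 + dx) > predict_response(m, x1)


class TestSerialization:
    def test_save_load_save_is_byte_identical(self, example_model, tmp_path):
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_calibration(example_model, p1)
        save_calibration(load_calibration(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_lossless_float_round_trip(self):
        m = CalibrationModel(
            form=ModelForm.CONSTRAINED, a=0.0, b=0.1 + 1e-17 + np.pi / 31,
            c=1.0 / 3.0, covariance=np.eye(2) * 1e-9,
            response_kind=ResponseKind.NET_DELTA_R,
            dose_quantity=DoseQuantity.AIR_KERMA_IN_AIR,
            valid_dose_range=(0.0, 10.0),
        )
        back = model_from_dict(json.loads(json.dumps(model_to_dict(m))))
        assert back.b == m.b and back.c == m.c
        np.testing.assert_array_equal(back.covariance, m.covariance)

    def test_missing_covariance_rejected(self, example_model, tmp_path):
        payload = model_to_dict(example_model)
        del payload["covariance"]
        with pytest.raises(CalibrationIOError, match="covariance"):
            model_from_dict(payload)

    def test_constrained_with_nonzero_a_rejected(self, example_model):
        payload = model_to_dict(example_model)
        payload["a"] = 0.01
        with pytest.raises(CalibrationIOError):
            model_from_dict(payload)

    def test_unknown_schema_rejected(self, example_model):
        payload = model_to_dict(example_model)
        payload["schema"] = "filmdose-calibration-99"
        with pytest.raises(CalibrationIOError, match="schema"):
            model_from_dict(payload)
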