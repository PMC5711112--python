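"""Rational-function dose-response calibration.

The film response y as a function of dose x (air kerma in air for XRQA2,
dose to water for EBT3) is modelled by the rational function

    y(x) = (a + c x) / (1 + b x),

either in its general three-parameter form or with the intercept
constrained to a = 0 ("constrained" form). The constraint is physically
motivated: an unexposed film must show zero net response, and freeing a
mostly buys a large, poorly determined intercept that inflates the dose
uncertainty at low dose. The model is monotone increasing on its valid
range whenever c - a*b > 0 and 1 + b*x > 0, saturating at the asymptote
y -> c/b, and inverts in closed form:

    general:     x = (y - a) / (c - b y)
    constrained: x = y / (c - b y)

Fits are weighted least squares (weights 1/sigma_y^2) via
scipy.optimize.least_squares, with the parameter covariance taken from the
linearization at the optimum.
"""

from __future__ import annotations

import enum
import json
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    CalibrationIOError,
    FitError,
    ModelRejectionError,
    SaturationError,
)
from .errors import ExtrapolationWarning
from .response import ResponseKind

SCHEMA = "filmdose-calibration-1"


class ModelForm(str, enum.Enum):
    GENERAL = "general"
    CONSTRAINED = "constrained"


class DoseQuantity(str, enum.Enum):
    AIR_KERMA_IN_AIR = "air_kerma_in_air"
    DOSE_TO_WATER = "dose_to_water"


@dataclass
class CalibrationPoint:
    """One (dose, response, response sigma) calibration triple."""

    dose: float  # cGy
    response: float
    sigma_y: float = 0.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("calibration dose must be nonnegative")
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be nonnegative")


@dataclass
class CalibrationModel:
    """Fitted rational calibration with parameter covariance.

    ``covariance`` is over the free parameters only: (a, b, c) for the
    general form, (b, c) for the constrained form.
    """

    form: ModelForm
    a: float
    b: float
    c: float
    covariance: np.ndarray
    response_kind: ResponseKind
    dose_quantity: DoseQuantity
    valid_dose_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.form = ModelForm(self.form)
        self.response_kind = ResponseKind(self.response_kind)
        self.dose_quantity = DoseQuantity(self.dose_quantity)
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        n_free = 3 if self.form == ModelForm.GENERAL else 2
        if self.covariance.shape != (n_free, n_free):
            raise CalibrationIOError(
                f"{self.form.value} form needs a {n_free}x{n_free} covariance, "
                f"got {self.covariance.shape}"
            )
        if self.form == ModelForm.CONSTRAINED and self.a != 0.0:
            raise CalibrationIOError("constrained form requires a = 0")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise CalibrationIOError("covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.covariance).min())
        scale = max(1.0, float(np.abs(self.covariance).max()))
        if eigmin < -1e-10 * scale:
            raise CalibrationIOError("covariance must be positive semidefinite")
        lo, hi = self.valid_dose_range
        if not (0 <= lo <= hi):
            raise ValueError("valid_dose_range must satisfy 0 <= lo <= hi")
        if self.c <= 0:
            raise ModelRejectionError("require c > 0")
        if 1 + self.b * lo <= 0 or 1 + self.b * hi <= 0:
            raise ModelRejectionError("1 + b*x must stay positive on the range")
        if self.c - self.a * self.b <= 0:
            raise ModelRejectionError(
                "model not strictly increasing on its range (c - a*b <= 0)"
            )

    @property
    def free_parameters(self) -> tuple[str, ...]:
        if self.form == ModelForm.GENERAL:
            return ("a", "b", "c")
        return ("b", "c")

    @property
    def parameter_values(self) -> np.ndarray:
        if self.form == ModelForm.GENERAL:
            return np.array([self.a, self.b, self.c])
        return np.array([self.b, self.c])

    @property
    def parameter_sigmas(self) -> dict[str, float]:
        sig = np.sqrt(np.diag(self.covariance))
        return dict(zip(self.free_parameters, sig.tolist()))

    @property
    def relative_uncertainties(self) -> dict[str, float]:
        """Per-parameter sigma/|value| (inf for an exactly zero parameter)."""
        out = {}
        for name, sigma in self.parameter_sigmas.items():
            value = getattr(self, name)
            out[name] = float(sigma / abs(value)) if value != 0 else float("inf")
        return out

    @property
    def saturation_response(self) -> float:
        """Asymptotic response c/b (inf for b <= 0)."""
        return self.c / self.b if self.b > 0 else float("inf")

    def attainable_response_range(self) -> tuple[float, float]:
        lo, hi = self.valid_dose_range
        return predict_response(self, lo), predict_response(self, hi)


def _rational(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return (a + c * x) / (1.0 + b * x)


def fit_calibration(
    points: Sequence[CalibrationPoint],
    form: ModelForm | str = ModelForm.CONSTRAINED,
    response_kind: ResponseKind | str = ResponseKind.NET_DELTA_R,
    dose_quantity: DoseQuantity | str = DoseQuantity.AIR_KERMA_IN_AIR,
) -> CalibrationModel:
    """Weighted least-squares fit of the rational calibration.

    Weights are 1/sigma_y^2; if every point has sigma_y == 0 the fit is
    unweighted and the covariance is scaled by the reduced chi-square
    (weighted fits use the unscaled local-linearization covariance).
    Starting values come from the low-dose linearization (c from the initial
    slope, b from the highest-dose curvature, a = 0).
    """
    form = ModelForm(form)
    x = np.array([p.dose for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    s = np.array([p.sigma_y for p in points], dtype=float)
    n_free = 3 if form == ModelForm.GENERAL else 2
    min_pts = 4 if form == ModelForm.GENERAL else 3
    if len(x) < min_pts:
        raise FitError(f"{form.value} fit needs at least {min_pts} points")
    if np.ptp(x) == 0:
        raise FitError("degenerate design: all calibration doses are equal")
    if np.all(s == 0):
        w = np.ones_like(s)
        weighted = False
    elif np.all(s > 0):
        w = 1.0 / s
        weighted = True
    else:
        raise FitError("sigma_y must be all positive (weighted) or all zero")

    p0 = _initial_guess(x, y, form)

    if form == ModelForm.GENERAL:
        def resid(p):
            return (_rational(x, *p) - y) * w

        def jac(p):
            a, b, c = p
            denom = 1.0 + b * x
            d_a = 1.0 / denom
            d_b = -(a + c * x) * x / denom**2
            d_c = x / denom
            return np.column_stack([d_a, d_b, d_c]) * w[:, None]
    else:
        def resid(p):
            b, c = p
            return (_rational(x, 0.0, b, c) - y) * w

        def jac(p):
            b, c = p
            denom = 1.0 + b * x
            d_b = -(c * x) * x / denom**2
            d_c = x / denom
            return np.column_stack([d_b, d_c]) * w[:, None]

    result = least_squares(resid, p0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise FitError(
            f"calibration fit did not converge (residual norm "
            f"{np.linalg.norm(result.fun):.3g})"
        )

    J = jac(result.x)
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix at the optimum") from exc
    dof = len(x) - n_free
    if not weighted and dof > 0:
        cov = cov * float(result.fun @ result.fun) / dof
    cov = (cov + cov.T) / 2.0

    if form == ModelForm.GENERAL:
        a, b, c = result.x
    else:
        a = 0.0
        b, c = result.x
    model = CalibrationModel(
        form=form,
        a=float(a),
        b=float(b),
        c=float(c),
        covariance=cov,
        response_kind=ResponseKind(response_kind),
        dose_quantity=DoseQuantity(dose_quantity),
        valid_dose_range=(float(x.min()), float(x.max())),
    )
    # __post_init__ raises ModelRejectionError on monotonicity violations.
    return model


def _initial_guess(x: np.ndarray, y: np.ndarray, form: ModelForm) -> np.ndarray:
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    low = xs <= np.median(xs)
    denom = float(xs[low] @ xs[low])
    c0 = float(xs[low] @ ys[low]) / denom if denom > 0 else 1.0
    if c0 <= 0:
        c0 = max(abs(c0), 1e-6)
    x_hi, y_hi = xs[-1], ys[-1]
    b0 = 1e-3
    if x_hi > 0 and y_hi > 0:
        b0 = max((c0 * x_hi / y_hi - 1.0) / x_hi, 1e-6)
    if form == ModelForm.GENERAL:
        return np.array([0.0, b0, c0])
    return np.array([b0, c0])


def predict_response(model: CalibrationModel, dose: float) -> float:
    """Evaluate y(x) = (a + c x)/(1 + b x); warns outside the valid range."""
    denom = 1.0 + model.b * dose
    if denom <= 0:
        raise ValueError(f"1 + b*dose <= 0 at dose {dose} (pole of the model)")
    lo, hi = model.valid_dose_range
    if dose < lo or dose > hi:
        warnings.warn(
            f"dose {dose:.4g} cGy outside calibrated range [{lo:.4g}, {hi:.4g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return (model.a + model.c * dose) / denom


def invert_dose(model: CalibrationModel, response: float) -> float:
    """Closed-form inverse x(y); raises SaturationError at/beyond y = c/b."""
    denom = model.c - model.b * response
    if denom <= 0:
        raise SaturationError(
            f"response {response:.6g} at or beyond the asymptote "
            f"c/b = {model.saturation_response:.6g}"
        )
    x = (response - model.a) / denom
    y_lo, y_hi = model.attainable_response_range()
    if response < y_lo or response > y_hi:
        warnings.warn(
            f"response {response:.4g} outside the attainable range "
            f"[{y_lo:.4g}, {y_hi:.4g}] of the calibration",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return x


def model_to_dict(model: CalibrationModel) -> dict:
    return {
        "schema": SCHEMA,
        "form": model.form.value,
        "a": model.a,
        "b": model.b,
        "c": model.c,
        "covariance": model.covariance.tolist(),
        "free_parameters": list(model.free_parameters),
        "response_kind": model.response_kind.value,
        "dose_quantity": model.dose_quantity.value,
        "valid_dose_range": list(model.valid_dose_range),
    }


def model_from_dict(payload: dict) -> CalibrationModel:
    if not isinstance(payload, dict) or payload.get("schema") != SCHEMA:
        raise CalibrationIOError(
            f"unsupported calibration schema {payload.get('schema')!r}; "
            f"expected {SCHEMA!r}"
        )
    required = {"form", "a", "b", "c", "covariance", "response_kind",
                "dose_quantity", "valid_dose_range"}
    missing = required - payload.keys()
    if missing:
        raise CalibrationIOError(f"calibration file missing fields: {sorted(missing)}")
    try:
        return CalibrationModel(
            form=ModelForm(payload["form"]),
            a=float(payload["a"]),
            b=float(payload["b"]),
            c=float(payload["c"]),
            covariance=np.asarray(payload["covariance"], dtype=float),
            response_kind=ResponseKind(payload["response_kind"]),
            dose_quantity=DoseQuantity(payload["dose_quantity"]),
            valid_dose_range=tuple(payload["valid_dose_range"]),
        )
    except (ValueError, KeyError) as exc:
        raise CalibrationIOError(f"invalid calibration file: {exc}") from exc


def save_calibration(model: CalibrationModel, path: str | os.PathLike) -> None:
    """JSON round trip is lossless: doubles serialize via repr."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_calibration(path: str | os.PathLike) -> CalibrationModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CalibrationIOError(f"not a JSON calibration file: {exc}") from exc
    return model_from_dict(payload)
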