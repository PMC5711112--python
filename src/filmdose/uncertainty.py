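"""One-sigma dose uncertainty budgets by the delta method.

With x(y; params) the closed-form inverse of the rational calibration, the
dose variance splits into a response-noise term and a calibration-parameter
term (the two are independent: calibration films are not measurement films):

    sigma_x^2 = (dx/dy)^2 sigma_y^2  +  g C g^T

where g is the gradient of x with respect to the free parameters and C the
fitted parameter covariance, off-diagonals included (b and c are strongly
correlated in rational fits; dropping them biases sigma low).

Partials, constrained form x = y/(c - b y):
    dx/dy = c/(c - b y)^2,  dx/db = y^2/(c - b y)^2,  dx/dc = -y/(c - b y)^2
General form x = (y - a)/(c - b y):
    dx/dy = (c - a b)/(c - b y)^2,  dx/da = -1/(c - b y),
    dx/db = y (y - a)/(c - b y)^2,  dx/dc = -(y - a)/(c - b y)^2
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .calibration import (
    CalibrationModel,
    CalibrationPoint,
    ModelForm,
    fit_calibration,
    invert_dose,
    predict_response,
)
from .errors import ExtrapolationWarning, SaturationError

SigmaYModel = Callable[[float], float] | float


@dataclass
class UncertaintyBudget:
    """Dose with its one-sigma uncertainty split into additive variance
    components (from_response, from_parameters), in cGy."""

    dose: float
    sigma_dose: float
    relative_pct: float
    components: dict[str, float]
    model_form: ModelForm


def _inverse_gradients(model: CalibrationModel, y: float):
    """Return (dx/dy, gradient w.r.t. free parameters) at response y."""
    denom = model.c - model.b * y
    if denom <= 0:
        raise SaturationError(
            f"uncertainty undefined at/beyond the asymptote (c - b*y = {denom:.3g})"
        )
    if model.form == ModelForm.CONSTRAINED:
        dx_dy = model.c / denom**2
        grad = np.array([y**2 / denom**2, -y / denom**2])  # (b, c)
    else:
        dx_dy = (model.c - model.a * model.b) / denom**2
        grad = np.array(
            [
                -1.0 / denom,                      # a
                y * (y - model.a) / denom**2,      # b
                -(y - model.a) / denom**2,         # c
            ]
        )
    return dx_dy, grad


def dose_uncertainty(
    model: CalibrationModel, response: float, sigma_y: float
) -> UncertaintyBudget:
    """Delta-method one-sigma dose uncertainty for a measured response."""
    if sigma_y < 0:
        raise ValueError("sigma_y must be nonnegative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        dose = invert_dose(model, response)
    dx_dy, grad = _inverse_gradients(model, response)
    var_response = (dx_dy * sigma_y) ** 2
    var_params = float(grad @ model.covariance @ grad)
    sigma = float(np.sqrt(var_response + var_params))
    rel = 100.0 * sigma / dose if dose > 0 else float("inf")
    return UncertaintyBudget(
        dose=float(dose),
        sigma_dose=sigma,
        relative_pct=float(rel),
        components={"from_response": var_response, "from_parameters": var_params},
        model_form=model.form,
    )


def uncertainty_curve(
    model: CalibrationModel,
    dose_grid: Sequence[float],
    sigma_y_model: SigmaYModel,
) -> list[UncertaintyBudget]:
    """Uncertainty budget at each grid dose.

    ``sigma_y_model`` is either a constant response sigma or a callable
    sigma_y(dose).
    """
    grid = np.asarray(dose_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose grid must be nonempty")
    budgets = []
    for dose in grid:
        sigma_y = sigma_y_model(dose) if callable(sigma_y_model) else sigma_y_model
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            y = predict_response(model, float(dose))
        budgets.append(dose_uncertainty(model, y, float(sigma_y)))
    return budgets


def threshold_dose(
    budgets: Sequence[UncertaintyBudget], bound_pct: float
) -> float | None:
    """Smallest grid dose above which relative_pct <= bound for every larger
    grid dose; None if the bound fails even at the top of the grid."""
    doses = np.array([b.dose for b in budgets])
    rel = np.array([b.relative_pct for b in budgets])
    order = np.argsort(doses)
    doses, rel = doses[order], rel[order]
    ok = rel <= bound_pct
    if not ok[-1]:
        return None
    # last index where the bound is violated; threshold is the next grid dose
    bad = np.nonzero(~ok)[0]
    idx = bad[-1] + 1 if bad.size else 0
    return float(doses[idx])


def log_dose_grid(lo: float, hi: float, n: int = 200) -> np.ndarray:
    """Log-spaced evaluation grid used for threshold statistics."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi for a log-spaced grid")
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class ModelComparison:
    """Side-by-side uncertainty analysis of the two calibration forms."""

    general: CalibrationModel
    constrained: CalibrationModel
    dose_grid: np.ndarray
    curves: dict[ModelForm, list[UncertaintyBudget]]
    thresholds: dict[ModelForm, float | None]
    bounds_pct: dict[ModelForm, float]
    relative_uncertainties: dict[ModelForm, dict[str, float]]
    b_c_consistent: bool


def compare_models(
    points: Sequence[CalibrationPoint],
    dose_grid: Sequence[float] | None = None,
    sigma_y_model: SigmaYModel = 0.0,
    bounds_pct: dict | None = None,
    **fit_kwargs,
) -> ModelComparison:
    """Fit both calibration forms on identical data and compare their dose
    uncertainty curves and threshold statistics.

    Default bounds are 2% for the constrained form and 3% for the general
    form; the default grid is 200 log-spaced doses from 1% of the top
    calibrated dose up to that top dose.
    """
    bounds = {ModelForm.CONSTRAINED: 2.0, ModelForm.GENERAL: 3.0}
    if bounds_pct:
        bounds.update({ModelForm(k): v for k, v in bounds_pct.items()})
    general = fit_calibration(points, ModelForm.GENERAL, **fit_kwargs)
    constrained = fit_calibration(points, ModelForm.CONSTRAINED, **fit_kwargs)
    if dose_grid is None:
        hi = general.valid_dose_range[1]
        dose_grid = log_dose_grid(hi / 100.0, hi)
    grid = np.asarray(dose_grid, dtype=float)

    curves, thresholds, rel_unc = {}, {}, {}
    for model in (general, constrained):
        curve = uncertainty_curve(model, grid, sigma_y_model)
        curves[model.form] = curve
        thresholds[model.form] = threshold_dose(curve, bounds[model.form])
        rel_unc[model.form] = model.relative_uncertainties

    sig_g = general.parameter_sigmas
    sig_c = constrained.parameter_sigmas
    b_c_consistent = all(
        abs(getattr(general, p) - getattr(constrained, p))
        <= np.hypot(sig_g[p], sig_c[p])
        for p in ("b", "c")
    )
    return ModelComparison(
        general=general,
        constrained=constrained,
        dose_grid=grid,
        curves=curves,
        thresholds=thresholds,
        bounds_pct={k: float(v) for k, v in bounds.items()},
        relative_uncertainties=rel_unc,
        b_c_consistent=b_c_consistent,
    )
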