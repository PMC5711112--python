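"""Forward-model generator: synthetic calibration sets, before/after scan
pairs, and phantom dose-map fixtures.

Every stage of the dosimetry pipeline is testable without physical films by
running the measurement chain forwards: a known ("truth") calibration maps
dose to film response, the response is imprinted on a synthetic scanner
image with Gaussian per-pixel noise, and the analysis pipeline must recover
the programmed dose. Ground truth is always returned alongside the
generated data so round-trip checks never consult the code under test.

Scanner model: unexposed film reads a uniform baseline pv0; both scans add
independent per-pixel Gaussian noise sigma_pv; pixel values are clipped to
the 16-bit range and the clipped fraction reported. Defaults (pv0 = 52000,
sigma_pv = 130) put the 5x5-pixel ROI response noise at a few 1e-4, the
regime in which the calibration's low-dose uncertainty behaviour is
meaningful; they are a model assumption, not a measured scanner property.

Forward response models:
    XRQA2 (reflective):   PV_after = PV_before - 2^16 * y(dose)
    EBT3 (transmission):  PV_after = PV_before * 10^(-y(dose))
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .calibration import (
    CalibrationModel,
    CalibrationPoint,
    DoseQuantity,
    ModelForm,
)
from .dose_engine import Aspect, Machine, Site, _load_json
from .errors import RegistryError, SaturationError
from .response import PV_FULL_SCALE, ResponseKind
from .scan_io import DEFAULT_RESOLUTION_MM_PER_PX, FilmModel, FilmScan, Timepoint

#: Default truth parameters for an XRQA2-like saturating response:
#: y(10 cGy) = 0.35 and near-linear behaviour below 1 cGy.
XRQA2_TRUTH_B = 0.2
XRQA2_TRUTH_C = 0.105

#: EBT3-like transmission response, netDeltaOD = 0.2 at 100 cGy.
EBT3_TRUTH_B = 0.01
EBT3_TRUTH_C = 0.004

#: Calibration designs: 10 doses spanning the stated ranges.
XRQA2_CAL_DOSES = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
EBT3_CAL_DOSES = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0, 70.0, 85.0, 100.0)

#: Per-point response noise of the calibration measurements.
DEFAULT_CAL_SIGMA_Y = 3e-4

#: Repeat-to-repeat (film piece, setup) relative dose scatter; chosen so
#: that triplicate standard errors land near the ~0.01 cGy level typical of
#: the sub-cGy surface measurements.
REPEAT_REL_SD = 0.035


def xrqa2_truth() -> CalibrationModel:
    """Constrained-form truth calibration for XRQA2 (air kerma, cGy)."""
    return CalibrationModel(
        form=ModelForm.CONSTRAINED,
        a=0.0,
        b=XRQA2_TRUTH_B,
        c=XRQA2_TRUTH_C,
        covariance=np.zeros((2, 2)),
        response_kind=ResponseKind.NET_DELTA_R,
        dose_quantity=DoseQuantity.AIR_KERMA_IN_AIR,
        valid_dose_range=(0.0, 10.0),
    )


def ebt3_truth() -> CalibrationModel:
    """Constrained-form truth calibration for EBT3 (dose to water, cGy)."""
    return CalibrationModel(
        form=ModelForm.CONSTRAINED,
        a=0.0,
        b=EBT3_TRUTH_B,
        c=EBT3_TRUTH_C,
        covariance=np.zeros((2, 2)),
        response_kind=ResponseKind.NET_DELTA_OD,
        dose_quantity=DoseQuantity.DOSE_TO_WATER,
        valid_dose_range=(0.0, 100.0),
    )


def truth_for_film(film_model: FilmModel | str) -> CalibrationModel:
    return (
        ebt3_truth()
        if FilmModel(film_model) == FilmModel.EBT3
        else xrqa2_truth()
    )


def _truth_response(truth: CalibrationModel, dose: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    denom = 1.0 + truth.b * dose
    if np.any(denom <= 0):
        raise ValueError("dose map crosses the pole of the truth model")
    return (truth.a + truth.c * dose) / denom


def generate_calibration_set(
    doses: Sequence[float] | None = None,
    truth: CalibrationModel | None = None,
    sigma_y: float | Sequence[float] = DEFAULT_CAL_SIGMA_Y,
    n_films: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CalibrationPoint], CalibrationModel]:
    """Noisy calibration triples from a truth model.

    y_i = truth(x_i) + Normal(0, sigma_y_i); each dose is measured on
    ``n_films`` film pieces. Returns (points, truth) — ground truth rides
    along so fits can be checked against it.
    """
    if truth is None:
        truth = xrqa2_truth()
    if doses is None:
        doses = (
            XRQA2_CAL_DOSES
            if truth.response_kind == ResponseKind.NET_DELTA_R
            else EBT3_CAL_DOSES
        )
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("calibration doses must be nonnegative")
    sig = np.broadcast_to(np.asarray(sigma_y, dtype=float), doses.shape).copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    points = []
    for _ in range(n_films):
        y_true = _truth_response(truth, doses)
        y = y_true + rng.normal(0.0, 1.0, size=doses.shape) * sig
        points.extend(
            CalibrationPoint(float(x), float(v), float(s))
            for x, v, s in zip(doses, y, sig)
        )
    return points, truth


@dataclass
class ScannerNoiseModel:
    """Per-pixel Gaussian scanner noise around a uniform unexposed baseline."""

    pv0: float = 52000.0
    sigma_pv: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pv0 <= 65535):
            raise ValueError("pv0 must lie in [0, 65535]")
        if self.sigma_pv < 0:
            raise ValueError("sigma_pv must be nonnegative")


def generate_scan_pair(
    dose_map: np.ndarray,
    truth: CalibrationModel,
    noise: ScannerNoiseModel | None = None,
    film_model: FilmModel | str = FilmModel.XRQA2,
    rng: np.random.Generator | None = None,
    resolution_mm_per_px: float = DEFAULT_RESOLUTION_MM_PER_PX,
    lot_id: str = "synthetic-lot",
) -> tuple[FilmScan, FilmScan, dict]:
    """Forward-model a before/after scan pair from a 2D dose map (cGy).

    The programmed response is written into the red channel; green and blue
    carry the unexposed baseline plus noise (diagnostics only). With nonzero
    noise pixel values are rounded to integers (as a scanner digitizes);
    noiseless pairs keep exact float values so round trips are exact.
    Returns (before, after, info) where info holds the ground truth.
    """
    film_model = FilmModel(film_model)
    if noise is None:
        noise = ScannerNoiseModel()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    dose_map = np.asarray(dose_map, dtype=float)
    if dose_map.ndim != 2:
        raise ValueError("dose_map must be a 2D array")
    if np.any(dose_map < 0):
        raise ValueError("dose_map must be nonnegative")

    y = _truth_response(truth, dose_map)
    h, w = dose_map.shape

    def _noisy_plane() -> np.ndarray:
        plane = np.full((h, w), noise.pv0, dtype=float)
        if noise.sigma_pv > 0:
            plane = plane + rng.normal(0.0, noise.sigma_pv, size=(h, w))
        return plane

    before_px = np.stack([_noisy_plane() for _ in range(3)], axis=-1)
    after_px = before_px.copy()
    if film_model == FilmModel.XRQA2:
        delta = PV_FULL_SCALE * y
        if np.any(delta >= noise.pv0):
            raise SaturationError(
                "programmed response exceeds the unexposed baseline "
                f"(max 2^16*y = {delta.max():.0f} >= pv0 = {noise.pv0:.0f})"
            )
        after_px[:, :, 0] = before_px[:, :, 0] - delta
    else:
        after_px[:, :, 0] = before_px[:, :, 0] * np.power(10.0, -y)
    if noise.sigma_pv > 0:
        after_px[:, :, 0] = after_px[:, :, 0] + rng.normal(
            0.0, noise.sigma_pv, size=(h, w)
        )

    n_total = before_px.size + after_px.size
    n_clipped = int((before_px < 0).sum() + (before_px > 65535).sum())
    n_clipped += int((after_px < 0).sum() + (after_px > 65535).sum())
    before_px = np.clip(before_px, 0, 65535)
    after_px = np.clip(after_px, 0, 65535)
    if noise.sigma_pv > 0:
        before_px = np.rint(before_px)
        after_px = np.rint(after_px)

    common = dict(
        resolution_mm_per_px=resolution_mm_per_px,
        film_model=film_model,
        lot_id=lot_id,
    )
    before = FilmScan(pixels=before_px, timepoint=Timepoint.BEFORE, **common)
    after = FilmScan(pixels=after_px, timepoint=Timepoint.AFTER, **common)
    info = {
        "dose_map_cgy": dose_map,
        "response_map": y,
        "truth": truth,
        "clip_fraction": n_clipped / n_total,
        "noise": noise,
    }
    return before, after, info


@dataclass
class DoseMapFixture:
    """Programmed phantom dose distribution for one machine/site.

    Surface endpoints and the profile peak are the fixture's ground truth
    (per reporting unit: per scan, or per 100 image pairs); profile shapes
    between endpoints are fixture-defined piecewise-monotone arcs. The
    vertical axis is positive toward the anterior aspect, the lateral axis
    positive toward the left; ``lateral_offset_mm`` shifts the lateral peak
    off the isocenter the way a treatment iso-shift offsets the phantom
    midplane.
    """

    machine: Machine
    site: Site
    surface_values: dict[Aspect, tuple[float, float]]  # aspect -> (mean, SE) cGy
    profile_peak_cgy: float
    vertical_peak_mm: float
    lateral_offset_mm: float
    half_span_mm: float = 30.0
    ground_truth: str = "programmed-endpoints"

    @property
    def film_model(self) -> FilmModel:
        return (
            FilmModel.EBT3
            if self.machine == Machine.TomoTherapy
            else FilmModel.XRQA2
        )

    def surface_dose(self, aspect: Aspect | str) -> float:
        return self.surface_values[Aspect(aspect)][0]

    def profile(self, axis: str, positions_mm) -> np.ndarray:
        """Programmed dose (cGy) along an axis at positions in
        [-half_span, +half_span] mm."""
        z = np.asarray(positions_mm, dtype=float)
        L = self.half_span_mm
        if axis == "vertical":
            hi_end = self.surface_dose(Aspect.Ant)   # +L side
            lo_end = self.surface_dose(Aspect.Post)  # -L side
            z_pk = self.vertical_peak_mm
        elif axis == "lateral":
            hi_end = self.surface_dose(Aspect.Left)
            lo_end = self.surface_dose(Aspect.Right)
            z_pk = self.lateral_offset_mm
        else:
            raise ValueError(f"unknown profile axis {axis!r}")
        peak = self.profile_peak_cgy
        out = np.empty_like(z)
        left = z <= z_pk
        # two monotone half-cosine arcs meeting at the programmed peak
        t = (z[left] + L) / (z_pk + L)
        out[left] = lo_end + (peak - lo_end) * np.sin(0.5 * np.pi * t) ** 2
        t = (L - z[~left]) / (L - z_pk)
        out[~left] = hi_end + (peak - hi_end) * np.sin(0.5 * np.pi * t) ** 2
        return out

    def strip_dose_map(
        self,
        axis: str,
        resolution_mm_per_px: float = DEFAULT_RESOLUTION_MM_PER_PX,
        width_mm: float = 10.0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(dose_map, column_positions_mm) for a film strip along ``axis``.

        Column j sits at position -half_span + j*resolution; the map is
        constant across the strip width.
        """
        res = resolution_mm_per_px
        n_cols = int(round(2 * self.half_span_mm / res)) + 1
        n_rows = int(round(width_mm / res))
        positions = -self.half_span_mm + res * np.arange(n_cols)
        line = self.profile(axis, positions)
        return np.tile(line, (n_rows, 1)), positions


def _build_fixture(machine: Machine, site: Site, row: dict) -> DoseMapFixture:
    surface = {
        Aspect(k): (float(v[0]), float(v[1])) for k, v in row["surface"].items()
    }
    return DoseMapFixture(
        machine=machine,
        site=site,
        surface_values=surface,
        profile_peak_cgy=float(row["profile_peak_cgy"]),
        vertical_peak_mm=float(row["vertical_peak_mm"]),
        lateral_offset_mm=float(row["lateral_offset_mm"]),
    )


_FIXTURES = _load_json("fixtures.json")["fixtures"]


def make_phantom_fixture(machine: Machine | str, site: Site | str) -> DoseMapFixture:
    """Packaged phantom fixture for a machine/site combination."""
    try:
        machine = Machine(machine)
        site = Site(site)
        row = _FIXTURES[machine.value][site.value]
    except (KeyError, ValueError) as exc:
        raise RegistryError(
            f"no phantom fixture for machine={machine!r} site={site!r}"
        ) from exc
    return _build_fixture(machine, site, row)
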