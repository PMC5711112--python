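"""End-to-end measurement chains tying the pipeline stages together.

Measurement path: paired scans -> ROI statistics -> film response ->
closed-form dose inversion with a delta-method uncertainty budget ->
(kV only) air kerma to dose to water -> per-acquisition scaling ->
triplicate aggregation. The simulate_* helpers run the same chain on
synthetic fixtures, which is how the system is validated end to end.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationModel, DoseQuantity
from .dose_engine import (
    Aspect,
    BeamQuality,
    DosePoint,
    ImagingProtocol,
    Machine,
    Site,
    aggregate_repeats,
    get_protocol,
    mu_en_ratio_water_air,
    per_scan_dose,
)
from .profiles import DoseProfile, ProfileAxis, build_profile
from .response import measure_response
from .scan_io import DEFAULT_ROI_SIDE_MM, Channel, FilmScan
from .synthetic import (
    DoseMapFixture,
    ScannerNoiseModel,
    generate_scan_pair,
    make_phantom_fixture,
    truth_for_film,
)
from .uncertainty import UncertaintyBudget, dose_uncertainty


def measure_point(
    before: FilmScan,
    after: FilmScan,
    center_mm: tuple[float, float],
    calibration: CalibrationModel,
    quality: BeamQuality | None = None,
    side_mm: float = DEFAULT_ROI_SIDE_MM,
    channel: Channel | str = Channel.RED,
    extra_sigma: float = 0.0,
    label: str = "",
    site: Site | None = None,
    aspect: Aspect | None = None,
    position_mm: float | None = None,
) -> tuple[DosePoint, UncertaintyBudget]:
    """Measure dose to water at one ROI from a before/after scan pair.

    The calibration's dose quantity decides the path: air-kerma
    calibrations (XRQA2) are converted to dose to water through the
    beam-quality lookup; dose-to-water calibrations (EBT3) are reported
    directly and ``quality`` is ignored.
    """
    meas = measure_response(
        before, after, center_mm, side_mm, channel, label=label,
        extra_sigma=extra_sigma,
    )
    if meas.response_kind != calibration.response_kind:
        raise ValueError(
            f"calibration reads {calibration.response_kind.value} but the "
            f"film pair produced {meas.response_kind.value}"
        )
    budget = dose_uncertainty(calibration, meas.value, meas.sigma_y)
    dose, sigma = budget.dose, budget.sigma_dose
    if calibration.dose_quantity == DoseQuantity.AIR_KERMA_IN_AIR:
        if quality is None:
            raise ValueError(
                "air-kerma calibration needs a beam quality for the "
                "dose-to-water conversion"
            )
        ratio = mu_en_ratio_water_air(quality.hvl_mm_al)
        dose, sigma = dose * ratio, sigma * ratio
    point = DosePoint(
        dose_cgy=float(dose),
        sigma_cgy=float(sigma),
        position_mm=position_mm,
        aspect=aspect,
        site=site,
        label=label,
    )
    return point, budget


def _fixture_scan_pair(
    fixture: DoseMapFixture,
    protocol: ImagingProtocol,
    dose_map_dw: np.ndarray,
    noise: ScannerNoiseModel | None,
    rng: np.random.Generator | None,
):
    """Forward-model an accumulated exposure of a fixture dose map (dose to
    water, cGy) into a synthetic scan pair."""
    truth = truth_for_film(fixture.film_model)
    if truth.dose_quantity == DoseQuantity.AIR_KERMA_IN_AIR:
        ratio = mu_en_ratio_water_air(protocol.beam_quality.hvl_mm_al)
        map_native = dose_map_dw / ratio  # film sees air kerma in air
    else:
        map_native = dose_map_dw
    return generate_scan_pair(
        map_native, truth, noise, fixture.film_model, rng=rng
    ), truth


def simulate_surface_measurement(
    machine: Machine | str,
    site: Site | str,
    aspect: Aspect | str,
    seed: int | np.random.Generator = 0,
    noise: ScannerNoiseModel | None = None,
    repeat_rel_sd: float = 0.0,
    calibration: CalibrationModel | None = None,
    roi_mm: float = 10.0,
) -> DosePoint:
    """Full synthetic chain for one surface film piece.

    Accumulates the protocol's number of acquisitions at the fixture's
    programmed per-unit surface dose, generates the scan pair, measures the
    central ROI, and scales back to the reporting unit. ``repeat_rel_sd``
    adds a relative repeat-to-repeat dose perturbation (film piece and
    setup variation) before exposure.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fixture = make_phantom_fixture(machine, site)
    protocol = get_protocol(machine, site)
    aspect = Aspect(aspect)
    per_unit = fixture.surface_dose(aspect)
    if repeat_rel_sd > 0:
        per_unit = per_unit * (1.0 + rng.normal(0.0, repeat_rel_sd))
    accumulated = per_unit * protocol.n_acquisitions_measured
    res = 0.2
    n_px = int(round(roi_mm / res))
    dose_map = np.full((n_px, n_px), accumulated)
    (before, after, _), truth = _fixture_scan_pair(
        fixture, protocol, dose_map, noise, rng
    )
    cal = calibration if calibration is not None else truth
    center = (roi_mm / 2.0, roi_mm / 2.0)
    point, _ = measure_point(
        before,
        after,
        center,
        cal,
        quality=protocol.beam_quality,
        site=fixture.site,
        aspect=aspect,
        label=f"{fixture.machine.value}/{fixture.site.value}/{aspect.value}",
    )
    scaled = per_scan_dose(point, protocol)
    return scaled


def simulate_triplicate_surface(
    machine: Machine | str,
    site: Site | str,
    aspect: Aspect | str,
    seeds: tuple[int, int, int] = (1, 2, 3),
    repeat_rel_sd: float | None = None,
    noise: ScannerNoiseModel | None = None,
) -> DosePoint:
    """Three repeat surface measurements aggregated to mean +/- SE."""
    from .synthetic import REPEAT_REL_SD

    if repeat_rel_sd is None:
        repeat_rel_sd = REPEAT_REL_SD
    repeats = [
        simulate_surface_measurement(
            machine, site, aspect, seed=s, noise=noise,
            repeat_rel_sd=repeat_rel_sd,
        )
        for s in seeds
    ]
    return aggregate_repeats(repeats)


def simulate_profile_measurement(
    machine: Machine | str,
    site: Site | str,
    axis: ProfileAxis | str = ProfileAxis.vertical,
    seed: int | np.random.Generator = 0,
    noise: ScannerNoiseModel | None = None,
    roi_step_mm: float = 1.0,
    calibration: CalibrationModel | None = None,
) -> tuple[DoseProfile, DoseMapFixture]:
    """Full synthetic chain for one film strip: programmed profile ->
    accumulated scan pair -> ROI grid -> per-unit dose profile."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fixture = make_phantom_fixture(machine, site)
    protocol = get_protocol(machine, site)
    axis = ProfileAxis(axis)
    dose_map_unit, positions = fixture.strip_dose_map(axis.value)
    dose_map = dose_map_unit * protocol.n_acquisitions_measured
    (before, after, _), truth = _fixture_scan_pair(
        fixture, protocol, dose_map, noise, rng
    )
    cal = calibration if calibration is not None else truth
    res = before.resolution_mm_per_px
    width_mm = before.shape_px[0] * res
    half = fixture.half_span_mm
    # ROI centres on a regular grid; edges inset so the ROI stays in bounds
    grid = np.arange(-half + 1.0, half - 1.0 + 1e-9, roi_step_mm)
    samples = []
    for pos in grid:
        x_scan = pos + half  # strip coordinate -> scan coordinate
        point, _ = measure_point(
            before,
            after,
            (x_scan, width_mm / 2.0),
            cal,
            quality=protocol.beam_quality,
            site=fixture.site,
            position_mm=float(pos),
            label=f"{fixture.machine.value}/{fixture.site.value}/{axis.value}",
        )
        samples.append(per_scan_dose(point, protocol))
    return build_profile(samples, axis, site=fixture.site), fixture
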