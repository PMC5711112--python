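"""Film response extraction from paired before/after ROI statistics.

Reflective XRQA2 film is read as the net change in reflectance,

    netDeltaR = (PV_before - PV_after) / 2^16,

and transmission EBT3 film as the net change in optical density,

    netDeltaOD = log10(PV_before / PV_after),

both from red-channel ROI means. One-sigma response uncertainties follow
from the two ROI-mean standard errors (sd/sqrt(n), independent pixels) by
first-order propagation; an optional additive sigma term lets callers fold
in inter-film (lot) variation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import PairingError
from .scan_io import Channel, FilmModel, FilmScan, ROISample, check_pair, sample_roi

#: Normalization of 16-bit pixel values into reflectance units (2^16,
#: matching the reference protocol's convention; differs from 65535 by <0.002%).
PV_FULL_SCALE = 65536.0

_LN10 = math.log(10.0)


class ResponseKind(str, enum.Enum):
    NET_DELTA_R = "net_delta_R"
    NET_DELTA_OD = "net_delta_OD"


#: Which response a film model is read with.
RESPONSE_FOR_FILM = {
    FilmModel.XRQA2: ResponseKind.NET_DELTA_R,
    FilmModel.EBT3: ResponseKind.NET_DELTA_OD,
}


@dataclass
class ResponseMeasurement:
    """A film response value y with its one-sigma uncertainty."""

    response_kind: ResponseKind
    value: float
    sigma_y: float
    before: ROISample
    after: ROISample
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be nonnegative")


def net_delta_R(
    before: ROISample,
    after: ROISample,
    label: str = "",
    extra_sigma: float = 0.0,
) -> ResponseMeasurement:
    """Net change in reflectance for XRQA2 film.

    value = (mean_before - mean_after) / 2^16; the uncertainty combines the
    two ROI-mean standard errors in quadrature.
    """
    value = (before.mean_pv - after.mean_pv) / PV_FULL_SCALE
    var = (before.sd_pv**2 / before.n_px + after.sd_pv**2 / after.n_px) / (
        PV_FULL_SCALE**2
    )
    sigma = math.sqrt(var + extra_sigma**2)
    return ResponseMeasurement(
        ResponseKind.NET_DELTA_R, value, sigma, before, after, label
    )


def net_delta_OD(
    before: ROISample,
    after: ROISample,
    label: str = "",
    extra_sigma: float = 0.0,
) -> ResponseMeasurement:
    """Net change in optical density for EBT3 film.

    value = log10(mean_before / mean_after); first-order propagation of the
    two ROI-mean standard errors through the log ratio.
    """
    if after.mean_pv <= 0:
        raise ValueError("after-exposure ROI mean must be strictly positive")
    if before.mean_pv <= 0:
        raise ValueError("before-exposure ROI mean must be strictly positive")
    value = math.log10(before.mean_pv / after.mean_pv)
    var = (
        (before.sd_pv / (math.sqrt(before.n_px) * before.mean_pv)) ** 2
        + (after.sd_pv / (math.sqrt(after.n_px) * after.mean_pv)) ** 2
    ) / _LN10**2
    sigma = math.sqrt(var + extra_sigma**2)
    return ResponseMeasurement(
        ResponseKind.NET_DELTA_OD, value, sigma, before, after, label
    )


def measure_response(
    before_scan: FilmScan,
    after_scan: FilmScan,
    center_mm: tuple[float, float],
    side_mm: float = 1.0,
    channel: Channel | str = Channel.RED,
    label: str = "",
    extra_sigma: float = 0.0,
) -> ResponseMeasurement:
    """Sample the same ROI on a validated before/after pair and convert to
    the response appropriate for the pair's film model."""
    check_pair(before_scan, after_scan)
    b = sample_roi(before_scan, channel, center_mm, side_mm)
    a = sample_roi(after_scan, channel, center_mm, side_mm)
    if before_scan.film_model == FilmModel.XRQA2:
        return net_delta_R(b, a, label=label, extra_sigma=extra_sigma)
    return net_delta_OD(b, a, label=label, extra_sigma=extra_sigma)


def response_for_film(film_model: FilmModel | str) -> ResponseKind:
    return RESPONSE_FOR_FILM[FilmModel(film_model)]


def check_kind_matches_film(kind: ResponseKind, film_model: FilmModel) -> None:
    if RESPONSE_FOR_FILM[film_model] != kind:
        raise PairingError(
            f"{film_model.value} film must be read as "
            f"{RESPONSE_FOR_FILM[film_model].value}, not {kind.value}"
        )
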