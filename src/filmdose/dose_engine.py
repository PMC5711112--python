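"""Dose conversion, per-scan scaling, and repeat aggregation.

kV film measurements are calibrated in air kerma in air; the clinical
quantity is dose to water at the phantom surface. Following the TG-61
in-air method the conversion is a single multiplication by the
spectrum-averaged water-to-air mass-energy-absorption-coefficient ratio,
looked up by beam quality (first HVL in mm Al). Over the beam qualities
used here (4.9-7.7 mm Al) the packaged ratios vary by less than 1%, which
bounds the conversion's contribution to the dosimetry error. MV (MVCT)
measurements use EBT3 film calibrated directly in dose to water, so no
conversion factor applies on that path.

Exposures are accumulated over several identical acquisitions to beat the
film's noise floor and scaled back to a single acquisition (five CBCT or
MVCT scans; CyberKnife doses are reported per 100 image pairs as acquired).
All measurements are repeated in triplicate and pooled to mean +/- standard
error.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .errors import AggregationError, BeamQualityError, RegistryError


class Machine(str, enum.Enum):
    OBI_21eX = "OBI_21eX"
    OBI_TrueBeam = "OBI_TrueBeam"
    CyberKnife = "CyberKnife"
    TomoTherapy = "TomoTherapy"


class Site(str, enum.Enum):
    head = "head"
    thorax = "thorax"
    pelvis = "pelvis"


class Aspect(str, enum.Enum):
    Ant = "Ant"
    Post = "Post"
    Left = "Left"
    Right = "Right"


@dataclass(frozen=True)
class BeamQuality:
    modality: str  # "kV" or "MV"
    kvp: int | None = None
    hvl_mm_al: float | None = None
    mv_nominal: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.modality == "kV":
            if self.kvp is None or not (40 <= self.kvp <= 150):
                raise ValueError("kV quality requires kvp in [40, 150]")
            if self.hvl_mm_al is None or self.hvl_mm_al <= 0:
                raise ValueError("kV quality requires hvl_mm_al > 0")
        elif self.modality != "MV":
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class ImagingProtocol:
    machine: Machine
    site: Site
    technique: str
    beam_quality: BeamQuality
    mAs_or_MU: float
    n_acquisitions_measured: int
    reporting_unit: str

    def __post_init__(self) -> None:
        if self.n_acquisitions_measured < 1:
            raise ValueError("n_acquisitions_measured must be >= 1")


@dataclass
class DosePoint:
    """Dose to water in cGy with one-sigma uncertainty; either a surface
    point (aspect set) or a profile point (position set)."""

    dose_cgy: float
    sigma_cgy: float = 0.0
    position_mm: float | None = None
    aspect: Aspect | None = None
    site: Site | None = None
    protocol: ImagingProtocol | None = None
    label: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        if self.sigma_cgy < 0:
            raise ValueError("sigma_cgy must be nonnegative")
        if self.aspect is not None:
            self.aspect = Aspect(self.aspect)
        if self.site is not None:
            self.site = Site(self.site)


def _load_json(name: str) -> dict:
    with resources.files("filmdose.data").joinpath(name).open() as fh:
        return json.load(fh)


_MUEN = _load_json("muen_ratio_hvl_al.json")
_HVL_GRID = np.asarray(_MUEN["hvl_mm_al"], dtype=float)
_RATIO_GRID = np.asarray(_MUEN["ratio_water_air"], dtype=float)


def mu_en_ratio_water_air(hvl_mm_al: float) -> float:
    """Water/air mass-energy-absorption ratio (free in air) at an HVL."""
    if not (_HVL_GRID[0] <= hvl_mm_al <= _HVL_GRID[-1]):
        raise BeamQualityError(
            f"HVL {hvl_mm_al} mm Al outside the packaged table range "
            f"[{_HVL_GRID[0]}, {_HVL_GRID[-1]}]"
        )
    return float(np.interp(hvl_mm_al, _HVL_GRID, _RATIO_GRID))


def air_kerma_to_dose_water(kerma_cgy: float, quality: BeamQuality) -> float:
    """Convert air kerma in air to dose to water at the surface (kV only)."""
    if quality.modality != "kV":
        raise BeamQualityError(
            "mass-energy-absorption conversion applies to kV beams only; "
            "EBT3/MV measurements are calibrated directly in dose to water"
        )
    if kerma_cgy < 0:
        raise ValueError("air kerma must be nonnegative")
    return kerma_cgy * mu_en_ratio_water_air(quality.hvl_mm_al)


def _build_registry() -> dict[tuple[Machine, Site], ImagingProtocol]:
    payload = _load_json("protocols.json")
    registry = {}
    for row in payload["protocols"]:
        quality = BeamQuality(
            modality=row["modality"],
            kvp=row.get("kvp"),
            hvl_mm_al=row.get("hvl_mm_al"),
            mv_nominal=row.get("mv_nominal"),
            label=f"{row['machine']}/{row['site']}",
        )
        proto = ImagingProtocol(
            machine=Machine(row["machine"]),
            site=Site(row["site"]),
            technique=row["technique"],
            beam_quality=quality,
            mAs_or_MU=float(row["mAs_or_MU"]),
            n_acquisitions_measured=int(row["n_acquisitions_measured"]),
            reporting_unit=row["reporting_unit"],
        )
        registry[(proto.machine, proto.site)] = proto
    return registry


PROTOCOL_REGISTRY = _build_registry()


def get_protocol(machine: Machine | str, site: Site | str) -> ImagingProtocol:
    try:
        return PROTOCOL_REGISTRY[(Machine(machine), Site(site))]
    except (KeyError, ValueError) as exc:
        raise RegistryError(f"no protocol for machine={machine!r} site={site!r}") from exc


def per_scan_dose(total: DosePoint, protocol: ImagingProtocol) -> DosePoint:
    """Scale an accumulated measurement to the protocol's reporting unit.

    CBCT/MVCT protocols divide by the number of acquisitions performed
    (five); CyberKnife measurements are already per 100 image pairs
    (divisor one) and are only relabelled.
    """
    n = protocol.n_acquisitions_measured
    return replace(
        total,
        dose_cgy=total.dose_cgy / n,
        sigma_cgy=total.sigma_cgy / n,
        protocol=protocol,
        unit=protocol.reporting_unit,
    )


def aggregate_repeats(values: list[DosePoint]) -> DosePoint:
    """Pool repeat measurements: mean dose, sigma = sample SD / sqrt(n)."""
    if len(values) < 2:
        raise AggregationError("need at least two repeats to aggregate")
    labels = {v.label for v in values}
    protocols = {id(v.protocol) if v.protocol is None else
                 (v.protocol.machine, v.protocol.site) for v in values}
    if len(labels) > 1 or len(protocols) > 1:
        raise AggregationError(
            f"cannot pool repeats with mixed labels/protocols: {sorted(labels)}"
        )
    doses = np.array([v.dose_cgy for v in values], dtype=float)
    se = float(doses.std(ddof=1) / np.sqrt(len(doses)))
    return replace(values[0], dose_cgy=float(doses.mean()), sigma_cgy=se)
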