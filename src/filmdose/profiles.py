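"""Dose profiles and the surface-dose comparison report.

Film strips inserted between phantom slabs give 1D dose profiles along a
lateral or vertical axis; taped surface pieces give per-aspect surface
doses. Positions are millimetres from the machine isocenter projected onto
the strip (the phantom midplane is generally offset from the isocenter by
the treatment iso-shift, which is what skews lateral profiles). Sign
convention: positive positions are the anterior (vertical axis) or left
(lateral axis) side.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .dose_engine import Aspect, DosePoint, Machine, Site
from .errors import ProfileError


class ProfileAxis(str, enum.Enum):
    lateral = "lateral"
    vertical = "vertical"


@dataclass
class DoseProfile:
    axis: ProfileAxis
    points: list[DosePoint]
    site: Site | None = None
    origin: str = "isocenter projection"

    def __post_init__(self) -> None:
        self.axis = ProfileAxis(self.axis)
        if len(self.points) < 2:
            raise ProfileError("a profile needs at least two points")
        pos = self.positions
        if not np.all(np.diff(pos) > 0):
            raise ProfileError("profile positions must be strictly increasing")
        if any(p.dose_cgy < 0 for p in self.points):
            raise ProfileError("profile doses must be nonnegative")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position_mm for p in self.points], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose_cgy for p in self.points], dtype=float)


def build_profile(
    samples: list[DosePoint], axis: ProfileAxis | str, site: Site | str | None = None
) -> DoseProfile:
    """Sort dose points by position into a profile; duplicates are an error."""
    if any(p.position_mm is None for p in samples):
        raise ProfileError("every profile sample needs a position_mm")
    positions = [p.position_mm for p in samples]
    if len(set(positions)) != len(positions):
        raise ProfileError("duplicate positions in profile samples")
    ordered = sorted(samples, key=lambda p: p.position_mm)
    return DoseProfile(
        axis=ProfileAxis(axis),
        points=ordered,
        site=Site(site) if site is not None else None,
    )


def profile_extrema(profile: DoseProfile) -> tuple[DosePoint, DosePoint]:
    """(min, max) dose points; ties broken by the smallest position."""
    doses = profile.doses
    # points are position-sorted, so argmin/argmax pick the smallest position
    return profile.points[int(np.argmin(doses))], profile.points[int(np.argmax(doses))]


def asymmetry_summary(profile: DoseProfile) -> float:
    """Signed asymmetry: (mean dose at positive positions - mean at
    negative) / overall mean. Positive means anterior/left excess."""
    pos = profile.positions
    doses = profile.doses
    if pos.min() >= 0 or pos.max() <= 0:
        raise ProfileError("profile must span both sides of the origin")
    mean_pos = doses[pos > 0].mean()
    mean_neg = doses[pos < 0].mean()
    return float((mean_pos - mean_neg) / doses.mean())


def format_cell(mean: float, se: float) -> str:
    """Render 'mean±SE' with two decimals, rounding half away from zero."""
    q = Decimal("0.01")
    m = Decimal(repr(float(mean))).quantize(q, rounding=ROUND_HALF_UP)
    s = Decimal(repr(float(se))).quantize(q, rounding=ROUND_HALF_UP)
    return f"{m}±{s}"


def parse_cell(cell: str) -> tuple[float, float]:
    mean, se = cell.split("±")
    return float(mean), float(se)


_SITES = [Site.head, Site.thorax, Site.pelvis]
_ASPECTS = [Aspect.Ant, Aspect.Post, Aspect.Left, Aspect.Right]
_MACHINES = [Machine.OBI_21eX, Machine.OBI_TrueBeam, Machine.CyberKnife,
             Machine.TomoTherapy]


def surface_dose_table(points: list[DosePoint]) -> pd.DataFrame:
    """Surface-dose comparison table: (site, aspect) rows by machine columns,
    cells formatted 'mean±SE' to two decimals. Expects one aggregated point
    per (machine, site, aspect); missing cells are left blank with a warning.
    """
    cells: dict[tuple[Site, Aspect], dict[Machine, str]] = {}
    for p in points:
        if p.aspect is None or p.site is None or p.protocol is None:
            raise ValueError("surface points need aspect, site and protocol")
        key = (p.site, p.aspect)
        machine = p.protocol.machine
        if machine in cells.get(key, {}):
            raise ValueError(f"duplicate surface point for {machine} {key}")
        cells.setdefault(key, {})[machine] = format_cell(p.dose_cgy, p.sigma_cgy)

    index = pd.MultiIndex.from_product(
        [[s.value for s in _SITES], [a.value for a in _ASPECTS]],
        names=["site", "aspect"],
    )
    table = pd.DataFrame("", index=index, columns=[m.value for m in _MACHINES])
    for (site, aspect), by_machine in cells.items():
        for machine, text in by_machine.items():
            table.loc[(site.value, aspect.value), machine.value] = text
    n_blank = int((table == "").sum().sum())
    if n_blank:
        warnings.warn(
            f"surface-dose table has {n_blank} empty cells (missing aspects)",
            UserWarning,
            stacklevel=2,
        )
    return table


def render_surface_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of the surface-dose table (cGy)."""
    lines = ["Surface dose [cGy]", ""]
    header = f"{'':>8}{'':>7}" + "".join(f"{m:>15}" for m in table.columns)
    lines.append(header)
    prev_site = None
    for (site, aspect), row in table.iterrows():
        site_txt = site if site != prev_site else ""
        prev_site = site
        lines.append(
            f"{site_txt:>8}{aspect:>7}" + "".join(f"{v:>15}" for v in row)
        )
    return "\n".join(lines) + "\n"
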