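"""Reading flatbed film scans and sampling ROI pixel statistics.

Films are scanned in 48-bit RGB mode (16 bits per color) at 0.2 mm/pixel;
dose is read from the red channel over small square regions of interest.
Coordinates are in millimetres with the origin at the centre of the top-left
pixel, x increasing rightward (columns) and y downward (rows).
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import PairingError, ROIBoundsError, ScanFormatError

#: Nominal scan resolution used throughout the measurement protocol.
DEFAULT_RESOLUTION_MM_PER_PX = 0.2

#: Default ROI edge length (mm); at 0.2 mm/px this is a 5x5 pixel square.
DEFAULT_ROI_SIDE_MM = 1.0

PV_MAX = 65535.0


class FilmModel(str, enum.Enum):
    XRQA2 = "XRQA2"  # reflective film, kV beams, reads net delta-R
    EBT3 = "EBT3"    # transmission film, MV beams, reads net delta-OD


class Timepoint(str, enum.Enum):
    BEFORE = "before"
    AFTER = "after"


class Channel(str, enum.Enum):
    RED = "red"
    GREEN = "green"
    BLUE = "blue"

    @property
    def index(self) -> int:
        return {"red": 0, "green": 1, "blue": 2}[self.value]


@dataclass
class FilmScan:
    """A single scanner image of a film piece.

    ``pixels`` is an (H, W, 3) float array of raw pixel values in
    [0, 65535]; floats are kept so that noiseless synthetic scans round-trip
    exactly, and quantization to 16-bit integers happens only on file write.
    """

    pixels: np.ndarray
    resolution_mm_per_px: float
    film_model: FilmModel
    timepoint: Timepoint
    lot_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ScanFormatError(
                f"expected an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.resolution_mm_per_px <= 0:
            raise ValueError("resolution_mm_per_px must be strictly positive")
        if self.pixels.min() < 0 or self.pixels.max() > PV_MAX:
            raise ValueError("pixel values must lie in [0, 65535]")
        self.film_model = FilmModel(self.film_model)
        self.timepoint = Timepoint(self.timepoint)

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (width, height) covered by pixel centres, in mm."""
        h, w = self.shape_px
        r = self.resolution_mm_per_px
        return w * r, h * r

    def channel(self, channel: Channel | str) -> np.ndarray:
        return self.pixels[:, :, Channel(channel).index]


@dataclass
class ROISample:
    """Pixel statistics over one square ROI of a single channel."""

    center_mm: tuple[float, float]
    side_mm: float
    mean_pv: float
    sd_pv: float  # population SD over ROI pixels
    n_px: int
    channel: Channel = Channel.RED

    def __post_init__(self) -> None:
        if self.n_px < 1:
            raise ValueError("ROI must contain at least one pixel")
        if not (0.0 <= self.mean_pv <= PV_MAX):
            raise ValueError("mean_pv out of 16-bit range")
        if self.sd_pv < 0:
            raise ValueError("sd_pv must be nonnegative")

    @property
    def sem_pv(self) -> float:
        """Standard error of the ROI mean, sd/sqrt(n) (independent pixels)."""
        return self.sd_pv / np.sqrt(self.n_px)


def load_scan(
    path: str | os.PathLike,
    film_model: FilmModel | str,
    timepoint: Timepoint | str,
    resolution_mm_per_px: float | None = None,
    lot_id: str = "",
) -> FilmScan:
    """Read a 48-bit RGB TIFF scan.

    Resolution is taken from the TIFF metadata when present, otherwise from
    ``resolution_mm_per_px`` (required in that case). Images that are not
    16 bits per sample, or that use a palette, are rejected.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            bits = page.bitspersample
            if isinstance(bits, (tuple, list)):
                bits = bits[0]
            if bits != 16:
                raise ScanFormatError(
                    f"expected 16 bits per sample (48-bit RGB), found {bits}-bit"
                )
            if page.photometric == tifffile.PHOTOMETRIC.PALETTE:
                raise ScanFormatError("palette-color TIFFs are not supported")
            data = page.asarray()
            res = _resolution_from_page(page)
    except (FileNotFoundError, PermissionError):
        raise
    except ScanFormatError:
        raise
    except Exception as exc:  # undecodable file
        raise OSError(f"could not read scan {path!r}: {exc}") from exc

    if data.ndim != 3 or data.shape[2] < 3:
        raise ScanFormatError(
            f"expected an RGB image, got array of shape {data.shape}"
        )
    if res is None:
        res = resolution_mm_per_px
    if res is None:
        raise ValueError(
            "file carries no resolution metadata; pass resolution_mm_per_px"
        )
    return FilmScan(
        pixels=data[:, :, :3].astype(np.float64),
        resolution_mm_per_px=float(res),
        film_model=FilmModel(film_model),
        timepoint=Timepoint(timepoint),
        lot_id=lot_id,
    )


def save_scan(scan: FilmScan, path: str | os.PathLike) -> None:
    """Write a scan as an uncompressed 48-bit RGB TIFF with resolution tags.

    Pixel values are rounded to the nearest integer on write.
    """
    data = np.clip(np.rint(scan.pixels), 0, PV_MAX).astype(np.uint16)
    px_per_cm = 10.0 / scan.resolution_mm_per_px
    tifffile.imwrite(
        path,
        data,
        photometric="rgb",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def _resolution_from_page(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = int(tags["ResolutionUnit"].value)
    px_per_unit = num / den
    if unit == 3:  # pixels per centimetre
        return 10.0 / px_per_unit
    if unit == 2:  # pixels per inch
        return 25.4 / px_per_unit
    return None


def sample_roi(
    scan: FilmScan,
    channel: Channel | str,
    center_mm: tuple[float, float],
    side_mm: float = DEFAULT_ROI_SIDE_MM,
) -> ROISample:
    """Mean/SD of pixel values in an axis-aligned square ROI.

    A pixel belongs to the ROI iff its centre lies in the closed square.
    The ROI must lie fully inside the image; out-of-bounds requests raise
    rather than clip. SD is the population SD over the ROI pixels.
    """
    if side_mm <= 0:
        raise ValueError("side_mm must be positive")
    ch = Channel(channel)
    plane = scan.channel(ch)
    res = scan.resolution_mm_per_px
    cx, cy = center_mm
    half = side_mm / 2.0
    eps = 1e-9  # guard against float jitter at exact pixel-centre boundaries
    lo_col = int(np.ceil((cx - half) / res - eps))
    hi_col = int(np.floor((cx + half) / res + eps))
    lo_row = int(np.ceil((cy - half) / res - eps))
    hi_row = int(np.floor((cy + half) / res + eps))
    n_rows, n_cols = plane.shape
    if lo_col < 0 or lo_row < 0 or hi_col >= n_cols or hi_row >= n_rows:
        raise ROIBoundsError(
            f"ROI centred at {center_mm} mm with side {side_mm} mm exceeds "
            f"the {n_cols}x{n_rows} px scan"
        )
    block = plane[lo_row : hi_row + 1, lo_col : hi_col + 1]
    return ROISample(
        center_mm=(float(cx), float(cy)),
        side_mm=float(side_mm),
        mean_pv=float(block.mean()),
        sd_pv=float(block.std(ddof=0)),
        n_px=int(block.size),
        channel=ch,
    )


def check_pair(before: FilmScan, after: FilmScan) -> None:
    """Validate that two scans form a legitimate before/after pair."""
    if before.timepoint != Timepoint.BEFORE or after.timepoint != Timepoint.AFTER:
        raise PairingError("scans must be a (before, after) pair in that order")
    if before.film_model != after.film_model:
        raise PairingError(
            f"film model mismatch: {before.film_model.value} vs "
            f"{after.film_model.value}"
        )
    if before.lot_id != after.lot_id:
        raise PairingError(f"lot mismatch: {before.lot_id!r} vs {after.lot_id!r}")
    if not np.isclose(before.resolution_mm_per_px, after.resolution_mm_per_px):
        raise PairingError("scan resolution mismatch between before and after")
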