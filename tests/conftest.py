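import numpy as np
import pytest

from filmdose.calibration import (
    CalibrationModel,
    DoseQuantity,
    ModelForm,
)
from filmdose.response import ResponseKind
from filmdose.scan_io import FilmModel, FilmScan, Timepoint


@pytest.fixture
def example_model():
    """Constrained rational model with the reference parameters b=0.2, c=0.1."""
    return CalibrationModel(
        form=ModelForm.CONSTRAINED,
        a=0.0,
        b=0.2,
        c=0.1,
        covariance=np.zeros((2, 2)),
        response_kind=ResponseKind.NET_DELTA_R,
        dose_quantity=DoseQuantity.AIR_KERMA_IN_AIR,
        valid_dose_range=(0.0, 10.0),
    )


@pytest.fixture
def make_scan():
    """Factory for uniform scans: make_scan(pv, shape_px, timepoint, ...)."""

    def _make(
        pv=40000.0,
        shape=(50, 50),
        timepoint=Timepoint.BEFORE,
        film_model=FilmModel.XRQA2,
        resolution=0.2,
        lot_id="lot-1",
    ):
        pixels = np.full((*shape, 3), float(pv))
        return FilmScan(
            pixels=pixels,
            resolution_mm_per_px=resolution,
            film_model=film_model,
            timepoint=timepoint,
            lot_id=lot_id,
        )

    return _make
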