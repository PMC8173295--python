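"""Shared fixtures: expensive aperture/grid-prediction objects built once."""

import numpy as np
import pytest

from neuroreserve import (HRFModel, SearchGrid, VisualFieldRaster,
                          concatenate_apertures, make_ring_aperture,
                          make_wedge_aperture)
from neuroreserve.prf import CandidatePredictions


@pytest.fixture(scope="session")
def raster1():
    """1-degree raster: coarse enough for fast fits, fine enough for pRFs."""
    return VisualFieldRaster(half_extent=45.0, step=1.0)


@pytest.fixture(scope="session")
def hrf():
    return HRFModel()


@pytest.fixture(scope="session")
def mapping_aperture(raster1):
    """Four wedge cycles followed by four ring cycles (one session's runs)."""
    wedge = make_wedge_aperture(raster1, n_cycles=4)
    ring = make_ring_aperture(raster1, n_cycles=4)
    return concatenate_apertures(wedge, ring)


@pytest.fixture(scope="session")
def candidates(raster1, mapping_aperture, hrf):
    """Precomputed grid predictions shared by every fitting test."""
    grid = SearchGrid.default(raster1)
    return CandidatePredictions(grid, mapping_aperture, hrf)
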