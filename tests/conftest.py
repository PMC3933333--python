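"""Shared fixtures: calibrated phantoms are expensive, so they are built
once per session and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pcstereo import assemble_region
from pcstereo.defaults import (
    REGION_CALIBRATIONS,
    box_region_spec,
    default_region_spec,
    validation_design,
)


@pytest.fixture(scope="session")
def default_phantoms():
    """The four calibrated regions at the published design scale."""
    return {
        name: assemble_region(default_region_spec(name, rng_seed=11 + i))
        for i, name in enumerate(REGION_CALIBRATIONS)
    }


@pytest.fixture(scope="session")
def unbias_phantom():
    """Large box phantom at 300 PC/mm^3 for estimator-unbiasedness checks.

    20 x 20 x 20 mm: chosen so the frame-placement edge effect of the fine
    validation design stays well below the 2% tolerance being tested.
    """
    spec = box_region_spec("phantom", 20000.0, 20000.0, 300.0, rng_seed=7)
    return assemble_region(spec)


@pytest.fixture(scope="session")
def fine_design():
    return validation_design(["phantom", "small"], pitch=800.0,
                             frame_area=1600.0)
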