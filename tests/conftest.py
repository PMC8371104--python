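from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from okcrp import (ConicSurface, OpticalConstants, TreatmentProfile,
                   apply_treatment, sample_grid)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> OpticalConstants:
    return OpticalConstants()


@pytest.fixture(scope="session")
def sphere() -> ConicSurface:
    return ConicSurface(r0=7.8, q=0.0)


@pytest.fixture(scope="session")
def prolate() -> ConicSurface:
    return ConicSurface(r0=7.8, q=-0.25)


@pytest.fixture(scope="session")
def standard_treatment() -> TreatmentProfile:
    """2 D central flattening, 2.5 D annulus at 3 mm, centred."""
    return TreatmentProfile(delta_center=-2.0, annulus_amp=2.5)


@pytest.fixture(scope="session")
def treated_prolate(prolate, standard_treatment):
    return apply_treatment(prolate, standard_treatment)


@pytest.fixture(scope="session")
def noisefree_pair(prolate, treated_prolate):
    """Noise-free baseline/post principal-meridian grids of one subject."""
    pre = sample_grid(prolate, n_meridians=4, map_id="pre", visit="baseline")
    post = sample_grid(treated_prolate, n_meridians=4, map_id="post", visit="post")
    return pre, post
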