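"""Shared fixtures: small, fast simulation configurations."""

import numpy as np
import pytest

from naaquant.simkit import (
    CalciumModel,
    ImagingConfig,
    KineticsConfig,
    NucleusGeometry,
)


@pytest.fixture
def geometry():
    return NucleusGeometry()


@pytest.fixture
def kinetics():
    return KineticsConfig()


@pytest.fixture
def fast_imaging():
    """Shorter movie than the default acquisition, for cheap unit tests."""
    return ImagingConfig(duration_s=90.0, stimulus_time_s=20.0, seed=11)


@pytest.fixture
def calcium_model():
    return CalciumModel()


@pytest.fixture
def rng():
    return np.random.default_rng(123)
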