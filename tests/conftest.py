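"""Shared fixtures: default models, a developed method, printed-table data."""

import numpy as np
import pytest

from synchrofluor.simulate import default_complexed_models, default_models
from synchrofluor.validation import develop_method


@pytest.fixture(scope="session")
def models():
    """(HL-complexed, HM-complexed) — the production analyte pair."""
    return default_complexed_models()


@pytest.fixture(scope="session")
def all_models():
    return default_models()


@pytest.fixture(scope="session")
def setup(models):
    """A developed method: auto-selected wavelengths + noise-free calibrations."""
    return develop_method(models)


# Published worked-example data: (added, found) ng/mL pairs and the printed
# percent recoveries for the synthetic-mixture and spiked-plasma studies.
MIXTURE_TABLE = {
    "HL": [(75.0, 74.29, 99.05), (100.0, 98.24, 98.24), (25.0, 24.85, 99.40)],
    "HM": [(25.0, 24.95, 99.80), (100.0, 99.62, 99.62), (75.0, 74.57, 99.42)],
}
PLASMA_TABLE = {
    "HL": [(67.0, 65.71, 98.07), (120.0, 118.59, 98.82), (200.0, 196.08, 98.04)],
    "HM": [(200.0, 197.08, 98.54), (120.0, 117.55, 97.95), (67.0, 65.99, 98.49)],
}


@pytest.fixture(scope="session")
def mixture_table():
    return MIXTURE_TABLE


@pytest.fixture(scope="session")
def plasma_table():
    return PLASMA_TABLE
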