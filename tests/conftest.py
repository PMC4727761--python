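import numpy as np
import pytest

from ftirquant.spectra_io import ReferenceTable, SpectraSet
from ftirquant.synthetic_data import generate_calibration_set, noiseless_design


@pytest.fixture(scope="session")
def noiseless_set() -> tuple[SpectraSet, ReferenceTable]:
    """A drift-free, scatter-free, noise-free 15-sample calibration set:
    exactly rank 3 after centering (three analyte profiles over a constant
    matrix background)."""
    return generate_calibration_set(noiseless_design(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
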