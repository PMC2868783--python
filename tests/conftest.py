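import pytest

from bilispec import (
    HIGH_PKA,
    LOW_PKA,
    DimerizationModel,
)


@pytest.fixture
def high_pka():
    """Solvent-partition-derived pKa pair (8.12, 8.44)."""
    return HIGH_PKA


@pytest.fixture
def low_pka():
    """Low literature pKa pair (4.2, 4.9) used as a counterfactual."""
    return LOW_PKA


@pytest.fixture
def dimer():
    """Default dianion dimerization model, KD = 0.26 uM^-1."""
    return DimerizationModel()
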