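import hypothesis
import pytest

from gradescreen.compound_io import CompoundRecord

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")

OLAPARIB_SMILES = (
    "C1CC1C(=O)N2CCN(CC2)C(=O)C3=C(C=CC(=C3)CC4=NNC(=O)C5=CC=CC=C54)F"
)


@pytest.fixture
def olaparib() -> CompoundRecord:
    return CompoundRecord("olaparib", "olaparib", OLAPARIB_SMILES)


@pytest.fixture
def ethanol() -> CompoundRecord:
    return CompoundRecord("ethanol", "ethanol", "CCO")


@pytest.fixture
def benzene() -> CompoundRecord:
    return CompoundRecord("benzene", "benzene", "c1ccccc1")
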