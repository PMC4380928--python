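import numpy as np
import pytest

from phosphonet.simulate import SimulationConfig, simulate_study
from phosphonet.types import LinearMotif, ProteinRecord


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default desk-scale configuration."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture()
def pik3r3_motif():
    """The established PIK3R3 recognition motif pY-E-x-M."""
    return LinearMotif("PIK3R3", "pYExM", {+1: {"E"}, +3: {"M"}})


def make_protein(sequence: str, **kwargs) -> ProteinRecord:
    return ProteinRecord(kwargs.pop("protein_id", "P1"), sequence, **kwargs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
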