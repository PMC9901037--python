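import numpy as np
import pytest

from mhcgroove.structure_io import PeptidePositionMap
from mhcgroove.synthetic import make_groove_complex


@pytest.fixture(scope="session")
def groove_fa20():
    """Synthetic stand-in complex: Phe P1, omega -110, gap 54-59, 12 extensions."""
    model, truth = make_groove_complex(
        -110.0, p1_resname="PHE", n_ext=12, missing_ranges=[(54, 59)], name="synthetic_fa20"
    )
    return model, truth


@pytest.fixture(scope="session")
def groove_fa8():
    """Synthetic stand-in complex: Phe P1, omega +96, fully modeled 8mer."""
    model, truth = make_groove_complex(96.0, p1_resname="PHE", name="synthetic_fa8")
    return model, truth


@pytest.fixture
def ring_pair_positions():
    """Position map matching the make_ring_pair topology (P1 on chain P, Tyr59 on H)."""
    return PeptidePositionMap("P", "H", {"P1": 1, "P7": 7})


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
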