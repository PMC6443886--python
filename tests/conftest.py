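import numpy as np
import pytest

from triazofold.foldamer_model import (
    TorsionState,
    build_conformation,
    parse_sequence,
)

HEPTAMER = "Boc-Ala-ValΨ[4Tz]Phe-LeuΨ[4Tz]Phe-LeuΨ[4Tz]Val-OAll"
POLY_ALA = "Boc-Ala-(AlaΨ[4Tz]Ala)6-OAll"


@pytest.fixture(scope="session")
def heptamer():
    return parse_sequence(HEPTAMER)


@pytest.fixture(scope="session")
def poly_ala():
    return parse_sequence(POLY_ALA)


@pytest.fixture(scope="session")
def extended_heptamer(heptamer):
    return build_conformation(
        heptamer, TorsionState.uniform(heptamer, 180.0, 180.0)
    )


def random_torsion_state(topology, rng):
    return TorsionState(
        [
            (r.position_index, float(rng.uniform(-179.9, 180.0)),
             float(rng.uniform(-179.9, 180.0)))
            for r in topology.residues
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
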