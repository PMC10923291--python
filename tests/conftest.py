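import warnings
from fractions import Fraction

import numpy as np
import pytest

from phasesep.stickers import Bead, KdRecord, KdTable, MoleculeTopology, build_energy_matrix
from phasesep.synthetic import make_kd_fixture

# renormalization of the printed move weights (sum 1.02) warns by design;
# keep test output clean
warnings.filterwarnings("ignore", message="move weights sum to")


@pytest.fixture(scope="session")
def kd_table():
    return make_kd_fixture()


@pytest.fixture(scope="session")
def energy_matrix(kd_table):
    return build_energy_matrix(kd_table)


@pytest.fixture(scope="session")
def construct_library():
    from phasesep.stickers import build_construct_library

    return build_construct_library()


def single_sticker(name: str, kind: str) -> MoleculeTopology:
    return MoleculeTopology(name=name, beads=(Bead(kind),), scaling=Fraction(1, 6))


def two_bead(name: str, kind: str) -> MoleculeTopology:
    """Sticker plus one spacer bead."""
    return MoleculeTopology(name=name, beads=(Bead(kind), Bead(None)), scaling=Fraction(1, 6))


@pytest.fixture(scope="session")
def single_pair_energy():
    """Energy matrix with exactly one interacting pair (SH3B-PRM4, 6 uM)."""
    return build_energy_matrix(KdTable([KdRecord(sh3="SH3B", prm="PRM4", kd=6e-6)]))
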