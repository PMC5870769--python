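import numpy as np
import pytest

from helixforge.core import Assembly, Atom, Polymer, Residue
from helixforge.specifications import (ALPHA, CrickParams, build_coiled_coil,
                                       build_helix)


def make_chain(ca_positions, chain_id="A", mol_code="GLY"):
    """Chain of residues with only CA atoms at the given positions."""
    poly = Polymer(id=chain_id)
    for i, xyz in enumerate(ca_positions, start=1):
        poly.add_residue(Residue(mol_code, str(i),
                                 [Atom("CA", xyz, element="C")]))
    return poly


@pytest.fixture
def alpha_helix():
    return build_helix(ALPHA, 18)


@pytest.fixture
def trimer():
    """A parallel coiled-coil trimer (the standard small test assembly)."""
    return build_coiled_coil(CrickParams(
        n_chains=3, superhelix_radius=6.0, pitch=150.0, interface_angle=0.0,
        n_residues=28))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
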