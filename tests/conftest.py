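import numpy as np
import pytest

from polarbind.core import Atom, MolecularSystem
from polarbind.synthetic_data import ToyComplexSpec, make_toy_complex


@pytest.fixture
def toy_complex():
    """Default 5-pair two-chain toy complex."""
    return make_toy_complex(ToyComplexSpec(n_hbond_pairs=5, seed=0))


@pytest.fixture
def small_complex():
    """Smaller 3-pair complex for the heavier pipeline tests."""
    return make_toy_complex(ToyComplexSpec(n_hbond_pairs=3, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_atom(serial, name, element, res_name, res_seq, chain, xyz, **kw):
    """Terse Atom constructor for hand-built fixtures."""
    return Atom(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain,
        coords=np.asarray(xyz, float),
        **kw,
    )


def make_system(atom_specs, bonds=()):
    """Build a MolecularSystem from (name, element, res_name, res_seq, chain, xyz, extra) tuples."""
    atoms = []
    for k, spec in enumerate(atom_specs):
        name, element, res_name, res_seq, chain, xyz = spec[:6]
        extra = spec[6] if len(spec) > 6 else {}
        atoms.append(make_atom(k + 1, name, element, res_name, res_seq, chain, xyz, **extra))
    return MolecularSystem(atoms, bonds=bonds)
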