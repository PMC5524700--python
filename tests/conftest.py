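import numpy as np
import pytest

from gridqsar.ensemble import AtomRecord, Ensemble
from gridqsar.grid import GridSpec, Probe


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def probe():
    return Probe(name="OH", charge=0.4, c6=437.0, c12=318900.0)


def make_ensemble(coords, charges=None, code="X", roles=None,
                  parameterized=True):
    """Build a small ensemble from raw coordinates (n_conf, n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    charges = charges if charges is not None else [0.1] * n_atoms
    roles = roles if roles is not None else ["enzyme"] * n_atoms
    topology = [
        AtomRecord(atom_name=f"A{i}", residue_name="RES", residue_number=i + 1,
                   chain_id="A" if roles[i] == "enzyme" else "S",
                   element="C", role=roles[i], charge=charges[i],
                   c6=500.0, c12=4e5)
        for i in range(n_atoms)
    ]
    return Ensemble(code=code, topology=topology, coords=coords,
                    parameterized=parameterized)


@pytest.fixture
def tiny_ensemble(rng):
    """5 atoms x 3 frames with random finite coordinates."""
    return make_ensemble(rng.normal(scale=2.0, size=(3, 5, 3)),
                         charges=[0.3, -0.2, 0.1, 0.0, -0.4])
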