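import numpy as np
import pytest

from oligoscore.structures import Assembly, Chain, Residue
from oligoscore.synthetic import ComplexSpec, make_complex


@pytest.fixture(scope="session")
def dimer_spec() -> ComplexSpec:
    """A1B1 heterodimer with one 8-contact interface."""
    return ComplexSpec(entities={"A": 30, "B": 24}, interfaces=(("A", "B", 8),),
                       seed=11, id="dimer")


@pytest.fixture(scope="session")
def dimer(dimer_spec) -> Assembly:
    return make_complex(dimer_spec)


@pytest.fixture(scope="session")
def homodimer() -> Assembly:
    spec = ComplexSpec(entities={"A": 20}, copies={"A": 2},
                       interfaces=(("A", "B", 8),), seed=13, id="homodimer")
    return make_complex(spec)


@pytest.fixture(scope="session")
def two_iface_complex() -> Assembly:
    """Four distinct entities with two equal-sized interfaces (A-B, C-D)."""
    spec = ComplexSpec(entities={"A": 20, "B": 20, "C": 20, "D": 20},
                       interfaces=(("A", "B", 8), ("C", "D", 8)),
                       seed=17, id="twoiface")
    return make_complex(spec)


def make_chain(coords, chain_id="A", start=1, name="ALA"):
    """Hand-built CA-only chain from a coordinate list."""
    return Chain(chain_id, [
        Residue(start + i, name, atom_names=["CA"], coords=[c])
        for i, c in enumerate(coords)
    ])


def identity_mapping(assembly: Assembly):
    """(chain_map, residue_maps) mapping an assembly onto itself."""
    chain_map = {c.id: c.id for c in assembly.chains}
    residue_maps = {
        c.id: {r.key: r.key for r in c.residues} for c in assembly.chains
    }
    return chain_map, residue_maps
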