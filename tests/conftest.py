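import numpy as np
import pytest

import fragshift as fs

K = fs.GmfccConfig().coulomb_k_ev_A


def single_atom_chain(n, seed=None, spread=4.0, charges=None):
    """n single-atom residues roughly along x; optionally jittered/charged."""
    rng = np.random.default_rng(seed) if seed is not None else None
    residues = []
    for i in range(1, n + 1):
        pos = np.array([(i - 1) * spread, 0.0, 0.0])
        if rng is not None:
            pos = pos + rng.normal(0, 1.0, 3)
        q = (
            charges[i - 1]
            if charges is not None
            else (float(rng.normal(0, 0.5)) if rng is not None else 1.0)
        )
        residues.append(
            fs.Residue(
                index=i,
                name="GLY",
                atoms=[fs.Atom(serial=i, name="X", element="X", coords=pos, charge=q)],
            )
        )
    return fs.ProteinStructure(residues=residues, label=f"chain{n}")


def brute_coulomb(structure, k=K):
    """Full-system pairwise Coulomb energy — the exactness oracle."""
    atoms = list(structure.iter_atoms())
    total = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            r = np.linalg.norm(atoms[i].coords - atoms[j].coords)
            total += k * atoms[i].charge * atoms[j].charge / r
    return total


@pytest.fixture
def unit_chain():
    """Five unit charges at x = 0, 4, 8, 12, 16 Å (one per residue)."""
    return single_atom_chain(5, charges=[1.0] * 5)


@pytest.fixture
def toy():
    """Default charged toy helix with chromophore at residue 6."""
    structure, charges = fs.make_toy_protein()
    return structure, charges


@pytest.fixture
def toy_structure(toy):
    return toy[0]
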