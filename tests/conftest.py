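"""Shared fixtures and small structure-building helpers."""

import numpy as np
import pytest

from uaatol.structures import Atom, Residue, SiteSelection, Structure, classify_atom
from uaatol.synthetic_data import SynthConfig, make_helix_structure


def build_structure(spec, structure_id="toy"):
    """Build a Structure from [(key, aa_code, [(name, element, xyz), ...])].

    Atom classification goes through ``classify_atom`` so toys obey the
    same backbone/polarity conventions as parsed structures.
    """
    residues = []
    for key, aa_code, atoms in spec:
        atom_objs = []
        for name, element, xyz in atoms:
            is_bb, pol = classify_atom(name, element, aa_code)
            atom_objs.append(
                Atom(
                    name=name,
                    element=element,
                    coords=np.asarray(xyz, dtype=float),
                    residue_key=key,
                    is_backbone=is_bb,
                    polarity=pol,
                )
            )
        residues.append(Residue(key=key, aa_code=aa_code, atoms=atom_objs))
    return Structure(id=structure_id, residues=residues)


def random_toy_structure(rng, n_residues=None, box=12.0):
    """Random unknown-residue toy: clustered heavy atoms, spaced residue ids.

    Residue numbers are spaced by 10 so no peptide-junction exclusions
    apply; intra-residue bonds are inferred from distances by both the
    implementation and the test oracles.
    """
    n_residues = n_residues or rng.integers(2, 8)
    spec = []
    for i in range(n_residues):
        center = rng.uniform(0, box, 3)
        n_atoms = rng.integers(2, 9)
        atoms = []
        for j in range(n_atoms):
            element = rng.choice(["C", "N", "O", "S"], p=[0.6, 0.15, 0.2, 0.05])
            name = f"{element}{j}"
            xyz = center + rng.uniform(-2.5, 2.5, 3)
            atoms.append((name, element, xyz))
        # guarantee a CA so site selections work
        atoms[0] = ("CA", "C", atoms[0][2])
        spec.append((("A", 10 * (i + 1)), "LIG", atoms))
    return build_structure(spec, structure_id="random_toy")


@pytest.fixture(scope="session")
def helix():
    return make_helix_structure(SynthConfig())


@pytest.fixture(scope="session")
def helix_site():
    return SiteSelection(("A", 15))
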