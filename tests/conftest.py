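import numpy as np
import pytest

from mdcons.structure_io import Atom, Frame, ResidueKey


def make_frame(coords_a, coords_b, res_names_a=None, res_names_b=None, index=0):
    """Frame with one single-heavy-atom residue per coordinate row."""
    residues, partner_of = {}, {}
    serial = 1
    for partner, coords, names in (
        ("A", coords_a, res_names_a),
        ("B", coords_b, res_names_b),
    ):
        for i, xyz in enumerate(np.atleast_2d(coords)):
            name = (names[i] if names else "ALA")
            key = ResidueKey(partner, i + 1, "", name)
            residues[key] = [Atom(serial, "CA", "C", np.asarray(xyz, float), True)]
            partner_of[key] = partner
            serial += 1
    return Frame(index=index, residues=residues, partner_of=partner_of)


def random_two_partner_frame(rng, n_a=15, n_b=15, atoms_per_res=3, box=20.0):
    """Random cloud of multi-atom residues split between two partners."""
    residues, partner_of = {}, {}
    serial = 1
    for partner, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            center = rng.uniform(0, box, 3)
            atoms = []
            for _ in range(atoms_per_res):
                xyz = center + rng.normal(0, 1.0, 3)
                atoms.append(Atom(serial, "CA", "C", xyz, True))
                serial += 1
            key = ResidueKey(partner, i + 1, "", "ALA")
            residues[key] = atoms
            partner_of[key] = partner
    return Frame(index=0, residues=residues, partner_of=partner_of)


@pytest.fixture
def rng():
    return np.random.default_rng(20140506)
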