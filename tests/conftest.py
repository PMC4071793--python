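"""Shared fixtures: hand-built mini structures and a reference triad template."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from funcsite.site import FUNCTIONAL_ATOMS, extract_template
from funcsite.structure import Atom, Residue, Structure

# A small hand-written PDB exercising altlocs, hetero groups, waters,
# a selenomethionine and a CRYST1 record.
MINI_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 21 21 21    4
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.633   7.208  -4.935  1.00 10.00           C
ATOM      4  CA AGLY A   2      13.905   6.951  -4.198  0.60 12.00           C
ATOM      5  CA BGLY A   2      13.805   6.851  -4.098  0.40 12.00           C
ATOM      6  CA  MSE A   3      15.000   7.500  -3.000  1.00 11.00          SE
HETATM    7  C1  GOL A 101      20.000   5.000  -2.000  1.00 20.00           C
HETATM    8  O   HOH A 201      25.000   5.000  -2.000  1.00 30.00           O
HETATM    9  O   HOH A 202      26.000   6.000  -1.000  1.00 30.00           O
END
"""


def carboxylate(center: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Idealised planar carboxylate group (C, O1, O2) at a given pose."""
    base = np.array([[0.0, 0.0, 0.0], [1.10, 0.60, 0.0], [1.10, -0.60, 0.0]])
    return base @ rot.T + center


def make_triad_structure() -> Structure:
    """Three acidic residues (Asp, Asp, Glu) with full carboxylate groups in
    a fixed, asymmetric constellation."""
    struct = Structure(id="triad-src")
    poses = [("ASP", np.array([0.0, 0.0, 0.0])),
             ("ASP", np.array([5.0, 1.0, 2.0])),
             ("GLU", np.array([3.0, 6.0, -1.0]))]
    for i, (name, centre) in enumerate(poses):
        rot = Rotation.from_euler("xyz", [30 * i, 45 + 20 * i, 10 * i],
                                  degrees=True).as_matrix()
        coords = carboxylate(centre, rot)
        names = FUNCTIONAL_ATOMS[name]
        atoms = [Atom(name=n, element=n[0], coords=c)
                 for n, c in zip(names, coords)]
        atoms.append(Atom(name="CA", element="C", coords=centre + [0, 0, 2.5]))
        struct.add_residue("A", Residue(name=name, number=10 + i, atoms=atoms))
    return struct


@pytest.fixture(scope="session")
def triad_structure() -> Structure:
    return make_triad_structure()


@pytest.fixture(scope="session")
def triad_template(triad_structure):
    return extract_template(
        triad_structure, [("A", 10, ""), ("A", 11, ""), ("A", 12, "")])


@pytest.fixture(scope="session")
def mini_pdb_text() -> str:
    return MINI_PDB


def oracle_hit_rmsd(truth, template, hit) -> float:
    """Independent superposition oracle for a template hit on planted data.

    Re-evaluates the hit's reported member->residue correspondence by direct
    Kabsch fits of the planted (ground-truth) functional-atom coordinates
    against the template, minimising only over the chemically symmetric
    carboxylate-oxygen swaps."""
    import itertools

    from funcsite.geometry import kabsch_superpose

    coords = np.asarray(truth.payload["coords"])
    groups = {key: coords[3 * i:3 * i + 3]
              for i, key in enumerate(truth.payload["residues"])}
    query = np.vstack([groups[hit.correspondence[m]]
                       for m in range(len(template.members))])
    best = np.inf
    swap_sets = [[(0, 1, 2), (0, 2, 1)]] * len(template.members)
    for swaps in itertools.product(*swap_sets):
        tmpl = np.vstack([np.asarray(mem.coords)[list(sw)]
                          for mem, sw in zip(template.members, swaps)])
        best = min(best, kabsch_superpose(query, tmpl).rmsd)
    return best


def make_buried_atom(res_name: str = "ALA") -> Structure:
    """A single atom tightly caged by a dense pseudo-atom sphere at 3 A, so
    no probe position around the central atom is solvent-accessible."""
    from funcsite.geometry import _golden_spiral

    struct = Structure(id="cage")
    struct.add_residue("B", Residue(name=res_name, number=1, atoms=[
        Atom(name="CA", element="C", coords=np.zeros(3))]))
    for i, xyz in enumerate(_golden_spiral(150) * 3.0, start=1):
        struct.add_residue("A", Residue(name="UNK", number=i, kind="polymer",
                                        atoms=[Atom(name="CA", element="C",
                                                    coords=xyz)]))
    return struct
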