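"""Shared fixtures: small synthetic structures and hand-written PDB texts."""

import numpy as np
import pytest

from memstab.fixtures import HelixSpec, build_dimer, build_helix
from memstab.structures import Atom, Residue, Structure

HELIX_SEQ = "AVILGFWSTYKLMCARDENQAVILGFWSTY"


@pytest.fixture(scope="session")
def helix():
    return build_helix(HelixSpec(HELIX_SEQ))


@pytest.fixture(scope="session")
def dimer():
    return build_dimer(
        HelixSpec("AVILGFWSTYKLMCARDENQ"), HelixSpec("LIVFAWGYSMTPHKRCQEND"), offset=9.0
    )


def make_residue(chain, number, aa3, aa1, atom_spec):
    """atom_spec: list of (name, element, (x, y, z))."""
    res = Residue(chain=chain, number=number, insertion_code=" ", aa3=aa3, aa1=aa1)
    for i, (name, element, xyz) in enumerate(atom_spec):
        res.atoms.append(
            Atom(
                serial=i + 1,
                name=name,
                element=element,
                residue_key=(chain, number, " "),
                coords=np.array(xyz, dtype=float),
                is_sidechain=name not in ("N", "CA", "C", "O"),
            )
        )
    return res


def make_structure(residues, structure_id="fixture"):
    chains = {}
    for res in residues:
        chains.setdefault(res.chain, []).append(res)
    return Structure(id=structure_id, chains=chains)


@pytest.fixture
def salt_bridge_structure():
    """ASP and LYS placed so OD1···NZ = 3.4 Å (ionic by construction)."""
    asp = make_residue(
        "A", 10, "ASP", "D",
        [
            ("N", "N", (0.0, 3.0, 0.0)),
            ("CA", "C", (0.0, 1.6, 0.0)),
            ("C", "C", (1.2, 0.8, 0.0)),
            ("O", "O", (2.3, 1.3, 0.0)),
            ("CB", "C", (-1.2, 0.8, 0.0)),
            ("CG", "C", (-1.2, -0.7, 0.0)),
            ("OD1", "O", (0.0, -1.4, 0.0)),
            ("OD2", "O", (-2.3, -1.3, 0.0)),
        ],
    )
    lys = make_residue(
        "A", 30, "LYS", "K",
        [
            ("N", "N", (3.4, -4.9, 0.0)),
            ("CA", "C", (2.4, -3.9, 0.0)),
            ("C", "C", (3.0, -2.6, 0.0)),
            ("O", "O", (4.2, -2.4, 0.0)),
            ("CB", "C", (1.2, -4.2, 0.9)),
            ("NZ", "N", (0.0, -4.8, 0.0)),  # 3.4 Å from OD1
        ],
    )
    return make_structure([asp, lys])


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   3.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   1.600   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.200   0.800   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.300   1.300   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -1.200   0.800   0.500  1.00  0.00           C
ATOM      6  N   GLY A   2       1.200  -0.500   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       2.300  -1.400   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       3.600  -0.800   0.500  1.00  0.00           C
ATOM      9  O   GLY A   2       3.700   0.400   0.700  1.00  0.00           O
ATOM     10  N   SER A   3       4.600  -1.600   0.700  1.00  0.00           N
ATOM     11  CA  SER A   3       5.900  -1.200   1.200  1.00  0.00           C
ATOM     12  C   SER A   3       6.900  -2.300   1.000  1.00  0.00           C
ATOM     13  O   SER A   3       6.700  -3.400   0.500  1.00  0.00           O
ATOM     14  CB  SER A   3       6.400   0.100   0.600  1.00  0.00           C
ATOM     15  OG  SER A   3       5.600   1.200   1.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.200   1.600   0.000  1.00  0.00           O
ATOM      5  CB AALA A   1       2.000  -0.800   1.200  0.60  0.00           C
ATOM      6  CB BALA A   1       2.100  -0.900   1.300  0.40  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.200   1.600   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       9.000   9.000   9.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      10.458   9.000   9.000  1.00  0.00           C
ATOM      3  C   ALA A   1      11.000  10.400   9.000  1.00  0.00           C
ATOM      4  O   ALA A   1      12.200  10.600   9.000  1.00  0.00           O
ENDMDL
END
"""

# a complete lysine (all heavy atoms) at arbitrary but valid coordinates
COMPLETE_LYS_PDB = """\
ATOM      1  N   LYS A   7       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  LYS A   7       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   LYS A   7       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   LYS A   7       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  LYS A   7       2.000  -0.760   1.220  1.00  0.00           C
ATOM      6  CG  LYS A   7       3.520  -0.880   1.280  1.00  0.00           C
ATOM      7  CD  LYS A   7       4.020  -1.650   2.500  1.00  0.00           C
ATOM      8  CE  LYS A   7       5.540  -1.770   2.560  1.00  0.00           C
ATOM      9  NZ  LYS A   7       6.040  -2.520   3.740  1.00  0.00           N
END
"""
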