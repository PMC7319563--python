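"""Protein structure model, PDB I/O and residue-environment geometry.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
collection of chains, each an ordered list of :class:`Residue` objects holding
:class:`Atom` records with coordinates in Å.  Parsing is delegated to
Biopython's ``Bio.PDB`` (first model only, ``ATOM`` records only, alternate
locations resolved to the highest-occupancy conformer); serialisation writes
the wwPDB v3.3 fixed-column dialect so that fixtures round-trip.

Two diagnostics used to characterise residue environments are provided:
numeric Shrake–Rupley solvent-accessible surface area and residue depth
(mean distance of a residue's atoms to the nearest solvent-exposed atom).
In membrane proteins neither correlates well with mutation effects — which
is precisely why the feature set is built from graph-based signatures
instead — but both remain useful sanity checks on input structures.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBFormatError",
    "ResidueNotFoundError",
    "read_pdb",
    "write_pdb",
    "get_environment",
    "compute_atom_sasa",
    "solvent_accessibility",
    "residue_depth",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "GXG_REFERENCE_AREA",
]

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: van der Waals radii (Å) used for SASA; single shipped element map.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW_RADIUS = 1.80

#: Gly-X-Gly tripeptide reference accessible areas (Å²), Tien et al. (2013)
#: theoretical values, used to express SASA as a relative fraction.
GXG_REFERENCE_AREA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class PDBFormatError(ValueError):
    """Raised when a PDB stream cannot be parsed."""


class ResidueNotFoundError(LookupError):
    """Raised when a residue key does not resolve in a structure."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_key: tuple  # (chain id, residue number, insertion code)
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_sidechain: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name} has non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name} has an empty element symbol")
        self.occupancy = float(min(max(self.occupancy, 0.0), 1.0))

    def vdw_radius(self) -> float:
        r = VDW_RADII.get(self.element.upper())
        if r is None:
            warnings.warn(
                f"no van der Waals radius for element {self.element!r}; "
                f"using default {DEFAULT_VDW_RADIUS} Å",
                stacklevel=2,
            )
            return DEFAULT_VDW_RADIUS
        return r


@dataclass
class Residue:
    chain: str
    number: int
    insertion_code: str
    aa3: str
    aa1: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chain, self.number, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain}{self.number} has no atom {name!r}")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    heteroatoms_excluded: bool = True

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [(r.number, r.insertion_code) for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue keys in chain {cid}")

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def residue(self, chain: str, number: int, insertion_code: str = " ") -> Residue:
        if chain not in self.chains:
            raise ResidueNotFoundError(f"chain {chain!r} not found in structure {self.id}")
        for res in self.chains[chain]:
            if res.number == number and res.insertion_code == insertion_code:
                return res
        raise ResidueNotFoundError(
            f"residue {number}{insertion_code.strip()} not found in chain {chain} of {self.id}"
        )

    def chain_sequence(self, chain: str) -> str:
        if chain not in self.chains:
            raise ResidueNotFoundError(f"chain {chain!r} not found in structure {self.id}")
        return "".join(r.aa1 for r in self.chains[chain])


def _resolve_key(key) -> tuple:
    """Accept (chain, number) or (chain, number, icode)."""
    if len(key) == 2:
        return (key[0], int(key[1]), " ")
    return (key[0], int(key[1]), key[2])


def read_pdb(source: str | bytes | IO, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL and ``ATOM`` records are retained; waters and other
    HETATM entries are excluded.  Alternate locations collapse to the
    highest-occupancy conformer (ties keep the first encountered, i.e.
    altloc 'A' in a conforming file).

    ``source`` may be a filesystem path, PDB text, bytes, or an open handle.
    """
    text = _as_text(source)
    if "ATOM" not in text:
        raise PDBFormatError("no ATOM records found in PDB input")
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio = parser.get_structure(structure_id, io.StringIO(text))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBFormatError(_format_error(text, exc)) from exc

    models = list(bio.get_models())
    if not models:
        raise PDBFormatError("PDB input contains no models")
    model = models[0]

    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resnum, icode = bio_res.id
            if hetflag != " ":
                continue  # HETATM / waters excluded
            aa3 = bio_res.get_resname().strip()
            res = Residue(
                chain=bio_chain.id,
                number=resnum,
                insertion_code=icode,
                aa3=aa3,
                aa1=AA3_TO_AA1.get(aa3, "X"),
            )
            for bio_atom in bio_res:
                # disordered atoms: Bio.PDB's selected child is the
                # highest-occupancy altloc, matching our policy
                name = bio_atom.get_name()
                element = (bio_atom.element or name[:1]).strip().upper()
                if element == "H":
                    continue
                res.atoms.append(
                    Atom(
                        serial=bio_atom.get_serial_number() or 0,
                        name=name,
                        element=element,
                        residue_key=(bio_chain.id, resnum, icode),
                        coords=np.array(bio_atom.get_coord(), dtype=float),
                        occupancy=bio_atom.get_occupancy() or 1.0,
                        is_sidechain=name not in BACKBONE_ATOMS,
                    )
                )
            if res.atoms:
                residues.append(res)
        if residues:
            chains[bio_chain.id] = residues
    structure = Structure(id=structure_id, chains=chains)
    if structure.n_atoms() == 0:
        raise PDBFormatError("PDB input parsed to an empty structure")
    return structure


def _as_text(source) -> str:
    if isinstance(source, bytes):
        return source.decode("ascii", errors="replace")
    if hasattr(source, "read"):
        data = source.read()
        return data.decode("ascii", errors="replace") if isinstance(data, bytes) else data
    text = str(source)
    if "\n" not in text and len(text) < 4096:
        try:
            with open(text) as fh:
                return fh.read()
        except OSError:
            pass
    return text


def _format_error(text: str, exc: Exception) -> str:
    """Locate the first malformed coordinate record for a helpful message."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                return f"malformed coordinate record at line {lineno}: {line.rstrip()!r}"
    return f"PDB parse error: {exc}"


def write_pdb(structure: Structure, destination: str | IO | None = None) -> str:
    """Serialize a structure as wwPDB v3.3 ATOM records (returns the text)."""
    lines = []
    serial = 0
    for cid, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.aa3:<3s} {cid:1s}"
                    f"{res.number:4d}{res.insertion_code:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {residues[-1].aa3:<3s} {cid:1s}{residues[-1].number:4d}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


def get_environment(
    structure: Structure,
    residue_key,
    radius: float,
    oligomer: bool = True,
) -> list[Atom]:
    """Atoms within ``radius`` Å of any atom of the residue, excluding the residue itself.

    With ``oligomer=True`` atoms of every chain are considered (homo-oligomer
    environments); otherwise only the residue's own chain.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    chain, number, icode = _resolve_key(residue_key)
    res = structure.residue(chain, number, icode)
    centre = res.coords()
    out: list[Atom] = []
    if radius == 0:
        return out
    for cid, residues in structure.chains.items():
        if not oligomer and cid != chain:
            continue
        for other in residues:
            if other.key == res.key:
                continue
            for atom in other.atoms:
                d = np.sqrt(((centre - atom.coords) ** 2).sum(axis=1)).min()
                if d <= radius:
                    out.append(atom)
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_atom_sasa(
    structure: Structure, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom Shrake–Rupley solvent-accessible surface area (Å²).

    Test points are placed on each atom's solvent-expanded sphere
    (radius ``vdW + probe``); a point is buried if it falls inside any
    neighbour's expanded sphere.  Returns areas in structure atom order.
    """
    if n_points < 100:
        raise ValueError("n_points must be at least 100 for a stable estimate")
    atoms = list(structure.atoms())
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius() for a in atoms]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    sasa = np.empty(len(atoms))
    for i, (xyz, ri) in enumerate(zip(coords, radii)):
        neighbours = [j for j in tree.query_ball_point(xyz, ri + rmax) if j != i]
        pts = xyz + ri * unit
        if neighbours:
            nb_xyz = coords[neighbours]
            nb_r = radii[neighbours]
            # keep only neighbours whose expanded sphere can reach ours
            close = np.linalg.norm(nb_xyz - xyz, axis=1) < ri + nb_r
            nb_xyz, nb_r = nb_xyz[close], nb_r[close]
            if len(nb_xyz):
                d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
                buried = (d2 < nb_r[None, :] ** 2).any(axis=1)
                accessible = np.count_nonzero(~buried)
            else:
                accessible = n_points
        else:
            accessible = n_points
        sasa[i] = 4.0 * np.pi * ri**2 * accessible / n_points
    return sasa


def solvent_accessibility(
    structure: Structure,
    residue_key,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, float]:
    """Residue SASA in Å² and as a fraction of its Gly-X-Gly reference area."""
    chain, number, icode = _resolve_key(residue_key)
    res = structure.residue(chain, number, icode)
    atoms = list(structure.atoms())
    sasa = compute_atom_sasa(structure, probe=probe, n_points=n_points)
    area = sum(s for a, s in zip(atoms, sasa) if a.residue_key == res.key)
    reference = GXG_REFERENCE_AREA.get(res.aa3)
    if reference is None:
        warnings.warn(f"no reference area for residue {res.aa3}; relative SASA is NaN")
        return area, float("nan")
    return area, area / reference


def residue_depth(
    structure: Structure,
    residue_key,
    probe: float = 1.4,
    n_points: int = 300,
    exposure_threshold: float = 0.05,
) -> float:
    """Mean distance (Å) from the residue's atoms to the nearest solvent-exposed atom.

    An atom is *exposed* when its SASA exceeds ``exposure_threshold`` of its
    isolated solvent-expanded sphere area.  A fully exposed residue has
    depth ≈ 0 (each atom is its own nearest exposed atom).
    """
    chain, number, icode = _resolve_key(residue_key)
    res = structure.residue(chain, number, icode)
    atoms = list(structure.atoms())
    sasa = compute_atom_sasa(structure, probe=probe, n_points=n_points)
    radii = np.array([a.vdw_radius() for a in atoms]) + probe
    frac = sasa / (4.0 * np.pi * radii**2)
    exposed = frac > exposure_threshold
    if not exposed.any():
        raise ValueError("structure has no solvent-exposed atoms")
    exposed_xyz = np.array([a.coords for a, e in zip(atoms, exposed) if e])
    exposed_keys = {id(a) for a, e in zip(atoms, exposed) if e}
    depths = []
    for i, atom in enumerate(atoms):
        if atom.residue_key != res.key:
            continue
        if id(atom) in exposed_keys:
            depths.append(0.0)
        else:
            depths.append(float(np.linalg.norm(exposed_xyz - atom.coords, axis=1).min()))
    return float(np.mean(depths))
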