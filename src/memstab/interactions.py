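"""Geometric detection of non-covalent interactions made by a residue.

Five interaction classes are evaluated with simple distance/angle rules over
heavy atoms: hydrogen bonds, ionic (salt-bridge) contacts, hydrophobic
carbon–carbon contacts, aromatic ring stacking and cation–π.  Participating
atom roles come from the pharmacophore typing table, so an editable typing
table also redefines who may interact.

Hydrogens are normally absent from PDB coordinates, so donor geometry is
approximated on the donor heavy atom and the hydrogen-bond angle criterion is
applied at the acceptor (donor···acceptor—antecedent angle); this is the
standard heavy-atom surrogate and a documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pharmacophores import load_typing_table
from .structures import Residue, Structure, get_environment, _resolve_key

__all__ = [
    "InteractionRule",
    "InteractionRecord",
    "InteractionSet",
    "default_rules",
    "INTERACTION_TYPES",
    "ring_centroid",
    "detect_interactions",
]

INTERACTION_TYPES = (
    "hydrogen_bond",
    "ionic",
    "hydrophobic_contact",
    "aromatic_aromatic",
    "cation_pi",
)

#: Ring atom names; TRP uses the 6-membered benzene ring by default.
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
RING_ATOMS_ALT = {  # five-membered alternative for TRP
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2"),
}


@dataclass
class InteractionRule:
    """Distance (and optional angle) bounds for one interaction type."""

    type: str
    max_distance: float  # Å
    min_distance: float = 0.0
    min_angle: float | None = None  # degrees

    def __post_init__(self) -> None:
        if self.min_distance < 0 or self.max_distance <= self.min_distance:
            raise ValueError(f"rule {self.type}: distance bounds must be positive and ordered")


def default_rules() -> dict[str, InteractionRule]:
    """Shipped default geometry, in the spirit of standard contact calculators."""
    return {
        "hydrogen_bond": InteractionRule("hydrogen_bond", max_distance=3.5, min_angle=90.0),
        "ionic": InteractionRule("ionic", max_distance=4.0),
        "hydrophobic_contact": InteractionRule("hydrophobic_contact", max_distance=4.5),
        "aromatic_aromatic": InteractionRule("aromatic_aromatic", max_distance=6.0),
        "cation_pi": InteractionRule("cation_pi", max_distance=6.0),
    }


@dataclass
class InteractionRecord:
    type: str
    partner_key: tuple  # (chain, residue number, insertion code)
    distance: float


@dataclass
class InteractionSet:
    records: list[InteractionRecord] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in INTERACTION_TYPES}
        for rec in self.records:
            out[rec.type] = out.get(rec.type, 0) + 1
        return out

    def to_table(self) -> str:
        """Tab-separated contact list (type, partner chain, partner residue, distance)."""
        lines = ["type\tpartner_chain\tpartner_residue\tdistance"]
        for rec in self.records:
            chain, number, icode = rec.partner_key
            lines.append(f"{rec.type}\t{chain}\t{number}{icode.strip()}\t{rec.distance:.2f}")
        return "\n".join(lines) + "\n"


def ring_centroid(residue: Residue, ring: str = "default") -> np.ndarray:
    """Centroid of the residue's aromatic ring atoms."""
    table = RING_ATOMS_ALT if ring == "five" else RING_ATOMS
    names = table.get(residue.aa3) or RING_ATOMS.get(residue.aa3)
    if names is None:
        raise ValueError(f"residue {residue.aa3} is not aromatic")
    present = {a.name: a for a in residue.atoms}
    missing = [n for n in names if n not in present]
    if missing:
        raise ValueError(
            f"incomplete ring in {residue.chain}{residue.number} {residue.aa3}: "
            f"missing {', '.join(missing)}"
        )
    return np.mean([present[n].coords for n in names], axis=0)


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _acceptor_antecedent(structure: Structure, acceptor) -> np.ndarray | None:
    """The heavy atom covalently carrying the acceptor (nearest in-residue atom ≤ 1.8 Å)."""
    try:
        res = structure.residue(*acceptor.residue_key)
    except LookupError:
        return None
    best, best_d = None, 1.8
    for atom in res.atoms:
        if atom is acceptor:
            continue
        d = float(np.linalg.norm(atom.coords - acceptor.coords))
        if d < best_d:
            best, best_d = atom.coords, d
    return best


def _is_peptide_neighbour(res_key: tuple, atom) -> bool:
    chain, number, _ = res_key
    a_chain, a_number, _ = atom.residue_key
    return a_chain == chain and abs(a_number - number) == 1


def detect_interactions(
    structure: Structure,
    residue_key,
    rules: dict[str, InteractionRule] | None = None,
    environment_radius: float = 12.0,
    oligomer: bool = True,
    typing_table=None,
) -> InteractionSet:
    """Evaluate all interaction rules between a residue and its environment.

    Atom pairs across a peptide bond (backbone atoms of sequence-adjacent
    residues in the same chain) are excluded as covalent rather than
    non-covalent contacts.
    """
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("no interaction rules supplied")
    if typing_table is None:
        typing_table = load_typing_table()
    chain, number, icode = _resolve_key(residue_key)
    res = structure.residue(chain, number, icode)
    env = get_environment(structure, residue_key, radius=environment_radius, oligomer=oligomer)

    def classes(atom):
        return typing_table.get((_aa3_of(structure, atom), atom.name), frozenset())

    res_classes = [(a, classes(a)) for a in res.atoms]
    env_classes = [(a, classes(a)) for a in env]

    out = InteractionSet()

    # --- pairwise atom rules ---------------------------------------------
    for a, cls_a in res_classes:
        for b, cls_b in env_classes:
            if (
                _is_peptide_neighbour(res.key, b)
                and not a.is_sidechain
                and not b.is_sidechain
            ):
                continue  # peptide-bonded backbone
            d = float(np.linalg.norm(a.coords - b.coords))

            rule = rules.get("hydrogen_bond")
            if rule is not None and rule.min_distance <= d <= rule.max_distance:
                for donor, acceptor in ((a, b), (b, a)):
                    dcls = cls_a if donor is a else cls_b
                    acls = cls_b if acceptor is b else cls_a
                    if "hbond_donor" in dcls and "hbond_acceptor" in acls:
                        antecedent = _acceptor_antecedent(structure, acceptor)
                        if (
                            rule.min_angle is None
                            or antecedent is None
                            or _angle(donor.coords, acceptor.coords, antecedent) >= rule.min_angle
                        ):
                            out.records.append(InteractionRecord("hydrogen_bond", b.residue_key, d))
                            break  # one record per atom pair

            rule = rules.get("ionic")
            if rule is not None and rule.min_distance <= d <= rule.max_distance:
                if ("positive" in cls_a and "negative" in cls_b) or (
                    "negative" in cls_a and "positive" in cls_b
                ):
                    out.records.append(InteractionRecord("ionic", b.residue_key, d))

            rule = rules.get("hydrophobic_contact")
            if rule is not None and rule.min_distance <= d <= rule.max_distance:
                if (
                    "hydrophobic" in cls_a
                    and "hydrophobic" in cls_b
                    and a.element == "C"
                    and b.element == "C"
                ):
                    out.records.append(InteractionRecord("hydrophobic_contact", b.residue_key, d))

    # --- ring-based rules -------------------------------------------------
    partner_residues: dict[tuple, Residue] = {}
    for atom in env:
        if atom.residue_key not in partner_residues:
            try:
                partner_residues[atom.residue_key] = structure.residue(*atom.residue_key)
            except LookupError:
                continue

    own_centroid = None
    if res.aa3 in RING_ATOMS:
        try:
            own_centroid = ring_centroid(res)
        except ValueError:
            own_centroid = None

    rule = rules.get("aromatic_aromatic")
    if rule is not None and own_centroid is not None:
        for key, partner in partner_residues.items():
            if partner.aa3 not in RING_ATOMS:
                continue
            try:
                c = ring_centroid(partner)
            except ValueError:
                continue
            d = float(np.linalg.norm(own_centroid - c))
            if rule.min_distance <= d <= rule.max_distance:
                out.records.append(InteractionRecord("aromatic_aromatic", key, d))

    rule = rules.get("cation_pi")
    if rule is not None:
        if own_centroid is not None:
            for b, cls_b in env_classes:
                if "positive" not in cls_b:
                    continue
                d = float(np.linalg.norm(own_centroid - b.coords))
                if rule.min_distance <= d <= rule.max_distance:
                    out.records.append(InteractionRecord("cation_pi", b.residue_key, d))
        cations = [a for a, cls_a in res_classes if "positive" in cls_a]
        if cations:
            for key, partner in partner_residues.items():
                if partner.aa3 not in RING_ATOMS:
                    continue
                try:
                    c = ring_centroid(partner)
                except ValueError:
                    continue
                d = min(float(np.linalg.norm(c - a.coords)) for a in cations)
                if rule.min_distance <= d <= rule.max_distance:
                    out.records.append(InteractionRecord("cation_pi", key, d))

    return out


def _aa3_of(structure: Structure, atom) -> str:
    try:
        return structure.residue(*atom.residue_key).aa3
    except LookupError:
        return "UNK"
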