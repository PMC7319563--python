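"""Sequence-derived features: substitution scores, physicochemical indices
and global protein properties.

Two kinds of per-mutation score are supported: *pair* matrices (e.g. BLOSUM62,
loaded from Biopython) scored by direct lookup, and *index* vectors (one value
per residue, e.g. Kyte–Doolittle hydropathy) scored as value(mut) − value(wt).
Global properties of the host sequence — length, average molecular weight,
isoelectric point, GRAVY hydropathy and amino-acid composition — follow the
classic ProtParam conventions, with the isoelectric point solved from the
Henderson–Hasselbalch net-charge function using the EMBOSS pKa set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .mutation import STANDARD_AA1

__all__ = [
    "AAIndexMatrix",
    "SequenceProperties",
    "load_index_bundle",
    "default_bundle",
    "blosum62",
    "matrix_score",
    "protein_properties",
    "net_charge",
    "read_fasta",
]

#: Average masses (Da) of the free amino acids; a peptide of n residues
#: weighs sum(masses) − (n−1)·water.
FREE_AA_MASS = {
    "A": 89.094, "R": 174.203, "N": 132.119, "D": 133.104, "C": 121.154,
    "Q": 146.146, "E": 147.131, "G": 75.067, "H": 155.156, "I": 131.175,
    "L": 131.175, "K": 146.189, "M": 149.208, "F": 165.192, "P": 115.132,
    "S": 105.093, "T": 119.120, "W": 204.228, "Y": 181.191, "V": 117.148,
}
WATER_MASS = 18.0153

#: EMBOSS pKa values for the ionisable groups.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass
class AAIndexMatrix:
    """A named amino-acid scoring table.

    ``kind='pair'`` holds a 20×20 substitution matrix; ``kind='index'`` holds
    one value per residue and is scored as a wild-type→mutant difference.
    """

    name: str
    kind: str  # 'pair' | 'index'
    values: dict = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("pair", "index"):
            raise ValueError(f"kind must be 'pair' or 'index', got {self.kind!r}")
        letters = set(STANDARD_AA1)
        if self.kind == "index":
            missing = letters - set(self.values)
            if missing:
                raise ValueError(f"index {self.name} missing letters {sorted(missing)}")
        else:
            missing = {(a, b) for a in letters for b in letters} - set(self.values)
            if missing:
                raise ValueError(f"matrix {self.name} incomplete ({len(missing)} missing pairs)")


def matrix_score(matrix: AAIndexMatrix, wt: str, mut: str) -> float:
    """Score a wt→mut substitution against one matrix or index."""
    for letter in (wt, mut):
        if letter not in STANDARD_AA1:
            raise ValueError(f"not a standard amino-acid letter: {letter!r}")
    if matrix.kind == "pair":
        return float(matrix.values[(wt, mut)])
    return float(matrix.values[mut]) - float(matrix.values[wt])


def load_index_bundle(path: str | Path | None = None) -> list[AAIndexMatrix]:
    """Load the shipped per-residue index vectors (or a custom TSV of the same shape)."""
    if path is None:
        text = resources.files("memstab.data").joinpath("aa_indices.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    names = header[1:]
    tables: dict[str, dict[str, float]] = {n: {} for n in names}
    for line in lines[1:]:
        parts = line.split("\t")
        aa = parts[0]
        for name, value in zip(names, parts[1:]):
            tables[name][aa] = float(value)
    return [AAIndexMatrix(name=n, kind="index", values=tables[n]) for n in names]


def blosum62() -> AAIndexMatrix:
    """BLOSUM62 as a pair matrix (via Biopython's substitution matrices)."""
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load("BLOSUM62")
    values = {
        (a, b): float(raw[a, b]) for a in STANDARD_AA1 for b in STANDARD_AA1
    }
    return AAIndexMatrix(name="blosum62", kind="pair", values=values)


def default_bundle() -> list[AAIndexMatrix]:
    """The default scoring bundle: BLOSUM62 plus the shipped index vectors."""
    return [blosum62(), *load_index_bundle()]


@dataclass
class SequenceProperties:
    length: int
    molecular_weight: float  # Da
    isoelectric_point: float
    gravy: float
    composition: dict[str, float]  # per-letter fractions, sums to 1


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    counts = {aa: sequence.count(aa) for aa in "KRHDECY"}
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def protein_properties(sequence: str) -> SequenceProperties:
    """Global sequence properties (ProtParam-style).

    ``X`` is tolerated but excluded from the weight and GRAVY averages with
    a warning; any other non-standard letter is an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    bad = set(sequence) - set(STANDARD_AA1) - {"X"}
    if bad:
        raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")
    counted = [aa for aa in sequence if aa in STANDARD_AA1]
    if len(counted) < len(sequence):
        warnings.warn(
            f"{len(sequence) - len(counted)} unknown residue(s) 'X' excluded "
            "from molecular weight and GRAVY"
        )
    if not counted:
        raise ValueError("sequence contains no standard residues")
    weight = sum(FREE_AA_MASS[aa] for aa in counted) - (len(counted) - 1) * WATER_MASS
    kd = next(m for m in load_index_bundle() if m.name == "kd_hydropathy").values
    gravy = float(np.mean([kd[aa] for aa in counted]))
    pi = brentq(lambda ph: net_charge("".join(counted), ph), 0.0, 14.0, xtol=1e-8)
    n = len(counted)
    composition = {aa: counted.count(aa) / n for aa in STANDARD_AA1}
    return SequenceProperties(
        length=len(sequence),
        molecular_weight=weight,
        isoelectric_point=float(pi),
        gravy=gravy,
        composition=composition,
    )


def read_fasta(source) -> dict[str, str]:
    """Read sequences from a FASTA file or handle as an id → sequence map."""
    from Bio import SeqIO

    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
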