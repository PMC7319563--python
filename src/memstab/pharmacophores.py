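"""Pharmacophore atom typing and residue-level pharmacophore arithmetic.

Each heavy atom of the 20 standard residues is assigned a subset of eight
coarse physicochemical classes (hydrophobic, positive, negative, hydrogen-bond
acceptor/donor, aromatic, sulfur, neutral).  These labels are the node colours
of the residue-environment graphs and the basis of the wild-type→mutant
*pharmacophore change vector*, which is how the mutant side chain enters the
feature set without modelling a mutant structure.

The typing table ships as a plain-text data file (``data/atom_typing.tsv``)
so the reconstruction can be audited or overridden; pass a custom table path
to :func:`load_typing_table`.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np

from .mutation import STANDARD_AA1
from .structures import AA1_TO_AA3

__all__ = [
    "PHARMACOPHORE_CLASSES",
    "load_typing_table",
    "assign_classes",
    "residue_counts",
    "change_vector",
]

#: Fixed, ordered class inventory; feature-vector layout depends on this order.
PHARMACOPHORE_CLASSES = (
    "hydrophobic",
    "positive",
    "negative",
    "hbond_acceptor",
    "hbond_donor",
    "aromatic",
    "sulfur",
    "neutral",
)

_CLASS_INDEX = {c: i for i, c in enumerate(PHARMACOPHORE_CLASSES)}

_TABLE_CACHE: dict[str, dict] = {}


def load_typing_table(path: str | Path | None = None) -> dict[tuple[str, str], frozenset[str]]:
    """Load the (residue aa3, atom name) → class-set map.

    The default is the shipped table; a custom tab-separated file with columns
    ``aa3 <TAB> atom <TAB> class[,class...]`` may be supplied instead.
    """
    cache_key = str(path) if path is not None else "__default__"
    if cache_key in _TABLE_CACHE:
        return _TABLE_CACHE[cache_key]
    if path is None:
        text = resources.files("memstab.data").joinpath("atom_typing.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[tuple[str, str], frozenset[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"atom typing table line {lineno}: expected 3 columns")
        aa3, atom, classes = parts
        cls = frozenset(c.strip() for c in classes.split(","))
        unknown = cls - set(PHARMACOPHORE_CLASSES)
        if unknown:
            raise ValueError(f"atom typing table line {lineno}: unknown classes {sorted(unknown)}")
        table[(aa3, atom)] = cls
    _TABLE_CACHE[cache_key] = table
    return table


def assign_classes(aa3: str, atom_name: str, table=None) -> frozenset[str]:
    """Pharmacophore classes of one atom; empty set (with a warning) if untyped.

    Modified or non-standard residues therefore degrade gracefully rather
    than aborting feature generation.
    """
    if table is None:
        table = load_typing_table()
    classes = table.get((aa3, atom_name))
    if classes is None:
        warnings.warn(f"no pharmacophore typing for ({aa3}, {atom_name}); treated as untyped")
        return frozenset()
    return classes


def residue_counts(aa1: str, table=None) -> np.ndarray:
    """Per-class atom counts over a residue's standard heavy-atom topology.

    The standard topology is the set of atoms the typing table enumerates for
    the residue (backbone N/CA/C/O plus side-chain heavy atoms).
    """
    if aa1 not in STANDARD_AA1:
        raise ValueError(f"not a standard amino-acid letter: {aa1!r}")
    if table is None:
        table = load_typing_table()
    aa3 = AA1_TO_AA3[aa1]
    counts = np.zeros(len(PHARMACOPHORE_CLASSES), dtype=int)
    for (res, _atom), classes in table.items():
        if res != aa3:
            continue
        for c in classes:
            counts[_CLASS_INDEX[c]] += 1
    return counts


def change_vector(wt: str, mut: str, table=None) -> np.ndarray:
    """Signed per-class difference ``residue_counts(mut) − residue_counts(wt)``.

    Antisymmetric by construction: ``change_vector(x, y) == -change_vector(y, x)``.
    """
    return residue_counts(mut, table) - residue_counts(wt, table)
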