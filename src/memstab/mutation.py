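"""Point-mutation specifications.

A mutation is written the way structural biologists write it: wild-type
one-letter code, residue number (PDB numbering, which may be negative),
mutant one-letter code — e.g. ``"W57A"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

_MUTATION_RE = re.compile(r"^\s*([A-Za-z])\s*(-?\d+)\s*([A-Za-z])\s*$")


class MutationParseError(ValueError):
    """Raised when a mutation string cannot be interpreted."""


@dataclass(frozen=True)
class MutationSpec:
    """A single-point missense mutation: ``wt`` at ``position`` becomes ``mut``."""

    wt: str
    position: int
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in STANDARD_AA1:
            raise MutationParseError(f"unknown wild-type residue letter {self.wt!r}")
        if self.mut not in STANDARD_AA1:
            raise MutationParseError(f"unknown mutant residue letter {self.mut!r}")
        if self.wt == self.mut:
            raise MutationParseError(
                f"wild-type and mutant residues are identical ({self.wt}{self.position}{self.mut})"
            )

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @property
    def reverse(self) -> "MutationSpec":
        return MutationSpec(self.mut, self.position, self.wt)


def parse_mutation(text: str) -> MutationSpec:
    """Parse a mutation string like ``"W57A"`` (case-insensitive, whitespace-tolerant).

    Raises :class:`MutationParseError` with a distinct message for a missing
    component, an unknown residue letter, or a wild-type equal to the mutant.
    """
    if not text or not text.strip():
        raise MutationParseError("empty mutation string")
    m = _MUTATION_RE.match(text)
    if m is None:
        raise MutationParseError(
            f"cannot parse mutation {text!r}: expected wild-type letter, "
            "residue number and mutant letter, e.g. 'W57A'"
        )
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MutationSpec(wt, pos, mut)
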