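"""Mutation datasets: tables, reverse-mutation augmentation and leakage-safe splits.

Stability datasets record ΔΔG = ΔG_WT − ΔG_MT in kcal/mol (negative =
destabilising); pathogenicity datasets record a benign/pathogenic label.
Measured (forward) mutations can be balanced by appending hypothetical
*reverse* mutations with the negated ΔΔG — applied only where the measured
effect is below 2 kcal/mol in magnitude, so a reversal cannot plausibly
compromise the fold.  A forward/reverse pair shares a ``pair_key`` and must
never be separated by a train/test split or a cross-validation fold.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .mutation import STANDARD_AA1

__all__ = [
    "MutationRecord",
    "ClassThresholds",
    "DatasetSplit",
    "read_mutation_table",
    "records_to_frame",
    "write_mutation_table",
    "augment_reverse",
    "classify_ddg",
    "split_by_protein",
]

BENIGN, PATHOGENIC = "benign", "pathogenic"


@dataclass
class MutationRecord:
    protein: str
    chain: str
    wt: str
    position: int
    mut: str
    ddg: float | None = None  # kcal/mol, ΔG_WT − ΔG_MT
    patho_label: str | None = None
    direction: str = "forward"
    pair_key: str = ""

    def __post_init__(self) -> None:
        if self.wt not in STANDARD_AA1 or self.mut not in STANDARD_AA1:
            raise ValueError(f"non-standard residue letters in {self.wt}{self.position}{self.mut}")
        if self.wt == self.mut:
            raise ValueError(f"wild-type equals mutant at position {self.position}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        if self.patho_label is not None and self.patho_label not in (BENIGN, PATHOGENIC):
            raise ValueError(f"pathogenicity label must be benign/pathogenic, got {self.patho_label!r}")
        if not self.pair_key:
            # symmetric in wt/mut, so a forward/reverse pair shares it
            lo, hi = sorted((self.wt, self.mut))
            self.pair_key = f"{self.protein}:{self.chain}:{self.position}:{lo}{hi}"

    @property
    def mutation(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


@dataclass(frozen=True)
class ClassThresholds:
    """ΔΔG class bounds: below the lower bound is destabilising, above the
    upper bound stabilising, and everything between (boundaries included)
    is neutral."""

    destabilising: float = -0.4  # kcal/mol
    stabilising: float = 0.4

    def __post_init__(self) -> None:
        if not (self.destabilising < 0 < self.stabilising):
            raise ValueError("thresholds must straddle zero")


@dataclass
class DatasetSplit:
    train: list[MutationRecord]
    test: list[MutationRecord]
    grouping: str = "protein"


_MANDATORY = ("protein", "chain", "wt", "position", "mut")


def read_mutation_table(source: str | Path | io.IOBase) -> list[MutationRecord]:
    """Read a delimited (tab or comma) mutation table into typed records.

    The header must name ``protein, chain, wt, position, mut`` plus exactly
    one of ``ddg`` (stability role) or ``label`` (pathogenicity role);
    an optional ``direction`` column marks pre-augmented reverse records.
    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing mandatory column(s): {', '.join(missing)}")
    has_ddg, has_label = "ddg" in df.columns, "label" in df.columns
    if has_ddg and has_label:
        raise ValueError(
            "mutation table has both 'ddg' and 'label' columns; a table serves "
            "a single task role (stability or pathogenicity)"
        )
    if not has_ddg and not has_label:
        raise ValueError("mutation table needs a 'ddg' or a 'label' column")

    records: list[MutationRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            ddg = None
            if has_ddg:
                ddg = float(row["ddg"])
                if not math.isfinite(ddg):
                    raise ValueError(f"non-finite ddg {row['ddg']!r}")
            label = str(row["label"]).strip().lower() if has_label else None
            records.append(
                MutationRecord(
                    protein=str(row["protein"]).strip(),
                    chain=str(row["chain"]).strip(),
                    wt=str(row["wt"]).strip().upper(),
                    position=int(row["position"]),
                    mut=str(row["mut"]).strip().upper(),
                    ddg=ddg,
                    patho_label=label,
                    direction=str(row.get("direction", "forward") or "forward").strip(),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError("malformed mutation table rows:\n" + "\n".join(errors))
    return records


def records_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "protein": r.protein, "chain": r.chain, "wt": r.wt,
            "position": r.position, "mut": r.mut, "direction": r.direction,
        }
        if r.ddg is not None:
            row["ddg"] = r.ddg
        if r.patho_label is not None:
            row["label"] = r.patho_label
        rows.append(row)
    return pd.DataFrame(rows)


def write_mutation_table(records: list[MutationRecord], destination, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(destination, sep=sep, index=False)


def augment_reverse(
    records: list[MutationRecord], max_abs_ddg: float = 2.0
) -> list[MutationRecord]:
    """Append a reverse record (swapped residues, negated ΔΔG, shared pair key)
    for every forward record whose measured |ΔΔG| is below ``max_abs_ddg``.

    Refuses input that already contains reverse records — re-augmenting would
    double-count pairs.
    """
    if any(r.direction == "reverse" for r in records):
        raise ValueError("input already contains reverse records; refusing to augment twice")
    out = list(records)
    for rec in records:
        if rec.ddg is None:
            raise ValueError("reverse augmentation applies to stability records with ΔΔG")
        if abs(rec.ddg) < max_abs_ddg:
            out.append(
                replace(
                    rec,
                    wt=rec.mut,
                    mut=rec.wt,
                    ddg=-rec.ddg,
                    direction="reverse",
                    pair_key=rec.pair_key,
                )
            )
    return out


def classify_ddg(ddg: float, thresholds: ClassThresholds | None = None) -> str:
    """Three-way stability class with strict outer inequalities.

    ΔΔG < −0.4 kcal/mol → ``destabilising``; ΔΔG > +0.4 → ``stabilising``;
    the closed band in between (boundary values included) → ``neutral``.
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    if not math.isfinite(ddg):
        raise ValueError(f"ΔΔG must be finite, got {ddg!r}")
    if ddg < thresholds.destabilising:
        return "destabilising"
    if ddg > thresholds.stabilising:
        return "stabilising"
    return "neutral"


def split_by_protein(
    records: list[MutationRecord], test_proteins: set[str]
) -> DatasetSplit:
    """Partition records by protein id (blind-test style).

    Forward/reverse pairs share a protein, so pair integrity holds by
    construction; an unknown test protein id is an error.
    """
    present = {r.protein for r in records}
    unknown = set(test_proteins) - present
    if unknown:
        raise ValueError(f"test protein(s) not present in records: {sorted(unknown)}")
    train = [r for r in records if r.protein not in test_proteins]
    test = [r for r in records if r.protein in test_proteins]
    return DatasetSplit(train=train, test=test, grouping="protein")
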