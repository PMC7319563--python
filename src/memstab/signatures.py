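"""Graph-based structural signatures of residue environments.

The environment of a wild-type residue is modelled as a family of graphs:
atoms are nodes coloured by pharmacophore class, and two atoms are linked
when their Euclidean distance is at or below a cutoff.  Sweeping the cutoff
over a ladder of distances and counting, for every unordered class pair, the
atom pairs within each cutoff yields a cumulative distance-pattern vector —
a compact, rigid-motion-invariant summary of the environment's geometry and
chemistry ("cutoff scanning").

:func:`assemble_features` concatenates this graph block with the
pharmacophore change vector, sequence-derived scores and non-covalent
interaction counts into one named feature row; :class:`MutationFeaturizer`
is the scikit-learn-style transformer that does this for whole mutation
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .interactions import INTERACTION_TYPES, detect_interactions
from .mutation import MutationSpec, parse_mutation
from .pharmacophores import PHARMACOPHORE_CLASSES, load_typing_table
from .seqfeatures import default_bundle, matrix_score, protein_properties
from .structures import Structure, get_environment

__all__ = [
    "CutoffLadder",
    "FeatureConfig",
    "environment_graph",
    "cutoff_scan",
    "graph_feature_names",
    "assemble_features",
    "feature_names",
    "MutationFeaturizer",
]


@dataclass(frozen=True)
class CutoffLadder:
    """Arithmetic ladder of distance cutoffs in Å.

    The default (1.0–10.0 Å, step 1.5) brackets covalent separations through
    second-shell contacts in seven rungs.
    """

    d_min: float = 1.0
    d_max: float = 10.0
    step: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max) or self.step <= 0:
            raise ValueError("require 0 < d_min < d_max and step > 0")

    @property
    def cutoffs(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return self.d_min + self.step * np.arange(n)


CLASS_PAIRS = tuple(combinations_with_replacement(PHARMACOPHORE_CLASSES, 2))
_PAIR_INDEX = {p: i for i, p in enumerate(CLASS_PAIRS)}
_CLASS_POS = {c: i for i, c in enumerate(PHARMACOPHORE_CLASSES)}


def _atom_classes(atom, typing, aa3_map: dict | None) -> frozenset:
    """Classes of one atom: explicit ``atom.classes`` wins, else table lookup.

    ``aa3_map`` maps residue keys to three-letter codes (atoms themselves do
    not know their residue type); fixture atoms may instead carry an ``aa3``
    or ``classes`` attribute directly.
    """
    explicit = getattr(atom, "classes", None)
    if explicit is not None:
        return frozenset(explicit)
    aa3 = getattr(atom, "aa3", None)
    if aa3_map is not None:
        aa3 = aa3_map.get(atom.residue_key, aa3)
    return typing.get((aa3, atom.name), frozenset())


def environment_graph(
    atoms,
    typing=None,
    cutoff: float = 10.0,
    aa3_map: dict | None = None,
    exclude_same_residue: bool = True,
) -> list[tuple[int, int]]:
    """Undirected edges (index pairs) between atoms within ``cutoff`` Å.

    Self-pairs are never edges; pairs within the same residue are excluded by
    default, since the signature should describe an environment rather than
    the internal geometry of single residues.
    """
    edges = []
    coords = np.array([a.coords for a in atoms]) if atoms else np.empty((0, 3))
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if exclude_same_residue and atoms[i].residue_key == atoms[j].residue_key:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                edges.append((i, j))
    return edges


def cutoff_scan(
    atoms,
    typing=None,
    ladder: CutoffLadder | None = None,
    aa3_map: dict | None = None,
    exclude_same_residue: bool = True,
) -> np.ndarray:
    """Cumulative pharmacophore-pair counts over the cutoff ladder.

    Returns a vector of length ``36 × |ladder|`` ordered pair-major
    (for each unordered class pair, one count per cutoff, non-decreasing
    along the ladder).  An atom carrying several classes contributes to every
    class pair it instantiates with its partner.
    """
    if typing is None:
        typing = load_typing_table()
    if ladder is None:
        ladder = CutoffLadder()
    cutoffs = ladder.cutoffs
    n_bins = len(cutoffs)
    raw = np.zeros((len(CLASS_PAIRS), n_bins), dtype=int)
    if atoms:
        coords = np.array([a.coords for a in atoms])
        classes = [_atom_classes(a, typing, aa3_map) for a in atoms]
        for i in range(len(atoms)):
            if not classes[i]:
                continue
            for j in range(i + 1, len(atoms)):
                if not classes[j]:
                    continue
                if exclude_same_residue and atoms[i].residue_key == atoms[j].residue_key:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                bin_idx = int(np.searchsorted(cutoffs, d - 1e-12))
                if bin_idx >= n_bins:
                    continue
                # each unordered class pair instantiated by this atom pair
                # counts once, however many labels the atoms share
                pairs = {
                    tuple(sorted((ci, cj), key=_CLASS_POS.get))
                    for ci in classes[i]
                    for cj in classes[j]
                }
                for p in pairs:
                    raw[_PAIR_INDEX[p], bin_idx] += 1
    return np.cumsum(raw, axis=1).reshape(-1).astype(float)


def graph_feature_names(ladder: CutoffLadder | None = None) -> list[str]:
    if ladder is None:
        ladder = CutoffLadder()
    return [
        f"graph:{a}~{b}:{c:.1f}" for (a, b) in CLASS_PAIRS for c in ladder.cutoffs
    ]


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of feature assembly.

    ``oligomer`` controls whether all chains contribute environment atoms
    (only the named chain's residue is ever mutated); the environment
    collection radius equals the ladder's ``d_max`` since farther atoms
    cannot contribute a counted pair.
    """

    ladder: CutoffLadder = field(default_factory=CutoffLadder)
    oligomer: bool = True
    include_intra_residue: bool = False
    interaction_radius: float = 12.0


@lru_cache(maxsize=1)
def _bundle():
    return default_bundle()


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """The stable, ordered names of an assembled feature row."""
    if config is None:
        config = FeatureConfig()
    names = graph_feature_names(config.ladder)
    names += [f"pharm_change:{c}" for c in PHARMACOPHORE_CLASSES]
    names += [f"seq:{m.name}" for m in _bundle()]
    names += ["seq:length", "seq:molecular_weight", "seq:isoelectric_point", "seq:gravy"]
    names += [f"interactions:{t}" for t in INTERACTION_TYPES]
    return names


def assemble_features(
    structure: Structure,
    chain: str,
    mutation: MutationSpec | str,
    config: FeatureConfig | None = None,
    expected_structure_wt: str | None = None,
    _seq_props_cache: dict | None = None,
) -> pd.Series:
    """One named feature row for a single mutation on a structure.

    The residue found at ``(chain, position)`` must match the mutation's
    wild-type letter (or ``expected_structure_wt`` when features for a
    reverse mutation are approximated on the forward wild-type structure);
    a mismatch raises, guarding against residue-numbering drift.
    """
    if config is None:
        config = FeatureConfig()
    if isinstance(mutation, str):
        mutation = parse_mutation(mutation)
    typing = load_typing_table()
    expected = expected_structure_wt or mutation.wt
    res = structure.residue(chain, mutation.position)
    if res.aa1 != expected:
        raise ValueError(
            f"wild-type mismatch at {chain}{mutation.position}: mutation expects "
            f"{expected}, structure has {res.aa1} ({res.aa3})"
        )

    aa3_map = {r.key: r.aa3 for r in structure.residues()}
    env = get_environment(
        structure, (chain, mutation.position), radius=config.ladder.d_max, oligomer=config.oligomer
    )
    graph_block = cutoff_scan(
        env,
        typing=typing,
        ladder=config.ladder,
        aa3_map=aa3_map,
        exclude_same_residue=not config.include_intra_residue,
    )

    from .pharmacophores import change_vector

    change_block = change_vector(mutation.wt, mutation.mut).astype(float)

    seq_scores = [matrix_score(m, mutation.wt, mutation.mut) for m in _bundle()]
    sequence = structure.chain_sequence(chain)
    cache_key = (structure.id, chain)
    if _seq_props_cache is not None and cache_key in _seq_props_cache:
        props = _seq_props_cache[cache_key]
    else:
        props = protein_properties(sequence)
        if _seq_props_cache is not None:
            _seq_props_cache[cache_key] = props
    seq_block = seq_scores + [
        float(props.length),
        props.molecular_weight,
        props.isoelectric_point,
        props.gravy,
    ]

    iset = detect_interactions(
        structure,
        (chain, mutation.position),
        environment_radius=config.interaction_radius,
        oligomer=config.oligomer,
        typing_table=typing,
    )
    counts = iset.counts
    inter_block = [float(counts[t]) for t in INTERACTION_TYPES]

    values = np.concatenate([graph_block, change_block, seq_block, inter_block])
    return pd.Series(values, index=feature_names(config), name=str(mutation))


class MutationFeaturizer:
    """scikit-learn-style transformer: mutation records → feature matrix.

    Parameters
    ----------
    structures:
        Mapping of protein id → :class:`Structure` (or a single structure,
        used for every record).
    config:
        :class:`FeatureConfig`; defaults are used when omitted.

    Reverse-direction records are feature-approximated on the wild-type
    structure: the environment is that of the forward wild-type residue
    (which is what the structure contains) while the pharmacophore change
    vector and sequence scores encode the reversed substitution.  Rows for
    such records are flagged in the output's ``attrs['direction']``.
    """

    def __init__(self, structures, config: FeatureConfig | None = None):
        self.structures = structures
        self.config = config if config is not None else FeatureConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"structures": self.structures, "config": self.config}

    def set_params(self, **params) -> "MutationFeaturizer":
        for k, v in params.items():
            if k not in ("structures", "config"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "MutationFeaturizer":
        self.feature_names_out_ = feature_names(self.config)
        return self

    def _structure_for(self, protein: str) -> Structure:
        if isinstance(self.structures, Structure):
            return self.structures
        try:
            return self.structures[protein]
        except KeyError:
            raise KeyError(f"no structure provided for protein {protein!r}") from None

    def transform(self, records) -> pd.DataFrame:
        """Assemble one row per mutation record.

        ``records`` is an iterable of :class:`memstab.dataset.MutationRecord`
        or of ``(protein, chain, mutation-string)`` tuples.
        """
        self.fit()
        rows, index, directions = [], [], []
        cache: dict = {}
        for rec in records:
            if isinstance(rec, tuple):
                protein, chain, mut = rec
                direction = "forward"
                spec = parse_mutation(mut) if isinstance(mut, str) else mut
            else:
                protein, chain, direction = rec.protein, rec.chain, rec.direction
                spec = MutationSpec(rec.wt, rec.position, rec.mut)
            structure = self._structure_for(protein)
            expected = spec.mut if direction == "reverse" else spec.wt
            row = assemble_features(
                structure,
                chain,
                spec,
                config=self.config,
                expected_structure_wt=expected,
                _seq_props_cache=cache,
            )
            rows.append(row.values)
            index.append(f"{protein}:{chain}:{spec}")
            directions.append(direction)
        X = pd.DataFrame(np.array(rows), index=index, columns=self.feature_names_out_)
        X.attrs["direction"] = directions
        return X

    def fit_transform(self, records, y=None) -> pd.DataFrame:
        return self.fit().transform(records)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names(self.config), dtype=object)
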