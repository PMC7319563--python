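"""Synthetic structures and datasets with known ground truth.

Every stage of the pipeline is testable without downloading anything:
:func:`build_helix` emits an ideal α-helical peptide (the canonical shape of
a transmembrane segment) as a PDB-serialisable :class:`Structure`,
:func:`build_dimer` pairs two helices into a homo-oligomer test bed, and
:func:`generate_dataset` writes mutation tables whose ΔΔG (or pathogenicity
label) is a known linear function of named signature features plus noise, so
recovery of the planted signal can be asserted.

The helix backbone lies on concentric cylinders: CA at radius 2.3 Å rising
1.5 Å and turning 100° per residue, with N, C and O at fixed offsets solved
so that defaults reproduce ideal bond lengths (N–CA 1.458, CA–C 1.525,
C–N(+1) 1.329, C–O 1.231 Å) and angles.  CB is placed tetrahedrally from the
backbone frame, pointing outward; side chains beyond CB are not built —
pharmacophore counts for synthetic records use the table-derived topology,
so rotamer geometry is unnecessary for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MutationRecord, BENIGN, PATHOGENIC
from .mutation import STANDARD_AA1
from .signatures import FeatureConfig, MutationFeaturizer
from .structures import AA1_TO_AA3, Atom, Residue, Structure

__all__ = [
    "HelixSpec",
    "SyntheticDatasetSpec",
    "build_helix",
    "build_dimer",
    "default_structures",
    "generate_dataset",
]

# Cylindrical offsets of backbone atoms relative to CA (Å / degrees), solved
# once for the default helix parameters to give ideal peptide geometry.
_BB_OFFSETS = {
    # name: (radius offset vs CA radius, twist offset deg, z offset)
    "N": (1.4793663 - 2.3, -27.5591711, -0.8247273),
    "C": (2.2095965 - 2.3, +37.0696250, +0.5131427),
    "O": (3.3938716 - 2.3, +41.9153745, +0.7565475),
}
_CB_BOND = 1.53
_CB_PITCH = np.deg2rad(54.0)


@dataclass(frozen=True)
class HelixSpec:
    sequence: str
    rise: float = 1.5  # Å per residue
    twist: float = 100.0  # degrees per residue
    radius: float = 2.3  # Å, CA cylinder
    jitter_sd: float = 0.0  # Å, Gaussian jitter applied to CB
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - set(STANDARD_AA1)
        if bad:
            raise ValueError(f"non-standard letters in helix sequence: {sorted(bad)}")
        if self.rise <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")


def _cyl(r: float, theta_deg: float, z: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([r * np.cos(t), r * np.sin(t), z])


def build_helix(
    spec: HelixSpec,
    chain_id: str = "A",
    structure_id: str = "helix",
    start_number: int = 1,
) -> Structure:
    """Ideal α-helix for ``spec.sequence`` (N, CA, C, O and CB per residue)."""
    rng = np.random.default_rng(spec.seed)
    residues: list[Residue] = []
    serial = 0
    seq = spec.sequence.upper()
    for i, aa1 in enumerate(seq):
        theta = i * spec.twist
        z = i * spec.rise
        ca = _cyl(spec.radius, theta, z)
        pos = {
            "CA": ca,
            **{
                name: _cyl(spec.radius + dr, theta + dt, z + dz)
                for name, (dr, dt, dz) in _BB_OFFSETS.items()
            },
        }
        aa3 = AA1_TO_AA3[aa1]
        number = start_number + i
        res = Residue(chain=chain_id, number=number, insertion_code=" ", aa3=aa3, aa1=aa1)
        order = ["N", "CA", "C", "O"]
        if aa1 != "G":
            b1 = pos["N"] - ca
            b2 = pos["C"] - ca
            b1 /= np.linalg.norm(b1)
            b2 /= np.linalg.norm(b2)
            bis = -(b1 + b2)
            bis /= np.linalg.norm(bis)
            nrm = np.cross(b1, b2)
            nrm /= np.linalg.norm(nrm)
            cb = ca + _CB_BOND * (bis * np.cos(_CB_PITCH) + nrm * np.sin(_CB_PITCH))
            if spec.jitter_sd > 0:
                cb = cb + rng.normal(0.0, spec.jitter_sd, size=3)
            pos["CB"] = cb
            order.append("CB")
        for name in order:
            serial += 1
            res.atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_key=(chain_id, number, " "),
                    coords=pos[name],
                    is_sidechain=name == "CB",
                )
            )
        residues.append(res)
    return Structure(id=structure_id, chains={chain_id: residues})


def build_dimer(
    spec_a: HelixSpec,
    spec_b: HelixSpec,
    offset: float,
    structure_id: str = "dimer",
) -> Structure:
    """Two parallel helices as chains A and B separated by ``offset`` Å."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    a = build_helix(spec_a, chain_id="A", structure_id="a")
    b = build_helix(spec_b, chain_id="B", structure_id="b")
    shift = np.array([offset, 0.0, 0.0])
    for res in b.chains["B"]:
        for atom in res.atoms:
            atom.coords = atom.coords + shift
    return Structure(id=structure_id, chains={"A": a.chains["A"], "B": b.chains["B"]})


# Membrane-segment-like sequences: predominantly hydrophobic with sprinkled
# polar, aromatic and charged residues so every feature block has variance.
_DEFAULT_SEQS = {
    "HLX1": "MALWIVLFGAILSYKTLFDAVNIGQRLMWFVACTLIPESMLHVGWIKA",
    "HLX2": "GVLFIWASYTLMRKAVLIDEFNQPGCILMVWHSTAYLFRVIKGLAEDT",
}
_DIMER_SEQS = ("AVILGFWSTYKLMCARDENQ", "LIVFAWGYSMTPHKRCQEND")


def default_structures(config: FeatureConfig | None = None) -> dict[str, Structure]:
    """The standard synthetic protein set: two helices and a contacting dimer."""
    out = {
        pid: build_helix(HelixSpec(seq), structure_id=pid)
        for pid, seq in _DEFAULT_SEQS.items()
    }
    out["DIM1"] = build_dimer(
        HelixSpec(_DIMER_SEQS[0]), HelixSpec(_DIMER_SEQS[1]), offset=9.0, structure_id="DIM1"
    )
    return out


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Generator settings; defaults are the package's standard study conditions.

    ``effect_weights`` name real features of the assembled row; the response
    is their z-scored linear combination.  For stability the response plus
    Gaussian noise (sd in kcal/mol) is ΔΔG; for pathogenicity the response is
    thresholded at its median and labels flipped at ``label_flip_rate``.
    """

    n_records: int = 400
    task: str = "stability"  # 'stability' | 'pathogenicity'
    noise_sd: float = 0.1  # kcal/mol
    label_flip_rate: float = 0.1
    effect_weights: dict[str, float] = field(
        default_factory=lambda: {
            "graph:hydrophobic~hydrophobic:7.0": 1.0,
            "graph:hbond_acceptor~hbond_donor:5.5": -0.7,
            "graph:hydrophobic~neutral:8.5": 0.5,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if self.task not in ("stability", "pathogenicity"):
            raise ValueError(f"unknown task {self.task!r}")
        if not (0.0 <= self.label_flip_rate <= 1.0):
            raise ValueError("label_flip_rate must be a probability")


def generate_dataset(
    spec: SyntheticDatasetSpec,
    structures: dict[str, Structure] | None = None,
    config: FeatureConfig | None = None,
):
    """Sample mutations, assemble their features and plant a known response.

    Returns ``(records, X, truth)`` where ``X`` is the assembled feature
    matrix (row order matches ``records``) and ``truth`` holds the weights
    and the standardisation used, for recovery tests.  Deterministic per
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if structures is None:
        structures = default_structures()
    featurizer = MutationFeaturizer(structures, config=config)
    names = featurizer.fit().feature_names_out_
    missing = [f for f in spec.effect_weights if f not in names]
    if missing:
        raise ValueError(f"effect weights reference unknown features: {missing}")

    proteins = sorted(structures)
    records: list[MutationRecord] = []
    seen = set()
    while len(records) < spec.n_records:
        pid = proteins[rng.integers(len(proteins))]
        structure = structures[pid]
        chain = sorted(structure.chains)[rng.integers(len(structure.chains))]
        residues = structure.chains[chain]
        res = residues[rng.integers(len(residues))]
        if res.aa1 not in STANDARD_AA1:
            continue
        mut = STANDARD_AA1[rng.integers(len(STANDARD_AA1))]
        if mut == res.aa1:
            continue
        key = (pid, chain, res.number, mut)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            MutationRecord(protein=pid, chain=chain, wt=res.aa1, position=res.number, mut=mut)
        )

    X = featurizer.transform(records)
    w_names = list(spec.effect_weights)
    w = np.array([spec.effect_weights[n] for n in w_names])
    sub = X[w_names].to_numpy()
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    if np.any(sd == 0):
        flat = [n for n, s in zip(w_names, sd) if s == 0]
        raise ValueError(f"effect features with no variance on these structures: {flat}")
    score = ((sub - mu) / sd) @ w

    if spec.task == "stability":
        ddg = score + rng.normal(0.0, spec.noise_sd, size=len(records))
        for rec, v in zip(records, ddg):
            rec.ddg = float(v)
    else:
        labels = np.where(score > np.median(score), PATHOGENIC, BENIGN)
        flip = rng.random(len(records)) < spec.label_flip_rate
        flipped = np.where(
            flip, np.where(labels == PATHOGENIC, BENIGN, PATHOGENIC), labels
        )
        for rec, lab in zip(records, flipped):
            rec.patho_label = str(lab)

    truth = {"weights": dict(spec.effect_weights), "mean": mu, "sd": sd, "score": score}
    return records, X, truth
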