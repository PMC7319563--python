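# Methods

## The model

`memstab` treats a single-point missense mutation as a perturbation of a
wild-type residue environment. Three feature blocks describe it:

1. **Graph-based structural signature of the wild-type environment.**
   All heavy atoms within `d_max` of the mutated residue (excluding the
   residue's own atoms) are collected — across every chain by default, so a
   homo-oligomer contributes its full environment while only the named
   chain's residue is mutated. Each atom carries a subset of eight
   pharmacophore classes (hydrophobic, positive, negative, hbond_acceptor,
   hbond_donor, aromatic, sulfur, neutral). For each unordered class pair
   and each cutoff in an arithmetic ladder, the signature records the
   number of atom pairs at or below that distance; counts are cumulative
   along the ladder by construction. Atom pairs within one residue are not
   counted (the signature should describe the *environment*, not internal
   residue geometry; switchable via `FeatureConfig.include_intra_residue`).
   A pair of atoms instantiating the same unordered class pair through
   several label combinations counts once.

2. **Pharmacophore change vector + sequence features.** The mutant residue
   enters only through arithmetic on standard residue topologies:
   `counts(mut) − counts(wt)` per class (antisymmetric by construction),
   plus BLOSUM62 and four physicochemical index differences
   (Kyte–Doolittle hydropathy, Zamyatnin volume, Grantham polarity,
   Bhaskaran–Ponnuswamy flexibility), plus global properties of the host
   chain sequence (length, average molecular weight, isoelectric point,
   GRAVY). No mutant structure is modelled; this is a deliberate design
   choice that keeps prediction cheap and makes reverse mutations
   representable (below).

3. **Non-covalent interaction counts** of the wild-type residue: hydrogen
   bonds (heavy-atom distance ≤ 3.5 Å and donor···acceptor–antecedent angle
   ≥ 90°), ionic contacts (≤ 4.0 Å between formally charged atoms),
   hydrophobic C–C contacts (≤ 4.5 Å), aromatic ring stacking and cation–π
   (ring-centroid distances ≤ 6.0 Å). Atom roles come from the same typing
   table as the signatures; atoms across a peptide bond (backbone atoms of
   sequence-adjacent residues) are excluded as covalent. Hydrogens are
   normally absent from PDB coordinates, so donor geometry is approximated
   on heavy atoms — a documented limitation shared by heavy-atom contact
   calculators generally.

With the default ladder this gives 252 + 8 + 9 + 5 = 274 named features.
Feature order is fixed and the estimators refuse prediction inputs whose
name manifest differs from training.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| cutoff ladder | 1.0–10.0, step 1.5 | Å | brackets covalent separations through second-shell contacts in 7 rungs; environment radius = `d_max` since farther atoms cannot contribute |
| ΔΔG class thresholds | ±0.4 | kcal/mol | strict outer inequalities; boundary values are neutral |
| reverse-augmentation filter | \|ΔΔG\| < 2.0 | kcal/mol | read as a magnitude bound: a large effect in either direction implies the reversal could compromise the fold |
| trees | 300, unlimited depth | — | standard forest size; variance is already controlled by the ensemble |
| CV protocol | 10 folds × 10 repetitions | — | repetitions are independent re-randomised foldings; each repetition pools its held-out predictions into one metric value |
| SASA | probe 1.4 Å, ≥100 sphere points | Å | Shrake–Rupley with golden-spiral points; vdW radii C 1.7, N 1.55, O 1.52, S 1.8, default 1.8 |
| depth exposure threshold | 5% of isolated-sphere area | — | robust to point-count noise |

## Reverse mutations

Each forward record with |ΔΔG| < 2 kcal/mol yields a reverse record with
swapped residues and negated ΔΔG, sharing the forward's pair key. Because
mutant-structure modelling is out of scope, reverse-record features are
approximated on the wild-type structure: the structural blocks (signature,
interactions) are those of the forward wild-type residue, while the change
vector and sequence scores encode the reversed substitution. Rows built
this way are flagged in the feature matrix metadata. Pair keys are
symmetric in (wt, mut), so grouping constraints hold automatically;
`augment_reverse` refuses already-augmented input to prevent double
counting.

## Cross-validation protocol

Stratified group k-fold (scikit-learn's `StratifiedGroupKFold`, shuffled,
seeded) with the three-way ΔΔG class (or the pathogenicity label) as the
stratifier and the pair key as the group. Each repetition re-randomises the
folding with `seed + repetition`; the grouping constraint is audited inside
the loop and violations are a hard failure. Metrics: Pearson/Spearman/
Kendall τ-b/RMSE for regression (plus classification-by-regression MCC, F1
and per-class recall over the stabilising/destabilising subset, neutral
predictions counting as errors), and MCC/F1/trapezoidal ROC AUC/per-class
recall for classification. The Fisher r-to-z test
(z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))) compares correlations.

## Synthetic data: what it emulates and what it does not

`build_helix` emits ideal α-helices — the canonical transmembrane fold —
with CA atoms on a 2.3 Å cylinder rising 1.5 Å and turning 100° per
residue; N, C and O sit at fixed cylindrical offsets solved once so the
defaults reproduce ideal peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N(+1) 1.329 Å, C–O 1.231 Å; consecutive CA–CA ≈ 3.83 Å, CA(i)–CA(i+4) ≈
6.20 Å). CB is placed tetrahedrally, pointing outward. Side chains beyond
CB are not built: pharmacophore change vectors use table-derived residue
topologies, so rotamer geometry is unnecessary for exercising every
feature block. `build_dimer` places two helices at a chosen axis offset as
chains A and B for homo-oligomer tests.

`generate_dataset` samples mutations over these structures and plants a
known response: ΔΔG = w·z(selected signature features) + N(0, sd), or
labels from the median-thresholded score with a given flip rate. The
standard study conditions are 400 stability records with sd = 0.1 kcal/mol
and 500 pathogenicity records with a 10% flip rate, over three default
weights on graph-block features chosen (once) for having robust variance
across helix positions.

What passing recovery tests shows: the full chain — environment
extraction, signature computation, feature assembly, grouped stratified
CV, tree ensembles, metrics — preserves a planted signal at realistic
noise (pooled CV Pearson ≥ 0.9 at the stability conditions; CV MCC ≥ 0.6
at the pathogenicity conditions) and destroys it under label shuffling.
What it does not show: performance on real membrane proteins, whose side
chains, packing heterogeneity, lipid-facing asymmetry and measurement
error the generator does not emulate. One structural mismatch is worth
noting: the generator plants ΔΔG purely on wild-type-environment features,
so a reverse record's target is the negation of a signal its structural
features still point the *forward* way — direction is only recoverable
from the change-vector block. Reverse-augmented synthetic CV is therefore
*harder* than the forward-only condition (Pearson ≈ 0.78 vs ≈ 0.99 in the
acceptance run), whereas on real data the substitution identity carries
much of the signal. The acceptance script reports the augmented protocol
because that is the method's actual training regime.

## Numerical choices and degenerate inputs

* Alternate locations resolve to the highest-occupancy conformer (ties:
  first encountered, i.e. altloc A in a conforming file); first model only;
  HETATM and waters excluded.
* Distance-threshold comparisons use ≤ with a 1e-12 guard in the cutoff
  binning so an exact boundary distance is counted at its cutoff.
* Zero-variance inputs to correlations are errors, never silent zeros;
  single-class truth makes MCC an error; |r| = 1 makes the Fisher
  transform an error.
* The isoelectric point is solved by bisection (Brent) on the
  Henderson–Hasselbalch net-charge function with EMBOSS pKa values
  (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
  Y 10.1); the residual charge at the solution is < 1e-4.
* Histidine is typed as neutral aromatic donor/acceptor (pH-7 convention);
  proline's backbone nitrogen carries no donor class. Unknown
  (residue, atom) pairs type as empty with a warning so modified residues
  degrade gracefully instead of aborting.
* `X` in sequences is tolerated and excluded from weight/GRAVY with a
  warning; any other non-standard letter is an error.
* Tryptophan ring rules use the 6-membered benzene ring by default (the
  5-membered ring is available); an incomplete ring is an error listing
  the missing atoms.

## Design choices where the design was open

* The eight-class pharmacophore inventory and the per-atom typing table
  are a documented reconstruction shipped as an editable plain-text data
  file (`data/atom_typing.tsv`), not a hard-coded constant.
* "Bootstrap repetitions" of the CV protocol are implemented as
  independent re-randomised refoldings (recorded seeds make the procedure
  reproducible either way).
* The ΔΔG boundary values ±0.4 exactly are assigned to neutral: the outer
  classes are defined by strict inequalities, the remainder is neutral.
* Interaction rule constants ship as an editable rule set; all five
  implemented interaction types enter the feature vector.
* Problem sizes in tests and the acceptance script (400/500 records,
  10×10 or reduced-repetition CV) are the package's standard desk-scale
  conditions; they exercise every stage at full protocol fidelity.

## Known limitations

* No mutant-structure modelling; the mutant exists only through the change
  vector and sequence scores.
* Heavy-atom donor geometry (no hydrogens) and no halogen/weak hydrogen
  bond classes.
* No membrane-plane placement or topology prediction; no mmCIF input.
* The SASA/depth diagnostics are intentionally *not* part of the feature
  set — in membrane proteins they correlate poorly with mutational
  effects, which is the method's motivation.
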