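# memstab

Predicting the effects of single-point missense mutations on **membrane
proteins**: the change in folding stability (ΔΔG, kcal/mol) and the
likelihood that a variant is disease-associated.

Most mutation-effect predictors were trained on globular, soluble proteins
and transfer poorly to proteins embedded in the lipid bilayer, where the
usual burial heuristics break down — residue depth and solvent accessibility
barely correlate with mutational effects in the membrane. `memstab`
therefore describes a mutated residue's 3D environment with **graph-based
structural signatures**: atoms are nodes labelled by pharmacophore class
(hydrophobic, positive, negative, H-bond acceptor/donor, aromatic, sulfur,
neutral), edges connect atoms within a distance cutoff, and sweeping the
cutoff over a ladder d ∈ {1.0, 2.5, …, 10.0} Å yields, for every unordered
class pair (i ≤ j), the cumulative count

&nbsp;&nbsp;&nbsp;&nbsp;σ<sub>ij</sub>(d) = #{ (a, b) : class i ∋ a, class j ∋ b, ‖**r**<sub>a</sub> − **r**<sub>b</sub>‖ ≤ d },

a compact, rigid-motion-invariant summary of the environment's geometry and
chemistry (36 class pairs × 7 cutoffs = 252 features). To this are appended
the wild-type→mutant **pharmacophore change vector** (per-class atom-count
differences, which is how the mutant enters without modelling a mutant
structure), sequence-derived scores (BLOSUM62, hydropathy/volume/polarity/
flexibility differences, and global ProtParam-style properties), and counts
of the wild-type residue's **non-covalent interactions** (hydrogen bonds,
salt bridges, hydrophobic contacts, ring stacking, cation–π) detected with
geometric rules.

Two tree ensembles consume the feature rows:

* `StabilityRegressor` — extremely randomised trees predicting ΔΔG =
  ΔG<sub>WT</sub> − ΔG<sub>MT</sub> (negative = destabilising). Stability
  *classes* come from thresholding the prediction at ±0.4 kcal/mol
  (classification by regression).
* `PathogenicityClassifier` — a random forest emitting benign/pathogenic
  probabilities.

Training data can be balanced by **reverse-mutation augmentation**: each
measured forward mutation with |ΔΔG| < 2 kcal/mol contributes a hypothetical
reverse record with the negated value (ΔΔG<sub>WT→MT</sub> =
−ΔΔG<sub>MT→WT</sub>). A forward/reverse pair shares a grouping key and is
never split across training and test sides, and evaluation uses stratified
group 10-fold cross-validation repeated 10 times, reporting Pearson r,
Spearman ρ, Kendall τ-b, RMSE, MCC, F1 and ROC AUC, plus a Fisher r-to-z
test for comparing correlations.

Both estimators follow scikit-learn conventions (`fit`/`predict`/
`get_params`, fitted attributes with trailing underscores) and refuse
prediction inputs whose feature-name manifest does not match training.

## Worked example

Everything below runs on synthetic fixtures — ideal transmembrane-style
α-helices generated by the package itself (CA trace on a 2.3 Å cylinder,
1.5 Å rise and 100° twist per residue):

```sh
memstab make-fixtures --out fx                 # helix.pdb, dimer.pdb
memstab build-dataset --n 40 --seed 2 --out tab.tsv
# write structures for the dataset's protein ids, then train:
memstab train --table tab.tsv \
    --pdb HLX1=HLX1.pdb --pdb HLX2=HLX2.pdb --pdb DIM1=DIM1.pdb \
    --mode stability --seed 1 --out model.joblib
memstab predict-single --pdb fx/helix.pdb --chain A \
    --mutation V2A --model model.joblib
```

prints

```
V2A	-1.033 kcal/mol
```

i.e. replacing the valine at position 2 of chain A with alanine is predicted
to destabilise this helix by about 1 kcal/mol. Batch mode
(`memstab predict-list --list muts.txt ...`) emits one tab-separated row per
input line, in order, with per-row errors reported in an `error` column
rather than aborting the run:

```
mutation	prediction	probability	error
V2A	-1.033		
bogus			cannot parse mutation 'bogus': expected wild-type letter, residue number and mutant letter, e.g. 'W57A'
I4G			wild-type mismatch at A4: mutation expects I, structure has L (LEU)
```

The wild-type guard in the last row is deliberate: the mutation string must
match the residue actually found at that position in the structure, which
catches residue-numbering drift early.

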