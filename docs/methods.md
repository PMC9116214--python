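# Methods

## The correction term

The package treats pose quality as a regression target: the
symmetry-corrected heavy-atom RMSD (Å) of a docked ligand pose with
respect to the native pose of its complex. A model that predicts this
quantity from structure alone, *S*(ℝ), can be added to any docking score
*P*(ℝ) as a penalty on non-native-like geometry:

E(ℝ) = α·P(ℝ) + β·S(ℝ), default α = β = 0.5.

*S* is measured in Å while *P* is an energy-like score, so *E* mixes
units. The combination is nevertheless meaningful as a pseudo-free
energy: *S* = 0 identifies a single (native-like) state and larger *S*
corresponds to an increasingly diverse ensemble of wrong states, which is
qualitatively how binding free energy behaves. The default weights are
appropriate for Vina-scale scores (roughly −12 to −2 kcal/mol); they are
not re-optimised for other engines, whose scores can still be supplied
as *P*.

## Featurization

A complex is summarised by counting protein–ligand heavy-atom pairs in
concentric distance shells, aggregated by the protein atom's residue
class and the ligand atom's element class:

- residue alphabet: the 20 standard amino acids plus `OTH` (21 classes);
  non-standard residues, and anything unrecognised, fall into `OTH`;
- element alphabet: C, N, O, S, P, `HAL` (F/Cl/Br/I pooled) and `OTH`
  (7 classes); hydrogens never enter (all structures are reduced to heavy
  atoms on read);
- shells: 14 half-open bins `[ (k−1)·1.5, k·1.5 )` Å from 0, covering
  contacts below 21 Å.

This gives 21 × 7 × 14 = 2058 integer bins whose total equals the number
of atom pairs within 21 Å — an exactly checkable pair census. Counting
atom–atom pairs (rather than residue-level minimum distances) and the
0 Å shell origin are our conventions; both are configurable through
`ShellScheme`. The vector is invariant under rigid motions of the whole
complex and sensitive to how the ligand sits in the pocket. The bin
ordering (residues alphabetical then `OTH`; elements C, N, O, S, P, HAL,
OTH; shells ascending) is hashed with the alphabets into a `schema_id`
that travels with feature frames and model artifacts; mismatches are
errors, not warnings.

## Pose RMSD

Docking RMSD is computed in the fixed receptor frame with no
superposition — a translated pose is a wrong pose, and superposition
would hide that. Chemically equivalent atoms are handled by minimising
over the automorphisms of the ligand's bond graph with elements as
vertex colours (the `obrms` convention): a benzene ring rotated 60° in
place has RMSD 0. Bond orders are deliberately ignored during matching,
since a ring rotation maps formal single bonds onto double bonds while
being the same pose. Automorphisms are enumerated with a cap (default
10 000); molecules whose symmetry group exceeds the cap fall back to the
identity mapping with a `capped` flag rather than stalling.

## The regressor

`train_sfct` fits scikit-learn's `AdaBoostRegressor` with a
`RandomForestRegressor` base — the exact estimator family and
hyperparameters the method prescribes: 10 boosting rounds, 50 trees per
forest, `max_features=512`, `max_depth=50`, `oob_score=True`, AdaBoost
loss `linear` (the AdaBoost.R2 default; the loss is not otherwise
pinned down). Everything is deterministic given the `seed`
hyperparameter.

Training-set conventions:

- crystal/native poses enter with label exactly 0 Å;
- poses with label > 10 Å are excluded (strictly: 10.0 Å is kept) —
  such poses sit outside the binding site and only add target noise;
- splitting is group-aware by native complex, so no complex contributes
  poses to both the training and validation side (pose-level splits leak
  badly because poses of one complex share most contacts);
- predictions are clamped at 0 Å, since a boosted ensemble can
  extrapolate below the physical floor.

Per-bin impurity importances (boosting-weight averaged) are exposed as a
(residue class × element class × shell) table for heatmap-style
inspection of which contacts drive the prediction.

Model artifacts are single joblib files with an embedded format version,
`schema_id`, hyperparameters and training summary; loading a truncated,
unversioned or schema-mismatched artifact raises a format error.

## Synthetic corpus

No external structures or docking engines are used anywhere; the
generator supplies all study material.

**Toy complexes.** A ligand is grown as a random connected tree with
~1.5 Å bonds and a drug-like element palette (68% C, 12% N, 12% O, 3% S,
3% Cl, 2% F). Pocket residues (backbone N/CA/C/O plus a residue-typed
number of side-chain heavy atoms) are anchored to randomly chosen ligand
atoms at 3–6.5 Å gaps, guaranteeing short-range contacts, with a hard
≥ 1.5 Å protein–ligand clearance. This emulates the feature geometry of
a binding site — contact shells populated near the ligand, emptying with
distance — not protein physics: there is no secondary structure, no
force field, no realistic side-chain rotamers. Passing tests therefore
demonstrate that the method recovers pose-quality signal from contact
geometry, not that it reproduces benchmark numbers on real complexes.

**Decoys.** Each decoy is a rigid perturbation of the native pose (plus
optional torsion moves about acyclic single bonds). For a rotation by θ
about an axis through the centroid, the displacement RMSD is
2·sin(θ/2)·√(mean |v⊥|²), and a subsequent translation adds in
quadrature; the generator inverts these closed forms to hit a stratified
grid of target RMSDs over the requested range exactly (rejection
sampling would achieve the same spectrum less directly). Default: 90
decoys per native spanning 0.2–12 Å, so both the ≤ 2 Å and the ≥ 8 Å
tails are well populated and the > 10 Å training filter has something to
remove. Every label is re-measured from the decoy coordinates with the
package's own symmetry-corrected RMSD, never taken from the target.

**Pseudo scores.** Engine scores are emulated as
P = base + coupling·RMSD + N(0, σ), defaults −9 kcal/mol, 0.4 kcal/mol/Å
and σ = 1 kcal/mol — Vina-range values with a realistic, imperfect
correlation to pose quality. Setting `rmsd_coupling = 0` produces the
adversarial case where *P* carries no pose-quality information, which
isolates the correction term's contribution in rescoring experiments.

**Screening libraries.** One shared toy receptor; each ligand gets its
own random topology and a pose set displaced from an in-pocket placement
— actives by 0.3–2 Å, decoy ligands by 4–10 Å. Actives therefore present
strong short-shell contacts (low predicted *S*) and better pseudo-scores.
The shipped scale (tens of actives, low hundreds of decoys, 5 poses per
ligand) keeps the enrichment factor well defined at the 1% level while
staying desk-sized; real screening decks are two orders of magnitude
larger and far more chemically diverse.

## Evaluation conventions

- **Top-N success rate**: fraction of complexes with a pose ≤ 2.0 Å
  (inclusive boundary, the CASF convention) among the N best-ranked.
- **Average top-1 RMSD**: mean over complexes of the top-ranked pose's
  RMSD.
- **Enrichment factor** at fraction f: actives-in-bucket concentration
  over base rate, bucket size ⌈f·N⌉ (rounding up keeps the bucket
  non-empty for any f > 0), ranking ascending with stable input-order
  tie-breaking.
- **ROC-AUC**: Mann–Whitney formulation on negated scores, ties ½.
- **Ranking determinism**: rescoring sorts by E, then lower P, then
  input order; ligand-level screening scores take the best E among the
  first 20 poses in engine output order; reverse screening ranks
  proteins by their best pocket score with lexicographic tie-breaks.

## Benchmark sizes

The packaged benchmark used by the test suite and `scripts/acceptance.py`
is 200 complexes × (1 native + 20 decoys), split 160/40 by complex; the
screening run uses 20 actives vs. 180 decoy ligands. These sizes give
stable metrics (held-out Pearson r and RMSE computed on ~700 poses;
success rates on 40 complexes; EF on a 200-ligand deck) while the whole
pipeline stays in the minutes range on a single CPU.

## Known limitations

- The synthetic pocket model has no chemistry beyond element identity and
  distance; absolute metric values on it do not transfer to PDB-scale
  benchmarks, only the qualitative behaviours (signal recovery, rescoring
  benefit, enrichment) do.
- The α = β = 0.5 weighting is only calibrated for Vina-scale scores.
- Torsional decoy perturbation treats all acyclic single bonds as freely
  rotatable and ignores ring conformers.
- PDBQT ligand connectivity is perceived from covalent radii (the format
  has no bond block); exotic coordination geometries may gain or lose a
  bond, which can alter the automorphism group used for symmetry RMSD.
- Receptor preparation removes all free-standing hetero molecules by
  default, including structural metals near the pocket; retaining them is
  possible via `strip_hetero=False` but they are then classified `OTH`.
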