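# funcsites

Discover functionally important sites in proteins by separating conservation
due to *function* from conservation due to *structural stability*.

Sequence conservation flags residues that matter, but not *why* they matter:
a position can be conserved because substitutions unfold the protein, or
because they break catalysis, binding or regulation while leaving the fold
intact. Paired multiplexed assays of variant effects (MAVEs) that read out
both cellular **abundance** and **activity** can tell these apart: variants
that lose activity but keep wild-type-like abundance — **stable but inactive
(SBI)** variants — mark residues with a direct functional role.

`funcsites` implements that idea as a supervised pipeline for structural
bioinformaticians and protein scientists:

1. **Features** per substitution: predicted stability change ΔΔG (Rosetta-style,
   rescaled to kcal/mol and clamped to [0, 5]), evolutionary conservation ΔΔE
   (GEMME-style, 0 to −7), their per-residue and flanking-neighbour averages,
   the target residue's hydrophobicity, and the weighted contact number

       WCN_i = Σ_{j≠i} s(r_ij),   s(r) = (1 − (r/r₀)⁶) / (1 − (r/r₀)¹²),  r₀ = 7 Å

   computed from Cα–Cα distances (evaluated via the equivalent
   singularity-free form 1/(1 + (r/r₀)⁶)).
2. **Labels** from paired MAVE data: each assay's score distribution is fitted
   with a three-Gaussian mixture and thresholded at the intersection of the
   outer components; the two binary calls combine into four classes —
   WT-like, total-loss, SBI, low-abundance/high-activity.
3. **Model**: a gradient-boosted multiclass classifier (multinomial
   cross-entropy, L2 leaf regularization) over the 8 features, tuned by
   stratified 5-fold cross-validation, with a most-frequent-class null model
   and a random-forest comparator.
4. **Sites**: a residue is assigned a class when ≥ 50% of its classified
   variants share it; positions with ≥ 50% SBI variants are called
   **functional sites**. Running the model with monomer- vs oligomer-context
   ΔΔG exposes protein–protein interface residues (functional → total-loss
   transitions).

External predictors (Rosetta/RaSP, GEMME) are *not* run here; their output
matrices are consumed as files. A synthetic-fixture generator with planted
class structure makes every stage testable end to end without downloads.

## Worked example

```python
import funcsites as fs
from funcsites.structure import per_position_wcn

# synthetic dataset with planted ground truth (160 residues, 3040 variants)
spec = fs.FixtureSpec(n_residues=160, seed=0)
fx = fs.make_fixture(spec)

wcn = per_position_wcn(fx["structure"])                   # r0 = 7 A
table = fs.assemble_features(fx["ddg"], fx["dde"], wcn)   # 8-feature table
labelling = fs.label_mave(fx["mave"], seed=0)             # 4-class labels

model = fs.VariantClassifierModel.from_tables(table, labelling.data, seed=0)
results = model.fit()
print(results.summary())

pred = results.predict(table)
assignments = fs.assign_residues(pred)
print(assignments.loc[assignments["functional_site"], "position"].tolist())
```

prints

```
Variant classifier (gradient-boosted trees)
===============================================
n variants        3040
classes           WT_like, total_loss, SBI, low_abundance_high_activity
features          ddG_variant, ddE_variant, ddG_residue_avg, ddE_residue_avg, ddG_neighbour_avg, ddE_neighbour_avg, hydrophobicity_target, wcn
iterations        31
hyperparameters   {"max_depth": 6, "learning_rate": 0.1, "reg_lambda": 3.0}
seed              0
-----------------------------------------------
CV accuracy       0.978 (5 folds)
CV MCC            0.963
[7, 14, 34, 36, 42, 45, 50, 52, 54, 57, 58, 59, 65, 69, 73, 78, 79, 80, 85, 87, 103, 105, 122, 134, 135, 138, 146, 154, 160]
```

The classifier reaches 97.8% stratified-CV accuracy on this strongly
separated synthetic dataset, and the 29 positions it calls functional sites
are exactly the 29 planted SBI positions. (Real paired-MAVE data are far
noisier; the synthetic regime tests the machinery, not real-data accuracy.)

The same steps are available from the shell:

```sh
funcsites make-fixture --seed 0 --out fixture/
funcsites featurize --pdb fixture/structure.pdb --ddg fixture/ddg.csv \
    --dde fixture/dde.csv --out feat/
funcsites label-mave --mave fixture/mave.csv --seed 0 --out lab/
funcsites train --features feat/features.csv --labels lab/labels.csv --out run/
funcsites predict --model run/model.joblib --features feat/features.csv --out run/
funcsites assign-sites --predictions run/predictions.csv \
    --structure fixture/structure.pdb --out run/
```

Every output directory gets a `manifest.json` with the config, input digests
and seeds; reruns with the same inputs and seed are byte-identical.

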