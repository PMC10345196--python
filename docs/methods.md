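# Methods

## Model

`funcsites` classifies single amino-acid substitutions into four classes —
WT-like, total-loss, stable-but-inactive (SBI), low-abundance/high-activity —
and aggregates the calls per position to nominate functional sites. The
underlying assumption is biophysical: loss of function can be mediated by
loss of stability/abundance (destabilising ΔΔG, usually buried, high packing)
or by direct perturbation of a functional site (strongly conserved ΔΔE with
small ΔΔG). Neither stability nor conservation alone separates the classes;
the classifier learns their joint structure.

### Features (fixed order, per substitution)

| # | feature | units | source |
|---|---------|-------|--------|
| 1 | `ddG_variant` | kcal/mol, clamped [0, 5] | stability predictor matrix |
| 2 | `ddE_variant` | dimensionless, ≈[−7, 0] | conservation predictor matrix |
| 3–4 | `ddG_residue_avg`, `ddE_residue_avg` | as above | mean over the position's available substitutions (wild-type self-substitutions excluded) |
| 5–6 | `ddG_neighbour_avg`, `ddE_neighbour_avg` | as above | mean pooled over all substitution values at positions i−1 and i+1 |
| 7 | `hydrophobicity_target` | Kyte–Doolittle hydropathy | scale table (configurable TSV) |
| 8 | `wcn` | dimensionless ≥ 0 | structure, Cα-based |

ΔΔG input in raw Rosetta energy units is divided by 2.9 to approximate
kcal/mol, then clamped to [0, 5] kcal/mol; normalisation is idempotent and
order-preserving. ΔΔE is used exactly as read; values outside [−7, 0] only
raise a warning since upstream tools can emit small excursions.

The weighted contact number uses the switching function
s(r) = (1−(r/r₀)⁶)/(1−(r/r₀)¹²) with r₀ = 7.0 Å over all Cα–Cα pairs in the
structure given (so an oligomeric input yields oligomer-context WCN). The
printed rational form is 0/0 at r = r₀; we evaluate the algebraically
identical factored form 1/(1+(r/r₀)⁶), which carries the removable
singularity's limit (1/2) and is monotone decreasing on (0, ∞). No distance
cutoff or neighbour list is used — the full O(n²) sum is exact and cheap for
chains up to a few thousand residues. In homo-oligomers the per-position WCN
used for the feature table is the mean over chains.

Relative solvent accessibility (Shrake–Rupley over heavy atoms, normalised by
per-residue-type theoretical maxima, buried below 20%) is provided for
stratified analyses only; it is deliberately **not** a classifier feature.

### Labelling

Each assay's score distribution is fitted with a three-component Gaussian
mixture (EM, k-means initialisation, 10 restarts, best likelihood kept,
deterministic per seed). The binary threshold is the score where the outer
components' weighted densities intersect, solved in closed form from the
quadratic (linear when the variances are equal); the root strictly between
the outer means is taken, as that is the decision-boundary reading of the
cutoff. The middle component only absorbs intermediate-effect variants.

Assay orientation (whether larger scores mean functional/abundant) is a
required configuration field, never inferred from the data. Scores exactly at
the threshold count as "high"; thresholds are continuous so ties are
measure-zero, the choice merely needs to be fixed. The 2×2 combination of
calls maps (high, high) → WT-like, (low, low) → total-loss, (high, low) →
SBI, (low, high) → low-abundance/high-activity.

**Tied variances.** Components share one variance by default. The
intersection threshold sits several standard deviations into both outer
tails, where its location is amplified ~(d/2σ)-fold against errors in the
fitted variances (d = distance from mean to crossing). With free
per-component variances, ordinary sampling noise at n = 5000 moves the
threshold by 2–4% of the mode spacing; tying the variance pools the estimate
over the whole sample and removes the instability, while displacing the
ideal threshold negligibly for well-separated, comparably wide modes — the
regime where a mixture threshold is meaningful at all. Free variances remain
available (`covariance_type="full"`).

### Classifier

Gradient-boosted trees (LightGBM) with multinomial cross-entropy loss and L2
leaf regularization, run deterministically (single thread, fixed seed), so
the full train → predict path is bit-identical for a fixed seed, input order
and hyperparameters. The iteration count is fixed first on the default
setting by early stopping (one stratified 20% holdout, patience 50, at most
2000 rounds); the remaining hyperparameters are then grid-scanned — depth
{4, 6, 8}, learning rate {0.03, 0.1, 0.3}, L2 {1, 3, 10} by default — by
mean stratified 5-fold CV accuracy, and the winner is refitted on all data.
Class weights are uniform by default (`class_weighting=True` enables
inverse-frequency weights). Metrics: accuracy, per-class precision/recall,
generalized (Gorodkin) multiclass Matthews correlation coefficient, and the
confusion matrix. Baselines: a most-frequent-class null model (ties broken
lexicographically) and a random-forest comparator evaluated on the same
folds. Rows with any missing feature never enter training or prediction;
they are reported as unpredicted and excluded from metric denominators.

### Residue assignment

Per position, class fractions use the number of *classified* variants at
that position as the denominator (not a fixed 19), mirroring partial-coverage
accounting. The class with fraction ≥ 0.5 is assigned; an exact 50/50
two-class tie yields "unclassified" with a tie note — a tie has no
majority-like winner. A position is a functional site iff its SBI fraction
is ≥ 0.5 (so a 50/50 SBI tie still flags functional). For single-assay
validation the four classes project onto two: function mode keeps the
activity axis (WT-like + low-abundance/high-activity = functional),
abundance mode keeps the abundance axis (WT-like + SBI = high). These
projections invert the label construction exactly.

Monomer- vs oligomer-context runs are compared by reference-sequence
position; positions moving functional-site → total-loss are reported as
candidate interface residues, since their conservation is explained by
oligomer-context stability.

## Synthetic data generator

The generator emulates the *statistical* structure of the real problem, not
protein physics:

* **Geometry** — an idealised Cα helix (rise 1.5 Å, radius 2.3 Å, 100°/residue;
  consecutive Cα–Cα ≈ 3.8 Å), folded into an antiparallel bundle (axes
  10 Å apart) so packed (high-WCN) and exposed (low-WCN) positions exist by
  construction. Arm junctions are not geometrically continuous.
* **Scores** — each position gets a planted class (defaults: 52% WT-like,
  25% total-loss, 15% SBI, 8% low-abundance/high-activity, roughly the
  class-imbalance ordering seen in paired-MAVE datasets); each variant
  inherits it with probability 0.9 (the rest are WT-like, emulating tolerated
  substitutions). ΔΔG/ΔΔE are drawn from class-conditional normals —
  SBI: (0.6, −5.0), total-loss: (4.0, −5.0), WT-like: (0.6, −0.8),
  low-abundance/high-activity: (4.0, −0.8) (ΔΔG, ΔΔE means; sds 0.4–1.0) —
  clipped to the valid ranges. By construction ΔΔG alone cannot separate SBI
  from WT-like and ΔΔE alone cannot separate SBI from total-loss; only the
  combination can, which is the premise the classifier is meant to test.
* **MAVE scores** — trimodal per assay (components at 0, 0.5, 1 with sd 0.08,
  i.e. >6 sd apart: the strong-separation regime), component membership
  dictated by the planted class. 2% of draws per assay come from the middle
  component so the fitted three-Gaussian mixture has genuine central mass;
  the fraction is kept small so planted labels remain recoverable.
* **Interface** — 6 of the planted SBI positions are designated interface;
  the oligomer-context ΔΔG matrix re-draws their variants from the
  total-loss stability profile floored at 3.2 kcal/mol.

Every artefact is a pure function of the serialisable `FixtureSpec` and its
seed. Passing tests on these fixtures demonstrates that the machinery —
thresholding, training, aggregation, comparison — recovers planted truth
under clean, well-separated conditions. It says nothing about accuracy on
real MAVE data, where score distributions overlap heavily, assays disagree,
predictors are biased, and coverage is incomplete.

## Default problem sizes

Unit and pipeline tests use fixtures of 50–220 residues. The repeatable
verification script (`scripts/acceptance.py`) uses: 50 random structures of
100–200 residues for the WCN oracle, 10⁵ values for normalisation
properties, 10 × 5000 scores for threshold recovery, 1000 random tables for
the assignment oracle, and a 220-residue / 4180-variant fixture for the
classifier and end-to-end site recovery.

## Known limitations

* Fixtures are statistical stand-ins; no real-data accuracy claims are made
  or reproduced here, since the real training inputs require external
  downloads and external predictors (Rosetta/RaSP, GEMME, MSAs).
* Residues important for *both* function and stability are intrinsically
  missed by the SBI signature (they present as total-loss).
* PDB input only (first model of multi-model files); no mmCIF, no DSSP.
* The exposure calculation normalises by theoretical maximal areas and will
  not numerically match server-based tools; it is analysis-only.
* ΔΔE is consumed as produced upstream; no MSA construction or filtering.
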