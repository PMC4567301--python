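# Methods

## The prediction problem

A single point mutation changes a protein's thermodynamic stability.
Two experimental readouts are modelled: the change in unfolding free
energy, ddG (kcal/mol), and the change in melting temperature, dTm
(degC).  Throughout the package, *positive values are stabilizing*; a
`flip_sign` curation flag accommodates sources with the opposite
convention.  `mutstab` treats the problem as tabular QSAR: each curated
mutation becomes a nine-descriptor vector, and classical learners are
trained either to classify mutations as stable / neutral / unstable or
to regress the continuous value.

## Curation

Curation (`mutstab.records.curate`) reproduces the filters typical of
ProTherm-derived benchmark sets:

* pH window [6, 8] (physiological conditions); records outside are
  dropped, records with no pH recorded are kept;
* monomeric proteins of at most 300 residues;
* replicate measurements of the same mutation — keyed on (protein,
  chain, wild-type residue, position, mutant residue) — are collapsed
  to their arithmetic mean;
* for ddG sets only, |ddG| > 10 kcal/mol is trimmed as likely
  measurement error.  The trim is applied *after* replicate averaging by
  default (`cap_after_averaging`), so a single wild replicate cannot
  delete an otherwise consistent mutation; the flag allows the opposite
  order.

Output is sorted by (protein, chain, position, mutant residue) so that
every downstream seeded split is reproducible from the input file alone.

## Class labels

Classes are defined by two boundary pairs with a deliberate gap between
them: for ddG, unstable <= -1, neutral in [-0.5, 0.5], stable >= 1
(kcal/mol); for dTm, unstable <= -3, neutral in [-1, 1], stable >= 3
(degC).  All boundaries are inclusive for their class; values inside
the open gaps (-1, -0.5), (0.5, 1) etc. are *excluded* from
classification tasks but retained for regression.  Binary tasks use
stable vs unstable only.

## Descriptors

Nine descriptors in a fixed column order:

| column | meaning | units |
| --- | --- | --- |
| delta_MW | residue mass difference (mut - wt) | Da |
| delta_Chg | formal side-chain charge difference at pH 7 | e |
| delta_ARM | aromatic indicator difference (F/W/Y = 1) | — |
| delta_Hydro | Kyte–Doolittle hydropathy difference | — |
| delta_VdwV | van der Waals volume difference | A^3 |
| delta_SASA | extended-state (Ala-X-Ala) surface area difference | A^2 |
| SecSt | secondary structure at the site: helix 1, sheet 2, coil 3, turn 4 | ordinal |
| ASA_pct | raw ASA / extended-state ASA of the wild-type residue | % |
| rosetta_ddg | Rosetta DDG_monomer score, consumed as an input column | score units |

Property scales ship as plain-text CSVs (`mutstab/data/`) naming their
literature source, and any scale can be swapped via
`PropertyTable.with_scale` — the choice of hydrophobicity scale, of the
His charge, and of the volume set are genuinely open, and only affect
their own column.  ASA_pct is not clipped at 100%: an observed ASA can
exceed the extended-tripeptide reference.  SecSt is kept as a single
ordinal feature rather than one-hot, mirroring how such models are
usually published; this encodes an arbitrary ordering and is a known
modelling quirk, not a recommendation.  Computing ASA or secondary
structure from coordinates, and running Rosetta itself, are out of
scope: both are inputs.

## Reverse-mutation augmentation

ddG and dTm are state functions, so the reverse mutation B->A of a
measured A->B has the negated value; the six property deltas and the
Rosetta score negate with it, while the two site descriptors (SecSt,
ASA_pct) are unchanged, and labels flip stable<->unstable.  Because
measured sets are dominated by destabilizing mutations, the combined
forward+reverse set is exactly class-balanced for binary tasks.
Reverse rows keep the source protein identifier so that a protein-level
split never separates a forward mutation from its reverse (any other
choice would make reverse-mutation testing tautological), and carry a
`direction` provenance column.  No structural relaxation of the mutant
is attempted — reverse rows are hypothetical by construction.

## Learners, tuning, and evaluation

Six families: RBF-kernel SVM, random forest (500 trees), Gaussian
naive Bayes (classification only), K nearest neighbors, a single hidden
layer neural network (lbfgs), and PLS (PLS-DA with one-hot targets and
argmax decoding for classification).  Features are standardized inside
the pipeline, so scaling parameters derive from training rows only; a
zero-variance column triggers a warning and is left unscaled.
Hyperparameters are tuned by grid search scored with seeded 10-fold CV
(accuracy, or RMSE for regression); defaults:

* SVM: C in {0.25, 0.5, 1, 2, 4}, kernel width from the median
  pairwise-distance heuristic on the standardized training rows;
* random forest: features-per-split in {2, 3, 5};
* KNN: k in {3, 5, 7, 9, 11};
* neural net: hidden size {1, 3, 5}, weight decay {0, 0.01, 0.1};
* PLS: 1–8 components.

All grids are config-overridable.  The reported CV metric is the pooled
out-of-fold accuracy of the tuned model, or for regression the squared
Pearson correlation between pooled out-of-fold predictions and observed
values — R^2 is the squared correlation throughout, so Pearson's r is
its square root, and zero-variance predictions report R^2 = 0 with a
warning.  Held-out evaluation uses a seeded 80/20 split: random by row,
or by whole protein (`by_protein`) for non-redundant testing where no
protein — hence no residue position — appears on both sides.  ROC
curves use "stable" as the positive class (AUC is reflection-invariant
to this choice).  Ternary accuracy is plain multiclass accuracy.  No
class reweighting is applied; imbalance is addressed only by the
reverse-mutation augmentation.  No multiple-testing correction is
involved anywhere — raw metrics are reported.

## Feature selection

Recursive feature elimination runs backward from all nine descriptors
to one: at each size, feature importance is scored (native impurity
importance averaged over seeded bootstrap refits for random forests;
drop-one-column CV loss otherwise) and the least important feature is
eliminated, receiving the current subset size as its rank; the last
survivor has rank 1.  Ties break by column order.  The acceptance
surface is the rank order, not importance values, which are estimator
specific.  The single-feature baseline is an ordinary least squares fit
of the target on one descriptor (by default `rosetta_ddg`), scored as
held-out R^2 on the same kind of 80/20 split; because a 160-row test
half makes a single-split R^2 noisy, summary numbers average it over
eight split seeds.

## Synthetic data

`synth.generate` plants a linear target — a weighted sum of the nine
descriptors plus Gaussian noise — on records with random residue pairs,
secondary structure, exposure and Rosetta scores, so every stage has a
testable known answer.  `synth.synthetic_benchmark` emulates the shape
of a curated ProTherm-derived sheet: exactly 798 ddG mutations over 51
proteins with ternary counts 323 neutral / 69 stable / 406 unstable,
and 799 dTm mutations over 82 proteins with 223 / 141 / 435.  Its
latent model is calibrated, once, to the correlation structure such
curated sets exhibit: the affine map from the unit-variance latent to
target units is solved analytically so the latent-normal class
proportions equal the published counts (making the exact-count
subsample a uniform thinning), and the variance shares are set so the
qualified rows show a marginal Rosetta R^2 near 0.22 (ddG) / 0.21 (dTm)
and a full-linear-model R^2 near 0.49 / 0.32 — dropping gap-zone rows
inflates target variance, which the pool-level constants compensate
for.  The non-Rosetta weights put percentage exposure and
hydrophobicity next in importance, matching the ranking feature
selection finds on real curated sets.

What the emulation does *not* reproduce: real structures or Rosetta
physics; inter-descriptor relationships beyond those induced by using
real residue property tables; measurement heteroscedasticity; and —
importantly — any nonlinear feature-target structure.  The latent model
is linear, which systematically flatters kernel/linear learners over
random forests: on real curated data RF ties SVM, whereas on the
emulation RF trails it by several accuracy points in the ternary task
and by ~0.06 R^2 in dTm regression.  Passing model-performance checks
on this emulation therefore demonstrates that the pipeline wiring,
tuning, and metric computations behave as intended at realistic size
and class skew — not that the learners would reach the same numbers on
any particular real data set.

## Problem sizes and numerical choices

Tests and the summary script run the benchmark at its natural size
(798/799 rows) with 10-fold CV and the default grids; CV checks in the
test suite average two dataset seeds, the summary script averages three
dataset/split replicates, and the single-feature baseline averages
eight split seeds.  Random draws all flow from explicit
integer seeds through `numpy.random.default_rng`; identical (data,
spec, seed) gives identical metrics to machine precision.  The
`by_protein` split adds randomly ordered proteins until the training
side first reaches 80% of rows, so the realized training fraction is
slightly above 0.8.  PLS component counts are capped at the number of
surviving features during elimination.  Degenerate inputs (single-class
label vectors for AUC, fewer rows than folds, zero-variance baseline
features, empty curation output) raise explicit errors rather than
returning sentinel values.

## Known limitations

* Multi-point mutations are out of scope.
* The exact property scales behind the hydrophobicity, charge,
  aromaticity and volume columns are a convention choice; shipped
  defaults are documented in the data files and swappable.
* Rosetta scores are taken as given; their accuracy bounds the whole
  model, as feature ranking (Rosetta rank 1 in every task) suggests.
* The ordinal SecSt encoding imposes an arbitrary metric on secondary
  structure classes.
* Reported metrics on the synthetic benchmark carry the linear-latent
  caveat above.
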