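# mutstab

QSAR models for the thermostability effect of protein single point
mutations.

Protein engineers screen mutants for thermostability — a slow and
expensive experiment — so an *in silico* predictor that triages a
mutagenesis library is valuable.  `mutstab` builds such predictors from
curated tables of measured single point mutations: the change in
unfolding free energy (ddG, kcal/mol) or in melting temperature (dTm,
degC), with **positive = stabilizing** throughout.

Each mutation is described by nine descriptors in three layers:

1. **physical** — differences (mutant − wild type) of six per-residue
   properties: molecular weight, formal charge, aromaticity,
   hydrophobicity, van der Waals volume, and extended-state solvent
   accessible surface area (ΔMW, ΔChg, ΔARM, ΔHydro, ΔVdwV, ΔSASA);
2. **structural** — secondary structure at the mutation site (helix=1,
   sheet=2, coil=3, turn=4) and percentage exposure
   ASA% = 100 · ASA / ASA_ext(X), where ASA_ext(X) is the residue's
   area in an extended Ala-X-Ala tripeptide;
3. **energetic** — a Rosetta DDG_monomer score, consumed as an input
   column (Rosetta itself is not run here).

Mutations are labelled **stable** (ddG ≥ 1, dTm ≥ 3), **neutral**
(|ddG| ≤ 0.5, |dTm| ≤ 1) or **unstable** (ddG ≤ −1, dTm ≤ −3), with the
gap zones excluded from classification; six learner families (RBF SVM,
random forest, naive Bayes, KNN, a small neural network, PLS/PLS-DA)
are tuned by grid search under seeded 10-fold cross-validation and
scored on held-out 20% splits — either random rows or whole proteins
(non-redundant).  Because measured sets are dominated by destabilizing
mutations, hypothetical **reverse mutations** (negate the target, the
property deltas and the Rosetta score; keep the site descriptors; flip
the label) can balance training exactly.  Recursive feature elimination
ranks the descriptors; a single-feature linear regression on the
Rosetta score provides the baseline the full models must beat.

## Worked example

All data here is synthetic: `synth.benchmark_dataset` emulates the
shape of a curated ProTherm-derived benchmark (798 ddG mutations over
51 proteins; class skew 323 neutral / 69 stable / 406 unstable), so the
example runs with no downloads.

```python
from mutstab import StabilityModel, synth

ds = synth.benchmark_dataset("ddg", "binary", seed=1)
res = StabilityModel(ds, "svm_rbf", seed=1).fit()
print(res.summary())
```

```
Thermostability prediction model
================================================
target:        ddg
task:          binary
algorithm:     svm_rbf
train rows:    380 (51 proteins)
test rows:     95 (38 proteins)
tuned params:  {'est__C': 4.0}
CV accuracy:  0.921
test accuracy: 0.947
test AUC:      0.971
confusion matrix (rows = observed):
          stable  unstable
stable         9         3
unstable       2        81
```

The binary task uses only the 69 stable + 406 unstable mutations (380
train / 95 test).  CV accuracy 0.921 is the pooled out-of-fold accuracy
of the tuned SVM on the training side; the held-out test accuracy
(0.947) being comparable indicates the model is not overfitted to the
training rows.  The AUC treats "stable" as the positive class.  Useful
follow-ups: `res.evaluate(...)` to score the same fitted model on
another set (e.g. the reversed test set), `res.rfe_ranks()` for the
descriptor importance ranking — the Rosetta score ranks first in every
task — and `augment="combined"` for reverse-mutation-balanced training.

The same pipeline is scriptable from a shell:

```
mutstab synth --benchmark --target ddg --seed 1 --out bench.csv
mutstab train bench.csv --task binary --algorithm svm_rbf --seed 1 --out report.json
mutstab run config.yaml --out reports/
```

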