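# ecknn

Multi-label prediction of Enzyme Commission (EC) numbers for proteins
represented as sparse binary vectors of InterPro-style signature presence,
using binary-relevance k-nearest neighbours — together with the full
evaluation machinery such a predictor needs (subset accuracy,
micro/macro/example-based metrics, seeded cross-evaluation,
leave-species-out proteome reannotation, redundancy reduction, baselines,
significance testing) and a synthetic annotation-database generator so the
whole pipeline is testable without downloading UniProt/KEGG/InterPro.

## The problem

Assigning enzymatic function is one of the first steps of metabolic
reconstruction, and manual curation cannot keep pace with sequencing.  EC
numbers classify enzymatic reactions with a four-field code (`1.2.3.4`);
annotations may be *incomplete* (`1.2.-.-`), proteins may carry *several*
EC numbers, and a large minority of proteins are non-enzymes.  Conserved
sequence signatures (InterPro domains, sites, repeats), computable from
sequence alone, turn each protein into a sparse binary attribute vector —
a remarkably compact representation: whole curated corpora collapse onto a
few hundred thousand distinct signature sets.

## The method

Prediction is **binary-relevance k-NN (BR-kNN)** with `k = 1` by default.
Binary relevance turns a *L*-label problem into *L* one-vs-rest problems,
but all of them share the same neighbour search: for a query vector **q**
the Euclidean distance to every training vector is computed **once**
(over binary coordinates, `d(a, b) = sqrt(|A Δ B|)`, the symmetric
difference of the signature sets — an integer under the root, so ties are
exact).  The neighbour set is the k nearest training instances including
every tie at the k-th distance; each label's confidence is the fraction of
that set carrying the label, and labels with confidence ≥ 0.5 are
predicted.  At `k = 1` without ties this copies the nearest neighbour's
label set.  Label sets are stored *hierarchically expanded* (a protein
annotated `1.2.3.4` carries `1.-.-.-`, `1.2.-.-`, `1.2.3.-`, `1.2.3.4`),
and an empty predicted set is the cumulative "no-EC" (non-enzyme) call.

The headline metric is **subset accuracy** — the fraction of proteins
whose predicted label set *exactly* equals the true set; predicting three
of four labels of a chain scores zero for that protein.  Micro averages
pool the confusion counts over all labels (favouring frequent classes),
macro averages weight all classes equally (exposing rare-class recall),
and example-based metrics average per-protein set overlap.  Two samples
of fold-level results are compared with
`t = (X − M) / (sd / √n)` (reference mean X and standard deviation sd,
`n − 1` degrees of freedom) and a two-tailed t-distribution p-value at
the 5% level.

## Worked example

```python
from ecknn import (GeneratorConfig, generate_dataset, make_folds,
                   cross_evaluate, brknn, significance)
from ecknn.classifier import zero_rule_factory

dataset, truth = generate_dataset(GeneratorConfig(seed=7))
print(f"{len(dataset)} proteins, {len(dataset.signature_vocabulary)} signatures, "
      f"{len(dataset.label_space)} EC labels")

folds = make_folds(dataset, n_folds=10, rounds=1, seed=1)
report = cross_evaluate(dataset, brknn(k=1), folds)
print(report.summary().round(3))

baseline = cross_evaluate(dataset, zero_rule_factory(), folds)
res = significance(report.fold_values("subset_accuracy"),
                   baseline.fold_values("subset_accuracy"))
print(f"t = {res.t:.2f}, p = {res.p_value:.2e}, significant: {res.significant}")
```

prints

```
5000 proteins, 1200 signatures, 337 EC labels
                    mean     sd
metric
subset_accuracy    0.970  0.010
micro_precision    0.988  0.006
micro_recall       0.970  0.010
macro_precision    0.916  0.036
macro_recall       0.905  0.034
example_precision  0.981  0.006
example_recall     0.981  0.006
example_accuracy   0.979  0.007
t = 160.82, p = 7.07e-17, significant: True
```

On this clean synthetic corpus (45% non-enzymes, Zipf-distributed classes,
recurring per-class signature combinations) 1-NN recovers 97% of exact
label sets per 10-fold cross-evaluation; the macro-averaged recall is the
lowest and most variable metric, as expected when rare classes have one or
two training examples.  The Zero Rule baseline (predict the majority
outcome, non-enzyme, for everyone) scores exactly the 45% non-enzyme
fraction, and the difference is highly significant.

The same workflows are available from a shell:

```sh
ecknn simulate --n 5000 --seed 7 --out-dir data/
ecknn xval --arff data/dataset.arff --xml data/dataset.xml --seed 1 --out report.csv
ecknn jackknife --arff data/dataset.arff --xml data/dataset.xml \
      --group-value species_01 --out jack.csv
```

Datasets travel as a sparse Weka-style ARFF file plus a Mulan-style XML
label hierarchy (see `ecknn.io_formats` for the exact dialect), or as
two-column annotation CSVs (`protein,EC` / `protein,signature` /
`protein,species`) assembled with `ecknn assemble`, optionally modernised
against an ENZYME-style EC status table (active/deleted/transferred).

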