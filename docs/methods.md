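# Methods

## Model

`ecknn` predicts the set of Enzyme Commission (EC) labels of a protein
from the presence/absence of conserved sequence signatures.  An EC label
has 1–4 specified components (`1.2.-.-` is a legitimate, *incomplete*
class of its own); per-protein label sets are stored hierarchically
expanded, so the unit the classifier manipulates is always a
prefix-closed set, and the empty set is the cumulative non-enzyme
("no-EC") outcome.  Before expansion, raw annotations can be modernised
against an ENZYME-style status table: deleted EC numbers are dropped and
transferred numbers replaced transitively by all their replacements
(cyclic transfer chains are rejected; a 4-digit number absent from the
table passes through with a warning rather than destroying data).

The classifier is binary-relevance k-nearest neighbours.  It is a lazy
learner: `fit` stores the training instances verbatim and never drops a
label, including singleton classes.  At query time squared Euclidean
distances over binary coordinates — integers, equal to the size of the
symmetric set difference — are computed once per query via one sparse
matrix product and shared across all label problems.  The neighbour set
is the k nearest training instances *including every instance tied with
the k-th distance*; per-label confidence is the fraction of the
neighbour set carrying the label, labels at confidence ≥ 0.5 are
predicted, and the non-enzyme call is scored `1 − max label confidence`.
Because training label sets are prefix-closed, an ancestor's vote count
is always ≥ any descendant's, so predictions are prefix-closed too.
Query signatures outside the training vocabulary add the same constant
to every distance and are therefore ignored.  Exact (brute-force) search
only: at the problem sizes the package targets, the sparse product is
fast and exactness keeps tie handling well defined.

Defaults that matter: `k = 1` (larger k dilutes exact-set copying and
degrades subset accuracy on this kind of data), decision threshold 0.5
(at k = 1 without ties this is exactly "copy the nearest neighbour's
label set"), 10 folds, and two cross-evaluation rounds for datasets
under 40,000 instances (one above), all overridable.

## Evaluation

*Subset accuracy* counts a protein as correct only when predicted and
true sets match exactly; empty-vs-empty is a correct non-enzyme call.
*Micro* precision/recall pool TP/FP/FN over all labels; *macro* averages
per-label values over labels with at least one true or predicted
occurrence in the evaluated set — never-occurring labels are an
undefined 0/0 and are skipped by default (`include_absent_labels=True`
forces them in as zeros; whether to do so is a genuine convention choice
and both are supported).  A label with positives but no predictions
contributes zero precision, and symmetrically for recall.
*Example-based* precision/recall/accuracy are `|T∩P|/|P|`, `|T∩P|/|T|`,
`|T∩P|/|T∪P|` averaged over instances, with the empty/empty instance
contributing 1.0 — consistent with subset accuracy rewarding the correct
non-enzyme call.  Fold-level means are reported with sample standard
deviations (ddof = 1).

Protocols: seeded-shuffle contiguous-slice folds (unstratified; fold
sizes differ by at most one; bit-reproducible from the seed);
leave-group-out "jackknife" reannotation of a held-out group such as one
species' proteome, with an inverse mode that trains on the group alone;
UniRef-style redundancy reduction consumes a member→representative map
and keeps exactly the self-representatives.  The significance test is
`t = (X − M) / (sd/√n)` using only the reference sample's sd (not a
pooled estimate), `n − 1` degrees of freedom, and a two-tailed p-value
`2·(1 − CDF(|t|))` of the t distribution — spreadsheet-style semantics,
which the test suite verifies against direct quadrature of the
Gamma-function form of the density to 1e-6.

Two baselines anchor the numbers: Zero Rule assigns every query the
modal exact label set of the training data (ties break toward the empty
set, then lexicographically), so its subset accuracy equals the majority
fraction by construction; the transitive baseline maps each signature
directly to EC numbers through a provided two-column list and predicts
the expanded union at confidence 1.0.

## Synthetic annotation databases

The generator emulates the structural features of curated corpora that
drive classifier behaviour; its defaults are the package's study
conditions: 5,000 proteins, 1,200 signatures, 200 leaf EC classes,
Zipf-1 class frequencies, 45% non-enzymes, mean ≈ 3.55 signatures per
protein (shifted Poisson capped at 12), ≈ 0.3% of the corpus with empty
signature vectors, 5% multi-EC and 9% partial-label enzymes, 8 species,
noise 0.  The 45%, 3.55, ~0.3% and ~9% figures mirror the profile of a
large doubly-curated protein corpus; the 5,000/200 scale is the package's
desk-scale choice, and 1,200 signatures keeps the signature-to-class
ratio (6:1) in a realistic range.

Mechanics: each leaf class owns 1–3 distinct signature combinations
(capped by the class's expected support — a class sampled twice cannot
exhibit three combinations; compare a real corpus where a thousand
proteins of one class share three combinations), built from a family
core shared by classes with a common 3-digit prefix plus class-specific
signatures, which creates realistic near-neighbour confusability.
Partial-label proteins are modelled as classes of their own with a
dedicated combination per partial label — incomplete annotations in real
sources are typically families lacking a specific assignment, not noisy
copies of fully annotated families.  Multi-EC proteins draw from a fixed
pool of recurring class *pairs* (n_classes/10), each with its own
combination, as bifunctional-enzyme families recur across species.
Non-enzymes draw from a disjoint background signature pool or carry an
empty vector.  `noise_rate` drops each present signature with that
probability and adds a Binomial(len, rate) number of spurious ones;
`corrupt_labels` separately reassigns whole label sets, emulating
disagreeing curation.  Combination collisions at noise 0 are resolved by
a deterministic bounded redraw.  One mandatory seed feeds named
substreams per stage (labels/combos/pairs/proteins) so stages can be
regenerated independently; a fixed configuration is byte-reproducible
down to the ARFF export.

What the generator does **not** model: real taxonomic census and
phylogenetic correlation between species (species labels are arbitrary
group keys), signature sub/super-set nesting within a class, corpus-wide
annotation biases, and any sequence-level realism — so passing tests
demonstrate the correctness of the machinery and the learnability of
combination-structured data, not the accuracy attainable on real
databases.

## Numerical and design choices

- Distances are integer-squared throughout, so nearest-neighbour ties
  are exact, order-independent, and resolved by including the whole tie
  set with proportional voting.
- Label order everywhere is numeric-lexicographic over digit tuples,
  which is stable and places ancestors before descendants; attribute and
  label columns in files follow this order, making exports byte-stable.
- The ARFF dialect is binary `{0,1}` attributes, signatures first then
  labels, sparse `{index 1, ...}` rows (dense rows accepted on input),
  instance ids and group keys carried in full-line `%` comments that
  other ARFF readers ignore.
- The agreeing-annotation join keeps exactly the (protein, EC) couples
  present in both sources; a protein is kept as a non-enzyme only when
  *both* sources record it with an empty set, and partially overlapping
  annotations keep their common couples — the literal reading of
  "annotation equal in both databases"; whether the original convention
  also dropped the non-agreeing couples of partially overlapping
  proteins is not decidable from published descriptions, so this choice
  is fixed here and documented.
- Frequency ranking for the cumulative EC-distribution curve counts only
  each instance's most specific (leaf) labels, so expanded ancestors do
  not double-count; the EC-digit histogram does the same per chain.
- The average-labels-per-protein statistic in published corpus
  descriptions (~3.97 with ~45% non-enzymes) is ambiguous about whether
  the denominator is all proteins or enzymes only; the package does not
  depend on it either way, and the generator targets signatures per
  protein (3.55) instead.
- `random_subset` and fold shuffles use numpy's PCG64 via
  `default_rng([seed, round])`; identical seeds give bit-identical
  partitions.

## Problem sizes

The test suite and the acceptance script run the default study
conditions (5,000 instances) for cross-evaluation, 250–600-instance
corpora for oracle-equivalence, format and reduction checks, and a
15-point (t, df) grid for the significance quadrature — sizes chosen so
a full run completes in well under a minute while every combination of
tie, empty-vector, partial-label and multi-label behaviour is exercised.

## Known limitations

Exact brute-force search is quadratic in dataset size per evaluation and
is not meant for corpora of millions of instances; the macro-average
convention (skip never-occurring labels) makes macro values depend on
the evaluated subset's label census; the generator's noise model is
symmetric and signature-independent, which is kinder than real
annotation error; and unseen classes can never be predicted — a
structural property of instance-based learning that the jackknife tests
document rather than work around.
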