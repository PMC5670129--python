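# hierclass

Hierarchical top-down classification and taxon prediction for biomolecular
feature matrices — mass-spectral profiles, RNA-seq expression tables, or any
samples × features data whose classes live in a taxonomy.

## The problem

Conventional "flat" classifiers treat every terminal class (bacterial species,
cancer subtype, …) as one label among dozens. That discards the taxonomy:
accuracy degrades as classes accumulate, distant classes interfere with each
other, and — critically — a sample from a class *absent from the database*
(a new species, an emerging subtype) can only be misassigned. Clinically, the
genus or family of an unknown isolate is often enough to act on.

`hierclass` instead trains one small discriminant model per **parent node** of
the class taxonomy. A sample descends from the root, assigned at each node to
the child with the highest probability, so:

* each classification problem is small and local;
* per-level accuracies and confusion matrices come out of the same machine;
* a sample from an unknown terminal class can still be routed to the correct
  upper-level taxon, with a probability-gap rule (`δ`) that leaves ambiguous
  samples "non-classified" instead of guessing.

## The method

At each internal node with children $1..c$ and stratified training data
$(X, y)$:

1. **Method selection.** Four linear discriminants are compared on identical
   stratified inner CV folds:
   * **PLS** (SIMPLS): components maximize covariance between centered $X$ and
     the one-hot class indicator $Y$ — between-class variance, ignoring
     within-class variance. The component count is tuned on the same folds.
   * **MMC-LDA**: top eigenvectors of $S_b - S_w$ (maximum margin criterion)
     — between-class scatter up, within-class scatter down, no $S_w^{-1}$.
   * **PCA-LDA** (Fisherfaces): PCA to $\min(n-c,\,d)$ dimensions, then Fisher
     LDA $S_b w = \lambda S_w w$ — usable when features outnumber samples.
   * **SVM**: one-vs-rest linear maximum-margin hyperplanes.

   The highest mean inner accuracy wins; ties resolve by the fixed efficiency
   order PLS > MMC-LDA > PCA-LDA > SVM. The per-node winners form the
   **method map**.
2. **Probability layer.** One-vs-all Firth (bias-reduced) logistic regressions
   on the reducer scores, normalized to a distribution over the children.
3. **Single-offspring rule.** A parent with one child is not a free pass: the
   child is discriminated against the offspring of the nearest ancestor's
   other branches, and samples that lose that contest are non-classified.

Evaluation is repeated stratified outer CV with the method map re-derived
inside each training fold (nested CV — outer test rows never touch selection
or fitting). **Leave-one-class-out** prediction removes a terminal class
entirely, retrains, and scores how often its samples pass through the correct
ancestor at the *highest prediction level* — the deepest ancestor that still
has other descendants.

Preprocessing chains are included for raw profile mass spectra (binning →
adaptive Otsu denoising → TIC-based replicate selection → Savitzky–Golay peak
picking → KDE peak matching → median-fold-change normalization → log
transform) and for expression tables (gene/normal-tissue filters, one sample
per patient, minimum subtype size, median-fold-change + log2).

## Worked example

```python
import hierclass as hc
from hierclass.model import HierarchicalClassifier

# synthetic two-level taxonomy: 2 x 3 leaves, 20 samples each,
# class means 6 sigma apart
spec = hc.TreeSpec(branching=[2, 3], samples_per_leaf=20,
                   n_features=30, separation=6.0, seed=7)
X, lineages, tree = hc.gen_hierarchical_gaussians(spec)

model = HierarchicalClassifier(X, lineages, config=hc.CVConfig(repetitions=2, seed=7))
print(model.fit().summary())
```

```
Hierarchical classifier
=======================================================
samples: 120   features: 30
tree depth: 2   leaves: 6   internal nodes: 3
seed: 7
-------------------------------------------------------
node                            method    inner acc %
(root)                          PLS             100.0
L1_0                            PLS             100.0
L1_1                            PLS             100.0
-------------------------------------------------------
* single-offspring node (child vs related classes)
```

Every node selected PLS (all four methods tie at 100% inner accuracy on this
clean fixture, and PLS is the cheapest). Nested cross-validation and
unknown-class prediction:

```python
print(model.cross_validate().summary())
rec = model.leave_one_class_out(tree.leaves[0])
print(rec["accuracy_at_evaluation_level"], rec["evaluation_node"])
```

```
       mean_accuracy_pct  sd_accuracy_pct  mean_accuracy_excl_nonclassified_pct  repetitions
level
1                  100.0              0.0                                 100.0            2
2                  100.0              0.0                                 100.0            2

100.0 L1_0
```

Both hierarchy levels are classified perfectly, and when the first leaf class
is withheld from training entirely, 100% of its samples are still routed
through its true parent `L1_0` — the class is "unknown" but its upper taxon is
recovered.

The same pipeline is scriptable:

```sh
hierclass synth --branching 2,3 --samples-per-leaf 20 --out data/
hierclass crossval --matrix data/matrix.csv --labels data/labels.tsv --out cv/
hierclass train   --matrix data/matrix.csv --labels data/labels.tsv --out model/
hierclass predict --model model/model.json --matrix data/matrix.csv --out pred/
hierclass loco    --matrix data/matrix.csv --labels data/labels.tsv --out loco/
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's core computation from scratch:
it generates the hierarchical Gaussian benchmark, performs the repeated
nested-CV evaluation, runs leave-one-class-out prediction for a held-out
terminal class, prints the per-level accuracy summary, and writes the results
file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model assumptions, tunable parameters, and the
limits of what the synthetic benchmarks establish.
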