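# Methods

## Model

A class taxonomy is a rooted tree whose leaves are terminal classes and whose
internal nodes are higher taxa. Node identity is the full path from the root,
so a species epithet repeated under two genera is two distinct nodes. Every
sample carries a lineage — its root-to-leaf path — serialized as a
semicolon-delimited string.

Classification is *local classifier per parent node*: every internal node with
at least two children carrying data gets its own discriminant model, fitted on
the samples under that node stratified by immediate child. Prediction descends
from the root. At each node the model emits a probability distribution over the
children; the sample moves to the argmax child (ties break by the tree's child
order). If the gap between the two highest probabilities is below the threshold
δ, descent stops and the sample is non-classified at that level. The design
trades error propagation (a mistake at an upper level is unrecoverable) for
small, local, interpretable subproblems and the ability to stop at a defensible
depth.

### Per-node models

Each node model is a linear reducer plus a probability layer.

Reducers (all deterministic; projection signs fixed by making each column's
largest-magnitude element positive):

* **SIMPLS** — de Jong's direct-deflation PLS on column-centered X against the
  one-hot child indicator. Score vectors are unit-norm and mutually orthogonal;
  the first k columns of a larger fit equal the k-component fit, which the
  component-count search exploits.
* **MMC-LDA** — eigenvectors of S_b − S_w, the maximum margin criterion. Works
  when S_w is singular. Scatter matrices use biased (1/n) scaling; only the
  relative scale reaches the eigenvectors.
* **PCA-LDA** — Fisherfaces: PCA retains min(n − c, d) components (with a
  1e-10-relative rank cut), then the generalized eigenproblem
  S_b w = λ S_w w is solved in the PCA space with a 1e-10-scaled ridge on S_w
  against exact singularity; output dimension c − 1.
* **SVM** — one-vs-rest binary linear SVMs (libsvm backend, C = 1 by default);
  scores are signed decision values. Hyperplanes are extracted to plain arrays
  so node models serialize to JSON without pickled estimators.

Probability layer: one-vs-all logistic regressions on the reducer scores,
normalized to sum to one (a two-child node uses a single symmetric model, so
binary probabilities are exact complements). The layer is fitted by **Firth
bias-reduced logistic regression** (Jeffreys-prior penalty, damped Newton,
tolerance 1e-8). This is a deliberate choice: well-separated nodes are the norm
in this setting, the unpenalized MLE then diverges, and the realized decision
boundary of a large-C solver is an optimizer artifact that can sit anywhere
inside the margin gap (we measured displacements up to ~0.9σ on
synthetic two-Gaussian nodes). The Firth fit is finite, unique, and keeps the
boundary near the margin center while probabilities at class centroids remain
above 0.95. Probabilities are calibrated on training scores, not held-out
folds.

**Single-offspring rule.** A parent with exactly one child cannot be tested by
classifying into it. Instead the child is discriminated against the offspring
of the nearest ancestor's other branches (the sibling genera's species, in the
taxonomic picture). At prediction time a sample whose most probable class is
not the single child is non-classified at that node.

### Method selection and evaluation

`select_method` compares the four reducers on identical stratified inner folds
(default 5, reduced to the smallest class size when necessary, with a logged
warning). The winner has the highest mean inner accuracy; exact ties resolve by
the fixed order PLS > MMC-LDA > PCA-LDA > SVM, a deterministic stand-in for
picking the computationally cheapest method. For PLS the same folds also choose
the component count from {c−1, and 2, 3, 5, 10, 15 above it}, ties to the
fewest; the floor of c − 1 exists because c classes in general position need
c − 1 discriminant dimensions, and a 1-D projection of a 3-way node is brittle
for samples off the training manifold (exactly the leave-one-class-out
situation). One SIMPLS fit at the largest k serves the whole grid because the
components are nested.

`cross_validate` runs R repetitions of stratified K-fold outer CV (defaults
R = 5, K = 5; each repetition reshuffles folds with seed + repetition index).
Within each outer fold the method map is re-derived from the training portion
only and the tree retrained, so outer test rows never influence selection or
fitting. Test samples descend with δ = 0. Per level, a confusion matrix over
that level's classes plus a `non_classified` column is accumulated; accuracy is
reported both counting non-classified as errors and excluding them from the
denominator (the two conventions differ in published work, so both are
exported).

### Leave-one-class-out prediction

To measure what happens with a class missing from the database, all samples of
one terminal class are removed, childless ancestors pruned, the method map
re-derived and the tree retrained on the remainder (single-offspring models are
rebuilt where pruning created them), and the held-out samples are predicted
top-down. The score at level ℓ is the fraction of held-out samples whose path
passes through their true level-ℓ ancestor. The headline number is taken at the
*highest prediction level*: the deepest proper ancestor with at least two
children, i.e. the deepest taxon that still exists after the class is removed.
A species sharing its genus is predictable to genus; a sole-species genus only
to its family (or higher, recursively).

## Preprocessing chains

**Mass spectra** (two-column m/z–intensity text per replicate; mzML via the
optional pyteomics): intensities are summed into half-open bins
[lo, lo + 0.001 Da) over 150–2000 m/z; noise is removed by zeroing bins at or
below an Otsu threshold computed on the log-intensities of nonzero bins
(adaptive, parameter-free; constant and all-zero inputs pass through); the 5
replicates with the highest post-threshold TIC are kept (stable ties by
replicate order); peak apexes are +/− zero crossings of a Savitzky–Golay first
derivative (window 11 bins, polynomial order 3); pooled apexes are aligned by
Gaussian KDE (bandwidth 0.003 Da) — each density mode is a candidate feature
whose common m/z is the pooled value with the highest peak count (ties to the
smallest), peaks assigned to the nearest feature within 3 bandwidths;
replicates are averaged per sample; samples are median-fold-change normalized
(divide by the median of nonzero ratios to the feature-wise median spectrum,
zeros excluded; a sample sharing no nonzero feature with the reference keeps
factor 1 with a warning) and log(1 + x) transformed, since technical variance
in MS grows with signal intensity.

**Expression tables**: median-fold-change then log2(1 + x); filtering drops
genes matching a configurable "dubious annotation" pattern (default `^\?`) and
normal-tissue samples, keeps one seeded-random sample per patient, then drops
subtypes below 15 samples — in that order, so subtype counts are patient-level.
The filter is idempotent.

## Synthetic benchmarks

`gen_hierarchical_gaussians` draws class means by walking the tree: each node
adds an offset of length separation × σ to its parent's mean, and samples are
isotropic Gaussians (σ = 1) around leaf means. Offsets are columns of one
random orthonormal frame by default, so the separation parameter is a
*guaranteed* distance between any two same-level means (siblings end up √2 ×
apart) rather than a random-direction average — with independent random
directions, unrelated branches can land arbitrarily close in low dimension and
"6σ separation" no longer implies near-zero Bayes error. The orthogonal layout
needs at least as many features as class nodes; a random-direction mode remains
available. Separation 0 collapses every class onto one distribution (the
permutation-null used for calibration checks). A heteroscedastic option scales
noise with |mean| to mimic MS intensity-dependent variance.

`gen_synthetic_spectra` renders planted peak positions per class as Gaussian
profiles (σ 0.01 Da, sampled at σ/20 so 0.001 Da binning sees no gaps) with
per-replicate m/z jitter, a log-uniform per-spectrum scale factor, and a
uniform low-level noise floor; a truth record carries planted positions and
scales.

What a green synthetic test does *not* establish: real spectra have correlated
chemical noise, isotope envelopes, baseline drift and mass-calibration error;
real expression data are overdispersed counts with batch structure; real
taxonomies have classes at wildly different separations. The benchmarks verify
the machinery (selection, training, routing, thresholds, conservation), not
field performance.

## Numerical choices and degenerate inputs

* Seeds: every stochastic step derives child seeds from the master seed via a
  fixed integer hash (< 2³¹); identical seeds reproduce method maps and
  confusion reports bitwise.
* SIMPLS truncates k above the centered-data rank with a warning; constant X
  is an error.
* Fold counts shrink to the smallest class size (minimum 2, else an error).
* A method that cannot be fitted on an inner fold (e.g. Fisherfaces with
  n ≤ c) scores NaN there and competes on its remaining folds.
* Probability ties at a node resolve to the earlier child in tree order.
* δ ∈ [0, 1]; δ = 0 disables the stop rule (single-offspring nodes still
  apply theirs). The default δ = 0.05 is our choice; no canonical value
  exists.
* Otsu on an all-zero or constant vector returns threshold 0 (nothing is
  corrupted); an empty spectrum bins to a zero vector with a warning.

## Known limitations

* Upper-level mistakes propagate; there is no backtracking or global
  reconciliation of the per-node decisions.
* Probabilities are calibrated on training scores; at very small nodes they
  are sharper than held-out calibration would make them.
* "Recursive" variants of MMC-LDA (deflation or feature elimination) are not
  implemented; the one-shot eigendecomposition matches the stated criterion.
* The single-offspring rule needs at least one related class under the nearest
  branching ancestor; a root with one child is untrainable by design.
* mzML input requires pyteomics at run time; the text format has no such
  dependency.
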