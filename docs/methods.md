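# Methods

This note documents the statistical model implemented by `dtikit`, the
default parameter choices and the reasoning behind them, and the known
limitations. It is written for a reader who wants to judge whether the
tool's outputs are trustworthy, not just run it.

## 1. Problem and representation

The tool predicts whether a drug and a protein interact, framed as
binary classification of (drug, protein) pairs. Each pair is
represented by concatenating a protein descriptor block and an 881-bit
PubChem-style drug substructure fingerprint.

Protein sequences are first normalized to a fixed length
`L_fixed = 100`: longer sequences are truncated, shorter ones are
right-padded with the dummy residue `O`. A fixed length is required by
the position-dependent encoders (EAAC, EGAAC, NUM, BINA, PSSM) so that
every protein yields the same number of features; 100 keeps the
binary/one-hot blocks (BINA: 21 x 100 = 2100, PSSM: 20 x 100 = 2000)
at a tractable width. Composition-style encoders (DDE, TF-IDF, k-gram,
PseAAC) use the raw, un-padded sequence, since padding would distort
their frequency statistics.

Eleven encoders are implemented; their widths at `L_fixed = 100`:

| encoder  | width | idea |
|----------|-------|------|
| EAAC     | 100   | amino-acid composition in 5 equal windows |
| EGAAC    | 25    | 5-group composition in 5 equal windows |
| DDE      | 400   | dipeptide deviation from codon-based expectation |
| TFIDF    | 20    | per-residue term frequency x corpus inverse document frequency |
| 1GRAM    | 21    | residue frequencies over the 21-letter alphabet |
| 2GRAM    | 400   | dipeptide frequencies over the 20 standard residues |
| NUM      | 100   | integer residue codes by position |
| BINA     | 2100  | one-hot residue identity by position |
| PSEAAC   | 28    | pseudo amino-acid composition (20 + 8 correlation terms) |
| PSSM     | 2000  | flattened length-normalized evolutionary profile |
| PSEPSSM  | 220   | PSSM column means + 10 lagged auto-covariances |

Three combination modes bundle encoders into a protein block:

* **Mode A** (default): PSSM + EGAAC + EAAC, 2125 features.
* **Mode B**: Mode A + DDE + BINA, 4625 features.
* **Mode C**: all eleven encoders, 5414 features.

With the fingerprint appended, a Mode A pair vector has
2125 + 881 = 3006 columns.

## 2. Feature selection: SU ranking + IWSSR

High-dimensional, partly redundant descriptor blocks motivate
selection before fitting. Features are first ranked by symmetric
uncertainty (SU) with the class label,

SU(X, Y) = 2 * I(X; Y) / (H(X) + H(Y)),

after equal-width discretization of each continuous column into
`bins = 5` levels. SU is normalized mutual information: 0 for
independent variables, 1 for deterministic relation, and symmetric in
its arguments.

Incremental Wrapper Subset Selection with Replacement (IWSSR) then
scans the ranking once. For each candidate feature it considers (a)
swapping it against each already-selected feature and (b) adding it;
the better of the two is accepted only if it improves the wrapper
score by more than `min_gain`. The wrapper score is stratified k-fold
cross-validated accuracy of a cheap inner classifier on the candidate
subset.

Default inner evaluator: **Gaussian naive Bayes with 10-fold CV**.
Naive Bayes is the classical inner classifier for IWSS-family
wrappers, and it admits a decisive optimization here: per-feature
per-fold log-density contributions are precomputed once as an
`(n, d, n_classes)` array, so scoring any subset is a cached column
sum rather than a model fit. A decision-tree evaluator is available
as an alternative (`make_tree_evaluator`) but is roughly two orders
of magnitude slower per subset and, being high-variance, tends to
swap genuinely informative features out on fold noise.

`min_gain = 0.01` requires each accepted change to beat the incumbent
by about one standard error of a 10-fold accuracy estimate at the
sample sizes the tool targets (hundreds of rows); smaller thresholds
let the scan chase CV noise and accrete spurious columns, larger ones
stop the scan before weakly informative features enter. `n_folds = 10`
rather than a cheaper 3 or 5 halves the variance of the inner
estimate, which matters because accept/reject decisions compare two
nearly equal accuracies. An optional `max_rank` caps the scan to the
top-ranked features when the full width is too wide to scan.

## 3. Classifier: rotation forest

The classifier is a rotation forest with `n_trees = 35` and
`subset_size = 3`. For each tree, the feature set is randomly
partitioned into subsets of 3; for each subset, a 75% bootstrap-free
row sample (drawn without replacement, on a random subset of classes)
is projected onto its principal axes, computed by symmetric
eigendecomposition of the subset covariance. The per-subset axes are
assembled into a block-diagonal rotation matrix (entries outside the
blocks are exactly zero), the training matrix is rotated, and an
unpruned CART tree is fit on the rotated data. Prediction averages
the per-tree class probabilities.

Numerical choices: eigenvectors come from `numpy.linalg.eigh` (exact
symmetric solver, deterministic given the input); each eigenvector's
sign is fixed by making its largest-magnitude entry positive, so
refitting with the same seed is bit-identical; a zero-variance subset
yields the identity block rather than a degenerate rotation. If fewer
features than `subset_size` remain after selection, a single
full-width subset is used.

## 4. Evaluation

Metrics: accuracy, sensitivity, specificity, precision, MCC, and AUC.
AUC is computed from the exact rank statistic (equivalent to the
Wilcoxon-Mann-Whitney form with half-credit for ties). Zero-denominator
metrics are reported as NaN with a flag rather than silently coerced.

Two protocols:

* **split** (default): a stratified 90/10 split; selection and
  training use only the 90% part, metrics are reported on the held-out
  10%. Fast, and the honest default for a single run.
* **kfold**: stratified k-fold (default k = 10) with selection nested
  inside each training fold; pooled out-of-fold predictions give the
  reported metrics. Slower but lower-variance; use for comparisons.

Selection is never run on evaluation rows in either protocol.

## 5. Synthetic benchmark

`dtikit.synthetic_data` generates a fully specified study:
random protein sequences, PSSMs whose score for the true residue at
each position is elevated, drug fingerprints with ~10% bit density,
and an interaction network planted through the *assembled features
themselves*: 5 feature columns of the Mode A pair representation are
chosen, z-scored, and combined in a logistic model

P(interact) = sigmoid(intercept + effect_size * sum(z_planted)),

with `effect_size = 2.0`, `intercept = -2.0`, then 5% of labels are
flipped. The negative intercept makes interactions a sparse minority
(roughly 30-35% of pairs), matching the sparse networks the tool is
meant for and leaving enough non-interacting pairs for 1:1 negative
sampling. Defaults: 40 proteins x 30 drugs.

What the generator does and does not emulate: it produces the right
shapes, formats, and a recoverable planted signal, so it exercises the
whole pipeline end to end and makes feature-recovery claims testable.
It does **not** emulate real protein homology structure, realistic
fingerprint correlation, or network topology (hub drugs/proteins), so
absolute metric values on synthetic data say nothing about performance
on real interaction data.

One caveat specific to small studies: with few distinct proteins and
drugs, different assembled columns are highly correlated across pairs
(every pair sharing a protein shares its whole protein block), so
exact recovery of the planted columns is not identifiable below
roughly 100 x 100 entities — the selector may legitimately pick a
near-duplicate column instead. Recovery experiments therefore use
100 proteins x 100 drugs, while end-to-end predictive-performance
experiments use the 40 x 30 default.

## 6. Determinism

Every stochastic step (negative sampling, splits, inner CV folds,
rotation partitions and row samples, the generator) is driven by an
explicit integer seed; independent substreams are derived with
`numpy.random.default_rng` offsets. Rerunning any command with the
same inputs and seed reproduces its artifacts byte-for-byte, and the
feature-matrix CSV round-trips losslessly (shortest-exact-decimal
writer, round-trip float parser).

## 7. Limitations

* Wrapper selection optimizes inner-CV accuracy; on very small
  studies the selected subset varies across seeds even when test AUC
  does not.
* The Gaussian naive Bayes inner evaluator assumes per-class
  conditional independence; strongly interacting feature pairs with
  no marginal signal can be missed by the forward scan.
* `L_fixed = 100` truncation discards C-terminal information for long
  proteins; raise `fixed_length` if sequences are long and memory
  allows (BINA and PSSM widths scale linearly).
* Synthetic results are a correctness harness, not a performance
  benchmark; validate on real data before drawing biological
  conclusions.
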