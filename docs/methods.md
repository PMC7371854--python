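# Methods

## Problem and scope

Given an unaligned riboswitch nucleotide sequence, predict which ligand
class (Rfam family) it belongs to. The package implements the full study
workflow at desk scale: sequence sanitization, two featurizations, eight
classifier families, multiclass ROC evaluation, a clustering-based family
diversity analysis, and class-incremental retraining. The real 32-family
Rfam collection (68,520 sequences) is not bundled; its published summary
statistics are (`riboclass.reference`), and everything else is exercised on
synthetic families from `riboclass.synthetic_data`.

## Sequence sanitization

Inputs are uppercased; alignment gaps (`-`, `.`) are stripped; `U→T`; the
ambiguity codes observed in the original data map as `R→G, Y→T, K→G, S→G,
W→A, H→A`. The remaining IUPAC codes (`M, B, D, V, N`) never occurred in
that pull, so their mapping is this package's extension (`M→A, B→G, D→G,
V→G, N→A`, following the core map's purine/first-listed preference); a
`strict` policy rejects them instead. Characters outside the IUPAC alphabet
are errors with the offending position reported. Sanitization is
idempotent.

## Features

**k-mer frequencies (conventional models).** Four mononucleotide
frequencies (count/len) followed by sixteen overlapping dinucleotide
frequencies (count/(len−1)) in lexicographic order; each block is a
probability simplex, which the denominator choice len−1 guarantees for the
dimers. Standardization to zero mean/unit variance is fitted on the
training split only and applied unchanged elsewhere — fitting on all data
would leak test-set statistics into training; constant columns get scale 1
(transform to zeros).

**Integer encoding (deep models).** The first *L* bases (default 250 —
longer than any family's average length) map to codes 1–4 with pad code 0
on the right. Right-padding preserves the 5′-proximal prefix across
instances. Pad positions carry no signal anywhere: the one-hot expansion
gives them an all-zero row, and the recurrent layers use pass-through
masking (state and cell are carried unchanged across pad steps). Masking is
essential, not cosmetic: without it the forward LSTM state decays through
up to L−len(seq) pad steps and short sequences lose their summary entirely.

## Classifiers

Six conventional families are scikit-learn estimators behind the package's
uniform interface (decision tree, Gaussian NB, k-NN, AdaBoost, random
forest, MLP), consuming the standardized 20-feature vectors. Probability
rows are re-expanded to the full class manifest if a class was absent at
fit time.

The two deep families are built on the in-package numpy/numba engine
(`riboclass.nn`): layers with hand-derived gradients (verified against
central finite differences in float64), Adam, global-norm gradient
clipping (5.0), inverted dropout, optional step learning-rate halving, and
bit-for-bit reproducibility from a single seed (one
`numpy.random.SeedSequence` fans out to split, initialisation and
shuffling). The BPTT recurrence is numba-jitted with a table-based fast
exponential (relative error ~1e-7); a float64 twin kernel with exact libm
activations backs the gradient tests.

* **CNN** — one-hot → Conv1D → Conv1D → max pool → dropout → flatten →
  dense softmax. Defaults: 128/64 filters, kernel 5, pool 4, dropout 0.3.
  With `pool_size` set to the conv output length the pooling becomes
  global, making motif detection translation-invariant — the configuration
  used in the benchmarks, where motif position is uniform.
* **RNN** — one-hot → dropout → biLSTM → dropout → biLSTM → dropout →
  flatten → dense softmax. Defaults: 128 units/direction, dropout 0.2. The
  second bidirectional layer returns final states only (the usual default
  for a terminal LSTM layer), so the flatten is trivial and the readout is
  the 2·units end-state summary. This was a genuinely open design point;
  the alternative (flatten over all per-position outputs) was measured to
  memorise rather than generalise at desk scale: its 10k–40k-parameter
  dense reached train accuracy 0.89 with held-out accuracy 0.30 on a
  composition-only probe and plateaued at 0.5–0.64 regardless of epochs,
  while the end-state readout continued to improve.

Weight initialisation is Glorot uniform (orthogonal for recurrent
kernels), forget-gate bias 1. LSTM cell: standard gates
i, f, g, o with c ← f·c + i·g, h ← o·tanh(c).

**Splitting.** Stratified train/validation/test with largest-remainder
per-class allocation, so each class's test count is within one instance of
the target fraction; the validation fraction is taken from the remaining
training part. Classes with a single member are rejected by name.

**Grid search.** Exhaustive Cartesian product, stratified k-fold (default
10), scored by macro F — with heavy class skew, accuracy and micro metrics
reward overfitting to large classes, macro-F does not. Failed fits are
recorded and scored worst rather than aborting; ties break to the first
combination in deterministic grid order.

## Evaluation

One-vs-rest ROC per class using the predicted probability of that class as
the score (not the argmax); AUROC by trapezoidal integration over the
threshold sweep, which equals the Mann–Whitney probability that a random
positive outscores a random negative with ties counted one half (asserted
against an exhaustive pairwise oracle in the tests). Micro-AUROC pools the
binarized (instance, class) pairs of all classes into one curve; macro-AUROC
is the unweighted mean of classwise AUROCs. Classes absent from the test
truth have undefined one-vs-rest AUROC and are excluded from the macro
average with a warning. Precision/recall/F are reported per class and
macro-averaged; a class with no predicted positives gets precision 0.

## Family diversity

Greedy incremental clustering: sort by decreasing length (ties keep input
order), each sequence joins the first cluster whose representative it
matches at ≥ threshold identity, else founds a cluster. Identity is
computed from an optimal global alignment (match 1, mismatch 0, linear gap
−1, via Biopython's pairwise aligner) as identical columns over alignment
length — exact rather than word-filter-accelerated, which is affordable at
desk scale and lets a brute-force oracle verify every property. The
diversity score is n_clusters/family_size: 1.0 means every sequence is its
own cluster. "Redundant sequences" counts exact duplicate strings (records
minus distinct strings); the published summary never defines this column,
so this is the package's definition.

## Synthetic data generator

Each class has (i) an i.i.d. background composition drawn from a symmetric
Dirichlet (concentration 20, giving realistic modest compositional
differences between families) and (ii) a planted class motif (default 12
bases) copied into every sequence at a uniform-random admissible position
with per-base mutation probability 0.05 (mutations change the base).
Sequence lengths are uniform in a configurable range; the default (45, 220)
spans the averages of the real 32 families.

The generator emulates exactly two properties of real families — class
composition and a conserved core — and none of the rest: no secondary
structure, no phylogenetic correlation between sequences of a class, no
length–family correlation, and a single contiguous (or split) motif rather
than multiple stems. Consequently the benchmarks show that the pipeline's
models learn compositional and positional signal under controlled
conditions; they do not certify performance on real Rfam data.

**Hard mode (long-range dependency).** The motif is split in half and
planted with a uniform gap of 8–24 background bases; classes come in pairs
whose motifs are half-swapped (`h1·h2` vs `h2·h1`). Paired classes thus
share the planted material's 1-mer and 2-mer content exactly (the halves
are separated by background, so no junction dimer exists), and k-mer
classifiers are blind to the pairing by construction; only the order and
relative position of the halves separates a pair. This operationalises the
claim that k-mer features mask long-range information that sequence-reading
models capture.

## Benchmark problem sizes

The discrimination benchmarks (in `tests/test_acceptance.py`) use 8 classes
× 200 sequences, motif length 12, mutation rate 0.05, fixed seed, sequence
lengths 60–100 (window 100) — the short half of the real family length
spectrum (about half of the 32 families average 45–110 bases). Deep-model
capacities there are reduced relative to the package defaults (32–64
filters, 24–32 LSTM units) with epochs chosen where the validation curves
flatten; all such values are plain configuration. Unit tests use smaller
fixtures still (2–5 classes, 50–70-base sequences).

## Numerical choices and degenerate inputs

* Engine arithmetic is float32 (float64 for gradient verification).
* AUROC tie handling: threshold sweep — equivalent to the ½-tie
  convention.
* Standardizer: constant columns map to zeros; the transform never divides
  by zero.
* Encoding: empty sequences are errors; sequences shorter than 2 bases
  have no dinucleotide frequencies and are rejected by the featurizer.
* Grid-search tie-break: first combination in grid order.
* Model persistence: a format-version field is checked on load; corrupted
  manifests, weight files or version mismatches raise instead of returning
  a silently wrong model.
* Greedy clustering representative ties (equal length): input order.

## Known limitations

* The identity computation is O(n·m) per pair and the greedy pass is
  quadratic in family size — appropriate for thousands, not hundreds of
  thousands, of sequences. No cd-hit-style word filter is provided.
* The deep engine targets clarity and desk-scale data; it is single-core
  and has no GPU path.
* The synthetic generator's i.i.d.-plus-motif model understates real
  within-family homology, so absolute metric values on synthetic data do
  not transfer to Rfam-scale collections; only the relative ordering of
  model families under controlled signal types is meaningful.
* Real-data ingestion is limited to FASTA/CSV; there is no Rfam client,
  by design — nothing in the package depends on network access.
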