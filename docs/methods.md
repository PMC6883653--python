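# Methods

## Problem and model

A cDNA sequencing read is the mRNA strand or its reverse complement with
equal prior probability. `readorient` treats orientation as binary
classification: label 1 means "not 5′-to-3′" (the read must be flipped).
Training data are sequences of known orientation from one of three source
kinds: an annotation's transcripts (defined to be 5′-to-3′), direct-RNA
sequencing reads (the protocol reads RNA natively, so reads are 5′-to-3′;
U is converted to T), or cDNA reads labeled through a PAF alignment to
5′-to-3′ transcripts. For the mapped source a read is labeled only if it
has exactly one alignment record and MAPQ ≥ 60 (minimap2's maximum, run
with secondary alignments suppressed); multimapping or low-MAPQ reads are
excluded and counted by reason. Class balance is constructed, not assumed:
a seeded random half of the training sequences is reverse-complemented and
labeled 1 (or, with `double=True`, every sequence contributes both
orientations).

Preprocessing discards reads containing N, optionally trims the same
number of bases from both ends, and drops reads shorter than `min_len`
(default 50 nt, preventing degenerate k-mer vectors).

## Featurization

*k-mer frequencies (MLP).* For each order k = 1…k_max the 4^k overlapping
k-mer counts are normalized per sequence and per order:
`frequency = count / (L − k + 1)`, so each order's block sums to 1 and the
representation is length-invariant. Blocks are concatenated in A<C<G<T
lexicographic order (k_max = 5 → 1,364 features). The reverse complement
of a sequence corresponds to an exact index permutation of its feature
vector, which the tests exploit as an oracle.

*One-hot windows (CNN).* Sequences are cut into 500-nt windows with
250-nt overlap; window starts are 0, 250, 500, … with a non-zero start
emitted only while it is < L − 250 (no window made only of already-covered
bases). Any window extending past the sequence end — including whole
sequences shorter than 500 nt — is right-padded with N. One-hot encoding
uses rows A, C, G, T; N columns are all-zero so padding carries no signal.
Padding short sequences rather than dropping them keeps the contract
uniform for reads between `min_len` and 500 nt.

## Classifiers

No GPU framework is assumed; both models run on a compact numpy
feed-forward/convolution core (`_nn.py`) with Adam (lr 1e-3), mini-batches
of 128, a 10% validation split, early stopping with best-weight restore,
and one integer seed driving initialization, shuffling and dropout.
Backend nondeterminism is therefore limited to BLAS reduction order;
reproducibility is treated as a tolerance on accuracy, not on weights.

*MLP.* Five hidden layers (512, 256, 128, 64, 32), ReLU, dropout 0.2
after each, one sigmoid output unit trained with binary cross-entropy.
The score approximates P(read is not 5′-to-3′).

*CNN.* Three convolutional, three pooling and three dense layers ending
in a 2-class softmax. The default shape is

    conv(32 filters, width 9) → maxpool(61)
    → conv(64, width 2) → maxpool(7)
    → conv(64, width 1) → pool(1)
    → dense(64) → dense(32) → dense(2, softmax), dropout 0.25

Pattern detection is concentrated in the wide first stage — the 32 filters
that motif extraction later converts to PWMs — and spatial resolution is
collapsed aggressively afterwards (8 coarse regions after the first pool;
the later convolutions act as network-in-network channel mixers, and the
final pool is a pass-through). This choice is deliberate: at
desk-scale training-set sizes (thousands of sequences rather than tens of
thousands), deeper stacks with fine-grained pooling and a large flattened
dense stage memorize individual windows — training loss collapses while
held-out accuracy stays at chance — whereas a tight post-convolution
bottleneck forces the filters to converge on sequence features. Max
pooling is essential here; average pooling was tried and fails, because
the mean activation is dominated by background and is nearly identical for
both strands. All sizes are configurable, so larger LeNet-like shapes
remain available for bigger training sets. Each training sequence
contributes all of its windows, every window inheriting the sequence
label.

*Prediction.* MLP: one score per read. CNN: per-window posteriors are
averaged per orientation independently and the larger mean wins;
equivalently the mean reverse posterior is compared to 0.5. The decision
rule everywhere is *reverse iff score > 0.5* — a score exactly at the
threshold stays forward. Reads too short to featurize are reported
UNDECIDED, written unchanged, and excluded from metrics (counted
separately) rather than silently inflating accuracy.

*Metrics.* REVERSE is the positive class; precision, recall and F1 come
from the confusion matrix, with macro-averages over both classes also
reported. When no positive predictions (or labels) exist the undefined
ratio is reported as 0 with an explicit flag. Per-group accuracy tables
(e.g. by transcript type) suppress groups with ≤ 10 reads from the main
table.

## Cluster majority vote

Reads clustered by molecule — strand-specifically, as minimizer-based
clusterers produce — share a true orientation, so per-read calls pool: if
strictly more than 50% of a cluster's reads are predicted forward, all are
set forward; otherwise (including an exact tie, following the
unconditional "otherwise" branch of the rule) all are set
reverse-complemented. Unclustered reads pass through. For a cluster of n
reads with independent per-read accuracy p > 0.5 the vote is correct with
the binomial majority probability, which exceeds p for n ≥ 3 — the
improvement the tests verify by simulation.

## Motif extraction

For each first-layer filter, every window position whose pre-pooling
convolution output (after bias, before pooling — the only stage where
positions align to input) is strictly greater than 0 contributes the
w-length input subsequence under the filter; subsequences overlapping
N-padding are skipped. Counts at each position plus an optional
pseudocount (default 0, matching raw conversion; the resulting information
content is low because background positions contribute too) are
normalized into a 4×w PWM. Motifs are written in MEME minimal format with
a uniform background by default. The probe set is caller-supplied (for
example the test reads); filters with no positive activation are dropped
with a log entry.

## Synthetic data

The simulator emulates what makes real transcriptomes learnable:
forward-strand transcripts drawn from a configurable base composition with
non-overlapping k-mer motifs (default: ten fixed non-palindromic hexamers)
planted at a Poisson density, an optional geometric poly-A tail, an error
channel with per-base substitutions and length-1 indels, 5′ truncation
(geometric length, at least 250 nt retained) mimicking internal priming,
and per-read random reverse-complementation recorded as the truth label.
Motif insertion overwrites background bases, keeping lengths exact;
overlapping draws are resampled with bounded retries. Clusters are
(transcript, strand) pairs by default so the majority-vote premise holds;
`cluster_by_strand=False` pools both strands of a molecule. Everything is
deterministic given the seed.

What the simulator does *not* model: homopolymer-specific ONT errors,
realistic quality strings, transcript-family homology, expression-level
skew, or adapter sequences. Passing the synthetic benchmarks therefore
demonstrates that the estimators recover strand-asymmetric signal through
the full pipeline — not that the desk-scale accuracies transfer to any
particular organism, where performance depends on the annotation size and
the biology.

## Benchmark conditions and numerical choices

The reference benchmark (`benchmarks.py`) uses 3,000 training and 1,000
held-out transcripts, lengths 500–2,000 nt, ten planted hexamers at one
per 100 nt, k_max = 4 for the MLP; the noise variant applies 5%
substitutions + 2.5% insertions + 2.5% deletions to the test reads while
training stays on clean transcripts (training on an annotation, testing
on noisy reads); the trimming variant removes 100 nt from both test-read
ends; the null control sets motif density to 0, where accuracy must stay
within 0.5 ± 0.05. The motif-recovery benchmark plants a single hexamer
(GATTAC) at one per 50 nt in 2,000 training sequences of 500–800 nt.
These sizes were chosen as the smallest at which both models converge
comfortably; all are parameters, not constants.

Numerical details: float32 arithmetic throughout the network; He
initialization for ReLU layers and Glorot for output layers; the k-mer
rolling index is computed in integer arithmetic (exact); PWM columns are
validated to sum to 1 within 1e-9; MEME round-trips renormalize columns to
absorb the file format's fixed precision (1e-6). Model persistence stores
weights in an `.npz` plus a JSON sidecar (kind, featurization, config,
label convention); loading restores bitwise-identical predictions and
refuses mismatched kinds or feature dimensions.

## Known limitations

* Scores are uncalibrated probabilities; near-0.5 scores are effectively
  coin flips and the vote step is the practical remedy.
* Very short reads (< k_max for the MLP) are UNDECIDED by construction.
* The numpy training loop is CPU-bound and single-threaded beyond BLAS;
  training on annotation-scale inputs (tens of thousands of sequences) is
  possible but slow compared to a GPU framework.
* Exact ties in the cluster vote flip the cluster; with well-calibrated
  per-read accuracy > 0.5 this is the rarer error direction, but it is a
  convention, not a fitted choice.
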