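# Methods

## Problem and model

`lncgat` classifies long non-coding RNA transcripts by their
bifunctional potential — whether a transcript annotated as non-coding
also encodes a (micro)peptide. The model treats each transcript as a
weighted directed De Bruijn graph over its k-mers and learns a
graph-attention classifier on top of it.

**Graph construction.** A transcript of length L is segmented into its
L−k+1 overlapping k-mers (default k = 3). Nodes are the distinct
k-mers in order of first occurrence; a directed edge i→j exists for
every adjacent k-mer pair and carries the count W_ij of the spanning
(k+1)-mer. Counts are degree-normalized,

    w_ij = W_ij / sqrt( S_down(i) · S_up(j) ),

with S_down(i) the total raw weight leaving node i and S_up(j) the
total entering j. We use the square-root (symmetric-style) form
because it is scale-invariant — replicating a sequence, or doubling
all counts, leaves every normalized weight unchanged, so the network
sees relative adjacency structure rather than transcript length. The
plain-product denominator, which shrinks weights quadratically with
coverage, is available as `edge_norm="product"` for comparison.
Ambiguous bases (N) turn their windows into skip markers: no node and
no edge is ever created from a window whose identity is unknown, and
adjacency is never bridged across a skip.

**Node features.** k-mers are embedded as words with a CBOW
(continuous bag-of-words) objective, one sentence per transcript: the
averaged input vectors of a ±5-token window predict the center k-mer
through a softmax over the vocabulary. With k = 3 the vocabulary is at
most 64 words, so the softmax is computed exactly — no negative
sampling or hierarchical approximation — and training is a small,
fully deterministic numpy loop (seeded shuffling, single thread).
Batches use the summed gradient rather than the mean, which
approximates the classic per-position SGD schedule of word2vec at the
same nominal learning rate (default 0.05, 10 epochs, d = 64).
Embeddings are trained only on the training split and are not
fine-tuned by the classifier; prediction on new sequences is a pure
lookup. Out-of-vocabulary k-mers (possible only for k > 3) map to the
zero vector with a warning.

**Attention layer.** One multi-head attention layer with K = 3
concatenated heads. The attention neighborhood of node i is its set of
in-neighbors — the k-mers that immediately precede it 5'→3' — plus i
itself. Per head, with transform W and attention vector a split into
halves a1 (attending node) and a2 (neighbor):

    e_ij = LeakyReLU( a1·W h_i + a2·W h_j ),  slope 0.2
    α_ij = w_ij exp(e_ij) / Σ_m w_im exp(e_im)
    h'_i = α_ii W h_i + Σ_j α_ij W h_j

The softmax is biased multiplicatively by the normalized De Bruijn
edge weight w_ij (self term weight 1), which is how the graph's
frequency structure reaches the attention distribution; the unbiased
variant is available as `edge_bias="none"`. A homopolymer self-loop
(e.g. AAA→AAA) stays in the graph for frequency analytics but is not
duplicated into the message list — the layer's own self term, with
weight 1, is the single self contribution per node, matching the form
of the output equation above. Head outputs are concatenated (no
nonlinearity between the attention layer and the head), mean-pooled
over nodes into a graph vector (mean is size-invariant across
transcripts; sum/max are config options), and classified by a
two-layer fully connected head (K·hidden → 64 → 1, ReLU inside,
logistic output). Dropout 0.1 is applied to the FC input during
training only.

The whole network is plain numpy with a hand-derived backward pass.
Gradients are verified against central finite differences in the test
suite (relative error < 1e-4 on sampled coordinates). Batches pack
graphs block-diagonally; per-node reductions run over dst-sorted edge
lists (`np.add.reduceat`) and sparse CSR matmuls, which keeps a
training epoch on ~320 graphs below 0.2 s on one CPU core.

**Training.** Stratified 5-fold cross-validation produces five
independent members; the ensemble probability is their arithmetic
mean, thresholded at 0.5 (ties positive). Each member minimizes binary
cross-entropy with Adam (lr 1e-4, batch 64, at most 200 epochs) and
early stopping: training halts after 10 epochs without validation-loss
improvement and the returned parameters are those of the best
validation epoch. BCE is the natural loss for a logistic output; the
monitor and patience are our choices, exposed in `TrainConfig`.
Training negatives can be downsampled to `neg_pos_ratio` × positives
(default 1:1) to avoid the sensitivity/specificity imbalance that
unbalanced pools produce.

**Metrics.** ACC, SN, SP and MCC follow the standard confusion-matrix
identities; AUC is the rank-based (Mann-Whitney) area with midranks
for ties — deterministic and equivalent to the trapezoidal ROC area.
Single-class inputs report AUC and MCC as NA with a warning.

## Interpretability

* **Attention entropy.** H_i = −Σ_j α_ij log2 α_ij over node i's
  attention row, with 0·log 0 = 0. Attention is aggregated as the mean
  of α across heads (and across the five ensemble members when applied
  post-training), renormalized per node before the entropy. Per-head or
  per-member entropies would be equally defensible; the averaged
  network is what the rest of the analytics (attention network, EPC)
  consume, so the entropy is computed on the same object.
* **Entropy–frequency correlation.** Spearman rank correlation of
  per-k-mer mean entropy against mean frequency, per class. Spearman
  rather than Pearson because k-mer frequencies are heavy-tailed.
* **Rank shift.** k-mers ranked by mean entropy within each class
  (rank 1 = highest, lexicographic tie-break); shift = rank_neg −
  rank_pos, so a positive shift marks a k-mer with relatively higher
  attention entropy in bifunctional transcripts. On synthetic data
  with planted coding signals, the start codon ATG shifts positive and
  the stop codons (TAA/TGA/TAG) and TTA shift negative in every seed
  we examined; the *largest* positive shifts, however, go to
  codon-composition 3-mers such as TAC/TAT/TCA — the in-frame
  depletion of stop codons inside the planted ORF is a stronger
  per-3-mer signal than the one-per-ORF start codon. Real transcript
  data, where start-codon context is not a single planted hexamer,
  need not show the same ordering.
* **Attention network and EPC centrality.** The per-transcript network
  has edge weights equal to head- and member-averaged attention,
  renormalized per attending node; no pruning by default (a display
  threshold is exposed). Edge-percolated-component centrality is
  operationalized as Monte-Carlo percolation: each edge is retained
  independently with probability equal to its weight, and a node's
  score is the mean size of its weakly connected component over
  `replicates` trials (default 1000). The estimator is exactly
  unbiased; tests verify it against exhaustive enumeration over all
  2^E edge subsets on small networks. Self-loops never affect
  connectivity and are excluded from percolation.
* **Motif enrichment.** Presence/absence 2×2 contingency per class,
  Pearson chi-squared without continuity correction (intended for
  hundreds of sequences), df = 1.

## Synthetic data

The generator emulates the signal structure the classifier is meant to
detect, so the whole pipeline is testable without downloads. The
background is i.i.d. nucleotides at a configurable GC content (default
0.45, a typical transcript value). Positives carry exactly one planted
open reading frame: the Kozak-like hexamer GCCATG (its terminal ATG is
the start codon), 30–90 stop-free sense codons, and one stop codon;
coordinates are recorded in a ground-truth table. Negatives receive
extra stop codons (TAA/TGA/TAG) scattered to roughly double the
background in-frame stop density, and any residual ORF of at least 15
codons is disrupted by an in-frame stop until none remains. One
boundary rule matters: writing TGA immediately after an A would
fabricate the trigram ATG, quietly enriching negatives in start-codon
content — the opposite of the intended class contrast — so in that
context negatives use TAA or TAG instead. The two classes thus differ
in stop density and ORF structure, not in spurious start codons.

What this emulates: start-codon context, ORF-length contrast, and the
stop-codon depletion/enrichment asymmetry between coding and
non-coding sequence. What it does not: real transcript composition
(higher-order Markov structure, splice features, codon usage bias,
database redundancy), so passing the synthetic benchmark demonstrates
that the machinery recovers a planted signal of this kind, not
performance on curated transcript databases. A 3rd-order background is
left as a config extension.

## Problem sizes and numerical choices

The packaged end-to-end benchmark trains on 400 synthetic transcripts
(balanced) and evaluates on 100 held-out ones, sizes chosen so the
full 5-fold run completes in minutes on a single CPU core while
remaining comfortably learnable. Tolerances: attention rows sum to 1
within 1e-6; the vectorized layer matches the dense oracle within
1e-5; early stopping uses a 1e-9 improvement margin to make
tie-breaking deterministic. Degenerate inputs fail loudly: sequences
shorter than k+1 or consisting entirely of ambiguous windows cannot
form a graph and are reported per-sequence as NA with a reason at
prediction time (and rejected at training time with a warning).

## Known limitations

* One attention layer; deeper stacks are a config extension, not
  implemented.
* The batched training path supports mean readout only (the
  single-graph inference path also offers sum/max).
* CBOW with an exact softmax is only practical for small vocabularies
  (k ≤ 5); larger k would need sampled objectives.
* No GPU path; the numpy kernels are tuned for the packaged problem
  sizes, not database-scale corpora.
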