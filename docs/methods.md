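# Methods

## Model and assumptions

The classifier assumes that each code ℓ in a fixed label set 𝓛 is
signalled by short, position-independent token spans ("informative
snippets"), most of them specific to one or a few codes ("non-generic"),
some shared across codes ("generic"). Under that assumption a single
convolutional layer over word embeddings is the right feature extractor —
a filter of width k is exactly a template for a ≤k-token span — and the
required capacity is governed by the *number of distinct snippets in the
task*, not by the depth of the network. The filter count d_c is therefore
the central architectural parameter: the package's ablation and shuffle
experiments measure what happens when it is too small (capacity
starvation: labels stuck at precision 0, with the identity of the starved
labels set by the order training data is visited).

Two pooling heads are provided. The per-label attention head computes
α_ℓ = SoftMax(Hᵀ u_ℓ) and v_ℓ = Σ_n α_ℓ,n h_n with a learned vector u_ℓ
per code; it is the default because the attention argmax yields snippet
explanations directly. The max-pooling head (v_j = max_n h_{n,j}) is the
textCNN form; its explanations come from the pooled argmax of the filter
with the largest |β_ℓ,j·v_j| contribution to the code's logit, a
documented design choice since max-pooling defines no per-label
attention.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| d_e | 100 | embedding size; the conventional value for discharge-summary coding (50 in the desk-scale experiments — ample for a synthetic vocabulary) |
| d_c | 500 | filter count for the headline configuration; 50 is the "narrow" comparison; the desk-scale pair is 80 vs 4 for a 10-label task |
| k | 4 | filter width (tokens), the grid optimum; even widths pad ⌊(k−1)/2⌋ left and ⌈(k−1)/2⌉ right so H keeps length N |
| g | tanh | elementwise nonlinearity; relu configurable |
| q | 0.2 | dropout on the embedded input, training only |
| lr | 0.001 | Adam step size; tuning grid {0.0001, 0.0003, 0.001, 0.003} |
| batch | 16 | fixed mini-batch size |
| patience | 10 | early-stopping epochs without strict validation macro-F1 improvement |
| threshold | 0.5 | probability cutoff for binary decisions and per-epoch validation F1 |
| min_doc_freq | 3 | vocabulary filter: token must occur in ≥3 *training* documents |
| max_len | 2500 | truncation (first 2500 tokens kept) |
| k (labels) | 50 | top-k label space for clinical corpora; 10 in the synthetic experiments |

Optimizer (Adam, no weight decay), activation, dropout placement (on the
embedded input), decision threshold, initialization (symmetric uniform
scaled by fan-in; seeded) and the strict-improvement early-stopping rule
are deliberate choices where the protocol is otherwise open; each is
configurable. Embeddings are fine-tuned during supervised training by
default (freezable). The PAD embedding row is pinned at zero and receives
no gradient. Document-padding positions are masked out of attention and
pooling; the zero-padding in the convolution is separate and always on,
preserving sequence length.

## Preprocessing

Tokenization lowercases and splits on maximal runs of non-alphanumeric
characters; tokens without an ASCII letter are dropped ("100" goes,
"100ml" stays). "Alphabetic" means ASCII a–z for reproducibility across
locales. Label frequencies for the top-k filter are counted on the full
corpus before splitting; the vocabulary is built from the training
partition only. Splits are by patient (default 0.70/0.15/0.15), so no
patient contributes documents to two partitions. Order of truncation and
UNK replacement does not affect the output under this scheme.

## CBOW pretraining

Word vectors can be pretrained with the continuous-bag-of-words
objective with negative sampling (5 negatives from the unigram^0.75
distribution, dynamic window ≤5, 5 epochs, linearly decaying step size),
implemented in numpy, single-threaded and bit-reproducible under its
seed. Tokens never seen as a center word keep their seeded random
initialization. For the synthetic experiments random initialization is
the default: pretraining is not what those experiments measure.

## Metrics

Macro metrics average per-label values; micro metrics flatten all
(document, code) pairs. Precision/recall/F1 with empty denominators are
defined as 0, which is what lets a per-label report say "precision 0" for
a label the model never predicts — the quantity the ablation tracks.
Macro-AUC skips labels lacking both classes in the evaluated split and
records the skip. P@n breaks score ties by ascending label index, making
it deterministic and invariant under strictly monotone score transforms.
The paired bootstrap resamples documents with replacement and reports the
fraction of resamples where model A's metric falls below B's, ties
counting one half (so identical models give exactly 0.5); it is one-sided
and deterministic under its seed. The baseline is one-vs-rest logistic
regression (liblinear) on raw unigram counts over the same vocabulary.

## Synthetic corpus: what it emulates, what it does not

The generator plants, for each true label (independent Bernoulli draws,
resampled if a document would have no label), one of its dedicated
3-token phrases at a uniform position with probability `plant_prob`, plus
generic phrases shared by label pairs, in documents of Zipf(1.1) noise
tokens over a 5000-word synthetic vocabulary (long-tailed, so the
document-frequency filter does real work). Snippet vocabulary is disjoint
from noise by default so ground-truth audits of extracted explanations
are unambiguous; a hard mode draws snippets from the noise vocabulary.
Patients are assigned round-robin. Ground truth (phrases, positions,
owning labels) is emitted as a sidecar, and positions remain valid after
tokenization and encoding.

At `plant_prob = 1` the corpus is exactly separable and the
string-matching classifier "predict ℓ iff one of ℓ's phrases occurs" is a
perfect ceiling (macro-F1 1); at lower plant probability its per-label
recall ≈ plant_prob at precision 1.

What passing tests on this corpus show: the optimization, masking,
attention and explanation machinery recover planted structure, and the
capacity-starvation and data-order phenomena appear exactly as the theory
of one-filter-per-snippet predicts. What they do not show: performance on
real clinical text, which has negation, section structure, spelling
variation, label correlation, and codes (e.g. "unspecified" diagnoses)
whose assignment depends on the *absence* of more specific evidence —
a failure mode no presence-based snippet detector addresses.

## Desk-scale study conditions

The experiments and the acceptance script use: 10 labels, 2 snippets per
label, 3 generic snippets, 2000 documents of 300 tokens over 400
patients, label probability 0.3, plant probability 1. The model pair is
d_c = 80 (wide) vs 4 (narrow) at d_e = 50, k = 4, dropout 0.2, trained
with lr 0.003 (the largest grid value, which converges in ~10–15 epochs
on the separable task), batch 16, patience 10, epoch cap 60. A full wide
run takes about a minute on one CPU; the complete acceptance protocol
about six.

## Numerical choices and degenerate inputs

Softmax is computed max-shifted; BCE on probabilities clamps to the open
unit interval at machine epsilon with a warning, and the training loss is
computed from logits via log-add-exp. A fully padded document is an error
in both heads. Max-pool and attention argmax ties resolve to the earliest
position. Training batches are formed once in length-sorted order and the
batch order is shuffled per epoch by the data-order seed — so padding
waste stays low while the data-order experiment retains its lever. A
non-finite training loss aborts with a diagnostic rather than continuing.
Checkpoints store the config plus all tensors and reload bit-exactly.

## Known limitations

Single filter width per model (an ensemble over widths is out of scope);
explanation windows are exactly k tokens, so multi-window evidence spans
are not merged; the CBOW trainer is plain numpy and meant for
desk-scale corpora, not tens of millions of tokens; no calibration of
the decision threshold; no code-hierarchy awareness.
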