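# swam

A shallow-and-wide attention CNN for multi-label medical-code assignment
from clinical free text, with attention-based snippet explanations.

## The problem

Hospital encounters are documented as free-text notes (e.g. ICU discharge
summaries) and annotated with sets of standardized diagnosis/procedure
codes such as ICD-9. Assigning those codes manually is slow and
error-prone; automating it is a multi-label text-classification problem
with a twist: for most codes, only a few short *informative snippets* in a
long document carry the signal ("endotracheal intubation" for code 96.04,
"hyponatremia" for 276.1), and a practical coder must be able to point at
them.

The architecture implemented here builds on two observations. First,
informative snippets are local, low-level features scattered at random
positions, so a *single* (shallow) convolutional layer suffices — depth
adds nothing. Second, each label-specific ("non-generic") snippet needs a
convolution filter of its own, so the layer must be *wide*: a network with
too few filters leaves some labels unlearnable, which shows up as labels
with precision 0. Widening the filter bank recovers them — the per-label
precision profile, not just the average metric, is the diagnostic.

## The model

For a document of N tokens embedded as X = [x₁ … x_N] (x_i ∈ ℝ^{d_e}),
one convolutional layer of d_c filters of width k (zero-padded so H keeps
length N):

    h_n = g(W_c ∗ x_{n:n+k−1} + b_c)            W_c ∈ ℝ^{k×d_e×d_c}

Two pooling heads turn H ∈ ℝ^{d_c×N} into document vectors:

* **per-label attention** — α_ℓ = SoftMax(Hᵀ u_ℓ), v_ℓ = Σ_n α_ℓ,n h_n,
  one attention distribution per code ℓ; the argmax of α_ℓ marks the most
  informative snippet and doubles as the model's explanation;
* **max pooling** (the classic textCNN head) — v_j = max_n h_{n,j},
  one shared document vector.

Per-label sigmoid classifiers ŷ_ℓ = σ(β_ℓᵀ v_ℓ + b_ℓ) are trained with
label-summed binary cross-entropy (Adam, batch 16, early stopping on
validation macro-F1). Embeddings are pretrained with word2vec CBOW on the
training corpus (or seeded random) and fine-tuned.

Everything — forward pass, analytic gradients, CBOW — is plain numpy.

Around the model, the package ships the full protocol: preprocessing
(lowercasing, dropping tokens with no letters, min-document-frequency 3
vocabulary, UNK replacement, truncation to 2500 tokens, top-k label space,
patient-level splits), the metric suite (macro/micro F1 and ROC-AUC, P@n,
per-label precision/recall, paired document bootstrap), a one-vs-rest
bag-of-words logistic-regression baseline, snippet-explanation extraction,
and a planted-snippet synthetic corpus generator so the width-ablation and
data-order shuffle experiments run on any machine without clinical data.
An adapter for real credentialed corpora is intentionally out of scope;
any JSON-lines file of `{patient_id, doc_id, text, codes}` works.

## Worked example

Generate a fully separable planted-snippet corpus (10 labels, two
dedicated 3-token phrases each, noise elsewhere), train the wide
per-label-attention model, evaluate, and extract explanations:

```bash
swam simulate --out corpus.jsonl --truth truth.jsonl \
    --n-labels 10 --n-docs 600 --doc-len 120 --seed 7
swam train --corpus corpus.jsonl --out-dir run --n-labels 10 \
    --d-c 80 --k 4 --dropout 0.2 --lr 0.003 --max-epochs 60 --patience 10
swam evaluate --corpus corpus.jsonl --checkpoint run/model.npz --n-labels 10
swam explain  --corpus corpus.jsonl --checkpoint run/model.npz \
    --n-labels 10 --out explanations.jsonl
```

which prints

```
wrote 600 documents to corpus.jsonl
best epoch 5 (patience_exhausted); test macro-F1 1.0000 micro-F1 1.0000 P@5 0.5685
test: AUC macro 1.0000 micro 1.0000  F1 macro 1.0000 micro 1.0000  P@5 0.5685
wrote 258 explanations to explanations.jsonl
```

The corpus is separable, so the trained model matches the string-matching
oracle's perfect F1 and AUC. P@5 is 0.57 rather than 1.0 because documents
carry ~2.8 true labels on average: even a perfect ranker cannot fill five
slots with true codes. Each explanation pins the prediction to a k-token
window; here the window covers the planted phrase for code c05.0:

```json
{"doc_id": "d00007", "code": "c05.0",
 "snippet": ["w00023", "sig05x1t0", "sig05x1t1", "sig05x1t2"],
 "position": 10, "center": 11, "attention": 0.375, "score": 0.992}
```

The width ablation (`swam ablate`) and shuffle study (`swam shuffle`)
compare an 80-filter and a 4-filter model: the narrow model leaves labels
at precision 0 and *which* labels starve depends on the order training
data is visited, while the wide model has none under any data order.

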