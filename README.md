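# stsfuse

Sentence-pair semantic similarity scoring (0–5 scale) for clinical-style
text.  A sentence pair is described two ways — by a 17-slot handcrafted
feature vector (lengths, IDF aggregates, distinct n-gram overlaps, eight
distance/kernel similarities over averaged word embeddings) and by a dense
vector from a neural pair encoder (Siamese CNN, Siamese BiLSTM, or a
transformer over `[CLS] s1 [SEP] s2 [SEP]`).  Both are projected into a
common space with tanh activations and blended componentwise by a learned
sigmoid gate; a bounded regression head maps the fused vector to a score.
Plain concatenation and single-representation baselines are included so the
full ablation grid can be trained and compared.

The neural stack (reverse-mode autodiff, the three encoders, Adam) is
implemented on numpy — no deep-learning framework is required.

## Data formats

* **Pair corpora**: UTF-8 TSV, no header, `sentence1<TAB>sentence2` with an
  optional third column holding the gold score in [0, 5].
* **Embeddings**: word2vec text or binary layout (`--emb-format`); without a
  file, a deterministic random table backs the kernel-similarity features.
* **Checkpoints**: single `.npz` archive with all parameter tensors, the
  config snapshot, the feature-name list and the feature scaler.
* **Pretrained transformer bundle**: a directory containing `weights.npz`
  and `vocab.txt` (one token per line, must match the training vocabulary);
  see `TransformerEncoder.load_weights`.

## CLI

```sh
# 1. generate a synthetic scored corpus (overlap-controlled, seeded)
stsfuse synth --out pairs.tsv --n-pairs 2000 --seed 7

# 2. inspect the handcrafted features
stsfuse featurize --pairs pairs.tsv --out features.tsv

# 3. train any mode x encoder combination (dev split is stratified over the
#    five unit score intervals)
stsfuse train --train pairs.tsv --mode gated --encoder cnn \
    --checkpoint model.npz --report dev_report --seed 7

# 4. predict and evaluate
stsfuse predict --checkpoint model.npz --pairs pairs.tsv --out preds.tsv --scored
stsfuse evaluate --predictions preds.tsv --json-out report.json
```

Modes: `onehot_only`, `encoder_only`, `concat`, `gated`; encoders: `cnn`,
`lstm`, `transformer`.  A YAML file passed via `--config` can preset any
training option (explicit flags win).  Exit codes: 0 ok, 1 usage error,
2 data/format error.

Evaluation reports overall Pearson plus per-interval Pearson and MSE over
the score bins [0,1), [1,2), [2,3), [3,4), [4,5].

## Preprocessing

`stsfuse.preprocess.normalize` lowercases, tokenizes on alphanumeric runs,
expands pure-digit tokens into English cardinal words ("24" → "twenty
four"), lemmatizes with conservative suffix rules, and removes a minimal
function-word stopword list (content-bearing prepositions like "within",
"without" and "every" are kept; the list is configurable per call).

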