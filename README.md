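# cvdnlp

Character-level clinical-text mining in two stages:

1. **Risk-factor tagging** — a BiLSTM-CRF labels each character of an EMR
   document with a BIO tag over (risk-factor category × time attribute)
   pairs (12 categories, 85 tags), then decodes mentions with Viterbi.
2. **CVD prediction** — an attention-based classifier (RFAB) encodes the
   character sequence with one BiLSTM, turns each extracted risk factor
   into a query over those encodings via dot-product attention, runs a
   second BiLSTM over the fused factor vectors (seeded from the first
   encoder's final state), and predicts a binary document label.

The original corpora are private, so the package ships a synthetic-EMR
generator with the same statistical structure: abstract-alphabet documents
with gold mention spans, time-attribute frequencies proportional to the
published count table, and a document label produced by a known linear rule
over the (category, attribute) pairs present. All tensor math (autodiff,
LSTMs, CRF, skip-gram, Adagrad) is implemented directly on numpy — the
package has no deep-learning framework dependency.

## Layout

```
src/cvdnlp/
  corpus_io.py      document/mention model, BIO codec, JSONL + CoNLL I/O
  synthetic_emr.py  corpus generator + published attribute-count fixture
  embeddings.py     skip-gram character embeddings, word2vec text format
  nn.py             numpy autodiff, LSTM/BiLSTM, Adagrad
  crf.py            linear-chain CRF: scoring, partition, Viterbi, NLL grad
  tagger.py         BiLSTM-CRF model, training, mention extraction
  rfab.py           attention classifier, ablation variants, training
  evaluation.py     classification/entity metrics, attention export
  cli.py            the `rfab` pipeline command
```

## CLI

Each stage reads a YAML config and writes artifacts plus a run log into a
work directory; reruns with the same config and seed are byte-identical.

```bash
rfab generate    --config cfg.yaml --seed 1      # synthetic corpora (JSONL)
rfab embed       --config cfg.yaml               # skip-gram pretraining
rfab train-tagger --config cfg.yaml              # BiLSTM-CRF checkpoint
rfab extract     --config cfg.yaml               # re-tag predictor corpus
rfab train-rfab  --config cfg.yaml --variant with-labels
rfab predict     --config cfg.yaml               # predictions + attention TSV
rfab evaluate    --config cfg.yaml               # metrics.json (A/P/R/F)
rfab visualize   --config cfg.yaml               # attention heatmap PNG
rfab all         --config cfg.yaml               # the whole flow
```

Config keys mirror the dataclasses (`GeneratorConfig`, `TaggerConfig`,
`RfabConfig`); omitted keys use the published hyperparameter defaults
(d_w=100, h=256, lr=1e-3, batch 10, dropout 0.5, decay 0.99/500, 60
epochs). RFAB variants: `with-labels`, `no-labels`, `no-att`, `raw`.

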