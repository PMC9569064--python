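"""Risk-factor attention classifier.

Two stacked bidirectional LSTMs: the first encodes the character sequence
(zero initial state), the second consumes one vector per extracted risk
factor and starts from the first encoder's final states.  Between them, a
dot-product attention turns each risk-factor query into a weighted sum of
the character encodings.  A sigmoid + softmax head maps the final state to
the two-class CVD distribution.

The factor query (dimension D) and the character encodings (dimension 2h)
live in different spaces, so a learned linear projection lifts the query
to 2h before the dot product.  Two ablation flags reproduce the published
variants: ``use_attention=False`` feeds the projected factor embeddings
straight to the second encoder, and ``use_labels=False`` drops the learned
category/time-attribute embeddings from the factor inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import EmrDocument, RiskFactorCategory, TimeAttribute
from .embeddings import EmbeddingTable
from .nn import Adagrad, BiLSTM, Tensor, concat, glorot, logsumexp, stack

logger = logging.getLogger(__name__)

__all__ = [
    "RfabConfig",
    "AttentionRecord",
    "PredictionOutput",
    "RfabModel",
    "attend",
    "cross_entropy",
    "variant_flags",
    "train_rfab",
    "predict_document",
]

UNK = "<unk>"
_CATEGORIES = list(RiskFactorCategory)
_ATTRIBUTES = list(TimeAttribute)
_CAT_INDEX = {c: i for i, c in enumerate(_CATEGORIES)}
_ATTR_INDEX = {a: i for i, a in enumerate(_ATTRIBUTES)}


@dataclass
class RfabConfig:
    embedding_dim: int = 100
    hidden: int = 256
    lr: float = 1e-3
    batch_size: int = 10
    dropout: float = 0.5
    decay_rate: float = 0.99
    decay_steps: int = 500
    epochs: int = 60
    seed: int = 0
    use_attention: bool = True
    use_labels: bool = True
    early_stop_f: float | None = None

    def __post_init__(self):
        if min(self.embedding_dim, self.hidden, self.batch_size, self.epochs) <= 0:
            raise ValueError("dimensions, batch size and epochs must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def variant_flags(name: str) -> tuple:
    """Map a variant name to (use_attention, use_labels)."""
    table = {
        "with-labels": (True, True),
        "no-labels": (True, False),
        "no-att": (False, True),
        "raw": (False, False),
    }
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown variant {name!r}; expected one of {sorted(table)}")


@dataclass
class AttentionRecord:
    factor_index: int
    surface: str
    weights: np.ndarray  # (m,) non-negative, sums to 1
    attended: np.ndarray  # (2h,)
    doc_id: str = ""


@dataclass
class PredictionOutput:
    logits: np.ndarray  # sigmoid outputs O, shape (2,)
    probabilities: np.ndarray  # softmax(O), shape (2,)
    label: int
    representation: np.ndarray  # Z, shape (2h,)


def attend(context: np.ndarray, query: np.ndarray):
    """Reference attention on plain arrays: softmax over the dot products
    of the query with each context row, then the weighted sum.

    Returns (weights, attended).  The model's training path computes the
    same thing through the autodiff graph.
    """
    context = np.asarray(context, dtype=np.float64)
    query = np.asarray(query, dtype=np.float64)
    raw = context @ query
    raw = raw - raw.max()
    weights = np.exp(raw)
    weights = weights / weights.sum()
    return weights, weights @ context


def cross_entropy(distributions: Sequence, gold_labels: Sequence[int]) -> float:
    """Mean negative log predicted probability of the gold class."""
    distributions = np.asarray(distributions, dtype=np.float64)
    gold = np.asarray(gold_labels, dtype=np.intp)
    if distributions.shape[0] != gold.shape[0]:
        raise ValueError("batch size mismatch between distributions and labels")
    picked = distributions[np.arange(len(gold)), gold]
    return float(np.mean(-np.log(np.clip(picked, 1e-300, None))))


class RfabModel:
    def __init__(self, config: RfabConfig, char_vocab: Sequence[str],
                 embedding_table: EmbeddingTable | None = None):
        self.config = config
        self.chars = [UNK] + sorted(set(char_vocab) - {UNK})
        self.char_index = {c: i for i, c in enumerate(self.chars)}
        D, H = config.embedding_dim, config.hidden
        rng = np.random.default_rng(config.seed)
        emb = (rng.random((len(self.chars), D)) - 0.5) / np.sqrt(D)
        if embedding_table is not None:
            if embedding_table.dim != D:
                raise ValueError("embedding table dimension does not match config")
            for ch, vec in embedding_table.vectors.items():
                if ch in self.char_index:
                    emb[self.char_index[ch]] = vec
        self.embedding = Tensor(emb, requires_grad=True)
        self.context_encoder = BiLSTM(rng, D, H)
        self.factor_encoder = BiLSTM(rng, 2 * H, H)
        self.projection = Tensor(glorot(rng, D, 2 * H), requires_grad=True)
        self.no_factor = Tensor(rng.normal(scale=0.1, size=D), requires_grad=True)
        self.category_emb = Tensor(rng.normal(scale=0.1, size=(len(_CATEGORIES), D)),
                                   requires_grad=True)
        self.attribute_emb = Tensor(rng.normal(scale=0.1, size=(len(_ATTRIBUTES), D)),
                                    requires_grad=True)
        self.w_out = Tensor(glorot(rng, 2 * H, 2), requires_grad=True)
        self._rng = rng

    def parameters(self):
        return (
            [self.embedding, self.projection, self.no_factor,
             self.category_emb, self.attribute_emb, self.w_out]
            + self.context_encoder.parameters()
            + self.factor_encoder.parameters()
        )

    # -- input assembly --------------------------------------------------

    def _char_ids(self, chars: str) -> np.ndarray:
        unk = self.char_index[UNK]
        return np.array([self.char_index.get(c, unk) for c in chars], dtype=np.intp)

    def _factor_vector(self, mention) -> Tensor:
        """Mean of the surface's character embeddings, plus the learned
        category and time-attribute embeddings when labels are in use."""
        ids = self._char_ids(mention.surface)
        vec = self.embedding[ids].mean(axis=0)
        if self.config.use_labels:
            vec = vec + self.category_emb[_CAT_INDEX[mention.category]]
            vec = vec + self.attribute_emb[_ATTR_INDEX[mention.time_attr]]
        return vec

    def factor_input(self, mentions) -> list:
        """Per-mention factor vectors in document order; a lone learned
        placeholder when the document has no extracted factors."""
        if not mentions:
            return [self.no_factor]
        return [self._factor_vector(m) for m in sorted(mentions, key=lambda m: m.start)]

    # -- forward ---------------------------------------------------------

    def forward(self, docs: Sequence[EmrDocument], train: bool = False):
        """Batched forward pass.

        Returns (log_probs, attention) where ``log_probs`` is a (B, 2)
        tensor of log class probabilities and ``attention`` a per-document
        list of (n, m) weight arrays (empty when attention is off).
        """
        B = len(docs)
        if any(len(d.chars) == 0 for d in docs):
            raise ValueError("cannot classify an empty character sequence")
        cfg = self.config
        H2 = 2 * cfg.hidden
        ids_list = [self._char_ids(d.chars) for d in docs]
        m_max = max(len(i) for i in ids_list)
        ids = np.zeros((B, m_max), dtype=np.intp)
        cmask = np.zeros((B, m_max))
        for b, i in enumerate(ids_list):
            ids[b, : len(i)] = i
            cmask[b, : len(i)] = 1.0

        x = self.embedding[ids]
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            x = x * Tensor((self._rng.random(x.shape) < keep) / keep)
        context, finals = self.context_encoder(x, cmask)  # (B, m, 2h)

        factor_lists = [self.factor_input(d.mentions) for d in docs]
        n_max = max(len(f) for f in factor_lists)
        fmask = np.zeros((B, n_max))
        rows = []
        zero = Tensor(np.zeros(cfg.embedding_dim))
        for b, factors in enumerate(factor_lists):
            fmask[b, : len(factors)] = 1.0
            rows.append(stack(factors + [zero] * (n_max - len(factors)), axis=0))
        ef = stack(rows, axis=0)  # (B, n, D)
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            ef = ef * Tensor((self._rng.random(ef.shape) < keep) / keep)

        queries = ef @ self.projection  # (B, n, 2h)
        attention: list = []
        if cfg.use_attention:
            raw = queries @ context.swapaxes(1, 2)  # (B, n, m)
            raw = raw + Tensor((1.0 - cmask[:, None, :]) * -1e9)
            log_alpha = raw - logsumexp(raw, axis=2, keepdims=True)
            alpha = log_alpha.exp()
            attended = alpha @ context  # (B, n, 2h)
            # residual fusion: the attended context is added to the
            # projected factor query rather than replacing it, so the
            # factor identity never has to survive a diluted softmax
            fused = queries + attended
            for b, factors in enumerate(factor_lists):
                attention.append(
                    (
                        alpha.data[b, : len(factors), : len(ids_list[b])],
                        attended.data[b, : len(factors), :],
                    )
                )
        else:
            fused = queries

        _, f_finals = self.factor_encoder(fused, fmask, init_state=finals)
        hf, _, hb, _ = f_finals
        z = concat([hf, hb], axis=1)  # (B, 2h)
        assert z.shape == (B, H2)
        logits = (z @ self.w_out).sigmoid()
        log_probs = logits - logsumexp(logits, axis=1, keepdims=True)
        return log_probs, attention, z

    def predict(self, docs: Sequence[EmrDocument]):
        """Deterministic inference; returns per-document PredictionOutput
        and AttentionRecord lists."""
        log_probs, attention, z = self.forward(docs, train=False)
        logits_all = 1.0 / (1.0 + np.exp(-(z.data @ self.w_out.data)))
        outputs = []
        records = []
        for b, doc in enumerate(docs):
            probs = np.exp(log_probs.data[b])
            outputs.append(
                PredictionOutput(
                    logits=logits_all[b],
                    probabilities=probs,
                    label=int(np.argmax(probs)),
                    representation=z.data[b].copy(),
                )
            )
            recs = []
            if attention:
                weights, fused = attention[b]
                mentions = sorted(doc.mentions, key=lambda m: m.start) if doc.mentions else []
                for i, row in enumerate(weights):
                    surface = mentions[i].surface if i < len(mentions) else ""
                    recs.append(
                        AttentionRecord(
                            factor_index=i,
                            surface=surface,
                            weights=row.copy(),
                            attended=fused[i].copy(),
                            doc_id=doc.doc_id,
                        )
                    )
            records.append(recs)
        return outputs, records

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "chars": self.chars,
            "weights": [p.data.tolist() for p in self.parameters()],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RfabModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(RfabConfig(**payload["config"]), payload["chars"])
        for p, d in zip(model.parameters(), payload["weights"]):
            p.data = np.array(d)
        return model

    def snapshot(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, snap: list) -> None:
        for p, d in zip(self.parameters(), snap):
            p.data = d.copy()


def train_rfab(train_docs: Sequence[EmrDocument], dev_docs: Sequence[EmrDocument],
               config: RfabConfig,
               embedding_table: EmbeddingTable | None = None):
    """Adagrad training of the classifier; returns the model restored to
    its best-dev-F epoch plus the per-epoch history."""
    from .evaluation import classification_report

    for doc in train_docs:
        if doc.cvd_label is None:
            raise ValueError(f"{doc.doc_id}: training document has no CVD label")
    char_vocab = sorted({c for d in train_docs for c in d.chars})
    if embedding_table is not None:
        char_vocab = sorted(set(char_vocab) | set(embedding_table.vectors))
    model = RfabModel(config, char_vocab, embedding_table)
    params = model.parameters()
    opt = Adagrad(params, lr=config.lr, decay_rate=config.decay_rate,
                  decay_steps=config.decay_steps)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    docs = list(train_docs)
    dev_gold = [d.cvd_label for d in dev_docs]
    history = []
    best_f, best_snap = -1.0, model.snapshot()
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(docs))
        losses = []
        for s in range(0, len(docs), config.batch_size):
            batch = [docs[i] for i in order[s : s + config.batch_size]]
            labels = np.array([d.cvd_label for d in batch], dtype=np.intp)
            log_probs, _, _ = model.forward(batch, train=True)
            picked = log_probs[np.arange(len(batch)), labels]
            loss = -picked.mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        outputs, _ = model.predict(dev_docs)
        report = classification_report(dev_gold, [o.label for o in outputs])
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "dev_f": report.f_score})
        logger.info("epoch %d: loss %.4f dev F %.2f", epoch + 1,
                    history[-1]["loss"], report.f_score)
        if report.f_score > best_f:
            best_f = report.f_score
            best_snap = model.snapshot()
        if config.early_stop_f is not None and best_f >= config.early_stop_f:
            break
    model.restore(best_snap)
    return model, history


def predict_document(doc: EmrDocument, tagger_model, rfab_model: RfabModel):
    """Full two-stage prediction: extract risk factors with the tagger,
    then classify with the attention model."""
    from .tagger import extract_risk_factors

    mentions = extract_risk_factors(doc, tagger_model)
    staged = EmrDocument(doc_id=doc.doc_id, chars=doc.chars, mentions=mentions,
                         cvd_label=doc.cvd_label)
    outputs, records = rfab_model.predict([staged])
    return outputs[0], records[0]
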