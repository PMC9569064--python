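"""BiLSTM-CRF risk-factor tagger.

Characters are embedded, encoded by a bidirectional LSTM, projected to
per-tag confidence scores through a tanh layer, and decoded by a
linear-chain CRF whose transition matrix is learned jointly with the
network.  Training minimises the negative log-likelihood of the gold tag
paths; decoding uses Viterbi.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import crf
from .corpus_io import (
    EmrDocument,
    TagVocabulary,
    build_tag_vocabulary,
    from_bio,
    to_bio,
)
from .embeddings import EmbeddingTable
from .nn import Adagrad, BiLSTM, Tensor, glorot

logger = logging.getLogger(__name__)

__all__ = [
    "TaggerConfig",
    "BiLstmCrfTagger",
    "emission_scores",
    "crf_nll",
    "train_tagger",
    "extract_risk_factors",
]

UNK = "<unk>"


@dataclass
class TaggerConfig:
    embedding_dim: int = 100
    hidden: int = 256
    lr: float = 1e-3
    decay_rate: float = 0.99
    decay_steps: int = 500
    batch_size: int = 10
    epochs: int = 60
    dropout: float = 0.5
    seed: int = 0
    early_stop_f: float | None = None  # stop once dev entity-F reaches this
    vocab: TagVocabulary | None = None

    def __post_init__(self):
        if min(self.embedding_dim, self.hidden, self.batch_size, self.epochs) <= 0:
            raise ValueError("dimensions, batch size and epochs must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def emission_scores(hidden: np.ndarray, w_e: np.ndarray) -> np.ndarray:
    """Per-tag confidence scores: tanh of the linear projection of each
    hidden state; every entry lies strictly inside (-1, 1)."""
    return np.tanh(np.asarray(hidden) @ np.asarray(w_e))


def crf_nll(emissions: Tensor, transitions: Tensor, tags: np.ndarray,
            mask: np.ndarray) -> Tensor:
    """Autodiff node for the batched CRF negative log-likelihood."""
    loss, d_em, d_t = crf.crf_nll_batch(emissions.data, transitions.data, tags, mask)

    def backward(g):
        emissions._acc(g * d_em)
        transitions._acc(g * d_t)

    return emissions._make(np.asarray(loss), (emissions, transitions), backward)


class BiLstmCrfTagger:
    """The trainable model: embeddings + BiLSTM + emission layer + CRF."""

    def __init__(self, config: TaggerConfig, char_vocab: Sequence[str],
                 embedding_table: EmbeddingTable | None = None):
        self.config = config
        self.tag_vocab = config.vocab or build_tag_vocabulary()
        self.chars = [UNK] + sorted(set(char_vocab) - {UNK})
        self.char_index = {c: i for i, c in enumerate(self.chars)}
        D, H, K = config.embedding_dim, config.hidden, len(self.tag_vocab)
        rng = np.random.default_rng(config.seed)
        emb = (rng.random((len(self.chars), D)) - 0.5) / np.sqrt(D)
        if embedding_table is not None:
            if embedding_table.dim != D:
                raise ValueError("embedding table dimension does not match config")
            for ch, vec in embedding_table.vectors.items():
                if ch in self.char_index:
                    emb[self.char_index[ch]] = vec
        self.embedding = Tensor(emb, requires_grad=True)
        self.encoder = BiLSTM(rng, D, H)
        # confidence scoring: tanh feature layer, then a linear map to tag
        # space.  A single bounded tanh output per tag traps training once
        # it saturates (ties at +/-1 with zero gradient), so the scores fed
        # to the CRF are left unbounded.
        self.w_e = Tensor(glorot(rng, 2 * H, H), requires_grad=True)
        self.w_s = Tensor(glorot(rng, H, K), requires_grad=True)
        self.transitions = Tensor(rng.normal(scale=0.01, size=(K + 2, K + 2)),
                                  requires_grad=True)
        self._rng = rng

    # -- plumbing -------------------------------------------------------

    def parameters(self):
        return [self.embedding, self.w_e, self.w_s,
                self.transitions] + self.encoder.parameters()

    def _encode_ids(self, chars: str) -> np.ndarray:
        unk = self.char_index[UNK]
        return np.array([self.char_index.get(c, unk) for c in chars], dtype=np.intp)

    def _batch_arrays(self, seqs: list):
        B = len(seqs)
        L = max(len(s) for s in seqs)
        ids = np.zeros((B, L), dtype=np.intp)
        mask = np.zeros((B, L))
        for b, s in enumerate(seqs):
            ids[b, : len(s)] = s
            mask[b, : len(s)] = 1.0
        return ids, mask

    def _emissions(self, ids: np.ndarray, mask: np.ndarray, train: bool) -> Tensor:
        x = self.embedding[ids]  # (B, L, D)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            drop = (self._rng.random(x.shape) < keep) / keep
            x = x * Tensor(drop)
        hidden, _ = self.encoder(x, mask)
        return (hidden @ self.w_e).tanh() @ self.w_s

    def encode(self, chars: str) -> np.ndarray:
        """Hidden states (n, 2h) for one character sequence."""
        if len(chars) == 0:
            raise ValueError("cannot encode an empty sequence")
        ids, mask = self._batch_arrays([self._encode_ids(chars)])
        x = self.embedding[ids]
        hidden, _ = self.encoder(x, mask)
        return hidden.data[0]

    # -- inference ------------------------------------------------------

    def decode(self, chars: str) -> list:
        """Viterbi-decoded tag strings for one document."""
        if len(chars) == 0:
            return []
        hidden = self.encode(chars)
        em = emission_scores(hidden, self.w_e.data) @ self.w_s.data
        path = crf.viterbi(em, self.transitions.data)
        return [self.tag_vocab.tags[i] for i in path.tags]

    def decode_batch(self, chars_list: Sequence[str], chunk: int = 64) -> list:
        """Viterbi decoding over many documents with batched encoding."""
        out: list[list] = []
        for s in range(0, len(chars_list), chunk):
            group = chars_list[s : s + chunk]
            nonempty = [c for c in group if len(c) > 0]
            if nonempty:
                ids, mask = self._batch_arrays(
                    [self._encode_ids(c) for c in nonempty]
                )
                hidden, _ = self.encoder(self.embedding[ids], mask)
                em_all = np.tanh(hidden.data @ self.w_e.data) @ self.w_s.data
            k = 0
            for chars in group:
                if len(chars) == 0:
                    out.append([])
                    continue
                em = em_all[k, : len(chars)]
                path = crf.viterbi(em, self.transitions.data)
                out.append([self.tag_vocab.tags[i] for i in path.tags])
                k += 1
        return out

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        cfg = asdict(self.config)
        cfg.pop("vocab")
        payload = {
            "config": cfg,
            "tags": self.tag_vocab.tags,
            "chars": self.chars,
            "weights": {
                "embedding": self.embedding.data.tolist(),
                "w_e": self.w_e.data.tolist(),
                "w_s": self.w_s.data.tolist(),
                "transitions": self.transitions.data.tolist(),
                "fwd.Wx": self.encoder.fwd.Wx.data.tolist(),
                "fwd.Wh": self.encoder.fwd.Wh.data.tolist(),
                "fwd.b": self.encoder.fwd.b.data.tolist(),
                "bwd.Wx": self.encoder.bwd.Wx.data.tolist(),
                "bwd.Wh": self.encoder.bwd.Wh.data.tolist(),
                "bwd.b": self.encoder.bwd.b.data.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "BiLstmCrfTagger":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        config = TaggerConfig(**payload["config"])
        model = cls(config, payload["chars"])
        if model.tag_vocab.tags != payload["tags"]:
            raise ValueError("checkpoint tag vocabulary mismatch")
        w = payload["weights"]
        model.embedding.data = np.array(w["embedding"])
        model.w_e.data = np.array(w["w_e"])
        model.w_s.data = np.array(w["w_s"])
        model.transitions.data = np.array(w["transitions"])
        model.encoder.fwd.Wx.data = np.array(w["fwd.Wx"])
        model.encoder.fwd.Wh.data = np.array(w["fwd.Wh"])
        model.encoder.fwd.b.data = np.array(w["fwd.b"])
        model.encoder.bwd.Wx.data = np.array(w["bwd.Wx"])
        model.encoder.bwd.Wh.data = np.array(w["bwd.Wh"])
        model.encoder.bwd.b.data = np.array(w["bwd.b"])
        return model

    def snapshot(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, snap: list) -> None:
        for p, d in zip(self.parameters(), snap):
            p.data = d.copy()


def train_tagger(train_docs: Sequence[EmrDocument], dev_docs: Sequence[EmrDocument],
                 config: TaggerConfig,
                 embedding_table: EmbeddingTable | None = None):
    """Train by batched CRF maximum likelihood; return the model restored
    to its best-dev-F epoch, plus the per-epoch history."""
    from .evaluation import entity_report  # local import to avoid a cycle

    for doc in train_docs:
        if doc.mentions is None:
            raise ValueError(f"{doc.doc_id}: training document has no gold annotation")
    char_vocab = sorted({c for d in train_docs for c in d.chars})
    if embedding_table is not None:
        char_vocab = sorted(set(char_vocab) | set(embedding_table.vectors))
    model = BiLstmCrfTagger(config, char_vocab, embedding_table)
    vocab = model.tag_vocab
    data = []
    for doc in train_docs:
        tag_ids = np.array([vocab.index[t] for t in to_bio(doc, vocab)], dtype=np.intp)
        data.append((model._encode_ids(doc.chars), tag_ids))

    params = model.parameters()
    opt = Adagrad(params, lr=config.lr, decay_rate=config.decay_rate,
                  decay_steps=config.decay_steps)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = []
    best_f, best_snap = -1.0, model.snapshot()
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(data))
        losses = []
        for s in range(0, len(data), config.batch_size):
            batch = [data[i] for i in order[s : s + config.batch_size]]
            ids, mask = model._batch_arrays([b[0] for b in batch])
            tags = np.zeros_like(ids)
            for b, (_, t) in enumerate(batch):
                tags[b, : len(t)] = t
            emissions = model._emissions(ids, mask, train=True)
            loss = crf_nll(emissions, model.transitions, tags, mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        gold = [d.mentions for d in dev_docs]
        pred = extract_risk_factors_corpus(dev_docs, model)
        report = entity_report(gold, pred)
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "dev_f": report.f_score})
        logger.info("epoch %d: loss %.4f dev entity-F %.2f", epoch + 1,
                    history[-1]["loss"], report.f_score)
        if report.f_score > best_f:
            best_f = report.f_score
            best_snap = model.snapshot()
        if config.early_stop_f is not None and best_f >= config.early_stop_f:
            break
    model.restore(best_snap)
    return model, history


def extract_risk_factors(doc: EmrDocument, model: BiLstmCrfTagger) -> list:
    """Viterbi tags decoded back into entity mentions (with BIO repair)."""
    tags = model.decode(doc.chars)
    return from_bio(doc.chars, tags, model.tag_vocab)


def extract_risk_factors_corpus(docs: Sequence[EmrDocument],
                                model: BiLstmCrfTagger) -> list:
    """Batched mention extraction over a corpus; one mention list per doc."""
    tag_lists = model.decode_batch([d.chars for d in docs])
    return [
        from_bio(d.chars, tags, model.tag_vocab)
        for d, tags in zip(docs, tag_lists)
    ]
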