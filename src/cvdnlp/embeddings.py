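"""Character embeddings pretrained with skip-gram negative sampling.

The training corpus is a set of character sequences; the risk-factor
lexicon is injected as extra training sentences (optionally repeated per a
frequency weight), which boosts co-occurrence statistics inside mention
surfaces.  Implemented directly on numpy so training is single-threaded
and exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingTable",
    "train_char_embeddings",
    "lookup",
    "word_embedding",
    "save_embeddings",
    "load_embeddings",
]


@dataclass
class EmbeddingTable:
    """Character -> vector map with a total lookup (zero OOV fallback)."""

    vectors: dict
    dim: int
    seed: int | None = None
    _oov: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        for ch, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {ch!r} has wrong dimension")
        if self._oov is None:
            self._oov = np.zeros(self.dim)

    @property
    def oov(self) -> np.ndarray:
        return self._oov

    def __contains__(self, ch: str) -> bool:
        return ch in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def lookup(table: EmbeddingTable, ch: str) -> np.ndarray:
    """Stored vector for a seen character, the OOV vector otherwise."""
    return table.vectors.get(ch, table.oov)


def word_embedding(table: EmbeddingTable, word: str) -> np.ndarray:
    """Mean of the word's character vectors (OOV characters included)."""
    if not word:
        raise ValueError("word must be non-empty")
    return np.mean([lookup(table, ch) for ch in word], axis=0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_char_embeddings(
    corpus: Iterable[str],
    risk_lexicon: Mapping | None = None,
    dim: int = 100,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 5,
    min_count: int = 1,
    lr: float = 0.025,
    seed: int = 0,
    lexicon_repeat: int = 3,
) -> EmbeddingTable:
    """Skip-gram with negative sampling over character sequences.

    ``risk_lexicon`` maps each category to its surface forms; every
    surface is appended ``lexicon_repeat`` times as an extra sentence
    (dictionary augmentation).  Negative samples follow the standard
    unigram^0.75 distribution.
    """
    sentences = [list(s) for s in corpus if len(s) > 0]
    if not sentences:
        raise ValueError("corpus must be non-empty")
    if risk_lexicon:
        for surfaces in risk_lexicon.values():
            for surface in surfaces:
                sentences.extend([list(surface)] * lexicon_repeat)

    counts: dict[str, int] = {}
    for sent in sentences:
        for ch in sent:
            counts[ch] = counts.get(ch, 0) + 1
    vocab = sorted(ch for ch, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no character reaches min_count")
    index = {ch: i for i, ch in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    freq = np.array([counts[ch] for ch in vocab], dtype=np.float64) ** 0.75
    noise = freq / freq.sum()

    # enumerate (center, context) pairs once; shuffle per epoch
    centers, contexts = [], []
    for sent in sentences:
        ids = [index[ch] for ch in sent if ch in index]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.intp)
    contexts = np.asarray(contexts, dtype=np.intp)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("corpus has no co-occurring characters")

    batch = 512
    total_steps = max(1, epochs * ((n_pairs + batch - 1) // batch))
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            sel = order[s : s + batch]
            c, o = centers[sel], contexts[sel]
            lr_t = lr * max(1e-4, 1.0 - step / total_steps)
            vc = W_in[c]  # (b, d)
            vo = W_out[o]
            g_pos = _sigmoid(np.einsum("bd,bd->b", vc, vo)) - 1.0  # (b,)
            grad_c = g_pos[:, None] * vo
            neg = rng.choice(V, size=(len(sel), negatives), p=noise)
            vn = W_out[neg]  # (b, k, d)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", vc, vn))  # (b, k)
            grad_c += np.einsum("bk,bkd->bd", g_neg, vn)
            # rows recur many times inside a batch (all gradients are taken
            # at the pre-update weights), so updates are averaged per row
            # rather than summed -- summing diverges for small vocabularies
            d_in = np.zeros_like(W_in)
            np.add.at(d_in, c, grad_c)
            cnt_in = np.bincount(c, minlength=V).clip(min=1)
            W_in -= lr_t * d_in / cnt_in[:, None]
            d_out = np.zeros_like(W_out)
            np.add.at(d_out, o, g_pos[:, None] * vc)
            np.add.at(d_out, neg.reshape(-1),
                      (g_neg[..., None] * vc[:, None, :]).reshape(-1, dim))
            cnt_out = (
                np.bincount(o, minlength=V) + np.bincount(neg.reshape(-1), minlength=V)
            ).clip(min=1)
            W_out -= lr_t * d_out / cnt_out[:, None]
            step += 1

    vectors = {ch: W_in[index[ch]].copy() for ch in vocab}
    return EmbeddingTable(vectors=vectors, dim=dim, seed=seed)


# ---------------------------------------------------------------------------
# word2vec text format
# ---------------------------------------------------------------------------


def save_embeddings(table: EmbeddingTable, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for ch in sorted(table.vectors):
            vals = " ".join(repr(float(x)) for x in table.vectors[ch])
            fh.write(f"{ch} {vals}\n")


def load_embeddings(path) -> EmbeddingTable:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        count, dim = int(header[0]), int(header[1])
        vectors: dict = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if not parts[0]:
                continue
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != count:
        raise ValueError(f"{path}: header promised {count} vectors, found {len(vectors)}")
    return EmbeddingTable(vectors=vectors, dim=dim)
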