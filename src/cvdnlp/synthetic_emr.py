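"""Synthetic EMR corpus generator.

The generator produces character-level documents with the statistical
structure the pipeline assumes: risk-factor mentions drawn from a lexicon
with per-category time-attribute frequencies taken from the published
count table, a cue symbol planted next to each timed mention so the
attribute is learnable from context, and a document-level label produced
by a known linear rule over the (category, attribute) pairs present.

Characters come from an abstract alphabet mapped onto CJK codepoints so
that documents remain ordinary strings.  Everything is driven by a single
``numpy`` generator seeded from the config, so identical configs produce
byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .corpus_io import (
    EmrDocument,
    EntityMention,
    RiskFactorCategory,
    TimeAttribute,
    admissible_attributes,
)

__all__ = [
    "AttributeCountTable",
    "reference_attribute_counts",
    "attribute_total",
    "GeneratorConfig",
    "default_lexicon",
    "default_attribute_weights",
    "default_label_rule",
    "default_split_sizes",
    "generate_corpus",
    "calibrate_intercept",
]

_BASE = 0x4E00
_CUE_OFFSET = 120
_CATEGORY_OFFSET = 200
_CHARS_PER_CATEGORY = 4

_TIMED = (
    TimeAttribute.BEFORE,
    TimeAttribute.DURING,
    TimeAttribute.AFTER,
    TimeAttribute.CONTINUE,
)

CUE_CHARS = {attr: chr(_BASE + _CUE_OFFSET + i) for i, attr in enumerate(_TIMED)}


# ---------------------------------------------------------------------------
# Published attribute-count fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttributeCountTable:
    """Per-category counts of mentions by time attribute.

    ``counts[category]`` maps each timed attribute to its count, or is
    ``None`` for rows where only the total is reliable (the printed row
    for Diabetes cannot be segmented unambiguously, and Age/Gender are
    not broken down by time).  ``totals[category]`` is always present.
    """

    counts: Mapping
    totals: Mapping

    def __post_init__(self):
        for cat, row in self.counts.items():
            if row is not None and sum(row.values()) != self.totals[cat]:
                raise ValueError(f"{cat.code}: counts do not sum to the total")


def reference_attribute_counts() -> AttributeCountTable:
    """Load the published per-attribute mention counts shipped as TSV."""
    text = (
        resources.files("cvdnlp.data").joinpath("attribute_counts.tsv").read_text("utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    assert header[0] == "category"
    counts: dict = {}
    totals: dict = {}
    for line in lines[1:]:
        cells = line.split("\t")
        cat = RiskFactorCategory.from_code(cells[0])
        totals[cat] = int(cells[5])
        if "-" in cells[1:5]:
            counts[cat] = None
        else:
            counts[cat] = {
                attr: int(cells[1 + i]) for i, attr in enumerate(_TIMED)
            }
    return AttributeCountTable(counts=counts, totals=totals)


def attribute_total(table: AttributeCountTable, category: RiskFactorCategory) -> int:
    """Total mention count for a category, recomputed from the per-attribute
    counts whenever they are available."""
    if category not in table.totals:
        raise KeyError(f"unknown category {category!r}")
    row = table.counts[category]
    if row is not None:
        return sum(row.values())
    return table.totals[category]


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


def default_lexicon() -> dict:
    """Three surface forms per category (lengths 2-4), each built from a
    four-character alphabet private to the category so surfaces never
    collide across categories."""
    lex: dict = {}
    for k, cat in enumerate(RiskFactorCategory):
        alphabet = [
            chr(_BASE + _CATEGORY_OFFSET + _CHARS_PER_CATEGORY * k + i)
            for i in range(_CHARS_PER_CATEGORY)
        ]
        surfaces = []
        for j, length in enumerate((2, 3, 4)):
            surfaces.append(
                "".join(alphabet[(j + i) % _CHARS_PER_CATEGORY] for i in range(length))
            )
        lex[cat] = surfaces
    return lex


def default_attribute_weights(
    table: AttributeCountTable | None = None,
) -> dict:
    """Per-category attribute sampling weights proportional to the published
    counts; rows without a reliable breakdown fall back to uniform."""
    if table is None:
        table = reference_attribute_counts()
    weights: dict = {}
    for cat in RiskFactorCategory:
        admissible = admissible_attributes(cat)
        if admissible == (TimeAttribute.NONE,):
            weights[cat] = {TimeAttribute.NONE: 1.0}
            continue
        row = table.counts.get(cat)
        if row is None or sum(row.values()) == 0:
            weights[cat] = {attr: 1.0 for attr in admissible}
        else:
            weights[cat] = {attr: float(row[attr]) for attr in admissible}
    return weights


def default_category_weights(table: AttributeCountTable | None = None) -> dict:
    if table is None:
        table = reference_attribute_counts()
    return {cat: float(table.totals[cat]) for cat in RiskFactorCategory}


def default_label_rule() -> dict:
    """Large positive weights on established modifiable risk factors with
    Continue/Before attributes, plus small varied weights on every other
    admissible pair.  The small weights spread the score distribution over
    many values, which lets the intercept place the positive rate
    precisely; the label stays dominated by the clinical factors."""
    rule = {
        (RiskFactorCategory.HYPERTENSION, TimeAttribute.CONTINUE): 2.0,
        (RiskFactorCategory.HYPERTENSION, TimeAttribute.BEFORE): 1.5,
        (RiskFactorCategory.DIABETES, TimeAttribute.CONTINUE): 2.0,
        (RiskFactorCategory.DIABETES, TimeAttribute.BEFORE): 1.5,
        (RiskFactorCategory.DYSLIPIDEMIA, TimeAttribute.CONTINUE): 1.5,
        (RiskFactorCategory.DYSLIPIDEMIA, TimeAttribute.BEFORE): 1.0,
        (RiskFactorCategory.SMOKING, TimeAttribute.CONTINUE): 1.0,
        (RiskFactorCategory.SMOKING, TimeAttribute.BEFORE): 1.0,
    }
    i = 0
    for cat in RiskFactorCategory:
        for attr in admissible_attributes(cat):
            if (cat, attr) not in rule:
                rule[(cat, attr)] = 0.015 * ((i * 7) % 13 + 1)
                i += 1
    return rule


@dataclass
class GeneratorConfig:
    n_background_chars: int = 60
    background_groups: int = 10
    background_stickiness: float = 0.7
    lexicon: dict = field(default_factory=default_lexicon)
    category_weights: dict = field(default_factory=default_category_weights)
    attribute_weights: dict = field(default_factory=default_attribute_weights)
    doc_length_range: tuple = (60, 120)
    mention_count_range: tuple = (0, 10)  # inclusive bounds
    label_rule: dict = field(default_factory=default_label_rule)
    intercept: float = -1.5000000001  # ~50/50 labels under the default rule
    label_noise: float = 0.05
    split_sizes: tuple = (830, 119, 237)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must be in [0, 1)")
        if any(s <= 0 for s in self.split_sizes):
            raise ValueError("split sizes must be positive")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be non-negative")
        for cat, w in self.category_weights.items():
            if w > 0 and not self.lexicon.get(cat):
                raise ValueError(
                    f"category {cat.code} has positive weight but an empty lexicon"
                )


def default_split_sizes(stage: str) -> tuple:
    """Split sizes used for the two experiment stages."""
    sizes = {
        "tagger": (830, 119, 237),
        "predictor": (461, 66, 132),
    }
    try:
        return sizes[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; expected 'tagger' or 'predictor'")


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _background(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> list:
    """Background filler with weak local co-occurrence: characters are
    grouped, and each step stays in the previous group with fixed
    probability, giving skip-gram something to learn."""
    per_group = cfg.n_background_chars // cfg.background_groups
    out = []
    group = int(rng.integers(cfg.background_groups))
    for _ in range(n):
        if rng.random() >= cfg.background_stickiness:
            group = int(rng.integers(cfg.background_groups))
        idx = group * per_group + int(rng.integers(per_group))
        out.append(chr(_BASE + idx))
    return out


def _weighted_choice(rng: np.random.Generator, items: list, weights: list):
    w = np.asarray(weights, dtype=np.float64)
    return items[int(rng.choice(len(items), p=w / w.sum()))]


def raw_label_score(mentions, rule: Mapping) -> float:
    """Sum of rule weights over the distinct (category, attribute) pairs
    present in a mention list."""
    pairs = {(m.category, m.time_attr) for m in mentions}
    return float(sum(rule.get(p, 0.0) for p in pairs))


def _make_document(rng: np.random.Generator, cfg: GeneratorConfig, doc_id: str) -> EmrDocument:
    cats = [c for c in RiskFactorCategory if cfg.category_weights.get(c, 0.0) > 0]
    cat_w = [cfg.category_weights[c] for c in cats]
    lo, hi = cfg.mention_count_range
    n_mentions = int(rng.integers(lo, hi + 1))

    chosen = []
    for _ in range(n_mentions):
        cat = _weighted_choice(rng, cats, cat_w)
        surface = cfg.lexicon[cat][int(rng.integers(len(cfg.lexicon[cat])))]
        attrs = list(cfg.attribute_weights[cat].keys())
        attr = _weighted_choice(rng, attrs, [cfg.attribute_weights[cat][a] for a in attrs])
        chosen.append((cat, attr, surface))

    # block = surface flanked by its attribute cue char on both sides (no
    # cue for the untimed categories); blocks are laid out left to right
    # with background gaps so mentions never overlap
    blocks = []
    for cat, attr, surface in chosen:
        cue = CUE_CHARS.get(attr)
        blocks.append((cue, cat, attr, surface))
    block_len = sum(len(s) + (2 if cue else 0) for cue, _, _, s in blocks)
    length = int(rng.integers(cfg.doc_length_range[0], cfg.doc_length_range[1] + 1))
    if length < block_len + len(blocks) + 2:
        length = block_len + len(blocks) + int(rng.integers(2, 12))
    free = length - block_len
    gaps = rng.multinomial(free - (len(blocks) + 1), [1.0 / (len(blocks) + 1)] * (len(blocks) + 1))
    gaps = gaps + 1  # every gap at least one background char

    chars: list[str] = []
    mentions: list[EntityMention] = []
    for gap, (cue, cat, attr, surface) in zip(gaps[:-1], blocks):
        chars.extend(_background(rng, int(gap), cfg))
        if cue is not None:
            chars.append(cue)
        start = len(chars)
        chars.extend(surface)
        mentions.append(EntityMention(start, start + len(surface), cat, attr, surface))
        if cue is not None:
            chars.append(cue)
    chars.extend(_background(rng, int(gaps[-1]), cfg))

    score = raw_label_score(mentions, cfg.label_rule) + cfg.intercept
    label = 1 if score > 0 else 0
    if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
        label = 1 - label
    return EmrDocument(doc_id=doc_id, chars="".join(chars), mentions=mentions, cvd_label=label)


def generate_corpus(cfg: GeneratorConfig):
    """Generate (train, dev, test) document lists per ``cfg.split_sizes``."""
    rng = np.random.default_rng(cfg.seed)
    splits = []
    for split_name, size in zip(("train", "dev", "test"), cfg.split_sizes):
        docs = [
            _make_document(rng, cfg, f"{split_name}-{i:05d}") for i in range(size)
        ]
        splits.append(docs)
    return tuple(splits)


def calibrate_intercept(
    cfg: GeneratorConfig, target_positive_rate: float, n_docs: int = 1000
) -> float:
    """Choose an intercept so that about ``target_positive_rate`` of
    generated documents are positive before label noise."""
    if not (0.0 < target_positive_rate < 1.0):
        raise ValueError("target rate must be in (0, 1)")
    probe = replace(cfg, intercept=0.0, label_noise=0.0,
                    split_sizes=(n_docs, 1, 1))
    train, _, _ = generate_corpus(probe)
    scores = np.array([raw_label_score(d.mentions, cfg.label_rule) for d in train])
    # label is positive iff raw + intercept > 0; scores are discrete, so
    # scan both sides of every attained value and keep the best cut
    best, best_err = -float(np.median(scores)), 1.0
    for v in np.unique(scores):
        for cand in (-v - 1e-9, -v + 1e-9):
            err = abs(float(np.mean(scores + cand > 0)) - target_positive_rate)
            if err < best_err:
                best, best_err = cand, err
    return best
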