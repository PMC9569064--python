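"""Document/mention data model, BIO tagging, and the JSONL / CoNLL readers
and writers.

Documents are sequences of characters.  Each risk-factor mention is a
half-open character span (0-based) carrying a category and a time
attribute; per-character tags combine the two, e.g. ``B-HyC`` marks the
first character of a Hypertension mention whose time attribute is
Continue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RiskFactorCategory",
    "TimeAttribute",
    "EntityMention",
    "EmrDocument",
    "TagVocabulary",
    "admissible_attributes",
    "default_attribute_rule",
    "build_tag_vocabulary",
    "to_bio",
    "from_bio",
    "read_documents",
    "write_documents",
    "read_conll",
    "write_conll",
]


class RiskFactorCategory(Enum):
    """The 12 cardiovascular risk-factor categories.

    The value tuple is (code, two-letter tag prefix, description).
    """

    O2 = ("O2", "Ov", "overweight or obesity")
    HYPERTENSION = ("Hypertension", "Hy", "diagnosis or history of hypertension")
    DIABETES = ("Diabetes", "Di", "diagnosis or history of diabetes")
    DYSLIPIDEMIA = ("Dyslipidemia", "Dy", "dyslipidemia or hyperlipidemia")
    CKD = ("CKD", "Ck", "chronic kidney disease")
    ATHEROSIS = ("Atherosis", "At", "atherosclerosis or atherosclerotic plaque")
    OSAS = ("OSAS", "Os", "obstructive sleep apnea syndrome")
    SMOKING = ("Smoking", "Sm", "smoking or history of smoking")
    A2 = ("A2", "Al", "alcohol abuse")
    FHCVD = ("FHCVD", "Fh", "family history of cardiovascular disease")
    AGE = ("Age", "Ag", "patient age")
    GENDER = ("Gender", "Ge", "patient gender")

    @property
    def code(self) -> str:
        return self.value[0]

    @property
    def prefix(self) -> str:
        return self.value[1]

    @property
    def description(self) -> str:
        return self.value[2]

    @classmethod
    def from_code(cls, code: str) -> "RiskFactorCategory":
        for member in cls:
            if member.code == code:
                return member
        raise KeyError(f"unknown risk-factor category {code!r}")


class TimeAttribute(Enum):
    """Temporal relation of a mention to the hospital stay."""

    BEFORE = ("Before", "B")
    DURING = ("During", "D")
    AFTER = ("After", "A")
    CONTINUE = ("Continue", "C")
    NONE = ("None", "N")

    @property
    def code(self) -> str:
        return self.value[0]

    @property
    def letter(self) -> str:
        return self.value[1]

    @classmethod
    def from_code(cls, code: str) -> "TimeAttribute":
        for member in cls:
            if member.code == code:
                return member
        raise KeyError(f"unknown time attribute {code!r}")


_TIMED = (
    TimeAttribute.BEFORE,
    TimeAttribute.DURING,
    TimeAttribute.AFTER,
    TimeAttribute.CONTINUE,
)
_UNTIMED_CATEGORIES = frozenset({RiskFactorCategory.AGE, RiskFactorCategory.GENDER})


def admissible_attributes(category: RiskFactorCategory) -> tuple:
    """Age and Gender carry only None; the other ten categories carry the
    four timed attributes."""
    if category in _UNTIMED_CATEGORIES:
        return (TimeAttribute.NONE,)
    return _TIMED


def default_attribute_rule() -> dict:
    return {cat: admissible_attributes(cat) for cat in RiskFactorCategory}


@dataclass(frozen=True)
class EntityMention:
    """Half-open character span [start, end) with its labels."""

    start: int
    end: int
    category: RiskFactorCategory
    time_attr: TimeAttribute
    surface: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.time_attr not in admissible_attributes(self.category):
            raise ValueError(
                f"time attribute {self.time_attr.code} not admissible for "
                f"category {self.category.code}"
            )
        if len(self.surface) != self.end - self.start:
            raise ValueError("surface length does not match the span")


@dataclass
class EmrDocument:
    doc_id: str
    chars: str
    mentions: list = field(default_factory=list)
    cvd_label: int | None = None  # 1 positive, 0 negative, None unlabeled

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = len(self.chars)
        spans = []
        for m in self.mentions:
            if m.end > n:
                raise ValueError(
                    f"{self.doc_id}: mention span [{m.start}, {m.end}) exceeds "
                    f"document length {n}"
                )
            if self.chars[m.start : m.end] != m.surface:
                raise ValueError(
                    f"{self.doc_id}: mention surface {m.surface!r} does not "
                    f"match text {self.chars[m.start:m.end]!r}"
                )
            spans.append((m.start, m.end))
        spans.sort()
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{self.doc_id}: overlapping mention spans")
        if self.cvd_label not in (None, 0, 1):
            raise ValueError(f"{self.doc_id}: cvd_label must be 0, 1 or None")


class TagVocabulary:
    """Ordered BIO tag set over (category, time-attribute) pairs.

    Index 0 is always ``O``; each admissible pair contributes a ``B-`` and
    an ``I-`` tag, so the size is ``2 * sum(|admissible attrs|) + 1``.
    """

    def __init__(self, tags: Sequence[str], pairs: Mapping[str, tuple]):
        self.tags = list(tags)
        self.index = {t: i for i, t in enumerate(self.tags)}
        if len(self.index) != len(self.tags):
            raise ValueError("duplicate tags in vocabulary")
        self._pair_of_suffix = dict(pairs)

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self.index

    def tag_of(self, prefix: str, category: RiskFactorCategory,
               attr: TimeAttribute) -> str:
        tag = f"{prefix}-{category.prefix}{attr.letter}"
        if tag not in self.index:
            raise KeyError(f"tag {tag} not in vocabulary")
        return tag

    def parse(self, tag: str):
        """Split a tag into (prefix, category, attribute); O -> (O, None, None)."""
        if tag == "O":
            return "O", None, None
        prefix, _, suffix = tag.partition("-")
        if prefix not in ("B", "I") or suffix not in self._pair_of_suffix:
            raise KeyError(f"malformed tag {tag!r}")
        cat, attr = self._pair_of_suffix[suffix]
        return prefix, cat, attr


def build_tag_vocabulary(
    categories: Iterable[RiskFactorCategory] = tuple(RiskFactorCategory),
    attribute_rule: Mapping | None = None,
) -> TagVocabulary:
    """Deterministic BIO tag inventory: O first, then B/I pairs in
    category-then-attribute order."""
    categories = list(categories)
    if not categories:
        raise ValueError("categories must be non-empty")
    seen: set[str] = set()
    for cat in categories:
        if cat.code in seen:
            raise ValueError(f"duplicate category {cat.code!r}")
        seen.add(cat.code)
    if attribute_rule is None:
        attribute_rule = default_attribute_rule()
    tags = ["O"]
    pairs: dict[str, tuple] = {}
    for cat in categories:
        for attr in attribute_rule[cat]:
            suffix = f"{cat.prefix}{attr.letter}"
            pairs[suffix] = (cat, attr)
            tags.append(f"B-{suffix}")
            tags.append(f"I-{suffix}")
    return TagVocabulary(tags, pairs)


def to_bio(doc: EmrDocument, vocab: TagVocabulary) -> list:
    """Per-character tag sequence: B at mention starts, I inside, O elsewhere."""
    doc.validate()
    tags = ["O"] * len(doc.chars)
    for m in doc.mentions:
        tags[m.start] = vocab.tag_of("B", m.category, m.time_attr)
        inside = vocab.tag_of("I", m.category, m.time_attr)
        for i in range(m.start + 1, m.end):
            tags[i] = inside
    return tags


def from_bio(chars: str, tags: Sequence[str], vocab: TagVocabulary) -> list:
    """Decode tags into mentions.

    Ill-formed sequences are repaired, never rejected: an I tag that does
    not continue a compatible run is promoted to B (IOB2 repair).
    """
    if len(chars) != len(tags):
        raise ValueError("chars and tags must have equal length")
    mentions: list[EntityMention] = []
    run_start = None
    run_pair = None

    def close(end: int) -> None:
        nonlocal run_start, run_pair
        if run_start is not None:
            cat, attr = run_pair
            mentions.append(
                EntityMention(run_start, end, cat, attr, chars[run_start:end])
            )
            run_start, run_pair = None, None

    for i, tag in enumerate(tags):
        prefix, cat, attr = vocab.parse(tag)
        if prefix == "O":
            close(i)
        elif prefix == "B":
            close(i)
            run_start, run_pair = i, (cat, attr)
        else:  # I
            if run_pair == (cat, attr):
                continue
            close(i)  # IOB2 repair: orphan I starts a new run
            run_start, run_pair = i, (cat, attr)
    close(len(tags))
    return mentions


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _doc_to_json(doc: EmrDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "chars": doc.chars,
        "mentions": [
            {
                "start": m.start,
                "end": m.end,
                "category": m.category.code,
                "time_attr": m.time_attr.code,
                "surface": m.surface,
            }
            for m in doc.mentions
        ],
        "cvd_label": doc.cvd_label,
    }


def _doc_from_json(obj: dict) -> EmrDocument:
    mentions = [
        EntityMention(
            start=m["start"],
            end=m["end"],
            category=RiskFactorCategory.from_code(m["category"]),
            time_attr=TimeAttribute.from_code(m["time_attr"]),
            surface=m["surface"],
        )
        for m in obj.get("mentions", [])
    ]
    return EmrDocument(
        doc_id=obj["doc_id"],
        chars=obj["chars"],
        mentions=mentions,
        cvd_label=obj.get("cvd_label"),
    )


def write_documents(docs: Iterable[EmrDocument], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_json(doc), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_documents(path) -> list:
    path = Path(path)
    docs = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                docs.append(_doc_from_json(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed document line: {exc}")
    return docs


def write_conll(tagged: Iterable[tuple], path) -> None:
    """Write (chars, tags) pairs: one character and one tag per line,
    tab-separated, blank line between documents."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for chars, tags in tagged:
            if len(chars) != len(tags):
                raise ValueError("chars/tags length mismatch")
            for ch, tag in zip(chars, tags):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


def read_conll(path, vocab: TagVocabulary) -> list:
    """Read the tab-separated dialect back into (chars, tags) pairs."""
    path = Path(path)
    out = []
    chars: list[str] = []
    tags: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                if chars:
                    out.append(("".join(chars), tags))
                    chars, tags = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2 or len(parts[0]) != 1:
                raise ValueError(f"{path}:{lineno}: malformed CoNLL line {line!r}")
            ch, tag = parts
            if tag not in vocab:
                raise ValueError(f"{path}:{lineno}: unknown tag {tag!r}")
            chars.append(ch)
            tags.append(tag)
    if chars:
        out.append(("".join(chars), tags))
    return out
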