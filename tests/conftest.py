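import numpy as np
import pytest

from cvdnlp.corpus_io import (
    EmrDocument,
    EntityMention,
    RiskFactorCategory,
    TimeAttribute,
    build_tag_vocabulary,
)
from cvdnlp.synthetic_emr import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def full_vocab():
    return build_tag_vocabulary()


@pytest.fixture
def small_doc():
    # 5 characters, one Hypertension/Continue mention on [1, 4)
    return EmrDocument(
        doc_id="d0",
        chars="abcde",
        mentions=[
            EntityMention(1, 4, RiskFactorCategory.HYPERTENSION,
                          TimeAttribute.CONTINUE, "bcd")
        ],
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small deterministic generated corpus shared across tests."""
    cfg = GeneratorConfig(seed=42, split_sizes=(30, 8, 8),
                          doc_length_range=(30, 60))
    return generate_corpus(cfg)


def random_document(rng: np.random.Generator, length: int = 20) -> EmrDocument:
    """Uniformly random valid document for round-trip properties."""
    chars = "".join(chr(ord("a") + rng.integers(26)) for _ in range(length))
    mentions = []
    pos = 0
    while pos < length - 2:
        if rng.random() < 0.3:
            span = int(rng.integers(1, min(4, length - pos) + 1))
            cat = list(RiskFactorCategory)[rng.integers(12)]
            from cvdnlp.corpus_io import admissible_attributes

            attrs = admissible_attributes(cat)
            attr = attrs[rng.integers(len(attrs))]
            mentions.append(
                EntityMention(pos, pos + span, cat, attr, chars[pos : pos + span])
            )
            pos += span + 1  # keep mentions separated
        else:
            pos += 1
    return EmrDocument(doc_id=f"r{rng.integers(1 << 30)}", chars=chars,
                       mentions=mentions)
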