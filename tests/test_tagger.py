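import numpy as np
import pytest

from cvdnlp import crf
from cvdnlp.corpus_io import (
    EmrDocument,
    build_tag_vocabulary,
    from_bio,
    to_bio,
)
from cvdnlp.nn import Tensor
from cvdnlp.synthetic_emr import GeneratorConfig, generate_corpus
from cvdnlp.tagger import (
    BiLstmCrfTagger,
    TaggerConfig,
    crf_nll,
    emission_scores,
    extract_risk_factors,
    extract_risk_factors_corpus,
    train_tagger,
)

TINY = dict(embedding_dim=8, hidden=6, lr=0.1, batch_size=4, epochs=2,
            dropout=0.0)


@pytest.fixture
def tiny_model():
    cfg = TaggerConfig(seed=0, **TINY)
    return BiLstmCrfTagger(cfg, char_vocab=list("abcdefgh"))


class TestEmissionScores:
    def test_zero_hidden_gives_zero_row(self):
        w = np.ones((4, 3))
        np.testing.assert_array_equal(emission_scores(np.zeros((2, 4)), w),
                                      np.zeros((2, 3)))

    def test_entries_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        scores = emission_scores(rng.normal(size=(5, 6)),
                                 rng.normal(size=(6, 4)))
        assert np.all(scores > -1.0) and np.all(scores < 1.0)

    def test_hand_computed_two_by_two(self):
        # h = [[1, 0], [0, 2]], W = [[0.5, -1], [0.25, 0.5]]
        # hW = [[0.5, -1], [0.5, 1]]; scores = tanh of that
        h = np.array([[1.0, 0.0], [0.0, 2.0]])
        w = np.array([[0.5, -1.0], [0.25, 0.5]])
        expected = np.tanh(np.array([[0.5, -1.0], [0.5, 1.0]]))
        np.testing.assert_allclose(emission_scores(h, w), expected, atol=1e-12)


class TestEncode:
    def test_single_character(self, tiny_model):
        out = tiny_model.encode("a")
        assert out.shape == (1, 2 * tiny_model.config.hidden)

    def test_shape_for_random_lengths(self, tiny_model):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(1, 12))
            assert tiny_model.encode("a" * n).shape == (n, 12)

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode("")

    def test_reversal_swaps_directional_halves(self, tiny_model):
        """With the backward cell tied to the forward cell, reversing the
        input reverses the time axis and swaps the two halves."""
        m = tiny_model
        for src, dst in zip(m.encoder.fwd.parameters(), m.encoder.bwd.parameters()):
            dst.data = src.data.copy()
        h = m.config.hidden
        fwd = m.encode("abcdef")
        rev = m.encode("fedcba")
        np.testing.assert_allclose(fwd[:, :h], rev[::-1, h:], atol=1e-12)
        np.testing.assert_allclose(fwd[:, h:], rev[::-1, :h], atol=1e-12)


class TestCrfNllNode:
    def test_matches_plain_function_and_backprops(self):
        rng = np.random.default_rng(3)
        B, L, K = 2, 4, 3
        em = Tensor(rng.normal(size=(B, L, K)), requires_grad=True)
        T = Tensor(rng.normal(size=(K + 2, K + 2)), requires_grad=True)
        tags = rng.integers(0, K, size=(B, L))
        mask = np.ones((B, L))
        loss = crf_nll(em, T, tags, mask)
        ref, d_em, d_T = crf.crf_nll_batch(em.data, T.data, tags, mask)
        assert float(loss.data) == pytest.approx(ref)
        loss.backward()
        np.testing.assert_allclose(em.grad, d_em, atol=1e-12)
        np.testing.assert_allclose(T.grad, d_T, atol=1e-12)

    def test_network_gradient_matches_finite_differences(self):
        """End-to-end CRF loss gradient through the encoder weights."""
        cfg = TaggerConfig(seed=1, **TINY)
        vocab = build_tag_vocabulary()
        model = BiLstmCrfTagger(cfg, char_vocab=list("abc"))
        rng = np.random.default_rng(0)
        ids, mask = model._batch_arrays([model._encode_ids("abca"),
                                         model._encode_ids("cb")])
        tags = rng.integers(0, len(vocab), size=ids.shape)

        def build():
            emissions = model._emissions(ids, mask, train=False)
            return crf_nll(emissions, model.transitions, tags, mask)

        loss = build()
        loss.backward()
        eps = 1e-5
        for tensor in (model.encoder.fwd.Wx, model.w_e, model.w_s,
                       model.embedding):
            grad = tensor.grad
            flat = tensor.data.ravel()
            for k in rng.choice(flat.size, size=5, replace=False):
                old = flat[k]
                flat[k] = old + eps
                f1 = float(build().data)
                flat[k] = old - eps
                f2 = float(build().data)
                flat[k] = old
                fd = (f1 - f2) / (2 * eps)
                g = grad.ravel()[k]
                assert abs(fd - g) <= 1e-4 * max(1.0, abs(fd)), (fd, g)


class TestExtraction:
    def test_zeroed_scorer_predicts_all_o(self, tiny_model):
        """Zero emissions and near-zero transitions tie every path, and the
        lowest-index tie-break is the all-O path, giving no mentions."""
        tiny_model.w_s.data[:] = 0.0
        tiny_model.transitions.data[:] = 0.0
        doc = EmrDocument(doc_id="x", chars="abcabc", mentions=[])
        assert tiny_model.decode("abcabc") == ["O"] * 6
        assert extract_risk_factors(doc, tiny_model) == []

    def test_forced_emissions_reproduce_gold(self, small_doc, full_vocab):
        """Emissions +10 on the gold tag and -10 elsewhere make Viterbi
        return the gold path, which decodes back to the gold mentions."""
        gold_tags = to_bio(small_doc, full_vocab)
        K = len(full_vocab)
        em = np.full((len(gold_tags), K), -10.0)
        for i, t in enumerate(gold_tags):
            em[i, full_vocab.index[t]] = 10.0
        path = crf.viterbi(em, np.zeros((K + 2, K + 2)))
        decoded = [full_vocab.tags[i] for i in path.tags]
        assert decoded == gold_tags
        assert from_bio(small_doc.chars, decoded, full_vocab) == small_doc.mentions

    def test_extraction_deterministic(self, tiny_model):
        doc = EmrDocument(doc_id="x", chars="abcdefgh", mentions=[])
        first = extract_risk_factors(doc, tiny_model)
        assert all(extract_risk_factors(doc, tiny_model) == first for _ in range(3))

    def test_batch_matches_single(self, tiny_model):
        docs = [EmrDocument(doc_id=str(i), chars="abcdefg"[: i + 2], mentions=[])
                for i in range(4)]
        batch = extract_risk_factors_corpus(docs, tiny_model)
        single = [extract_risk_factors(d, tiny_model) for d in docs]
        assert batch == single


class TestTraining:
    @pytest.fixture(scope="class")
    def mini_corpus(self):
        cfg = GeneratorConfig(seed=13, split_sizes=(10, 4, 4),
                              doc_length_range=(20, 30),
                              mention_count_range=(1, 3))
        return generate_corpus(cfg)

    def test_loss_decreases_over_epochs(self, mini_corpus):
        train, dev, _ = mini_corpus
        cfg = TaggerConfig(seed=0, embedding_dim=8, hidden=8, lr=0.1,
                           batch_size=4, epochs=10, dropout=0.0)
        _, history = train_tagger(train, dev, cfg)
        assert history[-1]["loss"] < history[0]["loss"]

    def test_checkpoint_round_trip(self, mini_corpus, tmp_path):
        train, dev, _ = mini_corpus
        cfg = TaggerConfig(seed=0, embedding_dim=8, hidden=8, lr=0.1,
                           batch_size=4, epochs=1, dropout=0.0)
        model, _ = train_tagger(train, dev, cfg)
        path = tmp_path / "tagger.json"
        model.save(path)
        clone = BiLstmCrfTagger.load(path)
        for doc in dev:
            assert clone.decode(doc.chars) == model.decode(doc.chars)

    def test_unannotated_training_doc_rejected(self, mini_corpus):
        train, dev, _ = mini_corpus
        broken = EmrDocument(doc_id="b", chars="abc", mentions=[])
        broken.mentions = None
        cfg = TaggerConfig(seed=0, **TINY)
        with pytest.raises(ValueError, match="gold"):
            train_tagger([broken], dev, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TaggerConfig(dropout=1.5)
        with pytest.raises(ValueError):
            TaggerConfig(hidden=0)
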