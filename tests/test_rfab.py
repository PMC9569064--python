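import numpy as np
import pytest
from scipy.special import softmax as sp_softmax

from cvdnlp.corpus_io import (
    EmrDocument,
    EntityMention,
    RiskFactorCategory,
    TimeAttribute,
)
from cvdnlp.rfab import (
    AttentionRecord,
    RfabConfig,
    RfabModel,
    attend,
    cross_entropy,
    predict_document,
    train_rfab,
    variant_flags,
)
from cvdnlp.synthetic_emr import GeneratorConfig, generate_corpus

TINY = dict(embedding_dim=8, hidden=6, lr=0.05, batch_size=4, dropout=0.0,
            epochs=2)


def make_model(seed=0, **overrides):
    cfg = RfabConfig(seed=seed, **{**TINY, **overrides})
    return RfabModel(cfg, char_vocab=list("abcdefgh"))


def doc_with_mentions(chars="abcdefgh", spans=((1, 3), (4, 6)), label=1):
    mentions = [
        EntityMention(s, e, RiskFactorCategory.HYPERTENSION,
                      TimeAttribute.CONTINUE, chars[s:e])
        for s, e in spans
    ]
    return EmrDocument(doc_id="d", chars=chars, mentions=mentions, cvd_label=label)


class TestAttend:
    def test_single_position(self):
        context = np.array([[1.0, 2.0, 3.0]])
        weights, fused = attend(context, np.array([0.5, 0.5, 0.5]))
        np.testing.assert_allclose(weights, [1.0])
        np.testing.assert_allclose(fused, context[0])

    def test_equal_dot_products_uniform(self):
        context = np.ones((5, 3))
        weights, _ = attend(context, np.array([1.0, -1.0, 2.0]))
        np.testing.assert_allclose(weights, np.full(5, 0.2), atol=1e-12)

    def test_matches_independent_softmax(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            context = rng.normal(size=(4, 3))
            query = rng.normal(size=3)
            weights, fused = attend(context, query)
            expected_w = sp_softmax(context @ query)
            np.testing.assert_allclose(weights, expected_w, atol=1e-8)
            np.testing.assert_allclose(fused, expected_w @ context, atol=1e-8)

    def test_rows_nonnegative_and_sum_to_one(self):
        rng = np.random.default_rng(1)
        weights, _ = attend(rng.normal(size=(7, 4)) * 5, rng.normal(size=4))
        assert weights.min() >= 0
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestForwardAttention:
    def test_model_alpha_matches_numpy_recomputation(self):
        """Dual route: the autodiff attention weights must equal a plain
        numpy softmax over dot products of the projected factor vectors
        with the context encodings."""
        model = make_model()
        doc = doc_with_mentions()
        _, attention, _ = model.forward([doc])
        weights, _ = attention[0]

        ids = model._char_ids(doc.chars)
        x = model.embedding.data[ids][None, :, :]
        from cvdnlp.nn import Tensor

        context, _ = model.context_encoder(Tensor(x), np.ones((1, len(ids))))
        y = context.data[0]
        factors = model.factor_input(doc.mentions)
        for i, f in enumerate(factors):
            q = f.data @ model.projection.data
            np.testing.assert_allclose(weights[i], sp_softmax(y @ q), atol=1e-8)

    def test_alpha_rows_sum_to_one(self):
        model = make_model()
        outputs, records = model.predict([doc_with_mentions()])
        assert len(records[0]) == 2
        for rec in records[0]:
            assert rec.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert rec.weights.min() >= 0

    def test_single_char_doc_alpha_is_one(self):
        model = make_model()
        doc = EmrDocument(
            doc_id="m1", chars="a",
            mentions=[EntityMention(0, 1, RiskFactorCategory.SMOKING,
                                    TimeAttribute.BEFORE, "a")],
            cvd_label=0,
        )
        _, records = model.predict([doc])
        np.testing.assert_allclose(records[0][0].weights, [1.0])

    def test_no_attention_variant_changes_outputs_and_drops_records(self):
        with_att = make_model(use_attention=True)
        without = make_model(use_attention=False)
        doc = doc_with_mentions()
        probs_att = with_att.predict([doc])[0][0].probabilities
        probs_no, records = without.predict([doc])
        assert records[0] == []
        assert not np.allclose(probs_att, probs_no[0].probabilities)


class TestPredictionHead:
    def test_argmax_invariant_under_softmax(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            o = rng.normal(size=4)
            assert int(np.argmax(sp_softmax(o))) == int(np.argmax(o))

    def test_zero_representation_gives_uniform_probabilities(self):
        # Z = 0 -> O = sigmoid(0) = (0.5, 0.5) -> softmax is uniform
        o = 1.0 / (1.0 + np.exp(-np.zeros(2)))
        np.testing.assert_allclose(sp_softmax(o), [0.5, 0.5])

    def test_hand_computed_head(self):
        # Z W = (0.3, -0.1); sigmoid -> (0.574442516811659, 0.47502081252106)
        # softmax of that -> (0.524815756592, 0.475184243408)
        z = np.array([0.3, -0.1])
        s = 1.0 / (1.0 + np.exp(-z))
        np.testing.assert_allclose(
            s, [0.574442516811659, 0.47502081252106], atol=1e-12
        )
        # exp(s_i) / sum_j exp(s_j), frozen at full precision
        expected = np.exp(s) / np.exp(s).sum()
        np.testing.assert_allclose(
            expected, [0.5248349723056486, 0.47516502769435154], atol=1e-12
        )
        np.testing.assert_allclose(sp_softmax(s), expected, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        model = make_model()
        outputs, _ = model.predict([doc_with_mentions()])
        assert outputs[0].probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert outputs[0].label in (0, 1)


class TestLoss:
    def test_confident_correct_prediction_loss_near_zero(self):
        dists = [[1.0 - 1e-12, 1e-12]]
        assert cross_entropy(dists, [0]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_gives_log_two(self):
        assert cross_entropy([[0.5, 0.5]] * 4, [0, 1, 0, 1]) == pytest.approx(
            np.log(2.0)
        )

    def test_matches_one_hot_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            raw = rng.random((6, 2)) + 1e-3
            dists = raw / raw.sum(axis=1, keepdims=True)
            gold = rng.integers(0, 2, size=6)
            one_hot = np.eye(2)[gold]
            oracle = float(np.mean(-np.sum(one_hot * np.log(dists), axis=1)))
            assert cross_entropy(dists, gold) == pytest.approx(oracle, abs=1e-12)

    def test_batch_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([[0.5, 0.5]], [0, 1])


class TestFactorInput:
    def test_without_labels_is_plain_surface_mean(self):
        model = make_model(use_labels=False)
        doc = doc_with_mentions()
        vectors = model.factor_input(doc.mentions)
        for m, v in zip(doc.mentions, vectors):
            ids = model._char_ids(m.surface)
            np.testing.assert_allclose(
                v.data, model.embedding.data[ids].mean(axis=0), atol=1e-12
            )

    def test_same_mentions_identical_vectors(self):
        model = make_model()
        doc = doc_with_mentions()
        v1 = [v.data.copy() for v in model.factor_input(doc.mentions)]
        v2 = [v.data.copy() for v in model.factor_input(doc.mentions)]
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a, b)

    def test_labels_shift_vectors(self):
        plain = make_model(use_labels=False)
        labelled = make_model(use_labels=True)
        labelled.embedding.data = plain.embedding.data.copy()
        doc = doc_with_mentions()
        v_plain = plain.factor_input(doc.mentions)[0].data
        v_lab = labelled.factor_input(doc.mentions)[0].data
        assert not np.allclose(v_plain, v_lab)

    def test_empty_mentions_use_placeholder(self):
        model = make_model()
        vectors = model.factor_input([])
        assert len(vectors) == 1
        np.testing.assert_array_equal(vectors[0].data, model.no_factor.data)

    def test_document_order(self):
        model = make_model()
        doc = doc_with_mentions(spans=((4, 6), (1, 3)))
        vectors = model.factor_input(doc.mentions)
        first = model.factor_input(
            [m for m in doc.mentions if m.start == 1]
        )[0]
        np.testing.assert_array_equal(vectors[0].data, first.data)


class TestEncodeContext:
    def test_single_char_one_row(self):
        model = make_model()
        from cvdnlp.nn import Tensor

        x = Tensor(np.zeros((1, 1, 8)))
        out, _ = model.context_encoder(x, np.ones((1, 1)))
        assert out.shape == (1, 1, 12)

    def test_zero_recurrent_weights_single_step_hand_formula(self):
        """With zero recurrent weights at the first step, the output is an
        explicit function of the input projection alone."""
        model = make_model()
        cell = model.context_encoder.fwd
        cell.Wh.data[:] = 0.0
        from cvdnlp.nn import Tensor

        x = np.random.default_rng(0).normal(size=(1, 1, 8))
        out, _ = model.context_encoder(Tensor(x), np.ones((1, 1)))
        z = x[0, 0] @ cell.Wx.data + cell.b.data
        H = cell.h
        sig = lambda v: 1 / (1 + np.exp(-v))
        c = sig(z[:H]) * np.tanh(z[2 * H : 3 * H])
        h = sig(z[3 * H :]) * np.tanh(c)
        np.testing.assert_allclose(out.data[0, 0, :H], h, atol=1e-12)

    def test_empty_sequence_rejected(self):
        model = make_model()
        doc = EmrDocument(doc_id="e", chars="", mentions=[], cvd_label=0)
        with pytest.raises(ValueError):
            model.forward([doc])

    def test_factor_encoder_init_state_matters(self):
        """Feeding a different initial state must change the output when
        recurrent weights are nonzero."""
        model = make_model()
        doc = doc_with_mentions()
        log_probs, _, z1 = model.forward([doc])
        # perturb the context encoder so its final states differ
        model.context_encoder.fwd.b.data += 0.5
        _, _, z2 = model.forward([doc])
        assert not np.allclose(z1.data, z2.data)


class TestVariants:
    def test_variant_flags(self):
        assert variant_flags("with-labels") == (True, True)
        assert variant_flags("no-labels") == (True, False)
        assert variant_flags("no-att") == (False, True)
        assert variant_flags("raw") == (False, False)
        with pytest.raises(KeyError):
            variant_flags("bogus")

    def test_parameter_count_is_function_of_config(self):
        counts = [
            sum(p.data.size for p in make_model(seed=s).parameters())
            for s in (0, 1, 2)
        ]
        assert counts[0] == counts[1] == counts[2]
        # regression: D=8, h=6, V=9 chars (incl. <unk>)
        # embed 9*8 + proj 8*12 + no_factor 8 + cat 12*8 + attr 5*8
        # + 2 BiLSTMs (2 cells each: 8*24 + 6*24 + 24 / 12*24+6*24+24)
        # + w_out 12*2
        expected = (
            9 * 8 + 8 * 12 + 8 + 12 * 8 + 5 * 8
            + 2 * (8 * 24 + 6 * 24 + 24)
            + 2 * (12 * 24 + 6 * 24 + 24)
            + 12 * 2
        )
        assert counts[0] == expected


class TestTraining:
    @pytest.fixture(scope="class")
    def mini_corpus(self):
        cfg = GeneratorConfig(seed=21, split_sizes=(30, 8, 8),
                              doc_length_range=(20, 40))
        return generate_corpus(cfg)

    def test_loss_decreases(self, mini_corpus):
        train, dev, _ = mini_corpus
        cfg = RfabConfig(seed=0, embedding_dim=8, hidden=8, lr=0.05,
                         batch_size=4, dropout=0.0, epochs=5)
        _, history = train_rfab(train, dev, cfg)
        assert history[4]["loss"] < history[0]["loss"]

    def test_unlabeled_training_doc_rejected(self, mini_corpus):
        _, dev, _ = mini_corpus
        doc = EmrDocument(doc_id="u", chars="abc", mentions=[], cvd_label=None)
        with pytest.raises(ValueError, match="label"):
            train_rfab([doc], dev, RfabConfig(seed=0, **TINY))

    def test_checkpoint_round_trip(self, mini_corpus, tmp_path):
        train, dev, _ = mini_corpus
        cfg = RfabConfig(seed=0, embedding_dim=8, hidden=8, lr=0.05,
                         batch_size=4, dropout=0.0, epochs=1)
        model, _ = train_rfab(train, dev, cfg)
        model.save(tmp_path / "rfab.json")
        clone = RfabModel.load(tmp_path / "rfab.json")
        a, _ = model.predict(dev)
        b, _ = clone.predict(dev)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.probabilities, y.probabilities)

    def test_predict_document_two_stage(self, mini_corpus):
        from cvdnlp.tagger import BiLstmCrfTagger, TaggerConfig

        train, dev, _ = mini_corpus
        tagger = BiLstmCrfTagger(
            TaggerConfig(seed=0, embedding_dim=8, hidden=6, lr=0.1,
                         batch_size=4, epochs=1, dropout=0.0),
            char_vocab=sorted({c for d in train for c in d.chars}),
        )
        rfab = RfabModel(
            RfabConfig(seed=0, **TINY),
            char_vocab=sorted({c for d in train for c in d.chars}),
        )
        out1, rec1 = predict_document(train[0], tagger, rfab)
        out2, rec2 = predict_document(train[0], tagger, rfab)
        np.testing.assert_array_equal(out1.probabilities, out2.probabilities)
        assert len(rec1) == len(rec2)
        for r1, r2 in zip(rec1, rec2):
            np.testing.assert_array_equal(r1.weights, r2.weights)
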