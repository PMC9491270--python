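"""Encoding, word2vec, classifier construction and training."""

from __future__ import annotations

import numpy as np
import pytest

from deplex.features import FeatureMatrix, Vocabulary, encode_posts
from deplex.models import (
    ModelConfig,
    TinyRandomEncoder,
    build_classifier,
    embedding_matrix,
    load_model,
    predict,
    save_model,
    train_classifier,
    train_word_embeddings,
)


@pytest.fixture
def vocab():
    return Vocabulary([f"tok{i}" for i in range(30)])


def _separable_fm(n=32, L=8, seed=0, vocab_size=32):
    """Positive rows contain token index vocab_size-1, negatives never do."""
    rng = np.random.default_rng(seed)
    X = rng.integers(2, vocab_size - 1, size=(n, L))
    y = np.arange(n) % 2
    X[y == 1, 0] = vocab_size - 1
    return FeatureMatrix(X, y, vocab_size=vocab_size)


class TestModelConfig:
    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelConfig(family="gru")

    def test_family_defaults(self):
        cnn = ModelConfig.for_family("cnn")
        assert (cnn.embed_dim, cnn.loss, cnn.optimizer, cnn.fc_layers) == (
            128, "binary_cross_entropy", "adam", 2)
        head = ModelConfig.for_family("transformer_head")
        assert (head.embed_dim, head.loss, head.optimizer, head.fc_layers) == (
            768, "cross_entropy", "adamw", 1)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=0)


class TestEncodePosts:
    def test_short_post_right_padded(self, vocab):
        fm = encode_posts([["tok1", "tok2"]], vocab, max_len=6)
        row = fm.X[0]
        assert row[0] != 0 and row[1] != 0 and np.all(row[2:] == 0)

    def test_long_post_truncated_at_tail(self, vocab):
        toks = [f"tok{i}" for i in range(20)]
        fm = encode_posts([toks], vocab, max_len=6)
        assert fm.X.shape == (1, 6)
        assert vocab.decode(fm.X[0]) == toks[:6]

    def test_round_trip_decode(self, vocab):
        toks = ["tok3", "tok7", "tok7", "tok1"]
        fm = encode_posts([toks], vocab, max_len=10)
        assert vocab.decode(fm.X[0]) == toks

    def test_unknown_tokens_map_to_unk_index(self, vocab):
        fm = encode_posts([["nope", "tok1"]], vocab, max_len=4)
        assert fm.X[0, 0] == vocab.unk_index

    def test_boundary_markers_bracket_sequence(self):
        v = Vocabulary(["a", "b"], boundaries=True)
        fm = encode_posts([["a", "b"]], v, max_len=6)
        assert fm.X[0, 0] == v.bos_index and fm.X[0, 3] == v.eos_index
        assert fm.boundary_indices == (v.bos_index, v.eos_index)


class TestWord2Vec:
    def test_dimension_and_reproducibility(self):
        corpus = [["a", "b", "c"], ["a", "c", "d"]] * 5
        w2v = train_word_embeddings(corpus, dim=16, seed=3, epochs=1)
        assert all(v.shape == (16,) for v in w2v.values())
        again = train_word_embeddings(corpus, dim=16, seed=3, epochs=1)
        assert all(np.array_equal(w2v[k], again[k]) for k in w2v)

    def test_shared_context_tokens_more_similar(self):
        # "x" and "y" appear in identical contexts; "z" lives elsewhere
        rng = np.random.default_rng(0)
        corpus = []
        for _ in range(300):
            ctx = [f"c{rng.integers(3)}", "mid", f"c{rng.integers(3)}"]
            corpus.append([ctx[0], "x" if rng.random() < 0.5 else "y", ctx[2]])
            corpus.append([f"q{rng.integers(3)}", "z", f"q{rng.integers(3)}"])
        w2v = train_word_embeddings(corpus, dim=24, seed=1, epochs=4)

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        assert cos(w2v["x"], w2v["y"]) > cos(w2v["x"], w2v["z"])

    def test_tiny_corpus_falls_back_to_random(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            w2v = train_word_embeddings([["solo"]], dim=8, seed=0)
        assert set(w2v) == {"solo"} and "fallback" in caplog.text

    def test_embedding_matrix_alignment(self, vocab):
        w2v = {"tok1": np.full(4, 0.25, dtype=np.float32)}
        table = embedding_matrix(w2v, vocab, dim=4, seed=0)
        assert np.allclose(table[vocab.index("tok1")], 0.25)
        assert np.all(table[vocab.pad_index] == 0)


class TestBuildClassifier:
    def test_cnn_architecture_description(self):
        cfg = ModelConfig.for_family("cnn")
        clf = build_classifier(cfg, vocab_size=50)
        d = clf.describe()
        assert d["layers"] == ["embedding", "conv1d", "dropout", "max_pool", "fc", "fc", "sigmoid"]
        assert d["conv"]["filters"] == 128 and d["conv"]["kernel_size"] == 4
        assert d["conv"]["n_weights"] == 128 * 4 * 128 and d["conv"]["n_biases"] == 128
        assert d["pool_size"] == 128
        assert d["fc_shapes"] == [(128, 64), (64, 1)]

    def test_bilstm_architecture_description(self):
        clf = build_classifier(ModelConfig.for_family("bilstm"), vocab_size=50)
        d = clf.describe()
        assert d["lstm"] == {"units_per_direction": 64, "bidirectional": True}
        assert clf.forward_cell.Wx.shape == (128, 4 * 64)
        assert clf.backward_cell.Wh.shape == (64, 4 * 64)

    def test_same_seed_builds_identical_parameters(self):
        cfg = ModelConfig.for_family("cnn", seed=11)
        a = build_classifier(cfg, vocab_size=40)
        b = build_classifier(cfg, vocab_size=40)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.data, pb.data)


class TestTrainClassifier:
    def test_separable_batch_loss_decreases(self):
        fm = _separable_fm()
        cfg = ModelConfig.for_family("cnn", max_len=8, epochs=5, seed=1, dropout_rate=0.0)
        trained = train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg)
        losses = trained.history["train_loss"]
        assert len(losses) == 5
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_zero_epochs_leaves_parameters_unchanged(self):
        fm = _separable_fm()
        cfg = ModelConfig.for_family("cnn", max_len=8, epochs=0, seed=1)
        clf = build_classifier(cfg, fm.vocab_size)
        before = [p.data.copy() for p in clf.params()]
        train_classifier(clf, fm, None, cfg)
        assert all(np.array_equal(b, p.data) for b, p in zip(before, clf.params()))

    def test_single_class_labels_rejected(self):
        fm = _separable_fm()
        fm.y[:] = 1
        cfg = ModelConfig.for_family("cnn", max_len=8)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg)

    def test_empty_split_rejected(self):
        cfg = ModelConfig.for_family("cnn", max_len=8)
        fm = FeatureMatrix(np.zeros((0, 8)), np.zeros(0), vocab_size=10)
        with pytest.raises(ValueError, match="empty"):
            train_classifier(build_classifier(cfg, 10), fm, None, cfg)

    @pytest.mark.parametrize("family", ["bilstm", "transformer_head"])
    def test_other_families_learn_separable_data(self, family):
        fm = _separable_fm(n=48)
        cfg = ModelConfig.for_family(
            family, max_len=8, epochs=8, seed=2, dropout_rate=0.0,
            **({"lr": 5e-3} if family == "transformer_head" else {}),
        )
        trained = train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg)
        assert trained.history["train_loss"][-1] < trained.history["train_loss"][0]

    def test_same_seed_training_is_reproducible(self):
        fm = _separable_fm()
        cfg = ModelConfig.for_family("cnn", max_len=8, epochs=3, seed=5)
        a = train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg)
        b = train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg)
        assert a.history["train_loss"] == b.history["train_loss"]


class TestPredict:
    @pytest.fixture
    def trained(self):
        fm = _separable_fm()
        cfg = ModelConfig.for_family("cnn", max_len=8, epochs=3, seed=0)
        return train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg)

    def test_probabilities_in_unit_interval(self, trained):
        X = np.random.default_rng(1).integers(0, 30, size=(10, 8))
        probs, labels = predict(trained, X)
        assert np.all((probs >= 0) & (probs <= 1))
        assert set(labels) <= {0, 1}

    def test_threshold_boundary_is_positive(self, trained):
        class Half:
            config = trained.config

            def predict_proba(self, X):
                return np.full(len(X), 0.5)

        from deplex.models import TrainedClassifier

        stub = TrainedClassifier(Half(), trained.config)
        _, labels = predict(stub, np.zeros((3, trained.config.max_len), dtype=int))
        assert np.all(labels == 1)

    def test_width_mismatch_rejected(self, trained):
        with pytest.raises(ValueError, match="max_len"):
            predict(trained, np.zeros((2, 5), dtype=int))

    def test_duplicated_rows_get_identical_outputs(self, trained):
        row = np.random.default_rng(2).integers(0, 30, size=(1, 8))
        probs, _ = predict(trained, np.vstack([row, row]))
        assert probs[0] == probs[1]


def test_tiny_random_encoder_is_deterministic_and_768d():
    enc = TinyRandomEncoder(vocab_size=20, dim=768, seed=4)
    X = np.random.default_rng(0).integers(0, 20, size=(3, 6))
    assert enc(X).shape == (3, 768)
    assert np.array_equal(enc(X), enc(X))


def test_save_load_round_trip(tmp_path, vocab):
    fm = _separable_fm()
    cfg = ModelConfig.for_family("cnn", max_len=8, epochs=2, seed=3)
    trained = train_classifier(build_classifier(cfg, fm.vocab_size), fm, None, cfg,
                               vocabulary=None)
    trained.vocabulary = Vocabulary([f"tok{i}" for i in range(fm.vocab_size - 2)])
    path = tmp_path / "model.npz"
    save_model(trained, path)
    back = load_model(path)
    X = np.random.default_rng(4).integers(0, fm.vocab_size, size=(6, 8))
    assert np.allclose(back.predict_proba(X), trained.predict_proba(X))
    assert back.config == trained.config
    assert len(back.vocabulary) == len(trained.vocabulary)
    assert back.vocabulary.index("tok5") == trained.vocabulary.index("tok5")
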