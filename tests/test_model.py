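import numpy as np
import pytest

from matchgraph import autodiff as ad
from matchgraph.autodiff import Tensor
from matchgraph.model import (
    MatchGraphTagger,
    TrainConfig,
    _Network,
    load_results,
)
from matchgraph.spans import TokenSequence

TINY = dict(lstm_hidden=6, emb_dim=8, batch_size=4, max_epochs=2, seed=9)


def make_model(bench, **kw):
    cfg = TrainConfig(**{**TINY, **kw})
    return MatchGraphTagger(bench.train, bench.dictionary, config=cfg,
                            dev_corpus=bench.dev)


class TestConfig:
    def test_published_defaults(self):
        c = TrainConfig()
        assert (c.lstm_hidden, c.emb_dim, c.batch_size) == (256, 100, 50)
        assert (c.dropout, c.l2_softmax, c.lr_model) == (0.1, 1e-4, 1e-3)
        assert (c.lr_decay, c.max_epochs, c.layers) == (0.98, 50, 2)

    def test_nested_sections_flatten(self):
        c = TrainConfig.from_dict({"encoder": {"lstm_hidden": 12}, "seed": 3})
        assert c.lstm_hidden == 12 and c.seed == 3

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="use_crf"):
            TrainConfig.from_dict({"use_crf": True})

    def test_negative_layers_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(layers=-1)


class TestConstruction:
    def test_empty_corpus_rejected(self, tiny_benchmark):
        with pytest.raises(ValueError, match="empty"):
            MatchGraphTagger([], tiny_benchmark.dictionary)

    def test_tagset_from_corpus_and_dictionary(self, tiny_benchmark):
        model = make_model(tiny_benchmark)
        for etype in tiny_benchmark.dictionary.etypes:
            assert f"B-{etype}" in model.tagset

    def test_malformed_tag_rejected(self, tiny_benchmark):
        sent, tags = tiny_benchmark.train[0]
        bad = [(sent, ["Q-t0"] + list(tags)[1:])]
        with pytest.raises(ValueError, match="Q-t0"):
            MatchGraphTagger(bad, tiny_benchmark.dictionary)


class TestForward:
    def test_probability_rows_sum_to_one(self, tiny_benchmark):
        model = make_model(tiny_benchmark)
        res = model.fit()
        sent, _ = tiny_benchmark.test[0]
        probs = res.predict_proba(sent)
        assert probs.shape == (len(sent), len(model.tagset))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_bit_deterministic(self, tiny_benchmark):
        model = make_model(tiny_benchmark)
        res = model.fit()
        sent, _ = tiny_benchmark.test[0]
        assert np.array_equal(res.predict_proba(sent), res.predict_proba(sent))

    def test_zero_graph_stack_equals_repeated_norm(self, tiny_benchmark):
        """With no matches, T graph layers reduce to T stacked normalizations."""
        cfg = TrainConfig(**{**TINY, "dropout": 0.0})
        model = make_model(tiny_benchmark)
        rng = np.random.default_rng(0)
        net = _Network(cfg, model.vocab, model.tagset, None, None, rng)
        cache = model._cache(*tiny_benchmark.train[0])
        cache.a_out_n = np.zeros_like(cache.a_out_n)
        cache.a_in_n = np.zeros_like(cache.a_in_n)
        cache.mask_ids = None
        h = net.hidden(cache, train=False, rng=None)
        x = Tensor(net.params["emb"].data[cache.token_ids])
        from matchgraph.nn import run_lstm

        manual = run_lstm(net.fwd, net.bwd, x)
        for _ in range(cfg.layers):
            manual = ad.layer_norm(manual)
        assert np.array_equal(h.data, manual.data)

    def test_layer_size_knob_runs_for_one_to_four(self, tiny_benchmark):
        sent, _ = tiny_benchmark.test[0]
        for T in (1, 2, 3, 4):
            model = make_model(tiny_benchmark, layers=T, max_epochs=1)
            res = model.fit()
            assert len(res.predict_tags(sent)) == len(sent)

    @pytest.mark.parametrize("kw", [
        {"single_gcn": True},
        {"no_residual": True},
        {"late_fusion": True},
        {"no_bilstm": True},
        {"mask_feature": True},
        {"share_gcn_weights": True},
        {"self_loops": False},
        {"layers": 0},
    ])
    def test_ablations_and_switches_train_and_predict(self, tiny_benchmark, kw):
        model = make_model(tiny_benchmark, max_epochs=1, **kw)
        res = model.fit()
        sent, _ = tiny_benchmark.test[0]
        tags = res.predict_tags(sent)
        assert len(tags) == len(sent)
        assert all(t in model.tagset for t in tags)


class TestLoss:
    def test_one_hot_correct_gives_zero(self):
        gold = np.array([0, 2])
        logits = Tensor(np.array([[50.0, 0.0, 0.0], [0.0, 0.0, 50.0]]))
        loss, probs = ad.softmax_cross_entropy(logits, gold)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probs_closed_form(self):
        L, C = 7, 13
        loss, _ = ad.softmax_cross_entropy(Tensor(np.zeros((L, C))), np.zeros(L, dtype=int))
        assert float(loss.data) == pytest.approx(L * np.log(C), abs=1e-9)

    def test_matches_naive_token_loop(self, rng):
        logits = rng.normal(size=(6, 5))
        gold = rng.integers(0, 5, 6)
        loss, probs = ad.softmax_cross_entropy(Tensor(logits), gold)
        naive = -sum(np.log(probs[i, gold[i]]) for i in range(6))
        assert float(loss.data) == pytest.approx(naive, abs=1e-9)


class TestTraining:
    def test_lr_follows_pure_exponential_decay(self, tiny_benchmark):
        model = make_model(tiny_benchmark, max_epochs=4)
        res = model.fit()
        lr0 = model.config.lr_model
        for _, row in res.history.iterrows():
            assert row["lr"] == pytest.approx(lr0 * 0.98 ** row["epoch"], rel=1e-12)

    def test_same_seed_same_first_epoch_loss(self, tiny_benchmark):
        r1 = make_model(tiny_benchmark, max_epochs=1).fit()
        r2 = make_model(tiny_benchmark, max_epochs=1).fit()
        assert r1.history["loss"][0] == r2.history["loss"][0]

    def test_different_seed_changes_loss(self, tiny_benchmark):
        r1 = make_model(tiny_benchmark, max_epochs=1, seed=1).fit()
        r2 = make_model(tiny_benchmark, max_epochs=1, seed=2).fit()
        assert r1.history["loss"][0] != r2.history["loss"][0]

    def test_history_and_summary(self, tiny_benchmark):
        res = make_model(tiny_benchmark).fit()
        assert {"epoch", "loss", "lr", "precision", "recall", "f1"} <= set(res.history.columns)
        text = res.summary()
        assert "graph layers (T)" in text and "BiLSTM(6)" in text


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_benchmark, tmp_path):
        res = make_model(tiny_benchmark).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        loaded = load_results(path)
        sent, _ = tiny_benchmark.test[0]
        assert loaded.predict_tags(sent) == res.predict_tags(sent)
        assert np.allclose(loaded.predict_proba(sent), res.predict_proba(sent))

    def test_bad_format_rejected(self, tmp_path):
        import json

        path = tmp_path / "bad.npz"
        meta = np.frombuffer(json.dumps({"format": "other"}).encode(), dtype=np.uint8)
        np.savez(path, __meta__=meta)
        with pytest.raises(ValueError, match="format"):
            load_results(path)


class TestAdapter:
    def test_sum_pooled_subword_adapter(self, tiny_benchmark):
        class Adapter:
            dim = 5

            def encode(self, tokens):
                # two subwords per word, each half the word's hash vector
                vecs, index = [], []
                for i, tok in enumerate(tokens):
                    rng = np.random.default_rng(abs(hash(tok)) % (2**31))
                    v = rng.normal(size=5)
                    vecs.extend([v / 2, v / 2])
                    index.extend([i, i])
                return np.array(vecs), index

        cfg = TrainConfig(**{**TINY, "max_epochs": 1})
        model = MatchGraphTagger(tiny_benchmark.train, tiny_benchmark.dictionary,
                                 config=cfg, encoder_adapter=Adapter())
        res = model.fit()
        sent, _ = tiny_benchmark.train[0]
        assert len(res.predict_tags(sent)) == len(sent)
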