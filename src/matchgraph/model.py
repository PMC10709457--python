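"""The matching-graph tagger as a model / results pair.

:class:`MatchGraphTagger` is constructed from a training corpus, an entity
dictionary, and a :class:`TrainConfig`; :meth:`MatchGraphTagger.fit` runs the
training loop and returns a :class:`TaggerResults` carrying the fitted
parameters, the per-epoch history, and prediction / evaluation / summary
methods — the same model-object / results-object split statsmodels users
expect.

Architecture (one sentence of length L):

  x_i   = embedding(w_i)            (or sum-pooled contextual subword vectors)
  H     = BiLSTM(x)                 L x d_h, d_h = 2 * lstm_hidden
  H_T   = T bidirectional graph-convolution layers over the matching graph
  p_i   = softmax(h_i W_p)          token-wise BIOES distribution
  loss  = sum_i -log p_i[gold_i]    (+ L2 penalty on W_p only)

Training uses Adam with a per-epoch exponential learning-rate decay, batch
shuffling, and dropout on the embeddings only.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .dictionary import EntityDictionary, find_matches, masked_baseline
from .evaluation import EvalReport, evaluate_spans
from .graph import build_match_graph
from .nn import AdamOptimizer, BiGCNLayer, LSTMCell, Parameters, glorot, row_normalize, run_lstm
from .spans import EntitySpan, Tagset, TokenSequence, decode_bioes

__all__ = ["TrainConfig", "MatchGraphTagger", "TaggerResults", "load_results"]

CHECKPOINT_FORMAT = "matchgraph-checkpoint-v1"
UNK = "<unk>"


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; defaults follow the published training setup.

    ``layers`` is the number of graph-convolution layers T (0 disables the
    graph module entirely); the ablation flags switch off the backward graph
    branch, the residual connection, the per-layer fusion, or the BiLSTM.
    """

    lstm_hidden: int = 256
    emb_dim: int = 100
    batch_size: int = 50
    dropout: float = 0.1
    l2_softmax: float = 1e-4
    lr_model: float = 1e-3
    lr_encoder_adapter: float = 1e-5
    lr_decay: float = 0.98
    max_epochs: int = 50
    layers: int = 2
    seed: int = 0
    # ablations
    single_gcn: bool = False
    no_residual: bool = False
    late_fusion: bool = False
    no_bilstm: bool = False
    # structural switches
    share_gcn_weights: bool = False
    self_loops: bool = True
    mask_feature: bool = False
    mask_emb_dim: int = 8
    mask_style: str = "bmes"

    def __post_init__(self) -> None:
        if self.layers < 0:
            raise ValueError("layers (T) must be >= 0")
        for name in ("lstm_hidden", "emb_dim", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):  # nested sections (encoder:, graph:, ...)
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


def _mask_vocab(etypes: Sequence[str], style: str) -> dict[str, int]:
    labels = ["O"]
    if style == "binary":
        labels.append("X")
    else:
        for t in sorted(etypes):
            labels.extend(f"{p}-{t}" for p in ("B", "M", "E", "S"))
    return {lab: i for i, lab in enumerate(labels)}


@dataclass
class _SentenceCache:
    sentence: TokenSequence
    token_ids: np.ndarray
    gold_ids: np.ndarray | None
    a_out_n: np.ndarray
    a_in_n: np.ndarray
    mask_ids: np.ndarray | None
    adapter_x: np.ndarray | None = None


class _Network:
    """Parameter container + forward pass, shared by model and results."""

    def __init__(self, config: TrainConfig, vocab: dict[str, int], tagset: Tagset,
                 mask_vocab: dict[str, int] | None, adapter_dim: int | None,
                 rng: np.random.Generator):
        self.config = config
        self.vocab = vocab
        self.tagset = tagset
        self.mask_vocab = mask_vocab
        self.adapter_dim = adapter_dim
        self.params = Parameters()
        c = config
        d_h = 2 * c.lstm_hidden
        self.d_h = d_h
        d_in = adapter_dim if adapter_dim is not None else c.emb_dim
        if adapter_dim is None:
            self.params.new("emb", rng.normal(0.0, 0.1, size=(len(vocab), c.emb_dim)))
        if mask_vocab is not None:
            self.params.new(
                "mask_emb", rng.normal(0.0, 0.1, size=(len(mask_vocab), c.mask_emb_dim))
            )
            d_in += c.mask_emb_dim
        if c.no_bilstm:
            self.params.new("proj", glorot(rng, d_in, d_h))
        else:
            self.fwd = LSTMCell(self.params, "lstm_f", d_in, c.lstm_hidden, rng)
            self.bwd = LSTMCell(self.params, "lstm_b", d_in, c.lstm_hidden, rng)
        n_unique = 1 if c.share_gcn_weights else c.layers
        self.gcn_layers = [
            BiGCNLayer(self.params, f"gcn{i}", d_h, rng, single_gcn=c.single_gcn)
            for i in range(n_unique)
        ]
        if c.late_fusion and c.layers > 0 and not c.single_gcn:
            self.params.new("w_fuse", glorot(rng, 2 * d_h, d_h))
        self.params.new("w_p", glorot(rng, d_h, len(tagset)))

    def _layer(self, i: int) -> BiGCNLayer:
        return self.gcn_layers[0 if self.config.share_gcn_weights else i]

    def hidden(self, cache: _SentenceCache, train: bool,
               rng: np.random.Generator | None) -> Tensor:
        c = self.config
        if cache.adapter_x is not None:
            x = Tensor(cache.adapter_x)
        else:
            emb = self.params["emb"]
            idx = cache.token_ids
            x = Tensor(emb.data[idx], (emb,))

            def bw(g, idx=idx, emb=emb):
                full = np.zeros_like(emb.data)
                np.add.at(full, idx, g)
                emb._accumulate(full)

            x._bw = bw
        if train and c.dropout > 0.0:
            keep = (rng.random(x.data.shape) >= c.dropout) / (1.0 - c.dropout)
            x = ad.mul(x, Tensor(keep))
        if cache.mask_ids is not None:
            memb = self.params["mask_emb"]
            midx = cache.mask_ids
            mx = Tensor(memb.data[midx], (memb,))

            def mbw(g, midx=midx, memb=memb):
                full = np.zeros_like(memb.data)
                np.add.at(full, midx, g)
                memb._accumulate(full)

            mx._bw = mbw
            x = ad.concat_cols([x, mx])
        if c.no_bilstm:
            h = ad.matmul(x, self.params["proj"])
        else:
            h = run_lstm(self.fwd, self.bwd, x)
        if c.layers > 0:
            a_out = Tensor(cache.a_out_n)
            a_in = Tensor(cache.a_in_n)
            if c.late_fusion and not c.single_gcn:
                h0 = h
                h_out, h_in = h, h
                for i in range(c.layers):
                    layer = self._layer(i)
                    q_out = ad.relu(ad.matmul(ad.matmul(a_out, h_out), layer.w_out))
                    q_in = ad.relu(ad.matmul(ad.matmul(a_in, h_in), layer.w_in))
                    if c.no_residual:
                        h_out, h_in = ad.layer_norm(q_out), ad.layer_norm(q_in)
                    else:
                        h_out = ad.layer_norm(ad.add(h_out, q_out))
                        h_in = ad.layer_norm(ad.add(h_in, q_in))
                merged = ad.relu(ad.matmul(ad.concat_cols([h_out, h_in]), self.params["w_fuse"]))
                h = ad.layer_norm(merged if c.no_residual else ad.add(h0, merged))
            else:
                for i in range(c.layers):
                    h = self._layer(i).forward(h, a_out, a_in, no_residual=c.no_residual)
        return h

    def forward(self, cache: _SentenceCache, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[Tensor, np.ndarray]:
        """Token-wise class probabilities (L x C) and the logits tensor."""
        h = self.hidden(cache, train, rng)
        logits = ad.matmul(h, self.params["w_p"])
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return logits, ez / ez.sum(axis=1, keepdims=True)

    def loss(self, cache: _SentenceCache, train: bool,
             rng: np.random.Generator | None) -> tuple[Tensor, np.ndarray]:
        h = self.hidden(cache, train, rng)
        logits = ad.matmul(h, self.params["w_p"])
        return ad.softmax_cross_entropy(logits, cache.gold_ids)


class MatchGraphTagger:
    """Dictionary-augmented neural tagger over a training corpus.

    Parameters
    ----------
    corpus :
        Sequence of ``(TokenSequence, tags)`` training pairs (BIOES tags).
    dictionary :
        The entity dictionary whose matches define the graph.
    config :
        Hyperparameters; ``TrainConfig()`` reproduces the published defaults.
    dev_corpus :
        Optional held-out pairs; if given, the best-epoch checkpoint is
        selected by dev F1, otherwise by training F1.
    encoder_adapter :
        Optional contextual encoder: any object with
        ``encode(tokens) -> (subword_vectors, word_index_per_subword)``
        and a ``dim`` attribute.  Subword vectors are sum-pooled per word and
        replace the trainable embedding table.
    """

    def __init__(
        self,
        corpus: Sequence[tuple[TokenSequence, Sequence[str]]],
        dictionary: EntityDictionary,
        config: TrainConfig | None = None,
        dev_corpus: Sequence[tuple[TokenSequence, Sequence[str]]] | None = None,
        encoder_adapter=None,
    ):
        if not corpus:
            raise ValueError("empty training corpus")
        self.config = config or TrainConfig()
        self.dictionary = dictionary
        self.corpus = list(corpus)
        self.dev_corpus = list(dev_corpus) if dev_corpus else None
        self.encoder_adapter = encoder_adapter
        corpus_tags = [t for _s, tags in self.corpus for t in tags]
        corpus_types = {tag.partition("-")[2] for tag in corpus_tags if tag != "O"}
        self.tagset = Tagset(corpus_types | set(dictionary.etypes))
        for _s, tags in self.corpus:
            for tag in tags:
                if tag not in self.tagset:
                    raise ValueError(f"tag {tag!r} not in the derived tagset")
        vocab: dict[str, int] = {UNK: 0}
        for sent, _tags in self.corpus:
            for tok in sent:
                vocab.setdefault(tok, len(vocab))
        self.vocab = vocab
        self.mask_vocab = (
            _mask_vocab(dictionary.etypes, self.config.mask_style)
            if self.config.mask_feature
            else None
        )

    # -- sentence preparation -------------------------------------------------

    def _cache(self, sentence: TokenSequence, tags: Sequence[str] | None) -> _SentenceCache:
        c = self.config
        token_ids = np.array([self.vocab.get(t, 0) for t in sentence], dtype=np.intp)
        gold_ids = (
            np.array([self.tagset.index(t) for t in tags], dtype=np.intp)
            if tags is not None
            else None
        )
        matches = find_matches(sentence, self.dictionary)
        if not c.self_loops:
            matches = [m for m in matches if len(m.span) > 1]
        graph = build_match_graph(sentence, matches)
        mask_ids = None
        if self.mask_vocab is not None:
            mask = masked_baseline(sentence, self.dictionary, style=c.mask_style)
            mask_ids = np.array([self.mask_vocab[m] for m in mask], dtype=np.intp)
        adapter_x = None
        if self.encoder_adapter is not None:
            vecs, word_ix = self.encoder_adapter.encode(list(sentence))
            adapter_x = np.zeros((len(sentence), self.encoder_adapter.dim))
            np.add.at(adapter_x, np.asarray(word_ix, dtype=np.intp), np.asarray(vecs))
        return _SentenceCache(
            sentence=sentence,
            token_ids=token_ids,
            gold_ids=gold_ids,
            a_out_n=row_normalize(graph.a_out),
            a_in_n=row_normalize(graph.a_in),
            mask_ids=mask_ids,
            adapter_x=adapter_x,
        )

    # -- training -------------------------------------------------------------

    def fit(self, early_stop_f1: float | None = None, verbose: bool = False) -> "TaggerResults":
        c = self.config
        rng = np.random.default_rng(c.seed)
        net = _Network(
            c,
            self.vocab,
            self.tagset,
            self.mask_vocab,
            self.encoder_adapter.dim if self.encoder_adapter is not None else None,
            rng,
        )
        train_caches = [self._cache(s, tags) for s, tags in self.corpus]
        monitor = self.dev_corpus if self.dev_corpus is not None else self.corpus
        monitor_caches = [self._cache(s, tags) for s, tags in monitor]
        monitor_gold = [decode_bioes(tags) for _s, tags in monitor]
        opt = AdamOptimizer(net.params, lr=c.lr_model)
        history: list[dict] = []
        best_state = net.params.state()
        best_f1 = -1.0
        best_epoch = -1
        order = np.arange(len(train_caches))
        for epoch in range(c.max_epochs):
            lr = c.lr_model * c.lr_decay**epoch
            rng.shuffle(order)
            epoch_loss = 0.0
            for b0 in range(0, len(order), c.batch_size):
                batch = order[b0 : b0 + c.batch_size]
                net.params.zero_grad()
                for k in batch:
                    loss, _probs = net.loss(train_caches[k], train=True, rng=rng)
                    epoch_loss += float(loss.data)
                    loss.backward()
                if c.l2_softmax > 0.0:
                    wp = net.params["w_p"]
                    epoch_loss += c.l2_softmax * float((wp.data**2).sum())
                    wp._accumulate(2.0 * c.l2_softmax * wp.data)
                opt.step(lr=lr)
            report = _evaluate(net, monitor_caches, monitor_gold, self.tagset)
            p, r, f1 = report.pooled
            history.append(
                {
                    "epoch": epoch,
                    "loss": epoch_loss,
                    "lr": lr,
                    "precision": p,
                    "recall": r,
                    "f1": f1,
                }
            )
            if verbose:
                print(
                    f"epoch {epoch:3d}  loss {epoch_loss:12.4f}  lr {lr:.6f}  "
                    f"P {p:.4f}  R {r:.4f}  F1 {f1:.4f}"
                )
            if f1 > best_f1:
                best_f1 = f1
                best_epoch = epoch
                best_state = net.params.state()
            if early_stop_f1 is not None and f1 >= early_stop_f1:
                break
        net.params.load_state(best_state)
        return TaggerResults(
            network=net,
            dictionary=self.dictionary,
            config=c,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            model=self,
        )


def _evaluate(net: _Network, caches: Sequence[_SentenceCache],
              gold: Sequence[set[EntitySpan]], tagset: Tagset) -> EvalReport:
    pred_spans = []
    for cache in caches:
        _logits, probs = net.forward(cache, train=False)
        tags = [tagset.tag(int(i)) for i in probs.argmax(axis=1)]
        pred_spans.append(decode_bioes(tags))
    return evaluate_spans(pred_spans, gold)


class TaggerResults:
    """Fitted tagger: parameters, history, and prediction/evaluation methods."""

    def __init__(self, network: _Network, dictionary: EntityDictionary,
                 config: TrainConfig, history: pd.DataFrame, best_epoch: int,
                 model: MatchGraphTagger | None = None):
        self._net = network
        self.dictionary = dictionary
        self.config = config
        self.history = history
        self.best_epoch = best_epoch
        self._model = model

    @property
    def tagset(self) -> Tagset:
        return self._net.tagset

    @property
    def params(self) -> Parameters:
        return self._net.params

    def _cache_for(self, sentence: TokenSequence) -> _SentenceCache:
        if self._model is not None:
            return self._model._cache(sentence, None)
        helper = MatchGraphTagger.__new__(MatchGraphTagger)
        helper.config = self.config
        helper.dictionary = self.dictionary
        helper.tagset = self._net.tagset
        helper.vocab = self._net.vocab
        helper.mask_vocab = self._net.mask_vocab
        helper.encoder_adapter = None
        return MatchGraphTagger._cache(helper, sentence, None)

    def predict_proba(self, sentence: TokenSequence) -> np.ndarray:
        """L x C token-wise BIOES probabilities; rows sum to one."""
        _logits, probs = self._net.forward(self._cache_for(sentence), train=False)
        return probs

    def predict_tags(self, sentence: TokenSequence) -> list[str]:
        probs = self.predict_proba(sentence)
        return [self._net.tagset.tag(int(i)) for i in probs.argmax(axis=1)]

    def predict_spans(self, sentence: TokenSequence) -> set[EntitySpan]:
        return decode_bioes(self.predict_tags(sentence))

    def predict(self, sentences: Iterable[TokenSequence]) -> list[list[str]]:
        return [self.predict_tags(s) for s in sentences]

    def evaluate(
        self, corpus: Sequence[tuple[TokenSequence, Sequence[str]]]
    ) -> EvalReport:
        pred = [self.predict_spans(s) for s, _t in corpus]
        gold = [decode_bioes(t) for _s, t in corpus]
        return evaluate_spans(pred, gold)

    def summary(self) -> str:
        c = self.config
        n_params = sum(t.data.size for t in self._net.params.values())
        buf = io.StringIO()
        buf.write("Matching-graph tagger results\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"{'graph layers (T)':28s} {c.layers}\n")
        buf.write(f"{'encoder':28s} "
                  f"{'projection' if c.no_bilstm else f'BiLSTM({c.lstm_hidden})'}\n")
        buf.write(f"{'embedding dim':28s} {c.emb_dim}\n")
        buf.write(f"{'graph direction':28s} "
                  f"{'forward only' if c.single_gcn else 'bidirectional'}\n")
        buf.write(f"{'fusion':28s} {'late' if c.late_fusion else 'per-layer'}\n")
        buf.write(f"{'residual connection':28s} {not c.no_residual}\n")
        buf.write(f"{'dictionary entries':28s} {len(self.dictionary)}\n")
        buf.write(f"{'tagset size':28s} {len(self._net.tagset)}\n")
        buf.write(f"{'trainable parameters':28s} {n_params}\n")
        buf.write(f"{'epochs run':28s} {len(self.history)}\n")
        buf.write(f"{'best epoch':28s} {self.best_epoch}\n")
        if len(self.history):
            row = self.history.iloc[-1]
            best = self.history.loc[self.history["f1"].idxmax()]
            buf.write(f"{'final loss':28s} {row['loss']:.4f}\n")
            buf.write(
                f"{'best monitored P/R/F1':28s} "
                f"{best['precision']:.4f} / {best['recall']:.4f} / {best['f1']:.4f}\n"
            )
        buf.write("=" * 64)
        return buf.getvalue()

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.config),
            "vocab": self._net.vocab,
            "etypes": list(self._net.tagset.etypes),
            "mask_vocab": self._net.mask_vocab,
            "dictionary": {
                "entries": [[list(toks), etype] for toks, etype in self.dictionary.entries],
                "normalization": self.dictionary.normalization,
            },
            "best_epoch": self.best_epoch,
            "history": self.history.to_dict(orient="list"),
        }
        arrays = {f"param:{k}": v.data for k, v in self._net.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_results(path) -> TaggerResults:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format in {path}")
        arrays = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    config = TrainConfig(**meta["config"])
    dictionary = EntityDictionary(
        [(tuple(toks), etype) for toks, etype in meta["dictionary"]["entries"]],
        normalization=meta["dictionary"]["normalization"],
    )
    tagset = Tagset(meta["etypes"])
    rng = np.random.default_rng(0)
    adapter_dim = None
    net = _Network(config, meta["vocab"], tagset, meta["mask_vocab"], adapter_dim, rng)
    net.params.load_state(arrays)
    history = pd.DataFrame(meta["history"])
    return TaggerResults(
        network=net,
        dictionary=dictionary,
        config=config,
        history=history,
        best_epoch=meta["best_epoch"],
    )
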