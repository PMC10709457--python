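# matchgraph

A dictionary matching-graph neural tagger for biomedical named entity
recognition (BioNER).

## The problem

BioNER systems must find and type gene/protein, chemical, and disease
mentions, including the many entities that never occur in the training data.
Curated entity dictionaries (gazetteers) carry exactly that missing
knowledge, but the common way of injecting them — masking the tokens covered
by a greedy longest dictionary match — breaks down as soon as dictionary
hits overlap or nest: the greedy mask keeps one overlong candidate and
discards the true entity even when the true entity is itself a dictionary
entry.

`matchgraph` implements the matching-graph alternative. *Every* dictionary
match in a sentence, overlapping and nested ones included, becomes a
directed edge from its first to its last token. The resulting L×L forward
adjacency A_out (and its transpose A_in) is encoded by a bidirectional graph
convolutional network (BiGCN) stacked on a BiLSTM sentence encoder, and a
token-wise softmax emits BIOES tags. The model sees all candidate spans at
once and learns which edges correspond to real entities.

## The model

For a sentence w_1..w_L with encoder states H = {h_1..h_L}
(h_i = [h_i^f, h_i^b], the concatenated forward/backward LSTM states), each
of T graph layers computes

    Q_out = ReLU( rownorm(A_out) · H_t · W_out )
    Q_in  = ReLU( rownorm(A_in)  · H_t · W_in  )
    H_t+1 = LayerNorm( H_t + ReLU( [Q_out, Q_in] · W_O ) )

where rownorm divides each nonzero adjacency row by its degree. The two
directions are fused in every layer; the residual path preserves encoder
states for tokens touched by no match. Classification and loss are

    p(y_i | X) = softmax(h_i^T W_p),     loss = Σ_i −log p(y_i = y_i^gold)

trained with Adam, per-epoch learning-rate decay (0.98), dropout on
embeddings (0.1), and an L2 penalty on W_p only (1e-4). Scoring is
exact-match entity F1 with pooled counts: P = Σc/Σp, R = Σc/Σg,
F1 = 2PR/(P+R), reported pooled, per type, and macro-averaged.

Since no GPU framework is required, the network (including a small
reverse-mode autodiff engine) is implemented directly on NumPy; matching
uses a token-level Aho–Corasick automaton.

## Worked example

Overlapping matches misleading the mask but not the graph (`overlong_mask_fixture`
is a built-in miniature of that situation):

```python
from matchgraph import overlong_mask_fixture, find_matches, masked_baseline

sentence, dictionary, gold = overlong_mask_fixture()
print("matches:", [(m.span.start, m.span.end, m.span.etype)
                   for m in find_matches(sentence, dictionary)])
print("mask:   ", masked_baseline(sentence, dictionary))
print("gold:   ", sorted((s.start, s.end, s.etype) for s in gold))
```

    matches: [(1, 3, 't0'), (1, 5, 't1'), (2, 4, 't1')]
    mask:    ['O', 'B-t1', 'M-t1', 'M-t1', 'E-t1']
    gold:    [(1, 3, 't0')]

The gold span (1, 3) is in the match list, but the greedy mask commits to
the overlong (1, 5) candidate.

Training on the synthetic benchmark (test entities are held out of the
training sentences, so the dictionary is the model's only source of
knowledge about them; takes about half a minute on one CPU):

```python
from matchgraph import (SynthConfig, generate_benchmark,
                        MatchGraphTagger, TrainConfig)

bench = generate_benchmark(SynthConfig(seed=11), n_train=150, n_dev=40, n_test=60)
config = TrainConfig(lstm_hidden=32, emb_dim=32, seed=11)
results = MatchGraphTagger(bench.train, bench.dictionary, config=config,
                           dev_corpus=bench.dev).fit()
print(results.summary())
print(results.evaluate(bench.test).to_text())
```

    Matching-graph tagger results
    ================================================================
    graph layers (T)             2
    encoder                      BiLSTM(32)
    embedding dim                32
    graph direction              bidirectional
    fusion                       per-layer
    residual connection          True
    dictionary entries           496
    tagset size                  13
    trainable parameters         54208
    epochs run                   50
    best epoch                   43
    final loss                   83.7737
    best monitored P/R/F1        0.8654 / 0.9000 / 0.8824
    ================================================================

                        P        R       F1   gold   pred
    pooled         0.6703   0.7262   0.6971     84     91
    t0             0.8462   0.8462   0.8462     13     13
    t1             0.8846   0.9583   0.9200     24     26
    t2             0.5192   0.5745   0.5455     47     52
    macro-avg      0.7500   0.7930   0.7705

A test F1 of 0.70 on entities never seen in training is far above what the
same encoder reaches without the graph (near zero under this budget) or with
the forward-only GCN ablation (≈ 0.45) — the matching graph is what carries
the dictionary knowledge to unseen mentions.

The same pipeline is available from the shell:

    matchgraph synth --seed 7 --out-prefix demo
    matchgraph train --corpus demo.conll --dictionary demo.dict.tsv --checkpoint m.npz
    matchgraph predict --corpus demo.conll --checkpoint m.npz --out pred.conll
    matchgraph evaluate --pred pred.conll --gold demo.conll
    matchgraph build-graph --corpus demo.conll --dictionary demo.dict.tsv

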