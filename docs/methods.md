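# Methods

## Task and representations

The package treats biomedical named entity recognition as BIOES sequence
labeling: each token of a sentence receives one of `O` or `{B,I,E,S}-t` for
the entity types `t` in a closed tagset derived at model construction from
the training corpus and the dictionary. Spans are 0-based half-open
`[start, end)` word intervals everywhere; the only place a different
convention appears is the matching-graph edge, which runs from a match's
first token to its *last* token (`end − 1`), because an entity is identified
by its start point and end point.

Decoding predicted tag sequences must be total, since a softmax classifier
can emit ill-formed runs. The repair rule is conservative: `S` and orphan
`E` tags become single-token entities; a `B` (or orphan `I`) absorbs the
following same-type `I` run plus one closing same-type `E`, and the whole
run is one span. On well-formed sequences this inverts the encoder exactly
(property-tested on random span sets).

## Dictionary matching and the matching graph

A dictionary is a deduplicated set of tokenized surface forms with optional
types. Matching is exact token-sequence equality after a normalization
policy; the default folds case only (mildest recall-friendly choice —
"RCC"/"rcc" match while the encoder still sees the original casing).
A token-level Aho–Corasick automaton returns *every* match — overlapping,
nested and disjoint — and an O(L²) hash-set scan of all substrings is kept
permanently as the reference implementation that the automaton is checked
against in the tests and acceptance script.

Each match contributes `a_out[start][end−1] = 1`; `a_in` is the transpose.
The adjacency is binary and type-agnostic: several entries sharing one span
still give one edge (the graph layers take a single unlabeled matrix; types
stay on the match objects for the masked baseline and diagnostics).
Single-token matches become diagonal self-loops so the graph still carries
their signal; the `self_loops` switch removes them for comparison.

The masked baseline is the greedy leftmost-longest non-overlapping cover
(ties to the lowest entry id), emitted as typed `B/M/E/S` labels (or a
binary flag). When enabled as a model feature it is embedded through a small
trainable lookup concatenated to the token embedding. This is the approach
the matching graph is designed to replace: it provably discards sub-matches
of whatever span the greedy scan commits to.

## Network

Tokens are embedded (dim 100 by default) or, through the contextual-encoder
adapter interface, represented by externally computed per-subword vectors
sum-pooled to words. A BiLSTM (hidden 256 per direction by default, so
`d_h = 512`) produces `H`; with the `no_bilstm` ablation a linear projection
of the embeddings stands in. Each of `T` graph layers computes

    Q_out = ReLU(rownorm(A_out) H_t W_out)
    Q_in  = ReLU(rownorm(A_in)  H_t W_in)
    H_t+1 = Norm(H_t + ReLU([Q_out, Q_in] W_O))

Design choices where the architecture was genuinely open:

- **Norm** is layer normalization over the hidden dimension, without learned
  gain/bias. It is the standard residual companion and keeps the zero-graph
  case exactly analyzable: with an all-zero adjacency a layer reduces to
  `Norm(H_t)` bit-for-bit, which the tests assert.
- **Shapes.** `W_out, W_in ∈ R^{d_h×d_h}`, `W_O ∈ R^{2d_h×d_h}` so the
  residual addition type-checks. With `single_gcn` (forward branch only) the
  fusion weight is `d_h×d_h`.
- **Weight tying.** Layers are untied by default (`share_gcn_weights`
  enables tying); untied is the least restrictive reading of a per-step
  update rule.
- **Row normalization** divides nonzero rows by their degree and leaves
  all-zero rows at zero, so isolated tokens aggregate nothing and receive
  only the residual path — no special-casing anywhere else.
- **Late fusion** (`late_fusion` ablation) runs the two branches separately,
  each with its own residual+norm update per layer, and merges them once
  after layer `T` through a dedicated `2d_h×d_h` fusion weight with a
  residual from the encoder states. The default merges every layer.

Classification is a token-wise softmax `p(y_i|X) = softmax(h_i W_p)` and the
loss is the *sum* (not mean) of token negative log-likelihoods, plus an L2
penalty on `W_p` only (1e-4). The optimizer is Adam (lr 1e-3) with the
per-epoch schedule `lr_e = lr_0 · 0.98^e`, batch shuffling (batch 50),
dropout 0.1 on embeddings only, and best-epoch checkpointing by dev F1
(training F1 when no dev split is supplied). One master seed drives
initialization, shuffling and dropout; eval-mode forward passes are
bit-deterministic. A linear-chain CRF head is deliberately not provided: the
loss above is the model's published objective, and a CRF would change it.

The whole network runs on a small reverse-mode automatic-differentiation
engine over NumPy arrays (`matchgraph.autodiff`). The computation graphs are
a few hundred nodes per sentence, so a dynamic tape is fast enough on one
CPU; every operation's gradient is verified against central finite
differences in the test suite, and the Adam/LSTM/GCN stack is exercised by
an end-to-end gradient check.

## Evaluation

An entity is correct only if start, end and type all match a gold entity
(each gold entity creditable once). The headline scores pool counts over
the evaluation set: `P = Σc/Σp`, `R = Σc/Σg`, `F1 = 2PR/(P+R)`; zero
denominators yield 0 by convention. Because "macro-F1" is used ambiguously
in the literature for both pooled-count and per-type-averaged scores, the
report carries the pooled scores as headline plus per-type scores and their
unweighted macro average, all labeled.

## Synthetic data: what it emulates and what it does not

The generator (`matchgraph.synthetic`) builds a world in which the value of
the matching graph is decidable by construction:

- every entity type has a dedicated marker token, and every entity surface
  is `marker + generic tokens` (default length 1–2);
- a fraction `p_gold_in_dict` (default 0.9) of entity surfaces is in the
  dictionary — dictionaries are never complete in practice;
- distractor entries are cut from real sentence windows that overlap or
  nest with gold spans (`super_left`, `super_both`, `overlap_right`,
  `nested`; Poisson rate 2.0 per sentence) and never start at a marker;
- bare markers are occasionally planted as plain text (rate 0.3 per
  sentence), positioned so they create no dictionary match.

Under these conditions gold tags are derivable from token identities plus
the matching graph by the planted rule *"the longest match starting at a
marker token is an entity of the marker's type"*: the marker gives the start
and the type, the edge gives the end. The end boundary is **not** derivable
from text alone for surfaces unseen in training (the tail tokens are
ordinary vocabulary), and the greedy mask is actively misled by the
super-span distractors. Gold surfaces are kept to 1–2 tokens because a
longer entity's *interior* tokens touch no edge and their tags would not be
token-wise decodable from the graph; the configuration accepts lengths up to
5 for users who want harder, noisier worlds.

The benchmark splitter holds a fraction of the entity inventory (default
0.4) out of the training and dev sentences and draws test-sentence entities
from it, so test performance measures dictionary-mediated generalization,
not surface memorization — the scenario that motivates dictionary
integration in the first place.

What the generator does *not* emulate: real biomedical token statistics,
subword morphology, ambiguous entity boundaries that are resolvable from
context, type confusion between plausible entities, or annotation noise.
Passing the synthetic comparisons therefore shows that the implementation
learns from graph structure exactly when graph structure is informative; it
does not certify performance on real corpora.

Defaults were chosen once as the package's standing study conditions:
vocabulary 120, 3 types, sentences of 6–14 tokens, 200 sentences (or
150/40/60 train/dev/test in the benchmark), 80-entry inventory. They are
small enough for minutes-scale CPU training and large enough that the
ablation ordering (full BiGCN > forward-only GCN > no graph) is stable
across seeds with double-digit F1 margins.

## Problem sizes and numerical choices

- Training demonstrations use `emb_dim=32`, `lstm_hidden=32`, `T=2`; the
  configured defaults remain the published full-scale settings (100/256/2).
- Layer-norm epsilon 1e-5; softmax computed with max-subtraction; the loss
  adds 1e-300 inside the log only to guard exact zeros from underflow.
- Adam uses β = (0.9, 0.999), ε = 1e-8; the forget-gate bias is initialized
  to 1 (standard retention initialization); other weights are Glorot-uniform
  from the master seed.
- Ties in the greedy mask go to the lowest entry id; match lists are sorted
  by (start, end, entry id), making every pipeline stage deterministic.

## Known limitations

- Training is single-CPU and dynamic-tape-based: fine for the corpus sizes
  above, not for the full benchmark corpora with a 62k-entry dictionary and
  a fine-tuned contextual encoder (the adapter interface exists, but no
  pretrained weights ship with the package).
- The matching graph is type-agnostic by design; when two entries of
  different types share a span, type disambiguation falls entirely to the
  encoder and classifier.
- Gold annotations are assumed non-overlapping (true of the standard
  BioNER corpora); nesting exists only among dictionary matches.
- The conservative decode rule can merge adjacent ill-formed fragments of
  the same type into one span; alternatives (e.g. dropping orphans) would
  trade recall for precision.
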