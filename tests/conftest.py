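import numpy as np
import pytest

from matchgraph.dictionary import EntityDictionary
from matchgraph.spans import EntitySpan, TokenSequence


def random_sentence_dictionary(rng, max_len=30, n_entries=100, entry_lens=(1, 4),
                               vocab=12):
    """A random (sentence, dictionary) pair over a small shared vocabulary.

    The vocabulary is deliberately tiny so that matches — including
    overlapping and nested ones — actually occur.
    """
    words = [f"v{i}" for i in range(vocab)]
    entries = []
    for k in range(n_entries):
        ell = int(rng.integers(entry_lens[0], entry_lens[1] + 1))
        toks = tuple(words[int(i)] for i in rng.integers(0, vocab, ell))
        entries.append((toks, f"t{int(rng.integers(2))}"))
    dictionary = EntityDictionary(entries)
    L = int(rng.integers(1, max_len + 1))
    sent = TokenSequence(tuple(words[int(i)] for i in rng.integers(0, vocab, L)))
    return sent, dictionary


def random_span_set(rng, length, n_types=3):
    """Random non-overlapping typed spans inside [0, length)."""
    spans = set()
    pos = 0
    while pos < length:
        if rng.random() < 0.4:
            end = min(length, pos + 1 + int(rng.integers(0, 4)))
            spans.add(EntitySpan(pos, end, f"t{int(rng.integers(n_types))}"))
            pos = end + 1
        else:
            pos += 1
    return spans


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small shared train/dev/test world used by the model tests."""
    from matchgraph.synthetic import SynthConfig, generate_benchmark

    return generate_benchmark(
        SynthConfig(seed=5, vocab_size=40, n_dict_entries=20, n_sentences=1),
        n_train=12,
        n_dev=4,
        n_test=4,
    )
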