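"""Seeded synthetic corpora with overlapping / nested / disjoint matches.

The generator emulates the situation that motivates the matching graph: a
sentence contains gold entities whose surfaces are (mostly) dictionary
entries, while the dictionary also hits *distractor* spans that overlap or
nest with the gold ones, so a greedy longest-match mask is misled but the
full match graph retains the gold span.

World model
-----------
Tokens are synthetic word ids (``w017``); every entity type ``t<k>`` has a
dedicated *marker* token (``mk<k>``) and every entity surface starts with its
type's marker, followed by generic tokens.  Gold tags are then derivable from
token identities plus the matching graph by the planted rule: *the longest
dictionary match starting at a marker token is an entity of the marker's
type*.  The end boundary of an unseen entity is unknowable from text alone
(its tail tokens are ordinary vocabulary), so the graph carries genuinely
necessary information, while the leftmost-longest mask is broken by planted
super-span distractors — the exact failure mode the graph method targets.

Distractor surfaces never start at a marker, so they add edges the model can
learn to ignore lexically without corrupting the planted rule.  Bare marker
tokens are also occasionally inserted as plain text (never forming a
dictionary match), so that marker identity alone does not reveal an entity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dictionary import EntityDictionary
from .spans import EntitySpan, TokenSequence, encode_bioes

__all__ = ["SynthConfig", "SynthCorpus", "Benchmark", "generate", "generate_benchmark", "overlong_mask_fixture"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults are the package's standing study conditions: a 120-word
    vocabulary with 3 entity types, 200 sentences of 6-14 tokens, an 80-entry
    entity inventory with surfaces of 1-2 tokens, 90% dictionary coverage of
    gold surfaces, and on average two distractor constructions per sentence.
    Entity surfaces are kept short so that the planted labeling rule stays
    exactly decodable from the matching graph (see the module docstring);
    distractor entries still reach up to two tokens beyond a gold span.
    """

    vocab_size: int = 120
    n_sentences: int = 200
    sentence_length: tuple[int, int] = (6, 14)
    n_dict_entries: int = 80
    entry_length: tuple[int, int] = (1, 2)
    n_types: int = 3
    p_gold_in_dict: float = 0.9
    distractor_rate: float = 2.0
    marker_noise_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vocab_size", "n_sentences", "n_dict_entries", "n_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.entry_length
        if not (1 <= lo <= hi <= 5):
            raise ValueError("entry_length must satisfy 1 <= lo <= hi <= 5")
        if not (0.0 <= self.p_gold_in_dict <= 1.0):
            raise ValueError("p_gold_in_dict must be a probability")
        if self.distractor_rate < 0 or self.marker_noise_rate < 0:
            raise ValueError("rates must be non-negative")
        # distinct marker-initial surfaces available at each length
        capacity = sum(
            self.n_types * self.vocab_size ** (ell - 1) for ell in range(lo, hi + 1)
        )
        if self.n_dict_entries > capacity // 2:
            raise ValueError(
                f"n_dict_entries={self.n_dict_entries} exceeds half the surface "
                f"space ({capacity}) for the given vocab/type/length settings"
            )


@dataclass
class SynthCorpus:
    """A generated corpus: sentences with gold tags, dictionary, manifest."""

    sentences: list[tuple[TokenSequence, list[str], frozenset[EntitySpan]]]
    dictionary_entries: list[tuple[tuple[str, ...], str]]
    manifest: list[dict]

    _dictionary: EntityDictionary | None = field(default=None, repr=False)

    @property
    def dictionary(self) -> EntityDictionary:
        if self._dictionary is None:
            self._dictionary = EntityDictionary(self.dictionary_entries)
        return self._dictionary

    def pairs(self) -> list[tuple[TokenSequence, list[str]]]:
        return [(s, tags) for s, tags, _g in self.sentences]

    def write_conll(self, path) -> None:
        from .conll import write_conll

        write_conll(path, self.pairs())

    def write_dictionary(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# synthetic entity dictionary\n")
            for toks, etype in self.dictionary_entries:
                fh.write(f"{' '.join(toks)}\t{etype}\n")

    def write_manifest(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for record in self.manifest:
                fh.write(json.dumps(record) + "\n")


class _World:
    """Shared vocabulary, inventory and dictionary for one seeded generation."""

    def __init__(self, config: SynthConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.words = [f"w{i:03d}" for i in range(config.vocab_size)]
        self.types = [f"t{k}" for k in range(config.n_types)]
        self.markers = {f"t{k}": f"mk{k}" for k in range(config.n_types)}
        lo, hi = config.entry_length
        surfaces: set[tuple[str, ...]] = set()
        inventory: list[tuple[tuple[str, ...], str, bool]] = []
        attempts = 0
        while len(inventory) < config.n_dict_entries:
            attempts += 1
            if attempts > 50 * config.n_dict_entries:
                raise ValueError("could not draw enough distinct entity surfaces")
            etype = self.types[int(rng.integers(config.n_types))]
            ell = int(rng.integers(lo, hi + 1))
            tail = tuple(self.words[int(i)] for i in rng.integers(0, config.vocab_size, ell - 1))
            surface = (self.markers[etype],) + tail
            if surface in surfaces:
                continue
            surfaces.add(surface)
            in_dict = bool(rng.random() < config.p_gold_in_dict)
            inventory.append((surface, etype, in_dict))
        self.inventory = inventory
        self.dict_surfaces: set[tuple[str, ...]] = {
            s for s, _t, in_d in inventory if in_d
        }
        self.entries: list[tuple[tuple[str, ...], str]] = [
            (s, t) for s, t, in_d in inventory if in_d
        ]
        self._entry_keys = set(self.entries)
        # markers that may appear as plain-text noise: their bare form must
        # not be a dictionary entry, or the noise would create a match
        self.noise_markers = [
            m for t, m in self.markers.items() if (m,) not in self.dict_surfaces
        ]

    def add_entry(self, surface: tuple[str, ...], etype: str) -> None:
        key = (surface, etype)
        if key not in self._entry_keys:
            self._entry_keys.add(key)
            self.entries.append(key)
            self.dict_surfaces.add(surface)

    def filler(self, forbidden: set[str] = frozenset()) -> str:
        while True:
            w = self.words[int(self.rng.integers(self.config.vocab_size))]
            if w not in forbidden:
                return w

    def sentence(self, doc_id: str, pool: Sequence[int]) -> tuple[
        TokenSequence, list[str], frozenset[EntitySpan], dict
    ]:
        cfg = self.config
        rng = self.rng
        n = int(rng.integers(cfg.sentence_length[0], cfg.sentence_length[1] + 1))
        k = 2 if rng.random() < 0.4 else 1
        chosen = [self.inventory[pool[int(i)]] for i in rng.integers(0, len(pool), k)]
        total = sum(len(s) for s, _t, _d in chosen)
        while k > 1 and total + (k - 1) > n:  # need a one-token gap between entities
            k -= 1
            chosen = chosen[:k]
            total = sum(len(s) for s, _t, _d in chosen)
        free = n - total
        mins = [0] + [1] * (k - 1) + [0]
        extra = free - sum(mins)
        alloc = rng.multinomial(extra, [1.0 / (k + 1)] * (k + 1)) if extra > 0 else [0] * (k + 1)
        gaps = [int(m + a) for m, a in zip(mins, alloc)]

        tokens: list[str] = []
        spans: list[EntitySpan] = []
        for slot in range(k + 1):
            for _ in range(gaps[slot]):
                forbidden: set[str] = set()
                if spans and spans[-1].end == len(tokens):
                    # do not extend the preceding entity into a longer
                    # dictionary surface by accident
                    prev_surface, _pt, _pd = chosen[slot - 1]
                    forbidden = {
                        s[len(prev_surface)]
                        for s in self.dict_surfaces
                        if len(s) == len(prev_surface) + 1 and s[: len(prev_surface)] == prev_surface
                    }
                tokens.append(self.filler(forbidden))
            if slot < k:
                surface, etype, _in_dict = chosen[slot]
                start = len(tokens)
                tokens.extend(surface)
                spans.append(EntitySpan(start, len(tokens), etype))

        noise_positions: list[int] = []
        if self.noise_markers and rng.random() < cfg.marker_noise_rate:
            candidates = [
                i
                for i in range(len(tokens))
                if not any(sp.start - 1 <= i < sp.end for sp in spans)
            ]
            if candidates:
                pos = int(rng.choice(candidates))
                marker = self.noise_markers[int(rng.integers(len(self.noise_markers)))]
                nxt = tokens[pos + 1] if pos + 1 < len(tokens) else None
                if nxt is None or (marker, nxt) not in self.dict_surfaces:
                    tokens[pos] = marker
                    noise_positions.append(pos)

        distractors: list[dict] = []
        L = len(tokens)
        for _ in range(int(rng.poisson(cfg.distractor_rate))):
            sp = spans[int(rng.integers(len(spans)))]
            options = []
            if sp.start >= 1 and tokens[sp.start - 1] not in self.markers.values():
                options.append(("super_left", sp.start - 1, sp.end))
                if sp.end < L:
                    options.append(("super_both", sp.start - 1, sp.end + 1))
            if sp.end < L and len(sp) >= 1:
                options.append(("overlap_right", sp.start + 1, sp.end + 1))
            if len(sp) >= 2:
                options.append(("nested", sp.start + 1, sp.end))
            if not options:
                continue
            rel, a, b = options[int(rng.integers(len(options)))]
            surface = tuple(tokens[a:b])
            if surface[0] in self.markers.values():
                continue
            etype = self.types[int(rng.integers(cfg.n_types))]
            self.add_entry(surface, etype)
            distractors.append({"surface": list(surface), "etype": etype, "relation": rel})

        sent = TokenSequence(tuple(tokens), doc_id=doc_id)
        tags = encode_bioes(spans, len(tokens))
        record = {
            "doc_id": doc_id,
            "tokens": tokens,
            "gold": [[sp.start, sp.end, sp.etype] for sp in spans],
            "gold_in_dict": [surface in self.dict_surfaces for surface, _t, _d in chosen],
            "distractors": distractors,
            "noise_positions": noise_positions,
        }
        return sent, tags, frozenset(spans), record


def generate(config: SynthConfig) -> SynthCorpus:
    """Generate a corpus, dictionary and manifest, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    world = _World(config, rng)
    pool = list(range(len(world.inventory)))
    sentences = []
    manifest: list[dict] = []
    for i in range(config.n_sentences):
        sent, tags, gold, record = world.sentence(f"synth-{i:04d}", pool)
        sentences.append((sent, tags, gold))
        manifest.append(record)
    manifest.append({"dictionary_size": len(world.entries)})
    return SynthCorpus(
        sentences=sentences,
        dictionary_entries=list(world.entries),
        manifest=manifest,
    )


@dataclass
class Benchmark:
    """Train/dev/test splits over one shared world and dictionary.

    Test-sentence gold entities are drawn from a held-out part of the entity
    inventory, so their surfaces never occur in training sentences: whatever
    the model knows about them must come from the dictionary.
    """

    train: list[tuple[TokenSequence, list[str]]]
    dev: list[tuple[TokenSequence, list[str]]]
    test: list[tuple[TokenSequence, list[str]]]
    dictionary: EntityDictionary
    manifest: list[dict]


def generate_benchmark(
    config: SynthConfig,
    n_train: int,
    n_dev: int,
    n_test: int,
    heldout_fraction: float = 0.4,
) -> Benchmark:
    rng = np.random.default_rng(config.seed)
    world = _World(config, rng)
    n_inv = len(world.inventory)
    order = rng.permutation(n_inv)
    n_held = max(1, int(round(heldout_fraction * n_inv)))
    test_pool = [int(i) for i in order[:n_held]]
    train_pool = [int(i) for i in order[n_held:]]
    manifest: list[dict] = []

    def make(split: str, count: int, pool: Sequence[int]):
        out = []
        for i in range(count):
            sent, tags, _gold, record = world.sentence(f"{split}-{i:04d}", pool)
            record["split"] = split
            manifest.append(record)
            out.append((sent, tags))
        return out

    train = make("train", n_train, train_pool)
    dev = make("dev", n_dev, train_pool)
    test = make("test", n_test, test_pool)
    dictionary = EntityDictionary(world.entries)
    return Benchmark(train=train, dev=dev, test=test, dictionary=dictionary, manifest=manifest)


def overlong_mask_fixture() -> tuple[TokenSequence, EntityDictionary, set[EntitySpan]]:
    """A hand-built sentence where the greedy mask is misled but the graph is not.

    The gold entity is a dictionary entry, yet a longer dictionary entry
    starts at the same position, so the leftmost-longest mask covers a strict
    super-span of the gold span while the exhaustive match list still
    contains the gold span — the structural failure mode of the masked
    baseline that the matching graph is designed to avoid.
    """
    sentence = TokenSequence(("w010", "mk0", "w042", "w033", "w007"), doc_id="overlong-mask")
    dictionary = EntityDictionary(
        [
            (("mk0", "w042"), "t0"),                    # the gold entity
            (("mk0", "w042", "w033", "w007"), "t1"),    # overlong super-span
            (("w042", "w033"), "t1"),                   # overlapping distractor
        ]
    )
    gold = {EntitySpan(1, 3, "t0")}
    return sentence, dictionary, gold
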