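"""Entity dictionaries and exhaustive in-sentence matching.

The dictionary is a set of tokenized surface forms with optional entity
types.  Matching is exact token-sequence matching after a normalization
policy (case-folding by default, so that e.g. "RCC" and "rcc" match while the
original casing stays available to the encoder).  ``find_matches`` returns
*every* match — overlapping, nested, and disjoint alike — via a token-level
Aho–Corasick automaton; a quadratic hash-set scan is kept alongside it as the
permanent reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .spans import EntitySpan, TokenSequence

__all__ = [
    "DEFAULT_TYPE",
    "Match",
    "EntityDictionary",
    "build_dictionary",
    "read_dictionary",
    "find_matches",
    "find_matches_bruteforce",
    "masked_baseline",
]

DEFAULT_TYPE = "entity"


def _casefold(tokens: Sequence[str]) -> tuple[str, ...]:
    return tuple(t.casefold() for t in tokens)


def _identity(tokens: Sequence[str]) -> tuple[str, ...]:
    return tuple(tokens)


_NORMALIZERS: dict[str, Callable[[Sequence[str]], tuple[str, ...]]] = {
    "casefold": _casefold,
    "none": _identity,
}


@dataclass(frozen=True)
class Match:
    """One dictionary hit: a typed span plus the entry that produced it."""

    span: EntitySpan
    entry_id: int


class EntityDictionary:
    """A deduplicated set of (token sequence, type) entries with a multi-pattern
    scanner.

    Entry ids are assigned in first-appearance order of the deduplicated
    (normalized surface, type) pairs, so they are deterministic for a given
    input list.
    """

    def __init__(
        self,
        entries: Iterable[tuple[Sequence[str], str]],
        normalization: str = "casefold",
    ):
        if normalization not in _NORMALIZERS:
            raise ValueError(f"unknown normalization policy {normalization!r}")
        self.normalization = normalization
        norm = _NORMALIZERS[normalization]
        seen: dict[tuple[tuple[str, ...], str], int] = {}
        stored: list[tuple[tuple[str, ...], str]] = []
        for lineno, (surface, etype) in enumerate(entries, start=1):
            toks = norm(tuple(surface))
            if len(toks) == 0 or any(t == "" for t in toks):
                raise ValueError(f"dictionary entry {lineno} has no tokens after normalization")
            key = (toks, etype)
            if key not in seen:
                seen[key] = len(stored)
                stored.append(key)
        if not stored:
            raise ValueError("empty dictionary: no entries supplied")
        self.entries: tuple[tuple[tuple[str, ...], str], ...] = tuple(stored)
        self._automaton: _TokenAhoCorasick | None = None
        self._surface_index: dict[tuple[str, ...], list[int]] = {}
        for eid, (toks, _etype) in enumerate(self.entries):
            self._surface_index.setdefault(toks, []).append(eid)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: Sequence[str]) -> bool:
        return self.normalize(surface) in self._surface_index

    @property
    def etypes(self) -> tuple[str, ...]:
        return tuple(sorted({etype for _toks, etype in self.entries}))

    @property
    def max_entry_len(self) -> int:
        return max(len(toks) for toks, _ in self.entries)

    def normalize(self, tokens: Sequence[str]) -> tuple[str, ...]:
        return _NORMALIZERS[self.normalization](tokens)

    def entry_ids(self, surface: Sequence[str]) -> list[int]:
        return list(self._surface_index.get(self.normalize(surface), []))

    @property
    def automaton(self) -> "_TokenAhoCorasick":
        if self._automaton is None:
            self._automaton = _TokenAhoCorasick(self.entries)
        return self._automaton


def build_dictionary(
    entries: Iterable[tuple[str, str] | str],
    tokenizer: Callable[[str], Sequence[str]] = str.split,
    normalization: str = "casefold",
) -> EntityDictionary:
    """Build a dictionary from raw surface strings.

    ``entries`` may mix bare surfaces (assigned :data:`DEFAULT_TYPE`) and
    (surface, type) pairs.  An entry that tokenizes to zero tokens is rejected
    with its position.
    """
    prepared: list[tuple[tuple[str, ...], str]] = []
    for lineno, entry in enumerate(entries, start=1):
        if isinstance(entry, str):
            surface, etype = entry, DEFAULT_TYPE
        else:
            surface, etype = entry
        toks = tuple(tokenizer(surface))
        if len(toks) == 0:
            raise ValueError(f"entry {lineno} ({surface!r}) tokenizes to zero tokens")
        prepared.append((toks, etype))
    return EntityDictionary(prepared, normalization=normalization)


def read_dictionary(path, normalization: str = "casefold") -> EntityDictionary:
    """Read a dictionary file: one ``surface<TAB>type`` entry per line.

    Lines starting with ``#`` are comments; a missing type column defaults to
    :data:`DEFAULT_TYPE`.
    """
    entries: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            surface, _, etype = line.partition("\t")
            if not surface.split():
                raise ValueError(f"{path}:{lineno}: entry tokenizes to zero tokens")
            entries.append((surface, etype.strip() or DEFAULT_TYPE))
    if not entries:
        raise ValueError(f"{path}: empty dictionary")
    return build_dictionary(entries, normalization=normalization)


class _TokenAhoCorasick:
    """Aho–Corasick automaton over word tokens (not characters)."""

    def __init__(self, entries: Sequence[tuple[tuple[str, ...], str]]):
        # goto[state] maps a token to the next state; state 0 is the root.
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[int]] = [[]]
        for eid, (toks, _etype) in enumerate(entries):
            state = 0
            for tok in toks:
                nxt = self._goto[state].get(tok)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto[state][tok] = nxt
                    self._goto.append({})
                    self._fail.append(0)
                    self._out.append([])
                state = nxt
            self._out[state].append(eid)
        self._entry_len = [len(toks) for toks, _ in entries]
        # BFS to wire failure links and merge output sets.
        queue: list[int] = list(self._goto[0].values())
        head = 0
        while head < len(queue):
            state = queue[head]
            head += 1
            for tok, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and tok not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(tok, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    def scan(self, tokens: Sequence[str]) -> list[tuple[int, int, int]]:
        """Yield (start, end, entry_id) for every pattern occurrence."""
        hits: list[tuple[int, int, int]] = []
        state = 0
        for j, tok in enumerate(tokens):
            while state and tok not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(tok, 0)
            for eid in self._out[state]:
                start = j + 1 - self._entry_len[eid]
                hits.append((start, j + 1, eid))
        return hits


def find_matches(sentence: TokenSequence, dictionary: EntityDictionary) -> list[Match]:
    """Every dictionary match in the sentence, overlaps and nestings included.

    Returns one :class:`Match` per (span, entry) pair, sorted by
    (start, end, entry_id).
    """
    tokens = dictionary.normalize(sentence.tokens)
    matches = [
        Match(EntitySpan(start, end, dictionary.entries[eid][1]), eid)
        for start, end, eid in dictionary.automaton.scan(tokens)
    ]
    matches.sort(key=lambda m: (m.span.start, m.span.end, m.entry_id))
    return matches


def find_matches_bruteforce(sentence: TokenSequence, dictionary: EntityDictionary) -> list[Match]:
    """Reference scanner: test every substring against the entry hash set.

    O(L^2) in the sentence length; kept permanently as the oracle the
    automaton is checked against.
    """
    tokens = dictionary.normalize(sentence.tokens)
    L = len(tokens)
    max_len = dictionary.max_entry_len
    matches: list[Match] = []
    for i in range(L):
        for j in range(i + 1, min(L, i + max_len) + 1):
            for eid in dictionary._surface_index.get(tokens[i:j], ()):
                matches.append(Match(EntitySpan(i, j, dictionary.entries[eid][1]), eid))
    matches.sort(key=lambda m: (m.span.start, m.span.end, m.entry_id))
    return matches


def masked_baseline(
    sentence: TokenSequence,
    dictionary: EntityDictionary,
    style: str = "bmes",
) -> list[str]:
    """The greedy masked-manner feature: a leftmost-longest non-overlapping cover.

    Scanning left to right, each position takes the longest match starting
    there (ties broken by lowest entry id), marks its tokens, and jumps past
    it.  ``style='bmes'`` emits typed ``B/M/E/S`` labels; ``style='binary'``
    emits ``X`` for covered tokens.  Uncovered tokens are ``O``.

    This is the baseline that fails on overlapping and nested matches: a
    longer dictionary entry can shadow the true entity and produce an
    overlong mask.
    """
    if style not in ("bmes", "binary"):
        raise ValueError(f"unknown mask style {style!r}")
    matches = find_matches(sentence, dictionary)
    by_start: dict[int, Match] = {}
    # matches are sorted by (start, end, entry_id); strict > keeps the lowest
    # entry id among same-length candidates
    for m in matches:
        cur = by_start.get(m.span.start)
        if cur is None or len(m.span) > len(cur.span):
            by_start[m.span.start] = m
    mask = ["O"] * len(sentence)
    pos = 0
    while pos < len(sentence):
        m = by_start.get(pos)
        if m is None:
            pos += 1
            continue
        s, e, t = m.span.start, m.span.end, m.span.etype
        if style == "binary":
            for i in range(s, e):
                mask[i] = "X"
        elif e - s == 1:
            mask[s] = f"S-{t}"
        else:
            mask[s] = f"B-{t}"
            for i in range(s + 1, e - 1):
                mask[i] = f"M-{t}"
            mask[e - 1] = f"E-{t}"
        pos = e
    return mask
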