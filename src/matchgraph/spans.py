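"""Sentences, entity spans, and the BIOES tag codec.

Spans are word-level, 0-based, half-open ``[start, end)`` everywhere in this
package.  The BIOES scheme marks each token of an entity as Begin / Inside /
End, a single-token entity as S, and everything else as O; a type suffix
(``B-disease``) carries the entity type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TokenSequence",
    "EntitySpan",
    "Tagset",
    "encode_bioes",
    "decode_bioes",
    "bio_to_bioes",
]


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized sentence with stable 0-based word indices."""

    tokens: tuple[str, ...]
    doc_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if len(self.tokens) == 0:
            raise ValueError("a TokenSequence must contain at least one token")
        for i, tok in enumerate(self.tokens):
            if tok == "":
                raise ValueError(f"empty token at position {i} (doc_id={self.doc_id!r})")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity occupying word positions ``[start, end)``."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end}): need 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


class Tagset:
    """The closed BIOES tag inventory for a fixed set of entity types.

    Tags are ``O`` plus ``{B,I,E,S}-t`` for every type ``t``.  The tagset is
    derived once, at model-construction time, from the training corpus and the
    dictionary; tags outside it are an error rather than being silently
    remapped.
    """

    def __init__(self, etypes: Iterable[str]):
        self.etypes: tuple[str, ...] = tuple(sorted(set(etypes)))
        tags = ["O"]
        for t in self.etypes:
            tags.extend(f"{p}-{t}" for p in ("B", "I", "E", "S"))
        self.tags: tuple[str, ...] = tuple(tags)
        self._index = {tag: i for i, tag in enumerate(self.tags)}

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self._index

    def __iter__(self):
        return iter(self.tags)

    def index(self, tag: str) -> int:
        try:
            return self._index[tag]
        except KeyError:
            raise KeyError(f"tag {tag!r} is not in the tagset {sorted(self._index)}") from None

    def tag(self, index: int) -> str:
        return self.tags[index]

    @classmethod
    def from_tags(cls, tags: Iterable[str]) -> "Tagset":
        etypes = set()
        for tag in tags:
            if tag == "O":
                continue
            prefix, _, etype = tag.partition("-")
            if prefix not in ("B", "I", "E", "S") or not etype:
                raise ValueError(f"malformed BIOES tag {tag!r}")
            etypes.add(etype)
        return cls(etypes)


def _split_tag(tag: str) -> tuple[str, str]:
    if tag == "O":
        return "O", ""
    prefix, sep, etype = tag.partition("-")
    if not sep or prefix not in ("B", "I", "E", "S") or not etype:
        raise ValueError(f"malformed BIOES tag {tag!r}")
    return prefix, etype


def encode_bioes(spans: Iterable[EntitySpan], length: int) -> list[str]:
    """Encode non-overlapping spans as a BIOES tag sequence of ``length``.

    Single-token spans become ``S-t``; longer spans ``B-t (I-t)* E-t``.

    Raises
    ------
    ValueError
        If a span lies outside ``[0, length)`` or two spans overlap; the
        message names the offending spans.
    """
    spans = sorted(spans)
    tags = ["O"] * length
    prev: EntitySpan | None = None
    for span in spans:
        if span.end > length:
            raise ValueError(f"span {span} out of range for sentence of length {length}")
        if prev is not None and prev.overlaps(span):
            raise ValueError(f"overlapping spans: {prev} and {span}")
        if len(span) == 1:
            tags[span.start] = f"S-{span.etype}"
        else:
            tags[span.start] = f"B-{span.etype}"
            for i in range(span.start + 1, span.end - 1):
                tags[i] = f"I-{span.etype}"
            tags[span.end - 1] = f"E-{span.etype}"
        prev = span
    return tags


def decode_bioes(tags: Sequence[str]) -> set[EntitySpan]:
    """Decode a BIOES sequence into spans; total on ill-formed input.

    Well-formed sequences invert :func:`encode_bioes` exactly.  Ill-formed
    runs (an I/E with no opener, a B that is never closed) are repaired
    conservatively: an opener (B, or an orphan I) absorbs the following
    same-type I run and one closing same-type E if present, and the whole run
    becomes a single span; an orphan E or an S is a single-token span.
    """
    spans: set[EntitySpan] = set()
    L = len(tags)
    i = 0
    while i < L:
        prefix, etype = _split_tag(tags[i])
        if prefix == "O":
            i += 1
        elif prefix in ("S", "E"):
            spans.add(EntitySpan(i, i + 1, etype))
            i += 1
        else:  # B, or an orphan I acting as an opener
            j = i + 1
            while j < L and tags[j] == f"I-{etype}":
                j += 1
            if j < L and tags[j] == f"E-{etype}":
                j += 1
            spans.add(EntitySpan(i, j, etype))
            i = j
    return spans


def bio_to_bioes(tags: Sequence[str]) -> list[str]:
    """Deterministically convert BIO tags to BIOES.

    A B/I token becomes E (or S for a one-token entity) when the entity does
    not continue at the next position.
    """
    out: list[str] = []
    L = len(tags)
    for i, tag in enumerate(tags):
        if tag == "O":
            out.append("O")
            continue
        prefix, sep, etype = tag.partition("-")
        if not sep or prefix not in ("B", "I"):
            raise ValueError(f"malformed BIO tag {tag!r} at position {i}")
        nxt = tags[i + 1] if i + 1 < L else "O"
        continues = nxt == f"I-{etype}"
        if prefix == "B":
            out.append(f"B-{etype}" if continues else f"S-{etype}")
        else:
            out.append(f"I-{etype}" if continues else f"E-{etype}")
    return out
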