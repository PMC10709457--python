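"""Two-column CoNLL corpus reading and writing.

Files are UTF-8, one ``token<whitespace>tag`` pair per line, sentences
separated by blank lines.  Tags are BIOES on disk; corpora shipped in BIO can
be converted deterministically at load time with ``scheme='bio'``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .spans import Tagset, TokenSequence, bio_to_bioes

__all__ = ["read_conll", "write_conll"]


def read_conll(
    path,
    tagset: Tagset | None = None,
    scheme: str = "bioes",
) -> list[tuple[TokenSequence, list[str]]]:
    """Parse a corpus file into (sentence, tags) pairs.

    A line with other than two columns is an error naming the line number;
    with an explicit ``tagset``, any tag outside it is an error listing the
    tag.  ``scheme='bio'`` converts BIO tags to BIOES after reading.
    """
    if scheme not in ("bioes", "bio"):
        raise ValueError(f"unknown tag scheme {scheme!r}")
    sentences: list[tuple[TokenSequence, list[str]]] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        nonlocal tokens, tags
        if tokens:
            out_tags = bio_to_bioes(tags) if scheme == "bio" else list(tags)
            if tagset is not None:
                for tag in out_tags:
                    if tag not in tagset:
                        raise ValueError(f"{path}: tag {tag!r} is not in the tagset")
            sentences.append(
                (TokenSequence(tuple(tokens), doc_id=f"s{len(sentences)}"), out_tags)
            )
            tokens, tags = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns (token, tag), got {len(cols)}"
                )
            tokens.append(cols[0])
            tags.append(cols[1])
    flush()
    return sentences


def write_conll(path, sentences: Iterable[tuple[TokenSequence, Sequence[str]]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent, tags in sentences:
            if len(sent) != len(tags):
                raise ValueError(
                    f"sentence {sent.doc_id!r}: {len(sent)} tokens but {len(tags)} tags"
                )
            for tok, tag in zip(sent, tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")
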