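"""The matching graph: dictionary hits as directed edges over a sentence.

Every dictionary match contributes one edge from its first token to its last
token, giving an L x L forward adjacency ``a_out``; the backward adjacency
``a_in`` is its transpose.  Single-token matches become self-loops.  The
adjacency is binary and type-agnostic: several entries sharing a span still
yield a single edge (types stay on the Match objects for diagnostics and the
masked baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dictionary import EntityDictionary, Match, find_matches
from .spans import TokenSequence

__all__ = ["MatchGraph", "build_match_graph", "match_graph_for"]


@dataclass(frozen=True)
class MatchGraph:
    a_out: np.ndarray
    a_in: np.ndarray
    matches: tuple[Match, ...]

    @property
    def n_edges(self) -> int:
        return int(self.a_out.sum())

    def edge_list(self) -> list[tuple[int, int]]:
        """(start token, end token) pairs, end here being the *last* token."""
        rows, cols = np.nonzero(self.a_out)
        return list(zip(rows.tolist(), cols.tolist()))


def build_match_graph(sentence: TokenSequence, matches: Sequence[Match]) -> MatchGraph:
    """Turn a match list into forward/backward adjacency matrices.

    An edge runs from the match's first token to its last token (index
    ``end - 1``; half-open spans are converted to inclusive endpoints at this
    boundary only), so ``a_out[start][end-1] = 1``.
    """
    L = len(sentence)
    a_out = np.zeros((L, L), dtype=np.int8)
    for m in matches:
        if m.span.end > L:
            raise ValueError(f"match {m} out of range for sentence of length {L}")
        a_out[m.span.start, m.span.end - 1] = 1
    return MatchGraph(a_out=a_out, a_in=a_out.T.copy(), matches=tuple(matches))


def match_graph_for(sentence: TokenSequence, dictionary: EntityDictionary) -> MatchGraph:
    """Scan the sentence and build its matching graph in one step."""
    return build_match_graph(sentence, find_matches(sentence, dictionary))
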