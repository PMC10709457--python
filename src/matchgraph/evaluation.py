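"""Exact-match entity scoring.

An entity counts as correct only when its start, end, and type all equal a
gold entity's.  Counts of correct (c), predicted (p) and gold (g) entities
are pooled over the evaluation set and turned into

    P = sum(c) / sum(p),   R = sum(c) / sum(g),   F1 = 2PR / (P + R).

The pooled-count scores are the headline numbers; per-type scores and their
unweighted (macro) average are reported alongside, clearly labeled, since
"macro" is used ambiguously in the literature for both.
Zero denominators give 0 by convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .spans import EntitySpan

__all__ = ["EvalCounts", "count_matches", "prf", "EvalReport", "evaluate_spans"]


@dataclass
class EvalCounts:
    """Correct / predicted / gold entity tallies, per type and pooled."""

    c: Counter = field(default_factory=Counter)
    p: Counter = field(default_factory=Counter)
    g: Counter = field(default_factory=Counter)

    def add(self, other: "EvalCounts") -> "EvalCounts":
        self.c.update(other.c)
        self.p.update(other.p)
        self.g.update(other.g)
        return self

    @property
    def etypes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.c) | set(self.p) | set(self.g)))

    def pooled(self) -> tuple[int, int, int]:
        return (
            sum(self.c.values()),
            sum(self.p.values()),
            sum(self.g.values()),
        )


def count_matches(pred: Iterable[EntitySpan], gold: Iterable[EntitySpan]) -> EvalCounts:
    """Tally one sample.  Each gold entity can be matched at most once."""
    counts = EvalCounts()
    gold_set = set(gold)
    matched: set[EntitySpan] = set()
    for span in pred:
        counts.p[span.etype] += 1
        if span in gold_set and span not in matched:
            counts.c[span.etype] += 1
            matched.add(span)
    for span in gold_set:
        counts.g[span.etype] += 1
    return counts


def _prf1(c: int, p: int, g: int) -> tuple[float, float, float]:
    prec = c / p if p else 0.0
    rec = c / g if g else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """Pooled precision, recall, F1 over all entity types."""
    return _prf1(*counts.pooled())


@dataclass
class EvalReport:
    counts: EvalCounts

    @property
    def pooled(self) -> tuple[float, float, float]:
        return prf(self.counts)

    @property
    def f1(self) -> float:
        return self.pooled[2]

    def per_type(self) -> dict[str, tuple[float, float, float]]:
        return {
            t: _prf1(self.counts.c[t], self.counts.p[t], self.counts.g[t])
            for t in self.counts.etypes
        }

    def macro_average(self) -> tuple[float, float, float]:
        """Unweighted mean of the per-type P/R/F1."""
        per = self.per_type()
        if not per:
            return 0.0, 0.0, 0.0
        n = len(per)
        return tuple(sum(v[i] for v in per.values()) / n for i in range(3))  # type: ignore[return-value]

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        p, r, f1 = self.pooled
        out["pooled.precision"], out["pooled.recall"], out["pooled.f1"] = p, r, f1
        mp, mr, mf = self.macro_average()
        out["macro.precision"], out["macro.recall"], out["macro.f1"] = mp, mr, mf
        for t, (tp, tr, tf) in self.per_type().items():
            out[f"type.{t}.precision"], out[f"type.{t}.recall"], out[f"type.{t}.f1"] = tp, tr, tf
        return out

    def to_text(self) -> str:
        lines = [f"{'':12s} {'P':>8s} {'R':>8s} {'F1':>8s} {'gold':>6s} {'pred':>6s}"]
        p, r, f1 = self.pooled
        c, pp, g = self.counts.pooled()
        lines.append(f"{'pooled':12s} {p:8.4f} {r:8.4f} {f1:8.4f} {g:6d} {pp:6d}")
        for t, (tp, tr, tf) in self.per_type().items():
            lines.append(
                f"{t:12s} {tp:8.4f} {tr:8.4f} {tf:8.4f} "
                f"{self.counts.g[t]:6d} {self.counts.p[t]:6d}"
            )
        mp, mr, mf = self.macro_average()
        lines.append(f"{'macro-avg':12s} {mp:8.4f} {mr:8.4f} {mf:8.4f}")
        return "\n".join(lines)

    def write_kv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v:.6f}\n")


def evaluate_spans(
    pred_per_sentence: Iterable[Iterable[EntitySpan]],
    gold_per_sentence: Iterable[Iterable[EntitySpan]],
) -> EvalReport:
    counts = EvalCounts()
    for pred, gold in zip(pred_per_sentence, gold_per_sentence, strict=True):
        counts.add(count_matches(pred, gold))
    return EvalReport(counts)
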