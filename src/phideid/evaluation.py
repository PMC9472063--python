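"""Entity-level precision / recall / F1 with exact span+type matching.

A predicted entity counts as a true positive only when its token span and
its category both match a gold entity exactly; unmatched predictions are
false positives, unmatched gold entities false negatives.  Metrics follow

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R)

reported in percent, per category and micro-averaged (counts pooled across
categories before the ratios).  Zero denominators yield 0 by convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TextIO

from .corpus import Corpus


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    counts: MatchCounts


@dataclass
class EvalReport:
    per_category: dict[str, Metrics] = field(default_factory=dict)
    micro: Metrics | None = None

    def to_dict(self) -> dict:
        def m2d(m: Metrics) -> dict:
            return {
                "precision": round(m.precision, 2),
                "recall": round(m.recall, 2),
                "f1": round(m.f1, 2),
                "tp": m.counts.tp,
                "fp": m.counts.fp,
                "fn": m.counts.fn,
            }

        return {
            "per_category": {c: m2d(m) for c, m in self.per_category.items()},
            "micro": m2d(self.micro),
        }

    def to_json(self, stream: TextIO) -> None:
        json.dump(self.to_dict(), stream, indent=1)

    def table(self) -> str:
        """Human-readable fixed-width table, percentages with 2 decimals."""
        lines = [f"{'type':>6} {'P%':>8} {'R%':>8} {'F1%':>8} {'TP':>6} {'FP':>6} {'FN':>6}"]
        rows = list(self.per_category.items()) + [("micro", self.micro)]
        for name, m in rows:
            lines.append(
                f"{name:>6} {m.precision:8.2f} {m.recall:8.2f} {m.f1:8.2f} "
                f"{m.counts.tp:6d} {m.counts.fp:6d} {m.counts.fn:6d}"
            )
        return "\n".join(lines)


def match_entities(gold: Corpus, pred: Corpus) -> dict[str, MatchCounts]:
    """Per-category TP/FP/FN from exact (start, end, category) matching."""
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold vs {len(pred)} predicted sentences")
    counts: dict[str, MatchCounts] = {}
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(f"sentence {i}: token counts differ ({len(g)} vs {len(p)})")
        gset = {(s.start, s.end, s.category) for s in g.entities}
        pset = {(s.start, s.end, s.category) for s in p.entities}
        for cat in sorted({c for *_, c in gset | pset}):
            gc = {s for s in gset if s[2] == cat}
            pc = {s for s in pset if s[2] == cat}
            c = counts.setdefault(cat, MatchCounts())
            c.tp += len(gc & pc)
            c.fp += len(pc - gc)
            c.fn += len(gc - pc)
    return counts


def _metrics(c: MatchCounts) -> Metrics:
    p = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p, r, f1, c)


def score(counts: dict[str, MatchCounts]) -> EvalReport:
    """Turn per-category counts into per-category and micro P/R/F1 (percent)."""
    report = EvalReport()
    pooled = MatchCounts()
    for cat in sorted(counts):
        report.per_category[cat] = _metrics(counts[cat])
        pooled = pooled + counts[cat]
    report.micro = _metrics(pooled)
    return report


def evaluate(gold: Corpus, pred: Corpus) -> EvalReport:
    return score(match_entities(gold, pred))
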