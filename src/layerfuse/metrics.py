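"""Strict entity-level precision / recall / F1.

A predicted entity counts as a true positive only when a gold entity
with the *same type and the same exact character boundaries* exists in
the same sentence; each gold span can be matched at most once, so
duplicated predictions cannot double-count.  Unmatched predictions are
false positives, unmatched gold spans false negatives.  Scores follow

    P = TP / (TP + FP),   R = TP / (TP + FN),   F1 = 2PR / (P + R),

with the usual zero-denominator policy: an undefined P, R or F1 is
reported as 0 (never NaN), which keeps micro-averages well-defined.

Predicted BIO sequences are decoded with the "start-new" repair policy
before scoring.  The micro-average (counts summed over all six entity
types) is the headline number; a macro-average is also emitted.

:func:`evaluate_bruteforce` recomputes the same report by exhaustive
pairwise comparison with no data-structure shortcuts; it exists purely
as an oracle twin for the test suite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .corpus import AnnotatedSentence
from .tagging import ENTITY_TYPES, EntitySpan, tags_to_spans

__all__ = ["TypeScore", "MetricReport", "evaluate", "evaluate_bruteforce"]


@dataclass(frozen=True)
class TypeScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass(frozen=True)
class MetricReport:
    """TP/FP/FN and P/R/F1 per entity type plus micro / macro averages."""

    per_type: Dict[str, TypeScore]

    @property
    def micro(self) -> TypeScore:
        return TypeScore(
            tp=sum(s.tp for s in self.per_type.values()),
            fp=sum(s.fp for s in self.per_type.values()),
            fn=sum(s.fn for s in self.per_type.values()),
        )

    @property
    def macro(self) -> Tuple[float, float, float]:
        """Unweighted mean of per-type P, R, F1 (not a headline number)."""
        n = len(self.per_type)
        if n == 0:
            return (0.0, 0.0, 0.0)
        return (
            sum(s.precision for s in self.per_type.values()) / n,
            sum(s.recall for s in self.per_type.values()) / n,
            sum(s.f1 for s in self.per_type.values()) / n,
        )

    def to_dict(self) -> dict:
        def row(s: TypeScore) -> dict:
            return {"tp": s.tp, "fp": s.fp, "fn": s.fn,
                    "precision": s.precision, "recall": s.recall, "f1": s.f1}

        return {
            "per_type": {t: row(s) for t, s in self.per_type.items()},
            "micro": row(self.micro),
            "macro": dict(zip(("precision", "recall", "f1"), self.macro)),
        }

    def to_table(self) -> str:
        """Aligned text table with percentages to 2 decimals."""
        lines = [f"{'type':<8}{'TP':>6}{'FP':>6}{'FN':>6}"
                 f"{'P%':>9}{'R%':>9}{'F1%':>9}"]
        rows = list(self.per_type.items()) + [("micro", self.micro)]
        for name, s in rows:
            lines.append(
                f"{name:<8}{s.tp:>6}{s.fp:>6}{s.fn:>6}"
                f"{100 * s.precision:>9.2f}{100 * s.recall:>9.2f}"
                f"{100 * s.f1:>9.2f}"
            )
        return "\n".join(lines)


def _check_inputs(gold: Sequence[AnnotatedSentence],
                  predicted: Sequence[Sequence[str]]) -> None:
    if len(gold) != len(predicted):
        raise ValueError(
            f"gold has {len(gold)} sentences, predictions {len(predicted)}"
        )
    for i, (g, p) in enumerate(zip(gold, predicted)):
        if len(g.tokens) != len(p):
            raise ValueError(
                f"sentence {i}: gold length {len(g.tokens)} != "
                f"prediction length {len(p)}"
            )


def evaluate(gold: Sequence[AnnotatedSentence],
             predicted: Sequence[Sequence[str]]) -> MetricReport:
    """Score predicted tag sequences against gold sentences.

    ``predicted`` holds one BIO tag sequence per gold sentence, same
    per-sentence length; decoding uses the "start-new" repair.
    """
    _check_inputs(gold, predicted)
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    for g, p in zip(gold, predicted):
        gold_spans = Counter(g.entities)
        pred_spans = Counter(tags_to_spans(p, repair="start-new"))
        matched = gold_spans & pred_spans
        for span, c in matched.items():
            tp[span.entity_type] += c
        for span, c in (pred_spans - matched).items():
            fp[span.entity_type] += c
        for span, c in (gold_spans - matched).items():
            fn[span.entity_type] += c
    return MetricReport(per_type={
        t: TypeScore(tp=tp[t], fp=fp[t], fn=fn[t]) for t in ENTITY_TYPES
    })


def evaluate_bruteforce(gold: Sequence[AnnotatedSentence],
                        predicted: Sequence[Sequence[str]]) -> MetricReport:
    """Oracle twin of :func:`evaluate`: exhaustive pairwise matching.

    Every predicted span is compared against every not-yet-matched gold
    span of the same sentence; identical (type, start, end) triples
    match.  Intentionally quadratic and shortcut-free.
    """
    _check_inputs(gold, predicted)
    counts = {t: [0, 0, 0] for t in ENTITY_TYPES}  # tp, fp, fn
    for g, p in zip(gold, predicted):
        gold_spans: List[EntitySpan] = list(g.entities)
        used = [False] * len(gold_spans)
        for span in tags_to_spans(p, repair="start-new"):
            hit = False
            for j, gs in enumerate(gold_spans):
                if used[j]:
                    continue
                if (gs.entity_type == span.entity_type
                        and gs.start == span.start and gs.end == span.end):
                    used[j] = True
                    hit = True
                    break
            if hit:
                counts[span.entity_type][0] += 1
            else:
                counts[span.entity_type][1] += 1
        for j, gs in enumerate(gold_spans):
            if not used[j]:
                counts[gs.entity_type][2] += 1
    return MetricReport(per_type={
        t: TypeScore(tp=c[0], fp=c[1], fn=c[2]) for t, c in counts.items()
    })
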