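"""Span-level precision/recall/F1 with exact-boundary, exact-channel matching.

A predicted span is correct iff a span with identical (channel, doc,
sentence, start, end) exists in the gold set; no partial credit. Zero
denominators are reported as 0 with an ``undefined`` flag. Human-readable
output truncates to two decimals (0.666... prints as 0.66); machine output
keeps full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

from .errors import InputError
from .lexicon import SpanAnnotation


@dataclass(frozen=True)
class PRF:
    n_gold: int
    n_pred: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_correct > min(self.n_gold, self.n_pred):
            raise InputError("n_correct exceeds min(n_gold, n_pred)")

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_gold if self.n_gold else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def precision_undefined(self) -> bool:
        return self.n_pred == 0

    @property
    def recall_undefined(self) -> bool:
        return self.n_gold == 0


@dataclass
class EvalReport:
    aggregate: PRF                 # micro average over all spans
    per_channel: dict[str, PRF]

    @property
    def macro_precision(self) -> float:
        vals = [p.precision for p in self.per_channel.values()]
        return sum(vals) / len(vals) if vals else 0.0

    @property
    def macro_recall(self) -> float:
        vals = [p.recall for p in self.per_channel.values()]
        return sum(vals) / len(vals) if vals else 0.0

    @property
    def macro_f1(self) -> float:
        vals = [p.f1 for p in self.per_channel.values()]
        return sum(vals) / len(vals) if vals else 0.0

    def to_json(self) -> str:
        def block(p: PRF) -> dict:
            return {"n_gold": p.n_gold, "n_pred": p.n_pred, "n_correct": p.n_correct,
                    "precision": p.precision, "recall": p.recall, "f1": p.f1,
                    "precision_undefined": p.precision_undefined,
                    "recall_undefined": p.recall_undefined}
        return json.dumps({
            "aggregate": block(self.aggregate),
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f1": self.macro_f1},
            "per_channel": {c: block(p) for c, p in sorted(self.per_channel.items())},
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"{'channel':<32}{'P':>8}{'R':>8}{'F1':>8}"]
        for c, p in sorted(self.per_channel.items()):
            lines.append(f"{c:<32}{trunc2(p.precision):>8}{trunc2(p.recall):>8}"
                         f"{trunc2(p.f1):>8}")
        a = self.aggregate
        lines.append(f"{'ALL (micro)':<32}{trunc2(a.precision):>8}{trunc2(a.recall):>8}"
                     f"{trunc2(a.f1):>8}")
        return "\n".join(lines) + "\n"


def trunc2(x: float) -> float:
    """Truncate toward zero at two decimals (the printing convention)."""
    return math.trunc(x * 100) / 100


def score_spans(gold: Iterable[SpanAnnotation],
                pred: Iterable[SpanAnnotation]) -> EvalReport:
    """Score predictions against gold; duplicates within a set are collapsed."""
    gold_keys = {s.key() for s in gold}
    pred_keys = {s.key() for s in pred}
    channels = {k[0] for k in gold_keys | pred_keys}
    per_channel: dict[str, PRF] = {}
    for c in sorted(channels):
        g = {k for k in gold_keys if k[0] == c}
        p = {k for k in pred_keys if k[0] == c}
        per_channel[c] = PRF(len(g), len(p), len(g & p))
    agg = PRF(len(gold_keys), len(pred_keys), len(gold_keys & pred_keys))
    return EvalReport(agg, per_channel)
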