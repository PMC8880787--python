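"""Corpus-viewer computations: occurrence rates, Welch's t-test group
comparison, KWIC concordance, and frequency tables.

The unit of analysis is the subject: one pooled per-morpheme rate per
subject per tag (tag span count / subject-speaker morpheme count over the
filtered documents). Group comparison applies Welch's two-sample t-test
with Welch-Satterthwaite degrees of freedom to the per-subject rates;
the default orientation is group A minus group B.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InputError, ReferenceError_
from .lexicon import AnnotatedCorpus, SpanAnnotation
from .morphio import Corpus, Document
from .scheme import AnnotationScheme

#: alias accepted wherever a group name is expected: both ASD subgroups pooled
GROUP_ALIASES = {"ASD": ("ASD-1", "ASD-2")}


def expand_group(group: str) -> tuple[str, ...]:
    return GROUP_ALIASES.get(group, (group,))


@dataclass(frozen=True)
class CorpusFilter:
    tasks: Optional[tuple[str, ...]] = None
    groups: Optional[tuple[str, ...]] = None
    min_age: Optional[int] = None
    max_age: Optional[int] = None

    def accepts(self, doc: Document) -> bool:
        if self.tasks is not None and doc.task_id not in self.tasks:
            return False
        if self.groups is not None:
            allowed = {g for grp in self.groups for g in expand_group(grp)}
            if doc.group not in allowed:
                return False
        if self.min_age is not None and doc.age < self.min_age:
            return False
        if self.max_age is not None and doc.age > self.max_age:
            return False
        return True


@dataclass(frozen=True)
class RateRecord:
    subject_id: str
    group: str
    tag_id: str
    count: int
    morphemes: int

    @property
    def rate(self) -> float:
        return self.count / self.morphemes


@dataclass(frozen=True)
class ComparisonRow:
    tag_id: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t: Optional[float]
    df: Optional[float]
    p: Optional[float]
    p_holm: Optional[float] = None


@dataclass(frozen=True)
class KWICHit:
    doc_id: str
    sentence_id: int
    span: tuple[int, int]
    left_context: tuple[str, ...]
    keyword: tuple[str, ...]
    right_context: tuple[str, ...]


# ---------------------------------------------------------------------------
# occurrence rates


def occurrence_rates(annotated: AnnotatedCorpus, tags: Sequence[str],
                     filt: CorpusFilter | None = None) -> list[RateRecord]:
    """One record per (subject, tag) over the filtered documents."""
    filt = filt or CorpusFilter()
    docs = [d for d in annotated.corpus if filt.accepts(d)]
    if not docs:
        warnings.warn("filter matches no documents; empty result", stacklevel=2)
        return []
    morphemes: dict[str, int] = {}
    group_of: dict[str, str] = {}
    counts: dict[tuple[str, str], int] = {}
    tagset = set(tags)
    for doc in docs:
        morphemes[doc.subject_id] = morphemes.get(doc.subject_id, 0) + doc.subject_morpheme_count()
        prev = group_of.setdefault(doc.subject_id, doc.group)
        if prev != doc.group:
            raise InputError(f"subject {doc.subject_id!r} appears in groups {prev} and {doc.group}")
        for s in annotated.spans.get(doc.doc_id, []):
            if s.tag_id in tagset:
                counts[(doc.subject_id, s.tag_id)] = counts.get((doc.subject_id, s.tag_id), 0) + 1
    out: list[RateRecord] = []
    for subject in sorted(morphemes):
        if morphemes[subject] == 0:
            continue
        for tag in tags:
            out.append(RateRecord(subject, group_of[subject], tag,
                                  counts.get((subject, tag), 0), morphemes[subject]))
    return out


# ---------------------------------------------------------------------------
# Welch's t-test


def welch_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df, and two-sided p from group summaries."""
    if n_a < 2 or n_b < 2:
        raise InputError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise InputError("standard deviations must be >= 0")
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    if va + vb == 0:
        raise DegenerateVarianceError("both samples have zero variance")
    t = (mean_a - mean_b) / math.sqrt(va + vb)
    # scale-invariant Welch-Satterthwaite form (robust to variance underflow)
    m = max(va, vb)
    ra, rb = va / m, vb / m
    df = (ra + rb) ** 2 / ((ra ** 2) / (n_a - 1) + (rb ** 2) / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


def welch_from_samples(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's test from raw samples (sample sds, ddof=1); same formulas as
    :func:`welch_from_summary`, applied to the computed summaries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("each sample needs >= 2 values")
    return welch_from_summary(float(x.mean()), float(x.std(ddof=1)), len(x),
                              float(y.mean()), float(y.std(ddof=1)), len(y))


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvalues[i])
        adjusted[i] = min(1.0, running)
    return adjusted


@dataclass
class ComparisonResult:
    rows: list[ComparisonRow]
    excluded: list[str] = field(default_factory=list)   # tags with degenerate variance

    def to_tsv(self, label_a: str = "A", label_b: str = "B",
               holm: bool = False) -> str:
        buf = io.StringIO()
        cols = ["tag", f"mean_{label_a}", f"SD_{label_a}", f"mean_{label_b}",
                f"SD_{label_b}", "t", "df", "p"]
        if holm:
            cols.append("p_holm")
        buf.write("\t".join(cols) + "\n")
        for r in self.rows:
            cells = [r.tag_id, f"{r.mean_a:.6f}", f"{r.sd_a:.6f}",
                     f"{r.mean_b:.6f}", f"{r.sd_b:.6f}",
                     "" if r.t is None else f"{r.t:.3f}",
                     "" if r.df is None else f"{r.df:.1f}",
                     "" if r.p is None else f"{r.p:.3f}"]
            if holm:
                cells.append("" if r.p_holm is None else f"{r.p_holm:.3f}")
            buf.write("\t".join(cells) + "\n")
        return buf.getvalue()


def compare_groups(annotated: AnnotatedCorpus, tags: Sequence[str],
                   filt: CorpusFilter | None, group_a: str, group_b: str,
                   holm: bool = False) -> ComparisonResult:
    """Per-tag Welch comparison of per-subject rates, group A minus group B."""
    base = filt or CorpusFilter()
    records = occurrence_rates(
        annotated, tags,
        CorpusFilter(base.tasks, tuple(expand_group(group_a) + expand_group(group_b)),
                     base.min_age, base.max_age))
    ga, gb = set(expand_group(group_a)), set(expand_group(group_b))
    rows: list[ComparisonRow] = []
    excluded: list[str] = []
    for tag in tags:
        xs = [r.rate for r in records if r.tag_id == tag and r.group in ga]
        ys = [r.rate for r in records if r.tag_id == tag and r.group in gb]
        if len(xs) < 2 or len(ys) < 2:
            raise InputError(f"tag {tag}: need >= 2 subjects per group "
                             f"(got {len(xs)}/{len(ys)})")
        mean_a, sd_a = float(np.mean(xs)), float(np.std(xs, ddof=1))
        mean_b, sd_b = float(np.mean(ys)), float(np.std(ys, ddof=1))
        try:
            t, df, p = welch_from_samples(xs, ys)
        except DegenerateVarianceError:
            excluded.append(tag)
            t = df = p = None
        rows.append(ComparisonRow(tag, mean_a, sd_a, mean_b, sd_b,
                                  len(xs), len(ys), t, df, p))
    if holm:
        defined = [r for r in rows if r.p is not None]
        adj = holm_adjust([r.p for r in defined])
        adj_map = {r.tag_id: a for r, a in zip(defined, adj)}
        rows = [ComparisonRow(r.tag_id, r.mean_a, r.sd_a, r.mean_b, r.sd_b,
                              r.n_a, r.n_b, r.t, r.df, r.p,
                              adj_map.get(r.tag_id)) for r in rows]
    return ComparisonResult(rows, excluded)


# ---------------------------------------------------------------------------
# KWIC


def kwic(corpus: Corpus, *, tag: str | None = None, surface: str | None = None,
         window: int = 5, annotated: AnnotatedCorpus | None = None,
         scheme: AnnotationScheme | None = None) -> list[KWICHit]:
    """Concordance hits for a tag (span) query or a surface-form query."""
    if (tag is None) == (surface is None):
        raise InputError("provide exactly one of tag= or surface=")
    hits: list[KWICHit] = []
    if tag is not None:
        if scheme is not None and tag not in scheme.tag_index:
            raise ReferenceError_(f"unknown tag_id {tag!r}")
        if annotated is None:
            raise InputError("tag queries require an annotated corpus")
        for doc in corpus:
            sents = {s.sentence_id: s for s in doc.sentences}
            for sp in annotated.spans.get(doc.doc_id, []):
                if sp.tag_id != tag:
                    continue
                sent = sents[sp.sentence_id]
                hits.append(_hit(doc, sent, sp.start, sp.end, window))
    else:
        for doc in corpus:
            for sent in doc.sentences:
                for i, m in enumerate(sent.morphemes):
                    if m.surface == surface:
                        hits.append(_hit(doc, sent, i, i + 1, window))
    hits.sort(key=lambda h: (h.doc_id, h.sentence_id, h.span))
    return hits


def _hit(doc: Document, sent, start: int, end: int, window: int) -> KWICHit:
    surfaces = sent.surfaces
    return KWICHit(doc.doc_id, sent.sentence_id, (start, end),
                   tuple(surfaces[max(0, start - window):start]),
                   tuple(surfaces[start:end]),
                   tuple(surfaces[end:end + window]))


def kwic_to_tsv(hits: Iterable[KWICHit]) -> str:
    buf = io.StringIO()
    buf.write("doc_id\tsentence_id\tstart\tend\tleft\tkeyword\tright\n")
    for h in hits:
        buf.write(f"{h.doc_id}\t{h.sentence_id}\t{h.span[0]}\t{h.span[1]}\t"
                  f"{' '.join(h.left_context)}\t{' '.join(h.keyword)}\t"
                  f"{' '.join(h.right_context)}\n")
    return buf.getvalue()


def kwic_to_text(hits: Iterable[KWICHit], width: int = 36) -> str:
    lines = []
    for h in hits:
        lines.append(f"{' '.join(h.left_context):>{width}} "
                     f"[{' '.join(h.keyword)}] "
                     f"{' '.join(h.right_context):<{width}}  "
                     f"({h.doc_id}:{h.sentence_id})")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# frequency tables


def freq_table(annotated: AnnotatedCorpus, grouping: str = "group",
               scheme: AnnotationScheme | None = None) -> pd.DataFrame:
    """Span counts and per-morpheme rates per cell of a one-way grouping.

    ``grouping`` is one of ``group``, ``task``, ``heading`` (the last
    requires a scheme to map tags onto headings).
    """
    if grouping not in ("group", "task", "heading"):
        raise InputError(f"unknown grouping {grouping!r}")
    if grouping == "heading" and scheme is None:
        raise InputError("heading grouping requires a scheme")
    counts: dict[str, int] = {}
    morphemes: dict[str, int] = {}
    for doc in annotated.corpus:
        if grouping != "heading":
            cell = doc.group if grouping == "group" else doc.task_id
            morphemes[cell] = morphemes.get(cell, 0) + doc.subject_morpheme_count()
        for s in annotated.spans.get(doc.doc_id, []):
            if grouping == "heading":
                cell = scheme.heading_of(s.tag_id).heading_id
            else:
                cell = doc.group if grouping == "group" else doc.task_id
            counts[cell] = counts.get(cell, 0) + 1
    if grouping == "heading":
        total = sum(d.subject_morpheme_count() for d in annotated.corpus)
        morphemes = {cell: total for cell in counts}
    cells = sorted(set(counts) | set(morphemes))
    return pd.DataFrame({
        "cell": cells,
        "count": [counts.get(c, 0) for c in cells],
        "morphemes": [morphemes.get(c, 0) for c in cells],
        "rate": [counts.get(c, 0) / morphemes[c] if morphemes.get(c) else float("nan")
                 for c in cells],
    })
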