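"""Synthetic annotated corpora with planted group-specific tag rates.

The generator walks candidate positions; every position emits one
distractor morpheme and, independently per tag with probability q, that
tag's marker sequence. q is adjusted so the realized expected per-morpheme
span rate equals the requested rate r: with one distractor per position
plus inserted sequences of length L_j, E[morphemes] per position is
1 + sum_j q_j L_j and E[spans_i] is q_i, so requiring
q_i / (1 + sum_j q_j L_j) = r_i gives q_i = r_i / (1 - sum_j r_j L_j).
Spans never overlap (insertions are atomic), so IOB2 validity holds by
construction, and the emitted lexicon reproduces the gold spans exactly.

Default shape mirrors the replication pipeline: groups TD (57 subjects)
and ASD (50, split over the two ASD subgroups), task A interviews, ages
13+, mean document length 1000 morphemes, and per-morpheme rates of order
1e-3 for the six sentence-final negotiating particles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .corpusstats import CorpusFilter, compare_groups, expand_group, occurrence_rates
from .errors import SynthSpecError
from .lexicon import (AnnotatedCorpus, Lexicon, LexiconEntry, MorphemePattern,
                      SpanAnnotation)
from .morphio import Corpus, Document, Morpheme, Sentence

DEFAULT_TAGS = ("negparticle.kana", "negparticle.kane", "negparticle.sa",
                "negparticle.ne", "negparticle.yo", "negparticle.yona")

#: per-morpheme rates of order 1e-3, the scale of the replication target
DEFAULT_RATES = {
    "TD": {"negparticle.kana": 0.003071, "negparticle.kane": 0.002423,
           "negparticle.sa": 0.0, "negparticle.ne": 0.010057,
           "negparticle.yo": 0.001900, "negparticle.yona": 0.000045},
    "ASD": {"negparticle.kana": 0.003423, "negparticle.kane": 0.001179,
            "negparticle.sa": 0.000017, "negparticle.ne": 0.005572,
            "negparticle.yo": 0.000839, "negparticle.yona": 0.000026},
}


def _default_sequences() -> dict[str, tuple[str, ...]]:
    return {tag: (tag.rsplit(".", 1)[1],) for tag in DEFAULT_TAGS}


def _default_distractors() -> tuple[str, ...]:
    return tuple(f"w{i:03d}" for i in range(200))


@dataclass(frozen=True)
class SynthSpec:
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"TD": 57, "ASD-1": 25, "ASD-2": 25})
    doc_length_mean: float = 1000.0
    doc_length_sd: float = 200.0
    sentence_length_mean: float = 14.0
    tag_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_RATES.items()})
    tag_sequences: dict[str, tuple[str, ...]] = field(default_factory=_default_sequences)
    distractors: tuple[str, ...] = field(default_factory=_default_distractors)
    task_id: str = "A"
    age_range: tuple[int, int] = (13, 45)
    seed: int = 0

    def __post_init__(self) -> None:
        seqs = {tuple(s) for s in self.tag_sequences.values()}
        if len(seqs) != len(self.tag_sequences):
            raise SynthSpecError("tag-bearing sequences must be unique")
        marker_tokens = {tok for s in self.tag_sequences.values() for tok in s}
        if marker_tokens & set(self.distractors):
            raise SynthSpecError("tag-bearing tokens must not occur among distractors")
        for g, rates in self.tag_rates.items():
            for tag, r in rates.items():
                if not (0 <= r <= 0.2):
                    raise SynthSpecError(f"rate {r} for ({g}, {tag}) outside [0, 0.2]")
                if tag not in self.tag_sequences:
                    raise SynthSpecError(f"rate given for {tag!r} without a sequence")

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(self.tag_sequences)

    def rates_for(self, group: str) -> dict[str, float]:
        """Group rates; subgroup names fall back to their pooled alias."""
        if group in self.tag_rates:
            return self.tag_rates[group]
        for alias, members in (("ASD", ("ASD-1", "ASD-2")),):
            if group in members and alias in self.tag_rates:
                return self.tag_rates[alias]
        raise SynthSpecError(f"no rates defined for group {group!r}")

    def insertion_probs(self, group: str) -> dict[str, float]:
        rates = self.rates_for(group)
        R = sum(r * len(self.tag_sequences[tag]) for tag, r in rates.items())
        if R >= 1.0:
            raise SynthSpecError(f"rates for {group!r} are infeasible (sum r*L = {R:.3f} >= 1)")
        probs = {tag: r / (1.0 - R) for tag, r in rates.items()}
        if any(q > 1.0 for q in probs.values()):
            raise SynthSpecError(f"rates for {group!r} imply insertion probability > 1")
        return probs

    def to_json(self) -> str:
        d = {
            "n_subjects_per_group": self.n_subjects_per_group,
            "doc_length_mean": self.doc_length_mean,
            "doc_length_sd": self.doc_length_sd,
            "sentence_length_mean": self.sentence_length_mean,
            "tag_rates": self.tag_rates,
            "tag_sequences": {k: list(v) for k, v in self.tag_sequences.items()},
            "distractors": list(self.distractors),
            "task_id": self.task_id,
            "age_range": list(self.age_range),
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SynthSpec":
        d = json.loads(text)
        if "tag_sequences" in d:
            d["tag_sequences"] = {k: tuple(v) for k, v in d["tag_sequences"].items()}
        if "distractors" in d:
            d["distractors"] = tuple(d["distractors"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


def load_spec(path: Union[str, Path]) -> SynthSpec:
    return SynthSpec.from_json(Path(path).read_text("utf-8"))


# ---------------------------------------------------------------------------


def emitted_lexicon(spec: SynthSpec) -> Lexicon:
    entries = [LexiconEntry(tag, tuple(MorphemePattern(surface=tok) for tok in seq))
               for tag, seq in spec.tag_sequences.items()]
    return Lexicon(entries=entries)


def _generate_document(spec: SynthSpec, rng: np.random.Generator, doc_id: str,
                       subject_id: str, group: str, age: int
                       ) -> tuple[Document, list[SpanAnnotation]]:
    tags = list(spec.tag_sequences)
    seqs = [spec.tag_sequences[t] for t in tags]
    lens = np.array([len(s) for s in seqs])
    probs = spec.insertion_probs(group)
    q = np.array([probs[t] for t in tags])

    target = max(20, int(round(rng.normal(spec.doc_length_mean, spec.doc_length_sd))))
    n_pos = max(1, int(round(target / (1.0 + float(q @ lens)))))

    insert = rng.random((n_pos, len(tags))) < q             # (positions, tags)
    d_idx = rng.integers(0, len(spec.distractors), size=n_pos)

    surfaces: list[str] = []
    kinds: list[int] = []        # -1 distractor, else tag index
    raw_spans: list[tuple[int, int, int]] = []   # (tag idx, global start, global end)
    for p in range(n_pos):
        surfaces.append(spec.distractors[d_idx[p]])
        kinds.append(-1)
        if insert[p].any():
            for ti in np.nonzero(insert[p])[0]:
                start = len(surfaces)
                surfaces.extend(seqs[ti])
                kinds.extend([ti] * lens[ti])
                raw_spans.append((int(ti), start, start + int(lens[ti])))

    total = len(surfaces)
    # sentence breaks, moved right so no span is split
    breaks: list[int] = []
    pos = 0
    span_bounds = sorted((s, e) for _, s, e in raw_spans)
    while pos < total:
        pos += max(2, int(rng.poisson(spec.sentence_length_mean)))
        for s, e in span_bounds:
            if s < pos < e:
                pos = e
                break
        breaks.append(min(pos, total))

    sentences: list[Sentence] = []
    spans: list[SpanAnnotation] = []
    start = 0
    for sid, stop in enumerate(breaks):
        morphs = [Morpheme(i, surfaces[start + i], surfaces[start + i],
                           "noun" if kinds[start + i] < 0 else "prt-final")
                  for i in range(stop - start)]
        sentences.append(Sentence(sid, "subject", morphs))
        start = stop
    sent_starts = [0] + breaks[:-1]
    for ti, s, e in raw_spans:
        sid = int(np.searchsorted(np.array(breaks), s, side="right"))
        off = sent_starts[sid]
        spans.append(SpanAnnotation(tags[ti], sid, s - off, e - off,
                                    source="manual", verified=True, doc_id=doc_id))
    spans.sort(key=lambda sp: (sp.tag_id, sp.sentence_id, sp.start))
    doc = Document(doc_id, subject_id, group, age, spec.task_id, sentences)
    return doc, spans


def generate(spec: SynthSpec) -> tuple[AnnotatedCorpus, Lexicon]:
    """Deterministically generate (annotated corpus with gold spans, lexicon)."""
    rng = np.random.default_rng(spec.seed)
    docs: list[Document] = []
    spans: dict[str, list[SpanAnnotation]] = {}
    lo, hi = spec.age_range
    for group in spec.n_subjects_per_group:
        for k in range(spec.n_subjects_per_group[group]):
            subject = f"{group}-s{k:03d}"
            doc_id = f"{subject}-d0"
            age = int(rng.integers(lo, hi + 1))
            doc, doc_spans = _generate_document(spec, rng, doc_id, subject, group, age)
            docs.append(doc)
            spans[doc_id] = doc_spans
    return AnnotatedCorpus(Corpus(docs), spans), emitted_lexicon(spec)


# ---------------------------------------------------------------------------


def recovery_report(spec: SynthSpec, replicates: int, *, alpha: float = 0.05,
                    group_a: str = "TD", group_b: str = "ASD",
                    tags: Sequence[str] | None = None) -> dict[str, dict]:
    """Per-tag rate-recovery bias and Welch rejection frequency over replicates."""
    if replicates < 2:
        raise SynthSpecError("need >= 2 replicates")
    tags = list(tags if tags is not None else spec.tags)
    est_a: dict[str, list[float]] = {t: [] for t in tags}
    est_b: dict[str, list[float]] = {t: [] for t in tags}
    rejections: dict[str, int] = {t: 0 for t in tags}
    for r in range(replicates):
        annotated, _ = generate(replace(spec, seed=spec.seed + r))
        result = compare_groups(annotated, tags, None, group_a, group_b)
        for row in result.rows:
            est_a[row.tag_id].append(row.mean_a)
            est_b[row.tag_id].append(row.mean_b)
            if row.p is not None and row.p < alpha:
                rejections[row.tag_id] += 1
    out: dict[str, dict] = {}
    ra = {t: np.mean(est_a[t]) for t in tags}
    rb = {t: np.mean(est_b[t]) for t in tags}
    rates_a = spec.rates_for(expand_group(group_a)[0])
    rates_b = spec.rates_for(expand_group(group_b)[0])
    for t in tags:
        out[t] = {
            "mean_rate_a": float(ra[t]), "mean_rate_b": float(rb[t]),
            "bias_a": float(ra[t] - rates_a[t]), "bias_b": float(rb[t] - rates_b[t]),
            "rejection_rate": rejections[t] / replicates,
        }
    return out


def write_outputs(annotated: AnnotatedCorpus, lexicon: Lexicon,
                  out_dir: Union[str, Path]) -> None:
    """Write corpus.tsv + lexicon.tsv + gold.tsv under ``out_dir``."""
    from .lexicon import write_lexicon, write_spans
    from .morphio import write_corpus
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus(annotated.corpus, out / "corpus.tsv")
    write_lexicon(lexicon, out / "lexicon.tsv")
    write_spans(annotated.all_spans(), out / "gold.tsv")
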