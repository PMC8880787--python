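"""Annotation dictionaries and dictionary-based span annotation.

A lexicon entry pairs a tag (channel) with a contiguous sequence of
morpheme constraints; each constraint may restrict surface, lemma and/or
POS (exact equality after NFKC normalization). Matching is per channel,
leftmost-longest: scan left to right, at each position take the longest
matching entry, resume after it. Channels never overlap internally;
different channels may overlap freely.

Lexicon TSV dialect: header ``tag_id<TAB>pattern``; pattern is a
``;``-joined list of constraints, each ``field=value(&field=value)*`` with
fields ``surface``, ``lemma``, ``pos``.
"""

from __future__ import annotations

import io
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import DuplicateEntryError, FormatError, ReferenceError_
from .morphio import Corpus, Document, Morpheme, Sentence
from .scheme import AnnotationScheme

_FIELDS = ("surface", "lemma", "pos")


def _norm(s: str) -> str:
    return unicodedata.normalize("NFKC", s)


@dataclass(frozen=True)
class MorphemePattern:
    surface: Optional[str] = None
    lemma: Optional[str] = None
    pos: Optional[str] = None

    def __post_init__(self) -> None:
        if self.surface is None and self.lemma is None and self.pos is None:
            raise FormatError("morpheme pattern needs at least one constraint")
        for f in _FIELDS:
            v = getattr(self, f)
            if v is not None:
                object.__setattr__(self, f, _norm(v))

    def matches(self, m: Morpheme) -> bool:
        if self.surface is not None and _norm(m.surface) != self.surface:
            return False
        if self.lemma is not None and _norm(m.lemma) != self.lemma:
            return False
        if self.pos is not None and _norm(m.pos) != self.pos:
            return False
        return True

    def to_text(self) -> str:
        parts = [f"{f}={getattr(self, f)}" for f in _FIELDS if getattr(self, f) is not None]
        return "&".join(parts)

    @classmethod
    def from_text(cls, text: str) -> "MorphemePattern":
        kwargs: dict[str, str] = {}
        for item in text.split("&"):
            if "=" not in item:
                raise FormatError(f"malformed constraint {item!r}")
            k, v = item.split("=", 1)
            if k not in _FIELDS:
                raise FormatError(f"unknown constraint field {k!r}")
            if k in kwargs:
                raise FormatError(f"repeated constraint field {k!r}")
            kwargs[k] = v
        return cls(**kwargs)


@dataclass(frozen=True)
class LexiconEntry:
    tag_id: str
    pattern: tuple[MorphemePattern, ...]

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise FormatError("lexicon entry pattern must have length >= 1")

    def pattern_text(self) -> str:
        return ";".join(p.to_text() for p in self.pattern)


@dataclass(frozen=True)
class SpanAnnotation:
    """A tagged morpheme span; coordinates are 0-based half-open per sentence."""

    tag_id: str
    sentence_id: int
    start: int
    end: int
    source: str = "dictionary"
    verified: bool = False
    doc_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid span [{self.start},{self.end})")
        if self.source not in ("dictionary", "model", "manual"):
            raise FormatError(f"unknown span source {self.source!r}")

    def key(self) -> tuple:
        return (self.tag_id, self.doc_id, self.sentence_id, self.start, self.end)


@dataclass
class Lexicon:
    entries: list[LexiconEntry] = field(default_factory=list)
    scheme: Optional[AnnotationScheme] = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for e in self.entries:
            k = (e.tag_id, e.pattern)
            if k in seen:
                raise DuplicateEntryError(f"duplicate lexicon entry {e.tag_id} {e.pattern_text()}")
            seen.add(k)
            self._check_tag(e.tag_id)

    def _check_tag(self, tag_id: str) -> None:
        if self.scheme is not None and tag_id not in self.scheme.tag_index:
            raise ReferenceError_(f"lexicon entry references unknown tag_id {tag_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def channels(self) -> list[str]:
        """Distinct tag_ids in first-appearance order."""
        out: dict[str, None] = {}
        for e in self.entries:
            out.setdefault(e.tag_id, None)
        return list(out)

    def by_dictionary(self) -> dict[str, list[LexiconEntry]]:
        """Entries grouped per dictionary (requires a governing scheme)."""
        if self.scheme is None:
            raise ReferenceError_("grouping by dictionary requires a scheme")
        out: dict[str, list[LexiconEntry]] = {}
        for e in self.entries:
            dname = self.scheme.heading_of(e.tag_id).dictionary_name
            out.setdefault(dname, []).append(e)
        return out


def add_entry(lexicon: Lexicon, entry: LexiconEntry) -> Lexicon:
    """Return a new lexicon with ``entry`` appended (duplicate -> error)."""
    if (entry.tag_id, entry.pattern) in {(e.tag_id, e.pattern) for e in lexicon.entries}:
        raise DuplicateEntryError(f"entry already present: {entry.tag_id} {entry.pattern_text()}")
    lexicon._check_tag(entry.tag_id)
    return replace(lexicon, entries=lexicon.entries + [entry])


# ---------------------------------------------------------------------------
# I/O

def parse_lexicon(text: str, scheme: Optional[AnnotationScheme] = None,
                  origin: str = "<string>") -> Lexicon:
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["tag_id", "pattern"]:
        raise FormatError(f"{origin}: missing 'tag_id\\tpattern' header")
    entries: list[LexiconEntry] = []
    seen: dict[tuple, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise FormatError(f"{origin}:{lineno}: expected 2 columns, got {len(cells)}")
        tag_id, pat_text = cells
        pattern = tuple(MorphemePattern.from_text(p) for p in pat_text.split(";"))
        k = (tag_id, pattern)
        if k in seen:
            raise DuplicateEntryError(
                f"{origin}: duplicate entry at lines {seen[k]} and {lineno}: {tag_id} {pat_text}")
        seen[k] = lineno
        entries.append(LexiconEntry(tag_id, pattern))
    return Lexicon(entries=entries, scheme=scheme)


def load_lexicon(path: Union[str, Path, None], scheme: Optional[AnnotationScheme] = None) -> Lexicon:
    """Load one lexicon TSV, a directory of them, or (``path=None``) the
    bundled dictionaries."""
    if path is None:
        root = resources.files("pragtag.data").joinpath("dictionaries")
        entries: list[LexiconEntry] = []
        for f in sorted(root.iterdir(), key=lambda p: p.name):
            if f.name.endswith(".tsv"):
                part = parse_lexicon(f.read_text("utf-8"), scheme, origin=f.name)
                entries.extend(part.entries)
        return Lexicon(entries=entries, scheme=scheme)
    p = Path(path)
    if p.is_dir():
        entries = []
        for f in sorted(p.glob("*.tsv")):
            entries.extend(parse_lexicon(f.read_text("utf-8"), scheme, origin=str(f)).entries)
        return Lexicon(entries=entries, scheme=scheme)
    try:
        text = p.read_text("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{p} is not UTF-8: {exc}") from exc
    return parse_lexicon(text, scheme, origin=str(p))


def write_lexicon(lexicon: Lexicon, path: Union[str, Path]) -> None:
    buf = io.StringIO()
    buf.write("tag_id\tpattern\n")
    for e in lexicon.entries:
        buf.write(f"{e.tag_id}\t{e.pattern_text()}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# matching

def _match_at(entry: LexiconEntry, morphemes: list[Morpheme], i: int) -> bool:
    if i + len(entry.pattern) > len(morphemes):
        return False
    return all(p.matches(morphemes[i + k]) for k, p in enumerate(entry.pattern))


def annotate_sentence(sentence: Sentence, lexicon: Lexicon,
                      doc_id: Optional[str] = None) -> list[SpanAnnotation]:
    """Leftmost-longest dictionary annotation of one sentence, per channel."""
    spans: list[SpanAnnotation] = []
    morphemes = sentence.morphemes
    for tag_id in sorted(lexicon.channels):
        entries = [e for e in lexicon.entries if e.tag_id == tag_id]
        i = 0
        while i < len(morphemes):
            best = 0
            for e in entries:
                if len(e.pattern) > best and _match_at(e, morphemes, i):
                    best = len(e.pattern)
            if best:
                spans.append(SpanAnnotation(tag_id, sentence.sentence_id, i, i + best,
                                            source="dictionary", verified=False, doc_id=doc_id))
                i += best
            else:
                i += 1
    return spans


def annotate_document(doc: Document, lexicon: Lexicon) -> list[SpanAnnotation]:
    """All dictionary spans of a document, sorted by (channel, sentence, start)."""
    spans: list[SpanAnnotation] = []
    for sent in doc.sentences:
        spans.extend(annotate_sentence(sent, lexicon, doc_id=doc.doc_id))
    spans.sort(key=lambda s: (s.tag_id, s.sentence_id, s.start))
    return spans


@dataclass
class AnnotatedCorpus:
    """A corpus together with its span annotations, keyed by doc_id."""

    corpus: Corpus
    spans: dict[str, list[SpanAnnotation]] = field(default_factory=dict)

    def all_spans(self) -> list[SpanAnnotation]:
        out: list[SpanAnnotation] = []
        for doc in self.corpus:
            out.extend(self.spans.get(doc.doc_id, []))
        return out


def annotate_corpus(corpus: Corpus, lexicon: Lexicon) -> AnnotatedCorpus:
    return AnnotatedCorpus(corpus, {d.doc_id: annotate_document(d, lexicon) for d in corpus})


# ---------------------------------------------------------------------------
# span TSV I/O (the editable verification surface)

_SPAN_HEADER = ["doc_id", "sentence_id", "tag_id", "start", "end", "source", "verified"]


def spans_to_string(spans: Iterable[SpanAnnotation]) -> str:
    buf = io.StringIO()
    buf.write("\t".join(_SPAN_HEADER) + "\n")
    for s in spans:
        buf.write(f"{s.doc_id or ''}\t{s.sentence_id}\t{s.tag_id}\t{s.start}\t{s.end}"
                  f"\t{s.source}\t{int(s.verified)}\n")
    return buf.getvalue()


def write_spans(spans: Iterable[SpanAnnotation], path: Union[str, Path]) -> None:
    Path(path).write_text(spans_to_string(spans), encoding="utf-8", newline="\n")


def read_spans(path: Union[str, Path]) -> list[SpanAnnotation]:
    lines = Path(path).read_text("utf-8").splitlines()
    if not lines or lines[0].split("\t") != _SPAN_HEADER:
        raise FormatError(f"{path}: missing span header")
    out: list[SpanAnnotation] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(_SPAN_HEADER):
            raise FormatError(f"{path}:{lineno}: expected {len(_SPAN_HEADER)} columns")
        doc_id, sid, tag_id, start, end, source, verified = cells
        out.append(SpanAnnotation(tag_id, int(sid), int(start), int(end), source,
                                  bool(int(verified)), doc_id or None))
    return out
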