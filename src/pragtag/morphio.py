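"""Reader/writer for morphologically analyzed, metadata-bearing transcripts.

PRAGMA-TSV dialect (UTF-8, LF):

* one ``#!pragma-tsv 1`` version comment at the top of a file,
* per document a header block of ``#key=value`` lines (keys: ``age``,
  ``doc_id``, ``group``, ``subject_id``, ``task``; canonical writer sorts
  them alphabetically),
* then sentence blocks separated by exactly one blank line; every morpheme
  line is ``surface<TAB>lemma<TAB>pos<TAB>pos_detail<TAB>speaker``.

Only subject-speaker morphemes count toward analysis totals; examiner
turns are kept for concordance context.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

from .errors import FormatError

GROUPS = ("ASD-1", "ASD-2", "TD")
TASKS = ("A", "E", "D", "DG", "P", "CT", "SM", "H", "I", "B", "C", "G")
SPEAKERS = ("subject", "examiner")

_VERSION_LINE = "#!pragma-tsv 1"
_HEADER_KEYS = ("age", "doc_id", "group", "subject_id", "task")


@dataclass(slots=True)
class Morpheme:
    index: int
    surface: str
    lemma: str
    pos: str
    pos_detail: str = ""

    def __post_init__(self) -> None:
        if not self.surface:
            raise FormatError("morpheme surface must be non-empty")


@dataclass(slots=True)
class Sentence:
    sentence_id: int
    speaker: str
    morphemes: list[Morpheme]

    def __post_init__(self) -> None:
        if self.speaker not in SPEAKERS:
            raise FormatError(f"unknown speaker {self.speaker!r}")
        for i, m in enumerate(self.morphemes):
            if m.index != i:
                raise FormatError(
                    f"sentence {self.sentence_id}: morpheme indices not contiguous "
                    f"(expected {i}, got {m.index})"
                )

    def __len__(self) -> int:
        return len(self.morphemes)

    @property
    def surfaces(self) -> list[str]:
        return [m.surface for m in self.morphemes]


@dataclass
class Document:
    doc_id: str
    subject_id: str
    group: str
    age: int
    task_id: str
    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r} (expected one of {GROUPS})")
        if self.task_id not in TASKS:
            raise FormatError(f"unknown task {self.task_id!r} (expected one of {TASKS})")
        if self.age < 0:
            raise FormatError(f"age must be >= 0, got {self.age}")

    def subject_morpheme_count(self) -> int:
        return sum(len(s) for s in self.sentences if s.speaker == "subject")


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise FormatError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def get(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


# ---------------------------------------------------------------------------
# reading

def read_corpus(path: Union[str, Path]) -> Corpus:
    """Read one PRAGMA-TSV file or every ``*.tsv`` file in a directory."""
    p = Path(path)
    if p.is_dir():
        docs: list[Document] = []
        for f in sorted(p.glob("*.tsv")):
            docs.extend(read_corpus(f).documents)
        return Corpus(docs)
    try:
        text = p.read_text("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{p} is not UTF-8: {exc}") from exc
    return parse_corpus(text, origin=str(p))


def parse_corpus(text: str, origin: str = "<string>") -> Corpus:
    lines = text.splitlines()
    docs: list[Document] = []
    header: dict[str, str] = {}
    sentences: list[Sentence] = []
    cur_rows: list[tuple[str, str, str, str, str]] = []
    in_doc = False

    def flush_sentence() -> None:
        if not cur_rows:
            return
        speakers = {r[4] for r in cur_rows}
        if len(speakers) > 1:
            raise FormatError(f"{origin}: mixed speakers within one sentence: {sorted(speakers)}")
        morphs = [Morpheme(i, s, l, pos, det) for i, (s, l, pos, det, _) in enumerate(cur_rows)]
        sentences.append(Sentence(len(sentences), cur_rows[0][4], morphs))
        cur_rows.clear()

    def flush_document() -> None:
        nonlocal header, sentences, in_doc
        flush_sentence()
        if not in_doc:
            return
        missing = [k for k in ("doc_id", "subject_id", "group", "age", "task") if k not in header]
        if missing:
            raise FormatError(f"{origin}: document header missing required keys {missing}")
        try:
            age = int(header["age"])
        except ValueError as exc:
            raise FormatError(f"{origin}: bad age {header['age']!r}") from exc
        docs.append(Document(
            doc_id=header["doc_id"], subject_id=header["subject_id"],
            group=header["group"], age=age, task_id=header["task"],
            sentences=list(sentences)))
        header, sentences = {}, []
        in_doc = False

    for lineno, raw in enumerate(lines, start=1):
        if raw.startswith("#!"):
            continue
        if raw.startswith("#"):
            if cur_rows or sentences:
                flush_document()
            body = raw[1:]
            if "=" not in body:
                raise FormatError(f"{origin}:{lineno}: malformed header line {raw!r}")
            key, value = body.split("=", 1)
            key = key.strip()
            if key not in _HEADER_KEYS:
                raise FormatError(f"{origin}:{lineno}: unknown header key {key!r}")
            if key in header:
                flush_document()
            header[key] = value.strip()
            in_doc = True
            continue
        if not raw.strip():
            flush_sentence()
            continue
        cells = raw.split("\t")
        if len(cells) != 5:
            raise FormatError(f"{origin}:{lineno}: expected 5 columns, got {len(cells)}")
        if not in_doc:
            raise FormatError(f"{origin}:{lineno}: morpheme line before any document header")
        cur_rows.append(tuple(cells))  # type: ignore[arg-type]
    flush_document()
    return Corpus(docs)


# ---------------------------------------------------------------------------
# writing

def corpus_to_string(corpus: Corpus) -> str:
    buf = io.StringIO()
    buf.write(_VERSION_LINE + "\n")
    for doc in corpus:
        meta = {"age": str(doc.age), "doc_id": doc.doc_id, "group": doc.group,
                "subject_id": doc.subject_id, "task": doc.task_id}
        for key in sorted(meta):
            buf.write(f"#{key}={meta[key]}\n")
        for si, sent in enumerate(doc.sentences):
            if si:
                buf.write("\n")
            for m in sent.morphemes:
                buf.write(f"{m.surface}\t{m.lemma}\t{m.pos}\t{m.pos_detail}\t{sent.speaker}\n")
    return buf.getvalue()


def write_corpus(corpus: Corpus, path: Union[str, Path]) -> None:
    Path(path).write_text(corpus_to_string(corpus), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# summaries and converters

def corpus_summary(corpus: Corpus) -> dict:
    """Document, per-group subject, and morpheme totals (subject speech only)."""
    subjects_per_group: dict[str, set[str]] = {}
    morphemes = 0
    for doc in corpus:
        subjects_per_group.setdefault(doc.group, set()).add(doc.subject_id)
        morphemes += doc.subject_morpheme_count()
    return {
        "documents": len(corpus),
        "subjects": len({d.subject_id for d in corpus}),
        "subjects_per_group": {g: len(s) for g, s in sorted(subjects_per_group.items())},
        "morphemes": morphemes,
    }


def convert_mecab(lines: Iterator[str] | list[str], *, speaker: str = "subject") -> list[Sentence]:
    """Convert raw MeCab/UniDic output lines into sentences.

    Each input line is ``surface<TAB>feature1,feature2,...`` where feature1
    is the coarse POS and the 7th feature, when present, is the lemma
    (classic ipadic-style feature layout). ``EOS`` lines close a sentence.
    """
    sentences: list[Sentence] = []
    cur: list[Morpheme] = []
    for raw in lines:
        line = raw.rstrip("\n")
        if line == "EOS" or not line:
            if cur:
                sentences.append(Sentence(len(sentences), speaker, cur))
                cur = []
            continue
        if "\t" not in line:
            raise FormatError(f"malformed analyzer line {line!r}")
        surface, feats = line.split("\t", 1)
        fields = feats.split(",")
        pos = fields[0] if fields else ""
        lemma = fields[6] if len(fields) > 6 and fields[6] != "*" else surface
        detail = fields[1] if len(fields) > 1 and fields[1] != "*" else ""
        cur.append(Morpheme(len(cur), surface, lemma, pos, detail))
    if cur:
        sentences.append(Sentence(len(sentences), speaker, cur))
    return sentences
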