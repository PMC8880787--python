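"""Annotation scheme: the tag-type inventory that defines every channel.

The scheme is a flat tagset organized under headings; each heading belongs
to one of two metafunctions (ideational / interpersonal) and maps to one
annotation dictionary. Several headings may share a dictionary, which is
why the bundled scheme has 16 headings but 15 dictionaries.

Scheme TSV dialect (UTF-8, LF, tab-separated)::

    metafunction  heading_id  heading_name  dictionary  tag_id  tag_name  notes

one row per tag type; heading rows are implied by their first tag row and
file order is preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import SchemaError

METAFUNCTIONS = ("ideational", "interpersonal")

_HEADER = ["metafunction", "heading_id", "heading_name", "dictionary", "tag_id", "tag_name", "notes"]


@dataclass(frozen=True)
class Heading:
    heading_id: str
    name: str
    metafunction: str
    dictionary_name: str

    def __post_init__(self) -> None:
        if self.metafunction not in METAFUNCTIONS:
            raise SchemaError(
                f"unknown metafunction {self.metafunction!r} for heading "
                f"{self.heading_id!r} (textual is out of scope)"
            )


@dataclass(frozen=True)
class TagType:
    tag_id: str
    heading_id: str
    name: str
    notes: str = ""


@dataclass
class AnnotationScheme:
    """Ordered collection of headings and tag types with resolved references."""

    headings: list[Heading] = field(default_factory=list)
    tag_types: list[TagType] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------

    @property
    def heading_index(self) -> dict[str, Heading]:
        return {h.heading_id: h for h in self.headings}

    @property
    def tag_index(self) -> dict[str, TagType]:
        return {t.tag_id: t for t in self.tag_types}

    @property
    def dictionary_names(self) -> list[str]:
        """Distinct dictionary names in heading order."""
        seen: dict[str, None] = {}
        for h in self.headings:
            seen.setdefault(h.dictionary_name, None)
        return list(seen)

    def heading_of(self, tag_id: str) -> Heading:
        tag = self.tag_index.get(tag_id)
        if tag is None:
            raise SchemaError(f"unknown tag_id {tag_id!r}")
        return self.heading_index[tag.heading_id]

    def tags_of_heading(self, heading_id: str) -> list[TagType]:
        return [t for t in self.tag_types if t.heading_id == heading_id]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        seen_h: set[str] = set()
        for h in self.headings:
            if h.heading_id in seen_h:
                raise SchemaError(f"duplicate heading_id {h.heading_id!r}")
            seen_h.add(h.heading_id)
        seen_t: set[str] = set()
        for t in self.tag_types:
            if t.tag_id in seen_t:
                raise SchemaError(f"duplicate tag_id {t.tag_id!r}")
            seen_t.add(t.tag_id)
            if t.heading_id not in seen_h:
                raise SchemaError(
                    f"tag {t.tag_id!r} references unknown heading {t.heading_id!r}"
                )
        used = {t.heading_id for t in self.tag_types}
        orphans = seen_h - used
        if orphans and self.tag_types:
            raise SchemaError(f"headings without tag types: {sorted(orphans)}")


def load_scheme(path: Union[str, Path, None] = None) -> AnnotationScheme:
    """Load a scheme TSV; ``path=None`` loads the bundled scheme."""
    if path is None:
        text = resources.files("pragtag.data").joinpath("scheme_paper.tsv").read_text("utf-8")
    else:
        try:
            text = Path(path).read_text("utf-8")
        except UnicodeDecodeError as exc:
            raise SchemaError(f"scheme file {path} is not UTF-8: {exc}") from exc
    return parse_scheme(text)


def parse_scheme(text: str) -> AnnotationScheme:
    lines = text.splitlines()
    if not lines:
        raise SchemaError("empty scheme file (missing header row)")
    header = lines[0].split("\t")
    if header != _HEADER:
        raise SchemaError(f"bad scheme header {header!r}; expected {_HEADER!r}")
    headings: list[Heading] = []
    seen_heading: dict[str, Heading] = {}
    tags: list[TagType] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(_HEADER):
            raise SchemaError(f"line {lineno}: expected {len(_HEADER)} columns, got {len(cells)}")
        meta, hid, hname, dname, tag_id, tag_name, notes = cells
        if hid in seen_heading:
            h = seen_heading[hid]
            if (h.name, h.metafunction, h.dictionary_name) != (hname, meta, dname):
                raise SchemaError(f"line {lineno}: heading {hid!r} redefined inconsistently")
        else:
            h = Heading(hid, hname, meta, dname)
            seen_heading[hid] = h
            headings.append(h)
        tags.append(TagType(tag_id, hid, tag_name, notes))
    return AnnotationScheme(headings=headings, tag_types=tags)


def write_scheme(scheme: AnnotationScheme, path: Union[str, Path]) -> None:
    """Serialize a scheme back to the TSV dialect (inverse of load)."""
    buf = io.StringIO()
    buf.write("\t".join(_HEADER) + "\n")
    hidx = scheme.heading_index
    for t in scheme.tag_types:
        h = hidx[t.heading_id]
        buf.write("\t".join([h.metafunction, h.heading_id, h.name, h.dictionary_name,
                             t.tag_id, t.name, t.notes]) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def summarize_scheme(scheme: AnnotationScheme) -> pd.DataFrame:
    """One row per heading: heading, metafunction, dictionary, tag count."""
    rows = []
    for h in scheme.headings:
        rows.append({
            "heading_id": h.heading_id,
            "heading_name": h.name,
            "metafunction": h.metafunction,
            "dictionary": h.dictionary_name,
            "n_tag_types": len(scheme.tags_of_heading(h.heading_id)),
        })
    return pd.DataFrame(rows, columns=["heading_id", "heading_name", "metafunction",
                                       "dictionary", "n_tag_types"])


def channels(scheme: AnnotationScheme, tags: Iterable[str] | None = None) -> list[str]:
    """Scheme-ordered channel list, optionally restricted to ``tags``.

    ``tags`` may contain glob-style ``prefix.*`` patterns.
    """
    if tags is None:
        return [t.tag_id for t in scheme.tag_types]
    wanted = list(tags)
    out: list[str] = []
    for t in scheme.tag_types:
        for w in wanted:
            if t.tag_id == w or (w.endswith(".*") and t.tag_id.startswith(w[:-1])):
                out.append(t.tag_id)
                break
    unknown = [w for w in wanted if not w.endswith(".*")
               and w not in {t.tag_id for t in scheme.tag_types}]
    if unknown:
        raise SchemaError(f"unknown tag_ids: {unknown}")
    return out
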