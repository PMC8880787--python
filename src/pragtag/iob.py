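"""Multi-channel IOB2 label matrices and span <-> matrix conversion.

One independent IOB2 row per channel (tag type): a C x T grid with cells
O/B/I. Within a channel spans cannot overlap; across channels they may.
Invalid rows coming out of a model (orphan I with no preceding B/I) are
repaired by promoting the orphan I to B, and the repair is reported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import FormatError, SpanBoundsError, SpanOverlapError
from .lexicon import SpanAnnotation

O, B, I = 0, 1, 2
LABELS = ("O", "B", "I")


@dataclass
class LabelMatrix:
    """C x T grid of IOB2 codes (0=O, 1=B, 2=I), one row per channel."""

    channels: list[str]
    labels: np.ndarray  # int8, shape (C, T)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.channels):
            raise FormatError(
                f"label grid shape {self.labels.shape} does not match "
                f"{len(self.channels)} channels")
        if self.labels.size and not np.isin(self.labels, (O, B, I)).all():
            raise FormatError("label cells must be in {O,B,I}")

    @property
    def T(self) -> int:
        return self.labels.shape[1]

    @property
    def C(self) -> int:
        return self.labels.shape[0]

    def row(self, channel: str) -> np.ndarray:
        return self.labels[self.channels.index(channel)]


@dataclass
class RepairReport:
    """Orphan-I positions promoted to B during decoding, per channel."""

    repaired: list[tuple[str, int]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.repaired)


def encode_spans(spans: Iterable[SpanAnnotation], T: int,
                 channels: Sequence[str]) -> LabelMatrix:
    """Encode within-channel non-overlapping spans as a C x T IOB2 matrix."""
    channels = list(channels)
    idx = {c: i for i, c in enumerate(channels)}
    grid = np.zeros((len(channels), T), dtype=np.int8)
    for s in spans:
        if s.tag_id not in idx:
            raise FormatError(f"span channel {s.tag_id!r} not in channel list")
        if s.end > T:
            raise SpanBoundsError(f"span [{s.start},{s.end}) exceeds T={T}")
        row = grid[idx[s.tag_id]]
        if row[s.start:s.end].any():
            raise SpanOverlapError(
                f"channel {s.tag_id}: span [{s.start},{s.end}) overlaps an earlier span")
        row[s.start] = B
        row[s.start + 1:s.end] = I
    return LabelMatrix(channels, grid)


def decode_matrix(matrix: LabelMatrix, *, sentence_id: int = 0,
                  doc_id: str | None = None, source: str = "model",
                  verified: bool = False) -> tuple[list[SpanAnnotation], RepairReport]:
    """Decode maximal B(I)* runs into spans, repairing orphan I as B."""
    report = RepairReport()
    spans: list[SpanAnnotation] = []
    for ci, channel in enumerate(matrix.channels):
        row = matrix.labels[ci]
        start: int | None = None
        for t in range(matrix.T):
            lab = row[t]
            if lab == I and start is None:
                report.repaired.append((channel, t))
                lab = B
            if lab == B:
                if start is not None:
                    spans.append(SpanAnnotation(channel, sentence_id, start, t,
                                                source, verified, doc_id))
                start = t
            elif lab == O:
                if start is not None:
                    spans.append(SpanAnnotation(channel, sentence_id, start, t,
                                                source, verified, doc_id))
                    start = None
        if start is not None:
            spans.append(SpanAnnotation(channel, sentence_id, start, matrix.T,
                                        source, verified, doc_id))
    spans.sort(key=lambda s: (s.tag_id, s.start))
    return spans, report


def validate_matrix(matrix: LabelMatrix) -> list[tuple[str, int]]:
    """Orphan-I positions, one (channel, index) per violation; empty iff valid."""
    violations: list[tuple[str, int]] = []
    for ci, channel in enumerate(matrix.channels):
        row = matrix.labels[ci]
        for t in range(matrix.T):
            if row[t] == I and (t == 0 or row[t - 1] == O):
                violations.append((channel, t))
    return violations


# ---------------------------------------------------------------------------
# TSV export: one line per token, one column per channel

def matrix_to_string(matrix: LabelMatrix) -> str:
    buf = io.StringIO()
    buf.write("\t".join(matrix.channels) + "\n")
    for t in range(matrix.T):
        buf.write("\t".join(LABELS[matrix.labels[c, t]] for c in range(matrix.C)) + "\n")
    return buf.getvalue()


def write_matrix(matrix: LabelMatrix, path: Union[str, Path]) -> None:
    Path(path).write_text(matrix_to_string(matrix), encoding="utf-8", newline="\n")


def parse_matrix(text: str) -> LabelMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty matrix file")
    channels = lines[0].split("\t")
    code = {lab: i for i, lab in enumerate(LABELS)}
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(channels):
            raise FormatError("matrix row width does not match channel header")
        rows.append([code[c] for c in cells])
    grid = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(channels), 0), np.int8)
    return LabelMatrix(channels, grid)
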