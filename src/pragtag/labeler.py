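"""Trainable sequence labeler: morpheme stream -> C x T IOB2 matrix.

The default backend is a one-layer Bi-LSTM over surface-form embeddings
(randomly initialized, trained with Adam; see :mod:`pragtag._bilstm`); a
per-channel first-order structured perceptron ships behind the same
interface for dependency-light smoke testing. Splitting, initialization
and batch order are all driven by explicit seeds.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from ._bilstm import BiLSTMTagger
from .errors import InputError
from .evalmetrics import score_spans
from .iob import LabelMatrix, RepairReport, decode_matrix, encode_spans
from .lexicon import AnnotatedCorpus, SpanAnnotation
from .morphio import Corpus, Document

PAD, UNK = "<pad>", "<unk>"


@dataclass(frozen=True)
class LabelerConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    embed_dim: int = 300
    hidden_dim: int = 300
    seed: int = 0
    optimizer: str = "adam"
    backend: str = "bilstm"          # bilstm | perceptron

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.embed_dim, self.hidden_dim) <= 0:
            raise InputError("all size parameters must be positive")
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise InputError(f"unsupported optimizer {self.optimizer!r}")
        if self.backend not in ("bilstm", "perceptron"):
            raise InputError(f"unsupported backend {self.backend!r}")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0
    unit: str = "document"

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios) or sum(self.ratios) <= 0:
            raise InputError("split ratios must be non-negative with positive sum")
        if self.unit != "document":
            raise InputError("only document-level splitting is supported")


def split_sizes(n: int, ratios: Sequence[float]) -> tuple[int, int, int]:
    """Ratio-proportional sizes; remainder goes train-first, then dev, test."""
    total = sum(ratios)
    base = [int(n * r / total) for r in ratios]
    rem = n - sum(base)
    for i in range(rem):
        base[i % 3] += 1
    return tuple(base)  # type: ignore[return-value]


def split_corpus(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus, Corpus]:
    if len(corpus) == 0:
        raise InputError("cannot split an empty corpus")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(corpus))
    n_train, n_dev, _ = split_sizes(len(corpus), spec.ratios)
    docs = [corpus.documents[i] for i in order]
    return (Corpus(docs[:n_train]),
            Corpus(docs[n_train:n_train + n_dev]),
            Corpus(docs[n_train + n_dev:]))


# ---------------------------------------------------------------------------


@dataclass
class TrainedLabeler:
    backend: object                       # BiLSTMTagger or _Perceptron
    vocabulary: dict[str, int]            # surface -> index, with <pad>/<unk>
    channels: list[str]
    config: LabelerConfig
    training_log: list[dict] = field(default_factory=list)


@dataclass
class PredictionResult:
    matrices: list[LabelMatrix]
    spans: list[SpanAnnotation]
    repairs: RepairReport


def _build_vocab(docs: Sequence[Document]) -> dict[str, int]:
    vocab = {PAD: 0, UNK: 1}
    for doc in docs:
        for sent in doc.sentences:
            for m in sent.morphemes:
                vocab.setdefault(m.surface, len(vocab))
    return vocab


def _sentence_examples(annotated: AnnotatedCorpus, channels: list[str]):
    """Yield (doc_id, sentence, gold label array (T,C)) triples."""
    chset = set(channels)
    for doc in annotated.corpus:
        by_sent: dict[int, list[SpanAnnotation]] = {}
        for s in annotated.spans.get(doc.doc_id, []):
            if s.tag_id in chset:
                by_sent.setdefault(s.sentence_id, []).append(s)
        for sent in doc.sentences:
            mat = encode_spans(by_sent.get(sent.sentence_id, []), len(sent), channels)
            yield doc.doc_id, sent, mat.labels.T.copy()  # (T,C)


def _encode_ids(surfaces: Sequence[str], vocab: dict[str, int]) -> np.ndarray:
    unk = vocab[UNK]
    return np.array([vocab.get(s, unk) for s in surfaces], dtype=np.int64)


def train(train_set: AnnotatedCorpus, dev_set: AnnotatedCorpus | None,
          channels: Sequence[str], config: LabelerConfig = LabelerConfig()) -> TrainedLabeler:
    """Fit the labeler on gold-annotated documents.

    Model selection keeps the best-dev-F1 epoch (ties -> earliest); without a
    dev set the final epoch is kept.
    """
    channels = list(channels)
    examples = list(_sentence_examples(train_set, channels))
    if not examples or not any(len(s) for _, s, _ in examples):
        raise InputError("empty training set")
    seen = {c for _, _, y in examples for c in np.array(channels)[np.unique(np.nonzero(y)[1])]}
    missing = [c for c in channels if c not in seen]
    if missing:
        warnings.warn(f"channels absent from gold annotations: {missing}", stacklevel=2)

    vocab = _build_vocab(train_set.corpus.documents)
    rng = np.random.default_rng(config.seed)

    if config.backend == "perceptron":
        return _train_perceptron(examples, dev_set, channels, vocab, config, rng)

    model = BiLSTMTagger(len(vocab), config.embed_dim, config.hidden_dim,
                         len(channels), rng)
    labeler = TrainedLabeler(model, vocab, channels, config)
    xs = [_encode_ids(s.surfaces, vocab) for _, s, _ in examples]
    ys = [y for _, _, y in examples]
    n = len(xs)
    best_f1, best_state = -1.0, None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        total_loss, n_batches = 0.0, 0
        for lo in range(0, n, config.batch_size):
            batch = [i for i in order[lo:lo + config.batch_size] if len(xs[i])]
            if not batch:
                continue
            T = max(len(xs[i]) for i in batch)
            B = len(batch)
            ids = np.zeros((B, T), dtype=np.int64)
            mask = np.zeros((B, T))
            y = np.zeros((B, T, len(channels)), dtype=np.int64)
            for bi, i in enumerate(batch):
                L = len(xs[i])
                ids[bi, :L] = xs[i]
                mask[bi, :L] = 1.0
                y[bi, :L] = ys[i]
            loss, grads = model.loss_and_grads(ids, mask, y)
            model.adam_step(grads, config.learning_rate)
            total_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "loss": total_loss / max(n_batches, 1)}
        if dev_set is not None and len(dev_set.corpus) > 0:
            entry["dev_f1"] = _dev_f1(labeler, dev_set, channels)
            if entry["dev_f1"] > best_f1:
                best_f1, best_state = entry["dev_f1"], model.state_copy()
        labeler.training_log.append(entry)
    if best_state is not None:
        model.load_state(best_state)
    return labeler


def _dev_f1(labeler: TrainedLabeler, dev_set: AnnotatedCorpus,
            channels: Sequence[str]) -> float:
    chset = set(channels)
    gold = [s for s in dev_set.all_spans() if s.tag_id in chset]
    pred: list[SpanAnnotation] = []
    for doc in dev_set.corpus:
        pred.extend(predict(labeler, doc).spans)
    return score_spans(gold, pred).aggregate.f1


def predict(labeler: TrainedLabeler, doc: Document) -> PredictionResult:
    """Per-sentence label matrices plus decoded spans (source=model)."""
    matrices: list[LabelMatrix] = []
    spans: list[SpanAnnotation] = []
    repairs = RepairReport()
    for sent in doc.sentences:
        if len(sent) == 0:
            matrices.append(LabelMatrix(list(labeler.channels),
                                        np.zeros((len(labeler.channels), 0), np.int8)))
            continue
        if isinstance(labeler.backend, BiLSTMTagger):
            ids = _encode_ids(sent.surfaces, labeler.vocabulary)[None, :]
            mask = np.ones_like(ids, dtype=float)
            labels = labeler.backend.predict_labels(ids, mask)[0]  # (T,C)
            grid = labels.T.astype(np.int8)
        else:
            grid = labeler.backend.predict_grid(sent)
        mat = LabelMatrix(list(labeler.channels), grid)
        decoded, rep = decode_matrix(mat, sentence_id=sent.sentence_id,
                                     doc_id=doc.doc_id, source="model")
        matrices.append(mat)
        spans.extend(decoded)
        repairs.repaired.extend(rep.repaired)
    return PredictionResult(matrices, spans, repairs)


# ---------------------------------------------------------------------------
# structured perceptron fallback


class _Perceptron:
    """Per-channel first-order averaged structured perceptron over O/B/I."""

    def __init__(self, channels: list[str]):
        self.channels = channels
        self.w: dict[tuple, float] = {}
        self._acc: dict[tuple, float] = {}
        self._steps = 0
        self.averaged = False

    @staticmethod
    def _feats(sent, t: int) -> list[tuple]:
        ms = sent.morphemes
        out = [("w", ms[t].surface), ("lem", ms[t].lemma), ("pos", ms[t].pos),
               ("wm1", ms[t - 1].surface if t else "<s>"),
               ("wp1", ms[t + 1].surface if t + 1 < len(ms) else "</s>")]
        return out

    def _score(self, c: int, feats: list[tuple], prev: int, lab: int) -> float:
        w = self.w
        s = w.get((c, "t", prev, lab), 0.0)
        for f in feats:
            s += w.get((c, f, lab), 0.0)
        return s

    def _viterbi(self, sent, c: int) -> list[int]:
        T = len(sent)
        feats = [self._feats(sent, t) for t in range(T)]
        delta = np.full((T, 3), -np.inf)
        back = np.zeros((T, 3), dtype=int)
        for lab in range(3):
            delta[0, lab] = self._score(c, feats[0], -1, lab)
        delta[0, 2] = -np.inf  # no orphan I at start
        for t in range(1, T):
            for lab in range(3):
                scores = [delta[t - 1, p] + self._score(c, feats[t], p, lab)
                          for p in range(3)]
                if lab == 2:  # I requires previous B or I
                    scores[0] = -np.inf
                back[t, lab] = int(np.argmax(scores))
                delta[t, lab] = scores[back[t, lab]]
        path = [int(np.argmax(delta[T - 1]))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]

    def _update(self, key: tuple, delta: float) -> None:
        self.w[key] = self.w.get(key, 0.0) + delta
        self._acc[key] = self._acc.get(key, 0.0) + delta * self._steps

    def learn_sentence(self, sent, gold: np.ndarray) -> int:
        """One perceptron update per channel; returns token error count."""
        errors = 0
        for c in range(len(self.channels)):
            self._steps += 1
            pred = self._viterbi(sent, c)
            g = gold[:, c].tolist()
            if pred == g:
                continue
            prev_g = prev_p = -1
            for t in range(len(sent)):
                feats = self._feats(sent, t)
                if pred[t] != g[t] or prev_g != prev_p:
                    for f in feats:
                        self._update((c, f, g[t]), +1.0)
                        self._update((c, f, pred[t]), -1.0)
                    self._update((c, "t", prev_g, g[t]), +1.0)
                    self._update((c, "t", prev_p, pred[t]), -1.0)
                errors += pred[t] != g[t]
                prev_g, prev_p = g[t], pred[t]
        return errors

    def finalize(self) -> None:
        if self.averaged or not self._steps:
            self.averaged = True
            return
        for k in self.w:
            self.w[k] -= self._acc.get(k, 0.0) / self._steps
        self.averaged = True

    def predict_grid(self, sent) -> np.ndarray:
        grid = np.zeros((len(self.channels), len(sent)), dtype=np.int8)
        for c in range(len(self.channels)):
            grid[c] = self._viterbi(sent, c)
        return grid


def _train_perceptron(examples, dev_set, channels, vocab, config, rng) -> TrainedLabeler:
    model = _Perceptron(list(channels))
    labeler = TrainedLabeler(model, vocab, list(channels), config)
    n = len(examples)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        errors = 0
        for i in order:
            _, sent, y = examples[i]
            if len(sent):
                errors += model.learn_sentence(sent, y)
        entry = {"epoch": epoch, "loss": float(errors)}
        if dev_set is not None and len(dev_set.corpus) > 0:
            entry["dev_f1"] = _dev_f1(labeler, dev_set, channels)
        labeler.training_log.append(entry)
    model.finalize()
    return labeler


# ---------------------------------------------------------------------------
# persistence (model artifact directory)


def save_labeler(labeler: TrainedLabeler, path: Union[str, Path]) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    cfg = labeler.config.__dict__.copy()
    (p / "config.json").write_text(json.dumps(cfg, indent=2), "utf-8")
    (p / "channels.txt").write_text("\n".join(labeler.channels) + "\n", "utf-8")
    with open(p / "vocab.tsv", "w", encoding="utf-8", newline="") as fh:
        for tok, idx in labeler.vocabulary.items():
            fh.write(f"{tok}\t{idx}\n")
    with open(p / "training_log.csv", "w", encoding="utf-8", newline="") as fh:
        cols = sorted({k for e in labeler.training_log for k in e})
        wr = csv.DictWriter(fh, fieldnames=cols)
        wr.writeheader()
        wr.writerows(labeler.training_log)
    if isinstance(labeler.backend, BiLSTMTagger):
        np.savez(p / "params.npz", **labeler.backend.params)
    else:
        ser = {json.dumps(list(k)): v for k, v in labeler.backend.w.items()}
        (p / "weights.json").write_text(json.dumps(ser), "utf-8")


def load_labeler(path: Union[str, Path]) -> TrainedLabeler:
    p = Path(path)
    config = LabelerConfig(**json.loads((p / "config.json").read_text("utf-8")))
    channels = (p / "channels.txt").read_text("utf-8").splitlines()
    vocab: dict[str, int] = {}
    for line in (p / "vocab.tsv").read_text("utf-8").splitlines():
        tok, idx = line.rsplit("\t", 1)
        vocab[tok] = int(idx)
    log: list[dict] = []
    with open(p / "training_log.csv", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            log.append({k: float(v) if v else None for k, v in row.items()})
    if config.backend == "bilstm":
        rng = np.random.default_rng(config.seed)
        model = BiLSTMTagger(len(vocab), config.embed_dim, config.hidden_dim,
                             len(channels), rng)
        with np.load(p / "params.npz") as data:
            model.params = {k: data[k].copy() for k in data.files}
    else:
        model = _Perceptron(channels)
        raw = json.loads((p / "weights.json").read_text("utf-8"))

        def detuple(x):
            return tuple(detuple(i) for i in x) if isinstance(x, list) else x

        model.w = {detuple(json.loads(k)): v for k, v in raw.items()}
        model.averaged = True
    return TrainedLabeler(model, vocab, channels, config, log)
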