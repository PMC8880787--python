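import numpy as np
import pytest

from pragtag._bilstm import BiLSTMTagger
from pragtag.errors import InputError
from pragtag.iob import encode_spans
from pragtag.labeler import (LabelerConfig, SplitSpec, load_labeler, predict,
                             save_labeler, split_corpus, split_sizes, train)
from pragtag.lexicon import AnnotatedCorpus, SpanAnnotation
from pragtag.morphio import Corpus

from conftest import make_doc

CHANNELS = ["negparticle.ne", "negparticle.yo"]


def _toy_annotated(n_docs=12, seed=0):
    """Tiny corpus where 'ne'/'yo' tokens always carry their tag."""
    rng = np.random.default_rng(seed)
    docs, spans = [], {}
    vocab = ["w1", "w2", "w3", "w4", "w5"]
    for d in range(n_docs):
        sents, doc_spans = [], []
        for sid in range(3):
            toks = [vocab[i] for i in rng.integers(0, len(vocab), 5)]
            for tag, marker in (("negparticle.ne", "ne"), ("negparticle.yo", "yo")):
                if rng.random() < 0.6:
                    pos = int(rng.integers(0, len(toks) + 1))
                    toks.insert(pos, marker)
            sents.append(toks)
        doc_id = f"doc{d}"
        doc = make_doc(doc_id, f"s{d}", "TD", sents)
        for sid, sent in enumerate(doc.sentences):
            for i, m in enumerate(sent.morphemes):
                if m.surface == "ne":
                    doc_spans.append(SpanAnnotation("negparticle.ne", sid, i, i + 1,
                                                    doc_id=doc_id))
                elif m.surface == "yo":
                    doc_spans.append(SpanAnnotation("negparticle.yo", sid, i, i + 1,
                                                    doc_id=doc_id))
        docs.append(doc)
        spans[doc_id] = doc_spans
    corpus = Corpus(docs)
    return AnnotatedCorpus(corpus, spans)


SMALL = dict(epochs=3, embed_dim=8, hidden_dim=8, batch_size=4, seed=1)


class TestSplit:
    def test_exact_ratio(self):
        assert split_sizes(10, (8, 1, 1)) == (8, 1, 1)

    def test_remainder_train_first(self):
        # 12 docs: floors (9,1,1), remainder 1 -> train
        assert split_sizes(12, (8, 1, 1)) == (10, 1, 1)

    def test_partition_disjoint_exhaustive(self):
        ann = _toy_annotated(17)
        tr, dev, te = split_corpus(ann.corpus, SplitSpec(seed=5))
        ids = [d.doc_id for part in (tr, dev, te) for d in part]
        assert sorted(ids) == sorted(d.doc_id for d in ann.corpus)
        assert (len(tr), len(dev), len(te)) == split_sizes(17, (8, 1, 1))

    def test_determinism(self):
        ann = _toy_annotated(13)
        a = split_corpus(ann.corpus, SplitSpec(seed=9))
        b = split_corpus(ann.corpus, SplitSpec(seed=9))
        assert [[d.doc_id for d in part] for part in a] == \
            [[d.doc_id for d in part] for part in b]

    def test_empty_corpus(self):
        with pytest.raises(InputError):
            split_corpus(Corpus([]), SplitSpec())

    def test_bad_ratios(self):
        with pytest.raises(InputError):
            SplitSpec(ratios=(0, 0, 0))


class TestConfig:
    def test_defaults_match_training_protocol(self):
        cfg = LabelerConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (50, 32, 0.001)
        assert (cfg.embed_dim, cfg.hidden_dim) == (300, 300)
        assert cfg.optimizer == "adam"

    def test_invalid(self):
        with pytest.raises(InputError):
            LabelerConfig(learning_rate=0)
        with pytest.raises(InputError):
            LabelerConfig(epochs=0)
        with pytest.raises(InputError):
            LabelerConfig(optimizer="sgd")


class TestGradients:
    def test_directional_derivative(self):
        rng = np.random.default_rng(0)
        m = BiLSTMTagger(7, 4, 5, 2, rng)
        ids = rng.integers(0, 7, (3, 6))
        mask = np.ones((3, 6))
        mask[1, 4:] = 0
        mask[2, 2:] = 0
        y = rng.integers(0, 3, (3, 6, 2))
        loss, grads = m.loss_and_grads(ids, mask, y)
        dirs = {k: rng.standard_normal(v.shape) for k, v in m.params.items()}
        eps = 1e-5
        for k in m.params:
            m.params[k] += eps * dirs[k]
        l1, _ = m.loss_and_grads(ids, mask, y)
        for k in m.params:
            m.params[k] -= 2 * eps * dirs[k]
        l2, _ = m.loss_and_grads(ids, mask, y)
        num = (l1 - l2) / (2 * eps)
        ana = sum((grads[k] * dirs[k]).sum() for k in grads)
        assert num == pytest.approx(ana, rel=1e-6)


class TestTraining:
    def test_seeded_determinism(self):
        ann = _toy_annotated()
        tr, dev, _ = split_corpus(ann.corpus, SplitSpec(seed=2))
        sub = lambda c: AnnotatedCorpus(c, {d.doc_id: ann.spans[d.doc_id] for d in c})
        cfg = LabelerConfig(**SMALL)
        log_a = train(sub(tr), sub(dev), CHANNELS, cfg).training_log
        log_b = train(sub(tr), sub(dev), CHANNELS, cfg).training_log
        assert log_a == log_b

    def test_one_entry_per_epoch(self):
        ann = _toy_annotated()
        model = train(ann, None, CHANNELS, LabelerConfig(**SMALL))
        assert [e["epoch"] for e in model.training_log] == [1, 2, 3]

    def test_empty_training_set(self):
        empty = AnnotatedCorpus(Corpus([]), {})
        with pytest.raises(InputError):
            train(empty, None, CHANNELS, LabelerConfig(**SMALL))

    def test_absent_channel_warns_but_retained(self):
        ann = _toy_annotated()
        with pytest.warns(UserWarning, match="absent"):
            model = train(ann, None, CHANNELS + ["filler.maa"],
                          LabelerConfig(**SMALL))
        assert "filler.maa" in model.channels

    def test_overfit_single_sentence(self):
        doc = make_doc("d0", "s0", "TD", [["w1", "ne", "w2"]] * 4)
        spans = [SpanAnnotation("negparticle.ne", sid, 1, 2, doc_id="d0")
                 for sid in range(4)]
        ann = AnnotatedCorpus(Corpus([doc]), {"d0": spans})
        cfg = LabelerConfig(epochs=30, embed_dim=8, hidden_dim=8, batch_size=4,
                            learning_rate=0.02, seed=0)
        model = train(ann, None, ["negparticle.ne"], cfg)
        losses = [e["loss"] for e in model.training_log]
        assert losses[0] > losses[1] > losses[2]
        # prediction on the training sentence reproduces the gold matrix
        res = predict(model, doc)
        gold = encode_spans([spans[0]], 3, ["negparticle.ne"])
        assert (res.matrices[0].labels == gold.labels).all()


@pytest.fixture(scope="module")
def trained():
    ann = _toy_annotated()
    return ann, train(ann, None, CHANNELS,
                      LabelerConfig(epochs=8, embed_dim=12, hidden_dim=12,
                                    batch_size=4, learning_rate=0.01, seed=0))


class TestPredict:
    def test_empty_doc(self, trained):
        _, model = trained
        doc = make_doc("empty", "s", "TD", [])
        res = predict(model, doc)
        assert res.matrices == [] and res.spans == []

    def test_shape_contract(self, trained):
        ann, model = trained
        doc = ann.corpus.documents[0]
        res = predict(model, doc)
        for sent, mat in zip(doc.sentences, res.matrices):
            assert (mat.C, mat.T) == (len(CHANNELS), len(sent))

    def test_decodable_after_repair(self, trained):
        from pragtag.iob import decode_matrix, validate_matrix
        ann, model = trained
        for doc in ann.corpus.documents[:3]:
            res = predict(model, doc)
            for mat in res.matrices:
                spans, _ = decode_matrix(mat)
                repaired = encode_spans(spans, mat.T, mat.channels)
                assert validate_matrix(repaired) == []

    def test_spans_carry_model_source(self, trained):
        ann, model = trained
        res = predict(model, ann.corpus.documents[0])
        assert all(s.source == "model" for s in res.spans)


class TestPersistence:
    @pytest.mark.parametrize("backend", ["bilstm", "perceptron"])
    def test_save_load_round_trip(self, tmp_path, backend):
        ann = _toy_annotated()
        cfg = LabelerConfig(epochs=3, embed_dim=8, hidden_dim=8, batch_size=4,
                            seed=1, backend=backend)
        model = train(ann, None, CHANNELS, cfg)
        save_labeler(model, tmp_path / "model")
        again = load_labeler(tmp_path / "model")
        assert again.channels == model.channels
        assert again.vocabulary == model.vocabulary
        doc = ann.corpus.documents[0]
        a, b = predict(model, doc), predict(again, doc)
        assert [s.key() for s in a.spans] == [s.key() for s in b.spans]


class TestPerceptron:
    def test_learns_marker_task(self):
        ann = _toy_annotated(n_docs=16)
        cfg = LabelerConfig(epochs=4, embed_dim=8, hidden_dim=8, seed=0,
                            backend="perceptron")
        model = train(ann, None, CHANNELS, cfg)
        from pragtag.evalmetrics import score_spans
        pred = [s for d in ann.corpus for s in predict(model, d).spans]
        rep = score_spans(ann.all_spans(), pred).aggregate
        assert rep.f1 >= 0.95
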