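import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pragtag.corpusstats import (ComparisonRow, CorpusFilter, compare_groups,
                                 freq_table, holm_adjust, kwic, kwic_to_tsv,
                                 occurrence_rates, welch_from_samples,
                                 welch_from_summary)
from pragtag.errors import (DegenerateVarianceError, InputError, ReferenceError_)
from pragtag.lexicon import AnnotatedCorpus, SpanAnnotation
from pragtag.morphio import Corpus, Sentence

from conftest import make_doc


def _annotated_fixture():
    """Two subjects per group; s1 has 3 'ne' spans in 1000 morphemes."""
    docs = [
        make_doc("d1", "s1", "TD", [["w"] * 500, ["w"] * 500]),
        make_doc("d2", "s2", "TD", [["w"] * 200]),
        make_doc("d3", "s3", "ASD-1", [["w"] * 300]),
        make_doc("d4", "s4", "ASD-2", [["w"] * 100]),
    ]
    spans = {
        "d1": [SpanAnnotation("negparticle.ne", 0, 1, 2, doc_id="d1"),
               SpanAnnotation("negparticle.ne", 0, 5, 6, doc_id="d1"),
               SpanAnnotation("negparticle.ne", 1, 7, 8, doc_id="d1")],
        "d2": [SpanAnnotation("negparticle.ne", 0, 0, 1, doc_id="d2")],
        "d3": [],
        "d4": [SpanAnnotation("negparticle.yo", 0, 3, 4, doc_id="d4")],
    }
    return AnnotatedCorpus(Corpus(docs), spans)


class TestOccurrenceRates:
    def test_rate_values(self):
        ann = _annotated_fixture()
        recs = occurrence_rates(ann, ["negparticle.ne", "negparticle.sa"])
        by = {(r.subject_id, r.tag_id): r for r in recs}
        assert by[("s1", "negparticle.ne")].rate == pytest.approx(0.003)
        assert by[("s1", "negparticle.ne")].count == 3
        assert by[("s1", "negparticle.ne")].morphemes == 1000
        assert by[("s1", "negparticle.sa")].rate == 0.0

    def test_one_record_per_subject_tag(self):
        recs = occurrence_rates(_annotated_fixture(), ["negparticle.ne"])
        assert len(recs) == 4

    def test_sentence_reorder_invariance(self):
        ann = _annotated_fixture()
        base = occurrence_rates(ann, ["negparticle.ne"])
        doc = ann.corpus.get("d1")
        doc.sentences = [
            Sentence(0, doc.sentences[1].speaker, doc.sentences[1].morphemes),
            Sentence(1, doc.sentences[0].speaker, doc.sentences[0].morphemes),
        ]
        # spans stay attached to sentence ids; totals and counts are unchanged
        again = occurrence_rates(ann, ["negparticle.ne"])
        assert [(r.subject_id, r.count, r.morphemes) for r in base] == \
            [(r.subject_id, r.count, r.morphemes) for r in again]

    def test_filters(self):
        ann = _annotated_fixture()
        recs = occurrence_rates(ann, ["negparticle.ne"],
                                CorpusFilter(groups=("TD",)))
        assert {r.subject_id for r in recs} == {"s1", "s2"}
        recs = occurrence_rates(ann, ["negparticle.ne"],
                                CorpusFilter(groups=("ASD",)))
        assert {r.subject_id for r in recs} == {"s3", "s4"}

    def test_empty_filter_warns(self):
        with pytest.warns(UserWarning, match="no documents"):
            out = occurrence_rates(_annotated_fixture(), ["negparticle.ne"],
                                   CorpusFilter(tasks=("G",)))
        assert out == []

    def test_examiner_speech_excluded(self):
        doc = make_doc("d1", "s1", "TD", [["w"] * 10], speaker="examiner")
        ann = AnnotatedCorpus(Corpus([doc]), {"d1": []})
        assert occurrence_rates(ann, ["negparticle.ne"]) == []


class TestWelch:
    def test_identical_samples(self):
        x = [0.1, 0.2, 0.3]
        t, df, p = welch_from_samples(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_against_scipy_oracle(self):
        x = [0.012, 0.009, 0.011, 0.008, 0.015]
        y = [0.007, 0.006, 0.009, 0.005, 0.004]
        t, df, p = welch_from_samples(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)

    def test_antisymmetry(self):
        x = [1.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0]
        t1, _, p1 = welch_from_samples(x, y)
        t2, _, p2 = welch_from_samples(y, x)
        assert t1 == -t2 and p1 == p2

    def test_summary_table_row_sa(self):
        # zero-variance group: df collapses to n_b - 1
        t, df, p = welch_from_summary(0.0, 0.0, 57, 0.000017, 0.000094, 50)
        assert t == pytest.approx(-1.279, abs=5e-4)
        assert df == pytest.approx(49.0)
        assert p == pytest.approx(0.207, abs=5e-4)

    def test_equal_means(self):
        t, _, p = welch_from_summary(0.5, 0.1, 10, 0.5, 0.3, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            welch_from_summary(0.1, 0.0, 5, 0.2, 0.0, 5)

    def test_small_n(self):
        with pytest.raises(InputError):
            welch_from_summary(0.1, 0.1, 1, 0.2, 0.1, 5)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=8),
           st.lists(st.floats(-10, 10), min_size=2, max_size=8))
    def test_samples_equal_summary(self, x, y):
        xa, ya = np.array(x), np.array(y)
        if xa.std(ddof=1) == 0 and ya.std(ddof=1) == 0:
            return
        direct = welch_from_samples(x, y)
        summary = welch_from_summary(float(xa.mean()), float(xa.std(ddof=1)), len(x),
                                     float(ya.mean()), float(ya.std(ddof=1)), len(y))
        assert direct == summary


class TestHolm:
    def test_adjustment(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == [0.03, 0.06, 0.06]

    def test_monotone_capped(self):
        adj = holm_adjust([0.5, 0.9, 0.7])
        assert all(0 <= a <= 1 for a in adj)


class TestCompareGroups:
    def test_copies_give_t_zero(self):
        docs, spans = [], {}
        for g, subjects in (("TD", ("a1", "a2")), ("ASD-1", ("b1", "b2"))):
            for i, s in enumerate(subjects):
                did = f"{g}-{s}"
                docs.append(make_doc(did, s, g, [["w"] * 100]))
                spans[did] = [SpanAnnotation("negparticle.ne", 0, i, i + 1, doc_id=did)] * 1
                if i == 0:
                    spans[did] = spans[did] + [
                        SpanAnnotation("negparticle.ne", 0, 50, 51, doc_id=did)]
        ann = AnnotatedCorpus(Corpus(docs), spans)
        res = compare_groups(ann, ["negparticle.ne"], None, "TD", "ASD")
        assert res.rows[0].t == pytest.approx(0.0)

    def test_degenerate_tag_excluded_row_emitted(self):
        ann = _annotated_fixture()
        res = compare_groups(ann, ["negparticle.sa"], None, "TD", "ASD")
        assert res.excluded == ["negparticle.sa"]
        row = res.rows[0]
        assert row.t is None and row.p is None and row.mean_a == 0.0

    def test_orientation_a_minus_b(self):
        ann = _annotated_fixture()
        res = compare_groups(ann, ["negparticle.ne"], None, "TD", "ASD")
        assert res.rows[0].t > 0  # TD uses ne more in the fixture

    def test_subject_relabel_invariance(self):
        ann = _annotated_fixture()
        base = compare_groups(ann, ["negparticle.ne"], None, "TD", "ASD").rows[0]
        for doc in ann.corpus:
            doc.subject_id = doc.subject_id.replace("s", "subj")
        again = compare_groups(ann, ["negparticle.ne"], None, "TD", "ASD").rows[0]
        assert (base.t, base.df, base.p) == (again.t, again.df, again.p)

    def test_too_few_subjects(self):
        docs = [make_doc("d1", "s1", "TD", [["w"]]),
                make_doc("d2", "s2", "ASD-1", [["w"]]),
                make_doc("d3", "s3", "ASD-1", [["w"]])]
        ann = AnnotatedCorpus(Corpus(docs), {d.doc_id: [] for d in docs})
        with pytest.raises(InputError, match="2 subjects"):
            compare_groups(ann, ["negparticle.ne"], None, "TD", "ASD")

    def test_tsv_layout(self):
        ann = _annotated_fixture()
        res = compare_groups(ann, ["negparticle.ne"], None, "TD", "ASD")
        header = res.to_tsv("TD", "ASD").splitlines()[0].split("\t")
        assert header == ["tag", "mean_TD", "SD_TD", "mean_ASD", "SD_ASD",
                          "t", "df", "p"]

    def test_holm_column(self):
        ann = _annotated_fixture()
        res = compare_groups(ann, ["negparticle.ne", "negparticle.yo"], None,
                             "TD", "ASD", holm=True)
        ps = [r.p_holm for r in res.rows if r.p_holm is not None]
        assert ps and all(0 <= p <= 1 for p in ps)


class TestKWIC:
    def _ann(self, fig6_doc):
        spans = {"d-fig6": [SpanAnnotation("filler.nanka", 0, 2, 3, doc_id="d-fig6")]}
        return AnnotatedCorpus(Corpus([fig6_doc]), spans)

    def test_tag_query_window2(self, fig6_doc, paper_scheme):
        ann = self._ann(fig6_doc)
        hits = kwic(ann.corpus, tag="filler.nanka", window=2, annotated=ann,
                    scheme=paper_scheme)
        assert len(hits) == 1
        h = hits[0]
        assert h.keyword == ("nanka",)
        assert h.left_context == ("oko", "ttari")
        assert h.right_context == ("suru", "koto")

    def test_window_zero(self, fig6_doc, paper_scheme):
        ann = self._ann(fig6_doc)
        h = kwic(ann.corpus, tag="filler.nanka", window=0, annotated=ann,
                 scheme=paper_scheme)[0]
        assert h.left_context == () and h.right_context == ()

    def test_surface_query(self, fig6_doc):
        hits = kwic(Corpus([fig6_doc]), surface="suru", window=1)
        assert len(hits) == 1 and hits[0].left_context == ("nanka",)

    def test_no_matches(self, fig6_doc):
        assert kwic(Corpus([fig6_doc]), surface="zzz") == []

    def test_unknown_tag(self, fig6_doc, paper_scheme):
        ann = self._ann(fig6_doc)
        with pytest.raises(ReferenceError_):
            kwic(ann.corpus, tag="nope.nope", annotated=ann, scheme=paper_scheme)

    def test_context_truncated_at_sentence_bounds(self, fig6_doc, paper_scheme):
        ann = self._ann(fig6_doc)
        h = kwic(ann.corpus, tag="filler.nanka", window=99, annotated=ann,
                 scheme=paper_scheme)[0]
        assert h.left_context == ("oko", "ttari")
        assert h.right_context == ("suru", "koto", "aru")

    def test_tsv_output(self, fig6_doc, paper_scheme):
        ann = self._ann(fig6_doc)
        hits = kwic(ann.corpus, tag="filler.nanka", window=2, annotated=ann,
                    scheme=paper_scheme)
        assert "oko ttari\tnanka\tsuru koto" in kwic_to_tsv(hits)


class TestFreqTable:
    def test_single_doc_single_cell(self):
        doc = make_doc("d1", "s1", "TD", [["w"] * 10])
        ann = AnnotatedCorpus(Corpus([doc]),
                              {"d1": [SpanAnnotation("negparticle.ne", 0, 0, 1,
                                                     doc_id="d1")]})
        table = freq_table(ann, "group")
        assert len(table) == 1
        assert table.iloc[0]["cell"] == "TD" and table.iloc[0]["count"] == 1

    def test_conservation(self):
        ann = _annotated_fixture()
        total = len(ann.all_spans())
        for grouping in ("group", "task"):
            assert freq_table(ann, grouping)["count"].sum() == total

    def test_heading_grouping(self, paper_scheme):
        ann = _annotated_fixture()
        table = freq_table(ann, "heading", scheme=paper_scheme)
        assert set(table["cell"]) == {"negotiating_particle"}
        assert table["count"].sum() == len(ann.all_spans())

    def test_planted_counts(self):
        ann = _annotated_fixture()
        table = freq_table(ann, "group").set_index("cell")
        assert table.loc["TD", "count"] == 4
        assert table.loc["ASD-2", "count"] == 1
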