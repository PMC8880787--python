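import pytest

from pragtag.lexicon import SpanAnnotation, load_lexicon
from pragtag.morphio import Corpus, Document, Morpheme, Sentence, parse_corpus
from pragtag.scheme import load_scheme

# six-token worked-example sentence: oko ttari nanka suru koto aru
FIG6_TOKENS = ["oko", "ttari", "nanka", "suru", "koto", "aru"]


@pytest.fixture(scope="session")
def paper_scheme():
    return load_scheme()


@pytest.fixture(scope="session")
def bundled_lexicon(paper_scheme):
    return load_lexicon(None, paper_scheme)


@pytest.fixture
def fig6_sentence():
    morphs = [Morpheme(i, s, s, "verb" if s in ("suru", "aru") else "noun")
              for i, s in enumerate(FIG6_TOKENS)]
    return Sentence(0, "subject", morphs)


@pytest.fixture
def fig6_doc(fig6_sentence):
    return Document("d-fig6", "subj1", "TD", 20, "A", [fig6_sentence])


@pytest.fixture
def fig6_gold():
    return [
        SpanAnnotation("erg.middle", 0, 0, 1),
        SpanAnnotation("erg.middle", 0, 4, 6),
        SpanAnnotation("modality.usuality", 0, 3, 6),
    ]


@pytest.fixture
def fig6_pred():
    # model guesses: middle on oko + suru, usuality on oko + suru-koto-aru
    return [
        SpanAnnotation("erg.middle", 0, 0, 1, source="model"),
        SpanAnnotation("erg.middle", 0, 3, 4, source="model"),
        SpanAnnotation("modality.usuality", 0, 0, 1, source="model"),
        SpanAnnotation("modality.usuality", 0, 3, 6, source="model"),
    ]


TINY_CORPUS_TSV = """\
#!pragma-tsv 1
#age=15
#doc_id=doc-a
#group=TD
#subject_id=s01
#task=A
kyou\tkyou\tnoun\t\tsubject
iku\tiku\tverb\t\tsubject
ne\tne\tprt-final\t\tsubject

dou\tdou\tadv\t\texaminer
desu\tdesu\taux\t\texaminer
ka\tka\tprt\t\texaminer
#age=14
#doc_id=doc-b
#group=ASD-1
#subject_id=s02
#task=P
maa\tmaa\tfiller\t\tsubject
sore\tsore\tnoun\t\tsubject
miru\tmiru\tverb\t\tsubject
yo\tyo\tprt-final\t\tsubject
"""


@pytest.fixture
def tiny_corpus_text():
    return TINY_CORPUS_TSV


@pytest.fixture
def tiny_corpus():
    return parse_corpus(TINY_CORPUS_TSV)


def make_doc(doc_id, subject_id, group, sentences_tokens, *, age=20, task="A",
             speaker="subject", pos="noun"):
    """Build a document from lists of surface tokens, one list per sentence."""
    sentences = []
    for sid, toks in enumerate(sentences_tokens):
        morphs = [Morpheme(i, t, t, pos) for i, t in enumerate(toks)]
        sentences.append(Sentence(sid, speaker, morphs))
    return Document(doc_id, subject_id, group, age, task, sentences)


@pytest.fixture
def make_document():
    return make_doc


@pytest.fixture
def two_group_corpus():
    """Four tiny documents, two subjects per group."""
    docs = [
        make_doc("d1", "s1", "TD", [["a", "ne", "b"], ["c", "d"]]),
        make_doc("d2", "s2", "TD", [["ne", "a", "a", "b"]]),
        make_doc("d3", "s3", "ASD-1", [["a", "b", "c"]]),
        make_doc("d4", "s4", "ASD-2", [["b", "ne", "c", "a"]]),
    ]
    return Corpus(docs)
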