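# pragtag

A library + CLI for span-based lexicogrammatical annotation of spoken-language
corpora and group-comparison statistics over the annotations. The pipeline:

1. **scheme** — a 159-tag annotation scheme (16 headings under two
   metafunctions, 15 annotation dictionaries) loaded from a TSV inventory.
2. **morphio** — reader/writer for morphologically analyzed transcripts
   (PRAGMA-TSV: one morpheme per line with surface/lemma/POS, per-document
   subject metadata), plus a converter for raw MeCab-style analyzer output.
3. **lexicon** — annotation dictionaries (surface/lemma/POS constraint
   sequences) and deterministic leftmost-longest dictionary tagging; spans
   in different channels may overlap, spans within one channel never do.
4. **iob** — multi-channel IOB2 label matrices (C×T, one row per tag type),
   encode/decode with orphan-I repair, validation, TSV export.
5. **labeler** — trainable sequence labeler (one-layer Bi-LSTM over
   surface embeddings, implemented in numpy with Adam; a structured
   perceptron fallback behind the same interface), 8:1:1 document-level
   splitting, fully seeded.
6. **evalmetrics** — span-level precision/recall/F1 with exact-boundary,
   exact-channel matching.
7. **corpusstats** — per-subject occurrence rates, Welch's t-test group
   comparison (from samples or from printed summary statistics), KWIC
   concordance, frequency tables.
8. **synthgen** — synthetic corpora with planted group-specific tag rates,
   for end-to-end testing and power/calibration studies.

## CLI

```sh
pragtag simulate --seed 5 --out corp/            # synthetic corpus + lexicon + gold spans
pragtag annotate --corpus corp/corpus.tsv --lexicon corp/lexicon.tsv --out spans.tsv
pragtag eval --gold corp/gold.tsv --pred spans.tsv
pragtag train --corpus corp/corpus.tsv --gold corp/gold.tsv \
    --channels 'negparticle.*' --model-out model/ --seed 3
pragtag predict --model model/ --corpus corp/corpus.tsv --out pred.tsv
pragtag kwic --corpus corp/corpus.tsv --spans corp/gold.tsv --tag negparticle.ne
pragtag compare --corpus corp/corpus.tsv --spans corp/gold.tsv \
    --tags 'negparticle.*' --group-a TD --group-b ASD --task A --min-age 13 \
    --out table.tsv
pragtag schema                                   # bundled scheme summary
```

Exit codes: 0 success, 1 domain error, 2 usage error. Logs go to stderr,
data only to declared output paths; seeds are explicit flags.

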