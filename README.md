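# varlit

**varlit** quantifies how much curated genetic-variant information can be
recovered from the different parts of a publication — abstract, narrative
full text, tables, pre-extracted PDF text and supplementary files — by
rule-based literature mining. It is written for biocurators and text-mining
researchers who want to measure, rather than assume, where the variants a
database curates actually live inside an article, and how much of the gap
between intrinsic extractor performance and real curation recall is
explained by format and placement rather than by the extractor.

## The task and the metrics

A curated variant database links each entry to its source article, so every
database row is a triple *(article id, gene, variant)* with the variant in
HGVS nomenclature at cDNA level (`c.676C>T`, `c.597_598delGA`) and/or
protein level (`A140T`, `p.Glu554_Val559del`). The pipeline extracts
candidate triples from each article's text sources, normalizes every
mention to canonical HGVS, associates genes by document-scope
co-occurrence, and reports four recall metrics over the curated set *C*
against the extracted set *E*:

- **Recall** — |matched| / |C|, where a record matches when some triple
  shares its article, matches its gene (HGNC id when both sides carry one,
  else symbol) and is equivalent to its DNA **or** protein variant;
- **Recall NG** — the same with the gene requirement dropped;
- **Recall Common** — the denominator restricted to *common articles*:
  processed articles with at least one curated record and at least one
  positive extraction;
- **Recall CmnNG** — both relaxations combined.

Variant equivalence works on canonical strings plus their expansion sets
(a codon-level position expands to nucleotide positions 3c−2, 3c−1, 3c; an
rs-number expands to its table of candidate variants) and, optionally,
deletion-length equivalence (`c.482_483delGA` ≡ `c.482_483del2`).
Articles are additionally labeled **high-throughput (HT)** when any of
their MeSH headings descends — by dotted-prefix tree-code test — from six
seed descriptors (e.g. *Genetic techniques*, E05.393), which splits the
corpus into a small HT group carrying a heavy tail of mutations and the
rest.

Because real curation studies need bulk database dumps and full-text
retrieval, the package ships a synthetic corpus generator
(`varlit.synth`) whose truth manifest makes every metric analytically
checkable: `expected_recall` states, without running the extractor, exactly
which curated records are recoverable under a given configuration, and the
pipeline must agree with it exactly on noiseless renders.

## Worked example

`examples/evaluate_synthetic_corpus.py` generates 60 articles whose
curated variants are 80 % canonical HGVS, 10 % exon/intron mentions and
10 % split across spreadsheet columns, then measures recall per source:

```
1563 curated records across 60 articles; 33945 extracted triples

source         recall  recall_ng  analytic
abstract       0.1190     0.1190    0.1190
body           0.3071     0.3071    0.3071
pdf_text       0.0000     0.0000    0.0000
table          0.0825     0.0825    0.0825
body+table     0.3896     0.3896    0.3896
supplement     0.4082     0.4082    0.4082
all            0.8049     0.8049    0.8049
```

Supplementary files dominate (the default placement puts half of all
curated mentions there), the sources are complementary (body+table ≈ body
plus table), and the union recall falls short of 1 by exactly the planted
fraction of unrecoverable formats — the measured column equals the
analytic column everywhere. `examples/extract_and_normalize.py` shows the
mention scanner and normalizer on prose, and
`examples/classify_high_throughput.py` reproduces the heavy-tail effect:
in its output the HT fifth of articles holds 88 % of mutations and the
"> 30 mutations per article" group's recall collapses to 0.11 while the
"≤ 10" group stays at 0.98.

There is also a thin CLI over the same library:

```bash
varlit generate --seed 17 --out corpus/
varlit report --corpus corpus/ --out-dir reports/
```

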