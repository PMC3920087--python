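# Methods

## Problem and matching model

The package measures curation recall: the fraction of curated
*(article, gene, variant)* triples that a rule-based extractor recovers
from an article's sources. Five sources are distinguished — abstract,
narrative body, tables, pre-extracted PDF text and supplementary files —
and evaluated separately, pooled pairwise (body ∪ table) and as the union
of all sources.

A curated record matches when some extracted triple from the same article
(i) matches its gene and (ii) is equivalent to either its DNA or its
protein variant; both sides matching still counts once. Gene matching
prefers HGNC-id equality when both sides carry an id, else case-folded
symbol equality; the NG ("no gene") metrics drop the gene requirement
entirely to bound the loss caused by gene-name normalization. The
common-article metrics restrict the denominator to articles that were
processed, have curated records and produced at least one extracted triple
— isolating extraction quality from corpus coverage. Duplicate curated
rows are deduplicated before any denominator is computed: recall is over
distinct curated facts. Articles cited by a database but linked to no
recorded mutation never enter a denominator.

Internally the matcher is an indexed single pass over the triples (keyed
by article, level and canonical string); the tests pin its output to an
exhaustive (record × triple) double loop, which the heavy-tailed articles
would otherwise make quadratic.

## Mention recognition and normalization

The scanner is a deliberately transparent pattern engine, not a trained
tagger. Supported surface classes, each toggleable: canonical cDNA
substitutions (`c.676C>T`), legacy DNA forms (`c580G > T`, `676C>T`,
compact `C676T`), cDNA indels with hyphen or underscore ranges and base or
count payloads, protein substitutions in one-letter, three-letter and
`p.`-prefixed forms, extended protein indels (`p.Glu554_Val559del`,
`delins`), dbSNP rs-numbers, natural-language substitutions ("C > T
mutation at nucleotide 2131", also at codon granularity) and imprecise
exon/intron deletion phrases. Overlapping candidates resolve leftmost
start, then longest match, then a fixed class priority. A compact
one-letter substitution whose two letters are both nucleotides is read as
DNA (`C676T` → `c.676C>T`); a `p.` prefix forces the protein reading.
Nucleotides and one-letter amino acids are matched case-sensitively
(uppercase), three-letter codes case-insensitively. Pattern whitespace is
restricted to literal spaces so that tab-linearized table cells can never
merge into one mention.

Normalization renders protein substitutions as one-letter wild-type,
position, one-letter mutant with `*` for stop (accepting `Ter`, `Stop`,
`X` and full names on input); DNA substitutions as
`c.[pos][wt]>[mut]`; indels with underscore ranges, upper-cased base
payloads and a `c.` prefix added when missing. Positions are 1-based.
Intronic offsets (`1410-54`) are carried as opaque tokens and compared as
strings — curator-side position corrections are not modeled and such pairs
simply do not match. Codon-level positions expand to the three candidate
nucleotide positions; when the alleles are known the expansion carries
them (matching on position + alleles), otherwise nothing is emitted.
Exon/intron mentions and positionless phrases ("entire gene deletion")
are dropped: no precise coordinate can be derived. Insertions are never
rewritten as duplications (`840insT` vs `c.839dupT` stay distinct): that
canonicalization needs a reference sequence the package does not have, and
the equivalence engine treats the pair as a genuine miss.

Gene mentions come from a surface-form dictionary with two standard
adjustments: surface forms identical to three-letter codon names are
stop-listed (so *MET* the gene is sacrificed to avoid methionine false
positives) and the alias *P53* is added for TP53. The historical h-prefix
(`hMLH1`) resolves only when the prefix-stripping flag is on; the flag is
off by default so both behaviours are testable. Gene–mutation association
is by co-occurrence at document scope within one source kind (every
mention pairs with every distinct gene symbol of that source, or with
ABSENT); sentence scope exists behind a naive terminal-punctuation
splitter but document scope is the operating mode.

### Match relaxations (`MatchConfig`)

| flag | default | effect |
| --- | --- | --- |
| `ignore_gene` | off | drop the gene requirement (the NG metrics) |
| `del_length_equivalence` | off | `c.482_483delGA` ≡ `c.482_483del2` at the same range |
| `tolerant_prefix` | on | accept indels without the `c.` prefix |
| `codon_expansion` | on | codon positions expand to 3 nucleotide candidates |
| `rsid_expansion` | on | rs-numbers expand via the local lookup table |

Defaults mirror the original operating point of such studies:
deletion-length equivalence is off because the count form is historically
reported as a miss; enabling any flag is monotone (never un-matches a
record), which the test suite asserts.

## Document ingestion

Abstracts are MEDLINE-style XML: entities decoded, tags stripped,
whitespace collapsed. Full text is a simplified JATS subset (article,
body, sec, p, table-wrap with caption and rows, back/ref-list); reference
lists are removed, unknown elements are ignored with a logged warning, and
a document whose body is absent or empty is rejected as body-missing,
mirroring the usual filter on title-and-abstract-only retrievals. Tables
stay rectangular grids until linearization: caption first, then cells
row-major, joined by tabs — a character that occurs in no supported
mention pattern, so linearization can neither create nor destroy mentions.
Footnote marks are declared per table (a `footnote-marks` attribute in the
fixture format, i.e. metadata, never auto-detection — auto-detection is
under-specified) and stripped from cell payloads before scanning, so
`1704_1705delᵉAGᵇ` scans as `1704_1705delAG`. Supplements are TSV/CSV or
plain text; PDF content is accepted only as pre-extracted text
(`pdf_text`), since binary extraction is a solved, external concern and
contributes little recall. How multi-row-header tables should be
linearized is genuinely open; row-major with the caption prepended is this
package's recorded choice.

## The synthetic corpus generator

The generator emulates three empirical features of curated corpora:

1. **Heavy-tailed per-article counts.** Articles are high-throughput (HT)
   with probability `ht_fraction` (default 0.2). NHT articles draw
   mutation counts from Poisson(`lambda_nht` = 5), matching the order of
   magnitude of a focused, gene-specific database; HT articles draw from a
   log-normal (μ = 4.0, σ = 1.2 on the log scale, mean ≈ 112, capped at
   2000) so that a ~20 % article minority carries ~85 % of mutations and
   the per-article count distribution has a standard deviation an order of
   magnitude above its mean — the regime where a handful of screens
   dominates a database. Only mean/dispersion targets are empirical; the
   log-normal form is this package's choice.
2. **Placement.** Each mutation lands in one source with default weights
   abstract 0.15 / body 0.25 / table 0.10 / supplement 0.50 / pdf 0.0 —
   supplementary material dominates, tables and abstracts trail.
   Abstract-placed mentions are echoed into the body with probability
   0.95, reflecting that abstract content is almost always restated in
   the full text (this is what makes the abstract-vs-full-text precision
   diagnostic land near its observed ~0.95 level). HT-specific placement
   and format overrides let HT articles bury their variants in
   supplements.
3. **Format mix.** Defaults are all-canonical, which isolates placement
   effects and makes every downstream number analytic. The mixed
   "catalogue" condition used in the acceptance script adds legacy,
   natural-language, codon-position and deletion-count forms plus the two
   formats that are unrecoverable by design: exon/intron mentions and
   `split_fields`, where position, wild-type and mutant allele sit in
   separate spreadsheet columns.

DNA/protein consistency comes from a fixed synthetic CDS per gene (5000
non-stop codons drawn per gene from a seed-derived stream) and the
standard codon table, so each substitution record's protein variant is the
true translation of its DNA change. Codon positions are unique within an
article, which guarantees that no two records of one article are
equivalent even under codon expansion — a precondition for the analytic
oracle to be exact. The gene pool is a fixed list of real human symbols
chosen so that no symbol collides with a mention pattern or a codon name.
Noise knobs add declared footnote marks to table cells, h-prefixed gene
renderings, dropped `c.` prefixes, uncurated true mentions (distractors)
and an "unplanted" fraction of curated records that never appear in any
source (curation from channels the miner cannot see). Distractors can
change the common-article denominators but never the full-set recall.

Every planted mention is a row of the truth manifest, and
`expected_recall` computes each source set's four metrics directly from
the manifest: a record is recoverable when some planted row in the source
set has a recognizable format under the given pattern/match flags, and
gene-matched when its symbol is recognizably present in the same article
and source kind. On noiseless renders the pipeline must equal this
expectation *exactly*; the test suite holds that equality across seeds,
formats and noise at every report field.

**What the generator does not emulate:** real biomedical prose (filler is
template text), gene-name ambiguity beyond the codon collision, OCR or
conversion artifacts, chromosome-offset coordinates, genome-build
remapping, and curator-side position corrections. Passing tests therefore
demonstrate the correctness of the measurement machinery under controlled
conditions, not the field recall of any particular extractor on real
articles.

## High-throughput classification

Articles are labeled HT when any MeSH heading carries a tree code equal to
or a dotted-prefix extension of a seed code (Computational biology
H01.158.273.180, Genetic techniques E05.393, Genome G05.360.340, Molecular
sequence data L01.453.245.667, Proteome D12.776.817, Proteomics
H01.181.122.738). The prefix test is equivalent to materializing the
descendant closure by construction of MeSH tree numbers; the tests assert
that equivalence over a small synthetic tree. Articles with no headings
are UNINDEXED and can be excluded from the HT/NHT denominators by flag.
Historical MeSH vintages (headings introduced after an article was
indexed) are documented behaviour, not modeled.

## Numerical and interface choices

- Per-article mean/SD statistics are over articles with ≥ 1 curated
  mutation; SD is the sample standard deviation (ddof = 1, 0.0 for a
  single article).
- Threshold groups are cumulative (≤ 10, ≤ 20, ≤ 30, > 30 by default),
  each reporting count statistics, its share of all mutations and a full
  recall report over its own records.
- Problem sizes: the default study conditions are 500 articles
  (~15 000 curated records, ~0.5 M triples); unit and property tests use
  6–60 articles. The acceptance script runs the 500-article conditions
  twice (canonical and mixed formats).
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; rendered files, manifests and reports are
  byte-identical across runs for a fixed configuration.
- The config file is YAML; CLI flags override config keys. Exit codes:
  0 success, 2 configuration error, 3 data error.

## Known limitations

- The pattern set covers the catalogued surface forms, not the full HGVS
  grammar; no claim of equivalence with any specific historical extractor
  is made.
- Mention-class monotonicity (enabling a class never removes a mention)
  is guaranteed on well-separated mentions, as rendered by the generator;
  adversarial text could in principle let a newly enabled longer match
  displace a shorter overlapping one under leftmost-longest resolution.
- Sentence-scope association uses a naive splitter; document scope is the
  supported operating mode.
- Precision against the curated database is reported only as diagnostic
  counts: uncurated true mentions (negative results, out-of-scope
  variants) make it systematically pessimistic as a headline metric.
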