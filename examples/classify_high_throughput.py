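"""Label articles high-throughput from MeSH headings and split the corpus.

High-throughput (HT) articles — here, articles whose MeSH headings descend
from seed descriptors like Genetic techniques (E05.393) — contribute a
heavy tail of curated mutations that they bury in split-field supplements,
so the highest-count threshold group shows the worst recall.
"""

from varlit import extract_corpus, threshold_grouping
from varlit.mesh import split_corpus
from varlit.synth import GeneratorConfig, generate_corpus

cfg = GeneratorConfig(
    n_articles=150,
    seed=17,
    ht_fraction=0.2,
    ht_placement={"abstract": 0.0, "body": 0.0, "table": 0.0,
                  "supplement": 1.0, "pdf_text": 0.0},
    ht_format_mix={"split_fields": 0.9, "canonical_hgvs": 0.1},
)
corpus = generate_corpus(cfg)
labels = corpus.mesh_labels()
stats = split_corpus(corpus.records, labels)

print(f"{'group':10s} {'articles':>9s} {'mutations':>10s} {'share':>7s}")
for lab, st in stats.items():
    print(f"{lab:10s} {st.n_docs_with_mut:9d} {st.n_mutations:10d} "
          f"{100 * (st.mutation_share or 0):6.2f}%")

result = extract_corpus(corpus.bundles(), gene_dict=corpus.gene_dictionary())
groups = threshold_grouping(corpus.records, [10, 20, 30],
                            result.triples, corpus.doc_ids)
print(f"\n{'threshold':10s} {'articles':>9s} {'share':>7s} {'recall':>7s}")
for label, (st, rep) in groups.items():
    print(f"{label:10s} {st.n_docs_with_mut:9d} "
          f"{100 * (st.mutation_share or 0):6.2f}% {rep.recall:7.4f}")

print(
    "\nA minority of HT articles holds most curated mutations (the share"
    "\ncolumn), and the '> 30' group's recall collapses because those"
    "\nvariants sit in spreadsheet columns the pattern engine cannot join."
)
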