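"""Generate a small synthetic corpus and measure per-source recall.

Curated variants are planted into abstracts, body text, tables and
supplementary files with known placement weights; the pipeline then tries
to recover each curated (article, gene, variant) triple. The analytic
expectation from the truth manifest must agree exactly with the measured
report — distractors and noise aside, nothing here is stochastic once the
seed is fixed.
"""

from varlit import expected_recall, extract_corpus, per_source_evaluation
from varlit.synth import GeneratorConfig, generate_corpus

cfg = GeneratorConfig(
    n_articles=60,
    seed=17,
    format_mix={"canonical_hgvs": 0.8, "exon_intron": 0.1, "split_fields": 0.1},
)
corpus = generate_corpus(cfg)
result = extract_corpus(corpus.bundles(), gene_dict=corpus.gene_dictionary())
measured = per_source_evaluation(result.triples, corpus.records, corpus.doc_ids)
analytic = expected_recall(corpus)

print(f"{len(corpus.records)} curated records across "
      f"{len(corpus.manifest.docs)} articles; "
      f"{len(result.triples)} extracted triples\n")
print(f"{'source':12s} {'recall':>8s} {'recall_ng':>10s} {'analytic':>9s}")
for label, rep in measured.items():
    print(f"{label:12s} {rep.recall:8.4f} {rep.recall_ng:10.4f} "
          f"{analytic[label].recall:9.4f}")

missing = 1.0 - measured["all"].recall
print(
    f"\nThe union ('all') recall falls short of 1 by {missing:.4f}: exactly"
    "\nthe fraction of records planted as exon/intron mentions or split"
    "\nacross spreadsheet columns, which no contiguous pattern can recover."
)
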