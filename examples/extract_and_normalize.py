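"""Scan a snippet of article text for variant mentions and normalize them.

The scanner recognizes canonical HGVS, legacy forms without the c. prefix
or dot, natural-language substitutions, protein indels, rs-numbers and
imprecise exon/intron mentions; the normalizer converts each to a canonical
HGVS string or drops it when no precise coordinate can be derived.
"""

from varlit import (
    DROPPED,
    DocumentSection,
    GeneDictionary,
    associate,
    normalize_mention,
    scan_genes,
    scan_mentions,
)

TEXT = (
    "In this series, KRAS c.35G>A was frequent, and TP53 carried C676T "
    "(Arg226Stop). One tumour showed c580G > T in a table, another a "
    "C > T mutation at nucleotide 2131, one carried 840insT, and one an "
    "entire gene deletion."
)

section = DocumentSection(source_kind="body", text=TEXT)
dictionary = GeneDictionary(entries={
    "KRAS": ("KRAS", "HGNC:6407"), "TP53": ("TP53", "HGNC:11998"),
}).apply_curation_adjustments()

mentions = scan_mentions(section)
genes = scan_genes(section, dictionary)
print(f"{len(mentions)} variant mentions, genes: "
      f"{sorted({g.symbol for g in genes})}\n")

for mention, symbol in associate(mentions, genes, scope="document"):
    result = normalize_mention(mention)
    if result is DROPPED:
        canonical = "DROPPED (no precise coordinate)"
    else:
        canonical = ", ".join(v.hgvs for v in result) or "(no candidates)"
    print(f"  {mention.raw!r:45s} [{mention.mention_class:13s}] "
          f"gene={symbol or 'ABSENT':6s} -> {canonical}")

print(
    "\nEach line is one (mention, gene) co-occurrence pair; document scope"
    "\npairs every mention with every distinct gene, so each mention"
    "\nappears once per gene. DROPPED mentions never reach the matcher."
)
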