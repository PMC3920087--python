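"""End-to-end extraction: bundles → normalized (article, gene, variant) triples.

Sections of one article are grouped by source kind; within each group the
scanner finds variant and gene mentions across all sections and pairs them
by document-scope co-occurrence (every mention with every distinct gene
symbol of the group — one mutation may yield several pairs), so that each
mutation source can be evaluated independently and unions of sources are
unions of their triples. Mentions that cannot be normalized to a precise
canonical variant (exon/intron positions, degenerate substitutions,
unknown rs-numbers) are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from varlit.hgvs import (
    DROPPED,
    MatchConfig,
    NormalizationError,
    NormalizedVariant,
    RsidLookup,
    normalize_mention,
)
from varlit.ingest import DocumentBundle
from varlit.mentions import (
    GeneDictionary,
    PatternConfig,
    associate,
    scan_genes,
    scan_mentions,
)


@dataclass(frozen=True)
class ExtractedTriple:
    """The matching unit: article id, associated gene (or None = ABSENT),
    canonical variant and the source it was extracted from."""

    doc_id: str
    gene: str | None
    variant: NormalizedVariant
    source_kind: str
    hgnc_id: str | None = None


@dataclass
class ExtractionResult:
    """Triples plus diagnostic counts of one extraction run."""

    triples: set[ExtractedTriple] = field(default_factory=set)
    mention_counts: Counter = field(default_factory=Counter)
    n_mentions: int = 0
    n_dropped: int = 0
    n_no_gene: int = 0
    docs_with_mentions: set[str] = field(default_factory=set)

    def merge(self, other: "ExtractionResult") -> None:
        self.triples |= other.triples
        self.mention_counts.update(other.mention_counts)
        self.n_mentions += other.n_mentions
        self.n_dropped += other.n_dropped
        self.n_no_gene += other.n_no_gene
        self.docs_with_mentions |= other.docs_with_mentions


def extract_bundle(
    bundle: DocumentBundle,
    patterns: PatternConfig | None = None,
    gene_dict: GeneDictionary | None = None,
    mcfg: MatchConfig | None = None,
    rsid_lookup: RsidLookup | None = None,
    scope: str = "document",
    strip_h_prefix: bool = False,
) -> ExtractionResult:
    """Extract all triples from one article bundle."""
    patterns = patterns or PatternConfig()
    gene_dict = gene_dict or GeneDictionary()
    mcfg = mcfg or MatchConfig()
    result = ExtractionResult()

    groups: dict[str, list] = {}
    for sec in bundle.sections:
        groups.setdefault(sec.source_kind, []).append(sec)

    for kind, sections in groups.items():
        pairs: list = []
        hgnc_of: dict[str, str | None] = {}
        if scope == "document":
            mentions, genes = [], []
            for sec in sections:
                mentions.extend(scan_mentions(sec, patterns))
                genes.extend(scan_genes(sec, gene_dict, strip_h_prefix))
            pairs = associate(mentions, genes, scope="document")
        else:
            mentions, genes = [], []
            for sec in sections:
                m = scan_mentions(sec, patterns)
                g = scan_genes(sec, gene_dict, strip_h_prefix)
                pairs.extend(associate(m, g, scope="sentence", text=sec.text))
                mentions.extend(m)
                genes.extend(g)
        for g in genes:
            hgnc_of.setdefault(g.symbol, g.hgnc_id)

        result.n_mentions += len(mentions)
        result.mention_counts.update(m.mention_class for m in mentions)
        if mentions:
            result.docs_with_mentions.add(bundle.doc_id)

        cache: dict[int, tuple] = {}
        seen_no_gene: set[int] = set()
        for mention, symbol in pairs:
            key = id(mention)
            if key not in cache:
                try:
                    v = normalize_mention(mention, cfg=mcfg, rsid_lookup=rsid_lookup)
                except NormalizationError:
                    v = ()
                if v is DROPPED:
                    result.n_dropped += 1
                    v = ()
                cache[key] = v
            variants = cache[key]
            if symbol is None and key not in seen_no_gene:
                seen_no_gene.add(key)
                result.n_no_gene += 1
            for variant in variants:
                result.triples.add(ExtractedTriple(
                    doc_id=bundle.doc_id,
                    gene=symbol,
                    variant=variant,
                    source_kind=kind,
                    hgnc_id=hgnc_of.get(symbol) if symbol else None,
                ))
    return result


def extract_corpus(
    bundles: Iterable[DocumentBundle],
    patterns: PatternConfig | None = None,
    gene_dict: GeneDictionary | None = None,
    mcfg: MatchConfig | None = None,
    rsid_lookup: RsidLookup | None = None,
    scope: str = "document",
    strip_h_prefix: bool = False,
) -> ExtractionResult:
    """Extract triples from every bundle and pool the results."""
    total = ExtractionResult()
    for bundle in bundles:
        total.merge(extract_bundle(
            bundle, patterns=patterns, gene_dict=gene_dict, mcfg=mcfg,
            rsid_lookup=rsid_lookup, scope=scope, strip_h_prefix=strip_h_prefix,
        ))
    return total
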