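"""Matching extracted triples against a curated variant database.

The matching unit is the triple (article id, gene, variant). A curated
record counts as matched when some extracted triple from the same article
agrees on the gene (HGNC id when both sides carry one, else case-folded
symbol; skipped entirely under ``ignore_gene``) and is equivalent to either
the record's DNA or its protein variant — both matching still counts once.

Four recall metrics are reported: ``recall`` over all distinct curated
records; ``recall_ng`` with the gene requirement dropped; ``recall_common``
with the denominator restricted to the common articles — articles that were
processed, have at least one curated record and yielded at least one
extracted triple — and ``recall_common_ng`` combining both relaxations.
Duplicate curated rows are deduplicated before any denominator is computed:
recall is over distinct curated facts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

from varlit.hgvs import MatchConfig, NormalizedVariant, variant_equivalent

if TYPE_CHECKING:  # pragma: no cover
    from varlit.pipeline import ExtractedTriple


class UndefinedRecallError(Exception):
    """Recall requested over an empty curated set or empty triple set."""


@dataclass(frozen=True)
class CuratedRecord:
    """One curated database row; at least one variant level must be present."""

    doc_id: str
    gene_symbol: str
    hgnc_id: str | None = None
    dna_variant: NormalizedVariant | None = None
    protein_variant: NormalizedVariant | None = None

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.dna_variant is None and self.protein_variant is None:
            raise ValueError("record needs a DNA or a protein variant")

    def key(self) -> tuple:
        return (
            self.doc_id,
            self.gene_symbol.upper(),
            self.dna_variant.hgvs if self.dna_variant else None,
            self.protein_variant.hgvs if self.protein_variant else None,
        )


@dataclass(frozen=True)
class CorpusStats:
    """Table-1-style corpus statistics over per-article curated counts."""

    n_docs: int
    n_docs_with_mut: int
    n_mutations: int
    mean_mut_per_doc: float
    sd_mut_per_doc: float
    mutation_share: float | None = None


@dataclass
class MatchResult:
    matched: set[CuratedRecord]
    matched_ng: set[CuratedRecord]
    common_docs: set[str]
    per_record_match_source: dict[tuple, set[str]]


@dataclass(frozen=True)
class RecallReport:
    n_curated: int
    n_common_curated: int
    n_common_docs: int
    matched: int
    matched_ng: int
    recall: float
    recall_ng: float
    recall_common: float
    recall_common_ng: float

    def as_dict(self) -> dict:
        return {
            "n_curated": self.n_curated,
            "n_common_curated": self.n_common_curated,
            "n_common_docs": self.n_common_docs,
            "matched": self.matched,
            "matched_ng": self.matched_ng,
            "recall": self.recall,
            "recall_ng": self.recall_ng,
            "recall_common": self.recall_common,
            "recall_common_ng": self.recall_common_ng,
        }


def _gene_matches(record: CuratedRecord, triple) -> bool:
    if triple.gene is None:
        return False
    if record.hgnc_id and getattr(triple, "hgnc_id", None):
        return record.hgnc_id == triple.hgnc_id
    return record.gene_symbol.upper() == triple.gene.upper()


def _variant_matches(record: CuratedRecord, triple, cfg: MatchConfig) -> bool:
    for side in (record.dna_variant, record.protein_variant):
        if side is not None and variant_equivalent(triple.variant, side, cfg):
            return True
    return False


def record_matches(
    record: CuratedRecord, extracted: Iterable, cfg: MatchConfig | None = None
) -> bool:
    """True iff some triple shares the article, matches the gene (unless
    ``ignore_gene``) and is equivalent to the record's DNA or protein
    variant."""
    cfg = cfg or MatchConfig()
    for t in extracted:
        if t.doc_id != record.doc_id:
            continue
        if not cfg.ignore_gene and not _gene_matches(record, t):
            continue
        if _variant_matches(record, t, cfg):
            return True
    return False


def dedupe_records(curated: Iterable[CuratedRecord]) -> list[CuratedRecord]:
    seen: dict[tuple, CuratedRecord] = {}
    for r in curated:
        seen.setdefault(r.key(), r)
    return list(seen.values())


def _derived_count_keys(identity_set: Iterable[str]) -> set[str]:
    """Deletion-count forms derivable from base-string deletions.

    ``c.482_483delGA`` derives ``c.482_483del2``. Derived keys are only
    ever intersected with the *raw* keys of the other side, so two
    different base strings of equal length never match each other.
    """
    from varlit.hgvs import _del_parts

    out = set()
    for k in identity_set:
        dp = _del_parts(k)
        if dp is not None and not dp[1].isdigit():
            out.add(f"c.{dp[0]}del{len(dp[1])}")
    return out


def match_records(
    curated: Iterable[CuratedRecord],
    extracted: Iterable,
    cfg: MatchConfig | None = None,
) -> MatchResult:
    """Match every curated record against the triples of its article.

    Indexed single pass over the triples; semantics are identical to the
    naive double loop over (record, triple) pairs with
    :func:`varlit.hgvs.variant_equivalent` (the heavy-tail articles make
    the double loop quadratic in per-article mutation count).
    """
    cfg = cfg or MatchConfig()
    records = dedupe_records(curated)

    raw_index: dict[tuple, list[int]] = {}
    derived_index: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        for side in (r.dna_variant, r.protein_variant):
            if side is None:
                continue
            for k in side.identity_set:
                raw_index.setdefault((r.doc_id, side.level, k), []).append(i)
            if cfg.del_length_equivalence and side.level == "dna":
                for k in _derived_count_keys(side.identity_set):
                    derived_index.setdefault((r.doc_id, "dna", k), []).append(i)

    matched_idx: set[int] = set()
    matched_ng_idx: set[int] = set()
    sources: dict[tuple, set[str]] = {}
    docs_with_triples: set[str] = set()
    for t in extracted:
        docs_with_triples.add(t.doc_id)
        level = t.variant.level
        keys = t.variant.identity_set
        cand: set[int] = set()
        for k in keys:
            cand.update(raw_index.get((t.doc_id, level, k), ()))
            if cfg.del_length_equivalence:
                # record-derived count form == triple raw count form
                cand.update(derived_index.get((t.doc_id, level, k), ()))
        if cfg.del_length_equivalence and level == "dna":
            # triple-derived count form == record raw count form
            for k in _derived_count_keys(keys):
                cand.update(raw_index.get((t.doc_id, level, k), ()))
        for i in cand:
            matched_ng_idx.add(i)
            if cfg.ignore_gene or _gene_matches(records[i], t):
                matched_idx.add(i)
                sources.setdefault(records[i].key(), set()).add(t.source_kind)

    curated_docs = {r.doc_id for r in records}
    return MatchResult(
        matched={records[i] for i in matched_idx},
        matched_ng={records[i] for i in matched_ng_idx},
        common_docs=curated_docs & docs_with_triples,
        per_record_match_source=sources,
    )


def compute_recall(
    curated: Iterable[CuratedRecord],
    extracted: Iterable,
    corpus_docs: set[str],
    cfg: MatchConfig | None = None,
) -> RecallReport:
    """The four recall metrics of one extraction run.

    ``corpus_docs`` are the articles the extractor actually processed; the
    common-article denominator is restricted to processed articles that have
    curated records and at least one positive extraction.
    """
    cfg = cfg or MatchConfig()
    records = dedupe_records(curated)
    if not records:
        raise UndefinedRecallError("empty curated set")
    triples = [t for t in extracted if t.doc_id in corpus_docs]
    res = match_records(records, triples, cfg)
    common = {d for d in res.common_docs if d in corpus_docs}
    n = len(records)
    common_records = [r for r in records if r.doc_id in common]
    n_common = len(common_records)
    matched_common = sum(1 for r in res.matched if r.doc_id in common)
    matched_ng_common = sum(1 for r in res.matched_ng if r.doc_id in common)
    return RecallReport(
        n_curated=n,
        n_common_curated=n_common,
        n_common_docs=len(common),
        matched=len(res.matched),
        matched_ng=len(res.matched_ng),
        recall=len(res.matched) / n,
        recall_ng=len(res.matched_ng) / n,
        recall_common=(matched_common / n_common) if n_common else 0.0,
        recall_common_ng=(matched_ng_common / n_common) if n_common else 0.0,
    )


#: Row labels and the source kinds they pool, in report order.
SOURCE_SETS: dict[str, frozenset[str]] = {
    "abstract": frozenset({"abstract"}),
    "body": frozenset({"body"}),
    "pdf_text": frozenset({"pdf_text"}),
    "table": frozenset({"table"}),
    "body+table": frozenset({"body", "table"}),
    "supplement": frozenset({"supplement"}),
    "all": frozenset({"abstract", "body", "pdf_text", "table", "supplement"}),
}


def per_source_evaluation(
    extracted: Iterable,
    curated: Iterable[CuratedRecord],
    corpus_docs: set[str],
    cfg: MatchConfig | None = None,
) -> dict[str, RecallReport]:
    """Recall per mutation source, for body∪table, and for the union of all
    sources ("all"). Union recall is at least every component recall."""
    triples = list(extracted)
    records = dedupe_records(curated)
    out = {}
    for label, kinds in SOURCE_SETS.items():
        subset = [t for t in triples if t.source_kind in kinds]
        out[label] = compute_recall(records, subset, corpus_docs, cfg)
    return out


def abstract_vs_fulltext_precision(abs_triples: Iterable, ft_triples: Iterable) -> float:
    """Precision of abstract-extracted triples using full text as reference.

    Triples are restricted to articles present in both sets; a triple
    counts as confirmed when the identical (article, gene, canonical
    variant) triple also occurs in the full text.
    """
    abs_list = list(abs_triples)
    ft_list = list(ft_triples)
    docs = {t.doc_id for t in abs_list} & {t.doc_id for t in ft_list}
    abs_keys = {
        (t.doc_id, (t.gene or "").upper(), t.variant.level, t.variant.hgvs)
        for t in abs_list if t.doc_id in docs
    }
    ft_keys = {
        (t.doc_id, (t.gene or "").upper(), t.variant.level, t.variant.hgvs)
        for t in ft_list if t.doc_id in docs
    }
    if not abs_keys:
        raise UndefinedRecallError("no abstract triples on common articles")
    return len(abs_keys & ft_keys) / len(abs_keys)


def corpus_stats(
    curated: Iterable[CuratedRecord],
    corpus_docs: set[str] | None = None,
    total_mutations: int | None = None,
) -> CorpusStats:
    """Per-article count statistics of a curated set (mean/SD over articles
    that have at least one curated mutation)."""
    records = dedupe_records(curated)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.doc_id] = counts.get(r.doc_id, 0) + 1
    values = list(counts.values())
    n_mut = sum(values)
    if values:
        mean = n_mut / len(values)
        var = (
            sum((v - mean) ** 2 for v in values) / (len(values) - 1)
            if len(values) > 1 else 0.0
        )
    else:
        mean, var = 0.0, 0.0
    return CorpusStats(
        n_docs=len(corpus_docs) if corpus_docs is not None else len(values),
        n_docs_with_mut=len(values),
        n_mutations=n_mut,
        mean_mut_per_doc=mean,
        sd_mut_per_doc=math.sqrt(var),
        mutation_share=(n_mut / total_mutations) if total_mutations else None,
    )


def threshold_grouping(
    curated: Iterable[CuratedRecord],
    thresholds: list[int],
    extracted: Iterable,
    corpus_docs: set[str],
    cfg: MatchConfig | None = None,
) -> dict[str, tuple[CorpusStats, RecallReport]]:
    """Statistics and recall per mutation-frequency group.

    Groups are cumulative: articles with at most ``t`` curated mutations
    for each threshold, plus one ``> max(t)`` group. Reveals the heavy
    tail: a small fraction of articles can hold most mutations.
    """
    if list(thresholds) != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly ascending")
    if not thresholds:
        raise ValueError("at least one threshold required")
    records = dedupe_records(curated)
    triples = list(extracted)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.doc_id] = counts.get(r.doc_id, 0) + 1
    total = len(records)

    out: dict[str, tuple[CorpusStats, RecallReport]] = {}

    def group(label: str, docs: set[str]):
        sub = [r for r in records if r.doc_id in docs]
        stats = corpus_stats(sub, corpus_docs=docs, total_mutations=total)
        if sub:
            report = compute_recall(sub, triples, corpus_docs, cfg)
        else:
            report = RecallReport(0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0)
        out[label] = (stats, report)

    for t in thresholds:
        group(f"<= {t}", {d for d, c in counts.items() if c <= t})
    group(f"> {thresholds[-1]}", {d for d, c in counts.items() if c > thresholds[-1]})
    return out


# --- curated database I/O ----------------------------------------------------

def load_curated_db(path: str | Path) -> list[CuratedRecord]:
    """Read the curated database TSV (doc_id, gene_symbol, hgnc_id,
    dna_hgvs, protein_hgvs); empty variant fields are absent sides."""
    records = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines:
        if not line.strip() or line.startswith("#") or line.startswith("doc_id\t"):
            continue
        f = (line.rstrip("\n").split("\t") + [""] * 5)[:5]
        dna = NormalizedVariant(level="dna", hgvs=f[3]) if f[3] else None
        prot = NormalizedVariant(level="protein", hgvs=f[4]) if f[4] else None
        records.append(
            CuratedRecord(
                doc_id=f[0], gene_symbol=f[1], hgnc_id=f[2] or None,
                dna_variant=dna, protein_variant=prot,
            )
        )
    return records


def write_curated_db(records: Iterable[CuratedRecord], path: str | Path) -> None:
    lines = ["doc_id\tgene_symbol\thgnc_id\tdna_hgvs\tprotein_hgvs"]
    for r in records:
        lines.append("\t".join([
            r.doc_id, r.gene_symbol, r.hgnc_id or "",
            r.dna_variant.hgvs if r.dna_variant else "",
            r.protein_variant.hgvs if r.protein_variant else "",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
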