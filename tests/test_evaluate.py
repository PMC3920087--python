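"""Recall metrics, threshold grouping and the abstract-precision analysis."""

import pytest

from varlit.evaluate import (
    CuratedRecord,
    UndefinedRecallError,
    abstract_vs_fulltext_precision,
    compute_recall,
    corpus_stats,
    per_source_evaluation,
    record_matches,
    threshold_grouping,
)
from varlit.hgvs import MatchConfig, NormalizedVariant
from varlit.pipeline import ExtractedTriple


def rec(doc, gene, dna=None, prot=None, hgnc=None):
    return CuratedRecord(
        doc_id=doc, gene_symbol=gene, hgnc_id=hgnc,
        dna_variant=NormalizedVariant("dna", dna) if dna else None,
        protein_variant=NormalizedVariant("protein", prot) if prot else None,
    )


def tri(doc, gene, hgvs, level="dna", source="body", hgnc=None):
    return ExtractedTriple(
        doc_id=doc, gene=gene, hgnc_id=hgnc,
        variant=NormalizedVariant(level, hgvs), source_kind=source,
    )


class TestRecordMatches:
    def test_protein_side_matches(self):
        r = rec("d1", "KRAS", dna="c.35G>A", prot="G12D")
        assert record_matches(r, {tri("d1", "KRAS", "G12D", level="protein")})

    def test_gene_relaxation(self):
        r = rec("d1", "KRAS", dna="c.35G>A", prot="G12D")
        t = {tri("d1", "TP53", "G12D", level="protein")}
        assert not record_matches(r, t)
        assert record_matches(r, t, MatchConfig(ignore_gene=True))

    def test_doc_mismatch_never_matches(self):
        r = rec("d1", "KRAS", dna="c.35G>A")
        assert not record_matches(r, {tri("d2", "KRAS", "c.35G>A")})

    def test_hgnc_preferred_over_symbol(self):
        r = rec("d1", "KRAS", dna="c.35G>A", hgnc="HGNC:6407")
        assert record_matches(r, {tri("d1", "K-RAS2", "c.35G>A", hgnc="HGNC:6407")})
        assert not record_matches(r, {tri("d1", "KRAS", "c.35G>A", hgnc="HGNC:9999")})


class TestComputeRecall:
    def test_half_matched(self):
        curated = [rec("d1", "KRAS", dna=f"c.{i}A>G") for i in (1, 4)]
        curated += [rec("d2", "TP53", dna=f"c.{i}A>G") for i in (7, 10)]
        triples = {tri("d1", "KRAS", "c.1A>G"), tri("d2", "TP53", "c.7A>G")}
        rep = compute_recall(curated, triples, {"d1", "d2"})
        assert rep.recall == 0.5
        assert rep.recall_common == 0.5

    def test_common_denominator_restriction(self):
        curated = [rec("d1", "KRAS", dna=f"c.{i}A>G") for i in (1, 4)]
        curated += [rec(f"d{k}", "TP53", dna="c.7A>G") for k in range(2, 10)]
        triples = {tri("d1", "KRAS", "c.1A>G"), tri("d1", "KRAS", "c.4A>G")}
        rep = compute_recall(curated, triples, {f"d{k}" for k in range(1, 10)})
        assert rep.recall == 0.2
        assert rep.recall_common == 1.0

    def test_duplicate_rows_deduplicated(self):
        curated = [rec("d1", "KRAS", dna="c.1A>G")] * 3
        rep = compute_recall(curated, {tri("d1", "KRAS", "c.1A>G")}, {"d1"})
        assert rep.n_curated == 1 and rep.recall == 1.0

    def test_empty_curated_is_error(self):
        with pytest.raises(UndefinedRecallError):
            compute_recall([], {tri("d1", "KRAS", "c.1A>G")}, {"d1"})

    def test_del_length_flag_changes_match(self):
        curated = [rec("d1", "KRAS", dna="c.482_483delGA")]
        triples = {tri("d1", "KRAS", "c.482_483del2")}
        off = compute_recall(curated, triples, {"d1"})
        on = compute_recall(curated, triples, {"d1"}, MatchConfig(del_length_equivalence=True))
        assert off.recall == 0.0 and on.recall == 1.0


class TestPerSource:
    def test_single_source_equals_union(self):
        curated = [rec("d1", "KRAS", dna="c.1A>G")]
        triples = {tri("d1", "KRAS", "c.1A>G", source="supplement")}
        reports = per_source_evaluation(triples, curated, {"d1"})
        assert reports["supplement"].recall == reports["all"].recall == 1.0
        for label in ("abstract", "body", "table", "pdf_text"):
            assert reports[label].recall == 0.0

    def test_disjoint_sources_are_additive(self):
        curated = [rec("d1", "KRAS", dna="c.1A>G"), rec("d1", "KRAS", dna="c.4A>G")]
        triples = {
            tri("d1", "KRAS", "c.1A>G", source="body"),
            tri("d1", "KRAS", "c.4A>G", source="table"),
        }
        rep = per_source_evaluation(triples, curated, {"d1"})
        assert rep["body+table"].matched == rep["body"].matched + rep["table"].matched
        assert rep["all"].matched == 2


class TestAbstractPrecision:
    def test_subset_is_perfect_precision(self):
        a = {tri("d1", "KRAS", "c.1A>G", source="abstract"),
             tri("d1", "KRAS", "c.4A>G", source="abstract")}
        f = {tri("d1", "KRAS", "c.1A>G"), tri("d1", "KRAS", "c.4A>G"),
             tri("d1", "KRAS", "c.7A>G")}
        assert abstract_vs_fulltext_precision(a, f) == 1.0

    def test_partial_overlap(self):
        a = {tri("d1", "KRAS", "c.1A>G"), tri("d1", "KRAS", "c.4A>G")}
        f = {tri("d1", "KRAS", "c.1A>G")}
        assert abstract_vs_fulltext_precision(a, f) == 0.5

    def test_empty_abstract_undefined(self):
        with pytest.raises(UndefinedRecallError):
            abstract_vs_fulltext_precision(set(), {tri("d1", "KRAS", "c.1A>G")})


class TestThresholdGrouping:
    def make_corpus(self, doc_counts):
        curated, triples = [], set()
        for k, n in enumerate(doc_counts):
            for i in range(n):
                curated.append(rec(f"d{k}", "KRAS", dna=f"c.{i + 1}A>G"))
                triples.add(tri(f"d{k}", "KRAS", f"c.{i + 1}A>G"))
        return curated, triples

    def test_cumulative_group_sizes(self):
        curated, triples = self.make_corpus([3, 12, 25, 40])
        docs = {r.doc_id for r in curated}
        groups = threshold_grouping(curated, [10, 20, 30], triples, docs)
        sizes = {g: stats.n_docs_with_mut for g, (stats, _) in groups.items()}
        assert sizes == {"<= 10": 1, "<= 20": 2, "<= 30": 3, "> 30": 1}

    def test_mutation_share_arithmetic(self):
        curated, triples = self.make_corpus([3, 12, 25, 40])
        docs = {r.doc_id for r in curated}
        groups = threshold_grouping(curated, [10, 20, 30], triples, docs)
        assert groups["> 30"][0].mutation_share == 40 / 80

    def test_unsorted_thresholds_rejected(self):
        curated, triples = self.make_corpus([3])
        with pytest.raises(ValueError):
            threshold_grouping(curated, [20, 10], triples, {"d0"})


class TestCorpusStats:
    def test_mean_and_sd_over_articles_with_mutations(self):
        curated = [rec("d1", "KRAS", dna=f"c.{i}A>G") for i in (1, 4, 7)]
        curated += [rec("d2", "TP53", dna="c.1A>G")]
        st = corpus_stats(curated, corpus_docs={"d1", "d2", "d3"})
        assert st.n_docs == 3 and st.n_docs_with_mut == 2
        assert st.n_mutations == 4 and st.mean_mut_per_doc == 2.0
        assert st.sd_mut_per_doc == pytest.approx(2 ** 0.5)
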