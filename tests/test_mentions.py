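"""Mention scanning, gene dictionary lookup and co-occurrence association."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varlit.ingest import DocumentSection
from varlit.mentions import (
    GeneDictionary,
    PatternConfig,
    associate,
    scan_genes,
    scan_mentions,
)


def body(text: str) -> DocumentSection:
    return DocumentSection(source_kind="body", text=text)


class TestScanMentions:
    @pytest.mark.parametrize(
        "text, klass, checks",
        [
            ("c580G > T", "dna_sub", {"pos": "580", "wt": "G", "mut": "T"}),
            ("c.676C>T", "dna_sub", {"pos": "676", "wt": "C", "mut": "T"}),
            ("676C>T", "dna_sub", {"pos": "676"}),
            ("C676T", "dna_sub", {"pos": "676", "wt": "C", "mut": "T"}),
            ("C > T mutation at nucleotide 2131", "nl_sub",
             {"pos": "2131", "wt": "C", "mut": "T", "codon": False}),
            ("G > A mutation at codon 12", "nl_sub", {"pos": "12", "codon": True}),
            ("p.Glu554_Val559del", "protein_indel", {"op": "del"}),
            ("p.Ser566_Glu571delinsArg", "protein_indel", {"op": "delins"}),
            ("Ala140Thr", "protein_sub", {"wt": "Ala", "mut": "Thr"}),
            ("p.A140T", "protein_sub", {"wt": "A", "mut": "T"}),
            ("840insT", "dna_indel", {"op": "ins", "payload": "T"}),
            ("c.597-598delGA", "dna_indel",
             {"pos": "597", "pos_end": "598", "payload": "GA"}),
            ("c.482_483del2", "dna_indel", {"payload": "2"}),
            ("Del exon 3", "dna_indel", {"exon_intron": True}),
            ("entire gene deletion", "dna_indel", {"exon_intron": True}),
            ("rs12345", "rsid", {}),
        ],
    )
    def test_single_mention_classes(self, text, klass, checks):
        mentions = scan_mentions(body(f"we found {text} here"))
        assert len(mentions) == 1
        m = mentions[0]
        assert m.mention_class == klass
        assert m.raw == text
        for f, v in checks.items():
            assert getattr(m.components, f) == v

    def test_no_mentions_in_plain_prose(self):
        assert scan_mentions(body("the cat sat on the mat")) == []

    def test_span_matches_raw(self):
        sec = body("see c.35G>A and G12D here")
        for m in scan_mentions(sec):
            assert sec.text[m.span[0]:m.span[1]] == m.raw

    def test_spans_disjoint_leftmost_longest(self):
        # canonical form wholly contains a bare legacy candidate
        mentions = scan_mentions(body("c.676C>T"))
        assert len(mentions) == 1
        assert mentions[0].raw == "c.676C>T"
        spans = [m.span for m in scan_mentions(body("c.1A>G c.2C>T 840insT"))]
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_tab_never_bridges_cells(self):
        # a table row whose cells would form a mention if concatenated
        assert scan_mentions(body("sample 35\tG > A level")) == []

    def test_disabled_class_not_matched(self):
        cfg = PatternConfig(nl_sub=False)
        assert scan_mentions(body("C > T mutation at nucleotide 5"), cfg) == []
        cfg = PatternConfig(legacy_dna=False)
        out = scan_mentions(body("C676T and c.35G>A"), cfg)
        assert [m.raw for m in out] == ["c.35G>A"]

    @settings(max_examples=60, derandomize=True)
    @given(
        picks=st.lists(
            st.sampled_from([
                "c.676C>T", "C676T", "840insT", "p.Glu554_Val559del",
                "rs12345", "Ala140Thr", "Del exon 3",
                "C > T mutation at nucleotide 2131",
            ]),
            min_size=1, max_size=5,
        ),
        flag=st.sampled_from([
            "legacy_dna", "nl_sub", "rsid", "protein_indel", "exon_intron",
        ]),
    )
    def test_enabling_a_class_is_monotone(self, picks, flag):
        """Enabling one more pattern class never removes a found mention
        (checked over well-separated mention surface forms)."""
        text = " and also ".join(picks)
        sec = body(text)
        reduced = PatternConfig(**{flag: False})
        before = {m.span for m in scan_mentions(sec, reduced)}
        after = {m.span for m in scan_mentions(sec, PatternConfig())}
        assert before <= after


@pytest.fixture
def gene_dict():
    return GeneDictionary(
        entries={
            "KRAS": ("KRAS", "HGNC:6407"),
            "TP53": ("TP53", "HGNC:11998"),
            "MLH1": ("MLH1", "HGNC:7127"),
            "MET": ("MET", "HGNC:7029"),
        }
    ).apply_curation_adjustments()


class TestScanGenes:
    def test_h_prefix_alias_flag(self, gene_dict):
        sec = body("hMLH1 variants were frequent")
        assert scan_genes(sec, gene_dict) == []  # off by default
        hits = scan_genes(sec, gene_dict, strip_h_prefix=True)
        assert [g.symbol for g in hits] == ["MLH1"]

    def test_p53_alias_added(self, gene_dict):
        hits = scan_genes(body("a P53 mutation"), gene_dict)
        assert [g.symbol for g in hits] == ["TP53"]

    def test_codon_name_collision_stop_listed(self, gene_dict):
        # MET collides with the methionine codon name and must not match
        assert "MET" in gene_dict.stop_list
        assert scan_genes(body("the MET proto-oncogene"), gene_dict) == []

    def test_case_insensitive_lookup(self, gene_dict):
        assert [g.symbol for g in scan_genes(body("kras status"), gene_dict)] == ["KRAS"]


class TestAssociate:
    def make(self, text, gene_dict):
        sec = body(text)
        return sec, scan_mentions(sec), scan_genes(sec, gene_dict)

    def test_document_scope_pairs_all_distinct_genes(self, gene_dict):
        sec, mentions, genes = self.make("KRAS and TP53 share c.35G>A", gene_dict)
        pairs = associate(mentions, genes, scope="document")
        assert len(pairs) == 2
        assert {p[1] for p in pairs} == {"KRAS", "TP53"}

    def test_zero_genes_yields_absent(self, gene_dict):
        sec, mentions, genes = self.make("only c.35G>A here", gene_dict)
        pairs = associate(mentions, genes, scope="document")
        assert pairs == [(mentions[0], None)]

    def test_sentence_scope_restricts(self, gene_dict):
        sec, mentions, genes = self.make(
            "KRAS was screened. We found c.35G>A later.", gene_dict
        )
        pairs = associate(mentions, genes, scope="sentence", text=sec.text)
        assert pairs == [(mentions[0], None)]
        pairs_doc = associate(mentions, genes, scope="document")
        assert pairs_doc == [(mentions[0], "KRAS")]

    @settings(max_examples=40, derandomize=True)
    @given(
        n_mentions=st.integers(0, 5),
        genes=st.lists(st.sampled_from(["KRAS", "TP53", "MLH1"]), max_size=4),
    )
    def test_document_scope_pair_count_formula(self, n_mentions, genes):
        """#pairs = mentions×distinct genes, or #mentions when no gene."""
        dictionary = GeneDictionary(entries={
            "KRAS": ("KRAS", None), "TP53": ("TP53", None), "MLH1": ("MLH1", None),
        })
        text = " ".join(f"c.{i + 1}A>G" for i in range(n_mentions))
        text += " " + " ".join(genes)
        sec = body(text)
        mentions = scan_mentions(sec)
        gm = scan_genes(sec, dictionary)
        pairs = associate(mentions, gm, scope="document")
        distinct = len({g.symbol for g in gm})
        expected = len(mentions) * distinct if distinct else len(mentions)
        assert len(pairs) == expected
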