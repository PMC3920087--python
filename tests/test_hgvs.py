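"""Normalization to canonical HGVS and the equivalence relaxations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varlit.hgvs import (
    DROPPED,
    MatchConfig,
    NormalizationError,
    NormalizedVariant,
    RsidLookup,
    drop_imprecise,
    expand_codon,
    expand_rsid,
    normalize_dna_sub,
    normalize_indel,
    normalize_mention,
    normalize_protein_sub,
    variant_equivalent,
)
from varlit.ingest import DocumentSection
from varlit.mentions import scan_mentions


def first_mention(text):
    out = scan_mentions(DocumentSection(source_kind="body", text=text))
    assert out, f"no mention found in {text!r}"
    return out[0]


class TestProteinSub:
    @pytest.mark.parametrize(
        "wt, pos, mut, expected",
        [
            ("Ala", 140, "Thr", "A140T"),
            ("Gly", 12, "Gly", "G12G"),
            ("Arg", 226, "Stop", "R226*"),
            ("alanine", 7, "threonine", "A7T"),
            ("C", 3, "*", "C3*"),
        ],
    )
    def test_examples(self, wt, pos, mut, expected):
        assert normalize_protein_sub(wt, pos, mut).hgvs == expected

    def test_unknown_token_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_protein_sub("Xyz", 5, "Thr")
        with pytest.raises(NormalizationError):
            normalize_protein_sub("Ala", 0, "Thr")


class TestDnaSub:
    def test_canonical_format(self):
        assert normalize_dna_sub(676, "C", "T").hgvs == "c.676C>T"
        assert normalize_dna_sub(1, "A", "G").hgvs == "c.1A>G"

    def test_intronic_offset_carried_verbatim(self):
        assert normalize_dna_sub("1410-54", "C", "T").hgvs == "c.1410-54C>T"

    def test_degenerate_and_bad_alleles(self):
        with pytest.raises(NormalizationError):
            normalize_dna_sub(5, "A", "A")
        with pytest.raises(NormalizationError):
            normalize_dna_sub(5, "A", "U")


class TestIndel:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("c.597-598delGA", "c.597_598delGA"),
            ("c.501delG", "c.501delG"),
            ("840insT", "c.840insT"),
            ("c.482_483del2", "c.482_483del2"),
            ("35dupA", "c.35dupA"),
            ("c.1_2delinsAT", "c.1_2delinsAT"),
        ],
    )
    def test_canonicalization(self, raw, expected):
        assert normalize_indel(raw).hgvs == expected

    def test_idempotent_on_canonical(self):
        for s in ("c.597_598delGA", "c.840insT", "c.501delG"):
            assert normalize_indel(s).hgvs == s

    def test_prefix_intolerance_flag(self):
        with pytest.raises(NormalizationError):
            normalize_indel("840insT", tolerant_prefix=False)

    def test_unparseable(self):
        with pytest.raises(NormalizationError):
            normalize_indel("delete everything")


class TestExpandCodon:
    @pytest.mark.parametrize("codon, expected", [(1, [1, 2, 3]), (140, [418, 419, 420])])
    def test_examples(self, codon, expected):
        assert expand_codon(codon) == expected

    def test_domain_bound(self):
        with pytest.raises(NormalizationError):
            expand_codon(0)

    @settings(max_examples=100, derandomize=True)
    @given(codon=st.integers(1, 10**6))
    def test_strictly_increasing_consecutive_triple(self, codon):
        out = expand_codon(codon)
        assert len(out) == 3
        assert out == [out[0], out[0] + 1, out[0] + 2]
        assert out[0] == 3 * codon - 2


class TestDropImprecise:
    def test_exon_and_natural_language_deletions_dropped(self):
        assert drop_imprecise(first_mention("Del exon 3")) is DROPPED
        assert drop_imprecise(first_mention("entire gene deletion")) is DROPPED

    def test_precise_mentions_pass_through(self):
        v = drop_imprecise(first_mention("c.676C>T"))
        assert v.hgvs == "c.676C>T"


class TestRsid:
    def lookup(self):
        return RsidLookup(table={
            "rs1000": frozenset({
                NormalizedVariant("dna", "c.35G>A"),
                NormalizedVariant("protein", "G12D"),
            })
        })

    def test_present_returns_candidates(self):
        hits = expand_rsid("rs1000", self.lookup())
        assert {v.hgvs for v in hits} == {"c.35G>A", "G12D"}

    def test_absent_returns_empty(self):
        assert expand_rsid("rs9999", self.lookup()) == set()

    def test_malformed_rejected(self):
        with pytest.raises(NormalizationError):
            expand_rsid("rsX", self.lookup())


def dna(s, alternates=()):
    return NormalizedVariant("dna", s, alternates=frozenset(alternates))


class TestEquivalence:
    def test_deletion_count_relaxation_cases(self):
        on = MatchConfig(del_length_equivalence=True)
        assert variant_equivalent(dna("c.482_483delGA"), dna("c.482_483del2"), on)
        assert variant_equivalent(dna("c.501delG"), dna("c.501del1"), on)
        assert not variant_equivalent(dna("c.482_483delGA"), dna("c.482_483del2"))
        assert not variant_equivalent(dna("c.482_483delGA"), dna("c.482_483del3"), on)

    def test_distinct_base_strings_of_equal_length_differ(self):
        on = MatchConfig(del_length_equivalence=True)
        assert not variant_equivalent(dna("c.1_2delGA"), dna("c.1_2delAT"), on)

    def test_insertion_duplication_not_canonicalized(self):
        # needs a reference sequence; kept distinct on purpose
        on = MatchConfig(del_length_equivalence=True)
        assert not variant_equivalent(dna("c.840insT"), dna("c.839dupT"), on)

    def test_level_mismatch_is_false_not_error(self):
        assert not variant_equivalent(
            dna("c.35G>A"), NormalizedVariant("protein", "G12D")
        )

    def test_alternate_intersection(self):
        codon = dna("c.34G>A", alternates=["c.35G>A", "c.36G>A"])
        assert variant_equivalent(codon, dna("c.35G>A"))
        assert not variant_equivalent(codon, dna("c.37G>A"))

    @settings(max_examples=60, derandomize=True)
    @given(
        pos=st.integers(1, 500),
        wt=st.sampled_from("ACGT"),
        mut=st.sampled_from("ACGT"),
    )
    def test_symmetric_reflexive_and_string_equality_when_unrelaxed(self, pos, wt, mut):
        if wt == mut:
            return
        a = dna(f"c.{pos}{wt}>{mut}")
        b = dna(f"c.{pos}{wt}>{mut}")
        c = dna(f"c.{pos + 1}{wt}>{mut}")
        assert variant_equivalent(a, a)
        assert variant_equivalent(a, b) == variant_equivalent(b, a) is True
        assert variant_equivalent(a, c) is False
        assert variant_equivalent(a, c) == (a.hgvs == c.hgvs)

    def test_relaxation_is_monotone(self):
        """Enabling any flag never turns a true equivalence false."""
        pairs = [
            (dna("c.482_483delGA"), dna("c.482_483delGA")),
            (dna("c.482_483delGA"), dna("c.482_483del2")),
            (dna("c.35G>A"), dna("c.35G>A")),
        ]
        base = MatchConfig()
        for fld in ("del_length_equivalence", "codon_expansion", "rsid_expansion"):
            relaxed = MatchConfig(**{fld: True})
            for a, b in pairs:
                if variant_equivalent(a, b, base):
                    assert variant_equivalent(a, b, relaxed)


class TestNormalizeMention:
    def test_codon_mention_expands_to_three_candidates(self):
        m = first_mention("G > A mutation at codon 12")
        (v,) = normalize_mention(m)
        assert v.identity_set == {"c.34G>A", "c.35G>A", "c.36G>A"}

    def test_codon_mention_dropped_without_expansion(self):
        m = first_mention("G > A mutation at codon 12")
        assert normalize_mention(m, MatchConfig(codon_expansion=False)) is DROPPED

    def test_legacy_compact_normalizes_to_canonical_dna(self):
        (v,) = normalize_mention(first_mention("C676T"))
        assert v.level == "dna" and v.hgvs == "c.676C>T"

    def test_protein_indel_canonical_form(self):
        (v,) = normalize_mention(first_mention("p.Glu554_Val559del"))
        assert v.hgvs == "p.Glu554_Val559del"

    @settings(max_examples=100, derandomize=True)
    @given(
        pos=st.integers(1, 3000),
        wt=st.sampled_from("ACGT"),
        mut=st.sampled_from("ACGT"),
    )
    def test_normalization_idempotent_on_canonical_subs(self, pos, wt, mut):
        if wt == mut:
            return
        s = f"c.{pos}{wt}>{mut}"
        (v,) = normalize_mention(first_mention(s))
        assert v.hgvs == s
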