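"""Shared fixtures: small synthetic study conditions used across tests."""

import pytest

from varlit.synth import GeneratorConfig

#: Format mix exercising every supported surface form, including the two
#: unrecoverable-by-design ones.
MIXED_FORMATS = {
    "canonical_hgvs": 0.5,
    "legacy_nodot": 0.1,
    "natural_language": 0.1,
    "codon_position": 0.1,
    "exon_intron": 0.08,
    "split_fields": 0.07,
    "del_count": 0.05,
}


def noisy_cfg(seed: int, n_articles: int = 10) -> GeneratorConfig:
    """A small, deliberately messy corpus: every format, every noise flag."""
    return GeneratorConfig(
        n_articles=n_articles,
        seed=seed,
        format_mix=dict(MIXED_FORMATS),
        placement={
            "abstract": 0.15, "body": 0.25, "table": 0.10,
            "supplement": 0.45, "pdf_text": 0.05,
        },
        noise_footnote_marks=True,
        noise_h_prefix_rate=0.1,
        noise_drop_c_prefix_rate=0.1,
        distractor_rate=2.0,
        unplanted_fraction=0.05,
        unindexed_fraction=0.1,
    )


@pytest.fixture
def small_noisy_corpus():
    from varlit.synth import generate_corpus

    return generate_corpus(noisy_cfg(seed=5, n_articles=10))
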