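"""High-throughput (HT) article labeling from MeSH headings.

An article counts as a high-throughput study when any of its MeSH headings
carries a tree code that is a descendant (dotted-prefix extension) of one of
six seed descriptors: Computational biology (H01.158.273.180), Genetic
techniques (E05.393), Genome (G05.360.340), Molecular sequence data
(L01.453.245.667), Proteome (D12.776.817) and Proteomics (H01.181.122.738).
Articles with no headings at all are UNINDEXED — typical of recently indexed
publications — and can be excluded from HT/NHT denominators.

Classification works on tree codes directly: by construction of MeSH tree
numbers, the dotted-prefix test is equivalent to walking the hierarchy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from varlit.evaluate import CorpusStats, CuratedRecord, corpus_stats, dedupe_records

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]+)*$")

HT = "HT"
NHT = "NHT"
UNINDEXED = "UNINDEXED"


class MalformedTreeCodeError(ValueError):
    pass


def _check_code(code: str) -> str:
    if not _CODE_RE.match(code):
        raise MalformedTreeCodeError(f"malformed MeSH tree code: {code!r}")
    return code


@dataclass(frozen=True)
class MeSHDescriptor:
    heading: str
    tree_codes: frozenset[str]

    def __post_init__(self):
        for c in self.tree_codes:
            _check_code(c)


#: The six seed descriptors denoting high-throughput studies.
DEFAULT_HT_SEEDS: tuple[MeSHDescriptor, ...] = (
    MeSHDescriptor("Computational biology", frozenset({"H01.158.273.180"})),
    MeSHDescriptor("Genetic techniques", frozenset({"E05.393"})),
    MeSHDescriptor("Genome", frozenset({"G05.360.340"})),
    MeSHDescriptor("Molecular sequence data", frozenset({"L01.453.245.667"})),
    MeSHDescriptor("Proteome", frozenset({"D12.776.817"})),
    MeSHDescriptor("Proteomics", frozenset({"H01.181.122.738"})),
)


@dataclass(frozen=True)
class HTSeedSet:
    descriptors: tuple[MeSHDescriptor, ...] = DEFAULT_HT_SEEDS

    @property
    def codes(self) -> frozenset[str]:
        out = set()
        for d in self.descriptors:
            out |= d.tree_codes
        return frozenset(out)

    def extended(self, extra: Iterable[MeSHDescriptor]) -> "HTSeedSet":
        return HTSeedSet(self.descriptors + tuple(extra))


def is_descendant(code: str, seed: str) -> bool:
    """True iff ``code`` equals ``seed`` or extends it at a dot boundary.

    ``E05.393.760`` descends from ``E05.393``; ``E05.3931`` does not.
    """
    _check_code(code)
    _check_code(seed)
    return code == seed or code.startswith(seed + ".")


def label_article(
    headings: Iterable[MeSHDescriptor], seeds: HTSeedSet | None = None
) -> str:
    """HT / NHT / UNINDEXED label for one article's MeSH headings."""
    seeds = seeds or HTSeedSet()
    headings = list(headings)
    if not headings:
        return UNINDEXED
    seed_codes = seeds.codes
    for h in headings:
        for code in h.tree_codes:
            if any(is_descendant(code, s) for s in seed_codes):
                return HT
    return NHT


def split_corpus(
    curated: Iterable[CuratedRecord],
    labels: Mapping[str, str],
    include_unindexed: bool = True,
) -> dict[str, CorpusStats]:
    """Per-label corpus statistics with each group's share of all mutations.

    Every curated article must carry a label. With ``include_unindexed``
    off, UNINDEXED articles are excluded from the statistics entirely
    (redoing the calculation without unindexed articles).
    """
    records = dedupe_records(curated)
    missing = {r.doc_id for r in records if r.doc_id not in labels}
    if missing:
        raise KeyError(f"curated articles without an HT label: {sorted(missing)[:5]}")
    if not include_unindexed:
        records = [r for r in records if labels[r.doc_id] != UNINDEXED]
    total = len(records)
    out = {}
    for lab in (HT, NHT, UNINDEXED):
        sub = [r for r in records if labels[r.doc_id] == lab]
        if not sub and lab == UNINDEXED:
            continue
        out[lab] = corpus_stats(sub, total_mutations=total or None)
    return out


# --- TSV interfaces ----------------------------------------------------------

def load_mesh_table(path: str | Path) -> dict[str, MeSHDescriptor]:
    """Descriptor table TSV: heading, semicolon-joined tree codes."""
    table = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("heading\t"):
            continue
        heading, codes = line.rstrip("\n").split("\t")[:2]
        table[heading] = MeSHDescriptor(
            heading, frozenset(c for c in codes.split(";") if c)
        )
    return table


def load_article_headings(
    path: str | Path, table: Mapping[str, MeSHDescriptor]
) -> dict[str, list[MeSHDescriptor]]:
    """Per-article headings TSV: doc_id, semicolon-joined heading list."""
    out: dict[str, list[MeSHDescriptor]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("doc_id\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        doc_id = parts[0]
        names = parts[1].split(";") if len(parts) > 1 and parts[1] else []
        out[doc_id] = [table[n] for n in names if n in table]
    return out
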