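"""HGVS normalization and variant equivalence.

Mentions found by the pattern engine are converted to canonical strings:
protein substitutions as one-letter ``A140T`` (stop codon rendered ``*``),
DNA substitutions as ``c.676C>T``, indels with underscore ranges and a
``c.`` prefix added when missing (``840insT`` → ``c.840insT``). Codon-level
positions expand to the three candidate nucleotide positions; rs-numbers
expand to the candidate variants of a local lookup table; exon/intron
mentions are dropped because no precise coordinate can be derived.

Positions are 1-based throughout. Intronic offsets such as ``1410-54`` are
carried verbatim as opaque position tokens and compared as strings; offset
arithmetic (curator position corrections) is out of scope, as is
insertion↔duplication canonicalization, which needs a reference sequence
(``840insT`` and ``c.839dupT`` stay distinct).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from varlit.mentions import MutationMention

logger = logging.getLogger(__name__)


class NormalizationError(Exception):
    """A mention could not be converted to canonical form."""


class DegenerateSubstitutionError(NormalizationError):
    """Wild-type and mutated allele are identical."""


class _Dropped:
    """Sentinel for mentions removed as imprecise."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "DROPPED"

    def __bool__(self):
        return False


DROPPED = _Dropped()


@dataclass(frozen=True)
class NormalizedVariant:
    """A canonical variant string at DNA or protein level.

    ``alternates`` holds equally valid canonical strings arising from codon
    or RSID expansion; equivalence treats ``{hgvs} ∪ alternates`` as the
    identity set. ``provenance`` records the mention class of origin and
    does not participate in equality.
    """

    level: str  # "dna" | "protein"
    hgvs: str
    alternates: frozenset[str] = frozenset()
    provenance: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.level not in ("dna", "protein"):
            raise ValueError(f"unknown level: {self.level!r}")

    @property
    def identity_set(self) -> frozenset[str]:
        return self.alternates | {self.hgvs}


@dataclass(frozen=True)
class MatchConfig:
    """Equivalence and matching relaxations.

    Defaults mirror the operating point of the original recall study:
    tolerant prefixes, codon and RSID expansion on; gene requirement on;
    deletion-length equivalence off (``c.482_483delGA`` vs
    ``c.482_483del2`` is reported there as a miss and only matches when the
    flag is enabled).
    """

    ignore_gene: bool = False
    del_length_equivalence: bool = False
    tolerant_prefix: bool = True
    codon_expansion: bool = True
    rsid_expansion: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "MatchConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown match flags: {sorted(unknown)}")
        return cls(**mapping)


# --- amino-acid code tables --------------------------------------------------

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
FULL_TO_1 = {
    "alanine": "A", "arginine": "R", "asparagine": "N", "aspartate": "D",
    "aspartic acid": "D", "cysteine": "C", "glutamine": "Q",
    "glutamate": "E", "glutamic acid": "E", "glycine": "G",
    "histidine": "H", "isoleucine": "I", "leucine": "L", "lysine": "K",
    "methionine": "M", "phenylalanine": "F", "proline": "P", "serine": "S",
    "threonine": "T", "tryptophan": "W", "tyrosine": "Y", "valine": "V",
}
_STOP_TOKENS = {"*", "X", "TER", "STOP", "TERM"}
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")
_NT = set("ACGT")


def _aa_to_one(token: str) -> str:
    """Resolve a 1-letter, 3-letter or full amino-acid name to one letter."""
    t = token.strip()
    if t.upper() in _STOP_TOKENS:
        return "*"
    if len(t) == 1 and t.upper() in _AA1:
        return t.upper()
    t3 = t[:1].upper() + t[1:].lower()
    if t3 in AA3_TO_1:
        return AA3_TO_1[t3]
    if t.lower() in FULL_TO_1:
        return FULL_TO_1[t.lower()]
    raise NormalizationError(f"unknown amino-acid token: {token!r}")


# --- normalization operations ------------------------------------------------

def normalize_protein_sub(wt: str, pos: int | str, mut: str) -> NormalizedVariant:
    """Protein substitution → one-letter canonical form (Ala,140,Thr → A140T)."""
    pos = int(pos)
    if pos < 1:
        raise NormalizationError(f"protein position must be >= 1, got {pos}")
    w, m = _aa_to_one(wt), _aa_to_one(mut)
    if w == "*":
        raise NormalizationError("wild-type amino acid cannot be a stop codon")
    return NormalizedVariant(
        level="protein", hgvs=f"{w}{pos}{m}", provenance="protein_sub"
    )


_POS_TOKEN = re.compile(r"^\d+(?:[+-]\d+)?$")


def normalize_dna_sub(pos: int | str, wt: str, mut: str) -> NormalizedVariant:
    """DNA substitution → ``c.[pos][wt]>[mut]``.

    ``pos`` may be an integer or an opaque intronic-offset token such as
    ``1410-54``, which is carried verbatim.
    """
    pos_s = str(pos)
    if not _POS_TOKEN.match(pos_s) or pos_s.startswith("0"):
        raise NormalizationError(f"bad DNA position: {pos!r}")
    wt, mut = wt.upper(), mut.upper()
    if wt not in _NT or mut not in _NT:
        raise NormalizationError(f"non-ACGT allele: {wt!r}>{mut!r}")
    if wt == mut:
        raise DegenerateSubstitutionError(f"degenerate substitution {wt}>{mut}")
    return NormalizedVariant(level="dna", hgvs=f"c.{pos_s}{wt}>{mut}", provenance="dna_sub")


# Hyphens inside an indel position are range separators, not intronic
# offsets (offset arithmetic is out of scope for indels).
_INDEL_RE = re.compile(
    r"^(?:c\.)?(\d+)(?:[_\-](\d+))?"
    r"(delins|del|ins|dup)([ACGTacgt]+|\d+)?$"
)


def normalize_indel(raw: str, tolerant_prefix: bool = True) -> NormalizedVariant:
    """Canonicalize a DNA indel string.

    Hyphen range separators become underscores (``c.597-598delGA`` →
    ``c.597_598delGA``), base payloads are upper-cased, and a missing
    ``c.`` prefix is added when ``tolerant_prefix`` is on (``840insT`` →
    ``c.840insT``). Already-canonical input is returned unchanged.
    """
    compact = raw.replace(" ", "")
    m = _INDEL_RE.match(compact)
    if m is None:
        raise NormalizationError(f"unparseable indel: {raw!r}")
    if not compact.startswith("c.") and not tolerant_prefix:
        raise NormalizationError(f"indel without c. prefix: {raw!r}")
    start, end, op, payload = m.groups()
    hgvs = "c." + start
    if end is not None:
        hgvs += "_" + end
    hgvs += op
    if payload is not None:
        hgvs += payload.upper() if not payload.isdigit() else payload
    return NormalizedVariant(level="dna", hgvs=hgvs, provenance="dna_indel")


def normalize_protein_indel(mention: MutationMention) -> NormalizedVariant:
    """Canonicalize an extended protein indel (p.Glu554_Val559del style)."""
    c = mention.components
    start = f"{c.wt[:1].upper()}{c.wt[1:].lower()}{c.pos}"
    hgvs = f"p.{start}"
    if c.mut is not None and c.pos_end is not None:
        hgvs += f"_{c.mut[:1].upper()}{c.mut[1:].lower()}{c.pos_end}"
    hgvs += c.op if c.payload is None else f"delins{c.payload}"
    return NormalizedVariant(level="protein", hgvs=hgvs, provenance="protein_indel")


def expand_codon(codon: int) -> list[int]:
    """Codon number → the three candidate nucleotide positions 3c−2..3c."""
    codon = int(codon)
    if codon < 1:
        raise NormalizationError(f"codon must be >= 1, got {codon}")
    return [3 * codon - 2, 3 * codon - 1, 3 * codon]


@dataclass
class RsidLookup:
    """Local rsid → candidate-variant table standing in for a dbSNP query."""

    table: dict[str, frozenset[NormalizedVariant]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RsidLookup":
        """Load from TSV columns (rsid, level, hgvs)."""
        table: dict[str, set[NormalizedVariant]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            rsid, level, hgvs = line.rstrip("\n").split("\t")[:3]
            if not re.match(r"^rs\d+$", rsid):
                raise ValueError(f"malformed rsid key: {rsid!r}")
            table.setdefault(rsid, set()).add(
                NormalizedVariant(level=level, hgvs=hgvs, provenance="rsid")
            )
        return cls(table={k: frozenset(v) for k, v in table.items()})


def expand_rsid(rsid: str, lookup: RsidLookup) -> set[NormalizedVariant]:
    """All candidate DNA/protein variants recorded for an rs-number.

    Unknown ids yield an empty set (logged); malformed ids are an error.
    """
    if not re.match(r"^rs\d+$", rsid):
        raise NormalizationError(f"malformed rsid: {rsid!r}")
    hits = lookup.table.get(rsid)
    if hits is None:
        logger.info("rsid %s not in lookup table", rsid)
        return set()
    return set(hits)


def normalize_mention(
    mention: MutationMention,
    cfg: MatchConfig | None = None,
    rsid_lookup: RsidLookup | None = None,
):
    """Convert one mention to canonical variants.

    Returns a tuple of :class:`NormalizedVariant` (an rsid may expand to
    several, and an unknown rsid to none), or :data:`DROPPED` for imprecise
    mentions (exon/intron positions, codon mentions when codon expansion is
    disabled). Raises :class:`NormalizationError` for malformed input.
    """
    cfg = cfg or MatchConfig()
    c = mention.components
    k = mention.mention_class

    if k == "rsid":
        if not cfg.rsid_expansion or rsid_lookup is None:
            return ()
        return tuple(sorted(expand_rsid(mention.raw, rsid_lookup), key=lambda v: v.hgvs))

    if c.exon_intron or (c.pos is None and k != "rsid"):
        return DROPPED

    if k == "dna_sub":
        return (normalize_dna_sub(c.pos, c.wt, c.mut),)

    if k == "nl_sub":
        if not c.codon:
            v = normalize_dna_sub(c.pos, c.wt, c.mut)
            return (replace(v, provenance="nl_sub"),)
        if not cfg.codon_expansion:
            return DROPPED
        positions = expand_codon(int(c.pos))
        wt, mut = c.wt.upper(), c.mut.upper()
        if wt == mut:
            raise DegenerateSubstitutionError(f"degenerate substitution {wt}>{mut}")
        candidates = [f"c.{p}{wt}>{mut}" for p in positions]
        return (
            NormalizedVariant(
                level="dna",
                hgvs=candidates[0],
                alternates=frozenset(candidates[1:]),
                provenance="nl_sub_codon",
            ),
        )

    if k == "protein_sub":
        return (normalize_protein_sub(c.wt, int(c.pos), c.mut),)

    if k == "dna_indel":
        return (normalize_indel(mention.raw, tolerant_prefix=cfg.tolerant_prefix),)

    if k == "protein_indel":
        return (normalize_protein_indel(mention),)

    raise NormalizationError(f"unhandled mention class: {k!r}")


def drop_imprecise(mention: MutationMention, cfg: MatchConfig | None = None):
    """Gatekeeper: imprecise mentions → :data:`DROPPED`, others normalize.

    A mention whose position is an exon/intron number, or that carries no
    position at all ("entire gene deletion"), cannot yield a precise
    coordinate and is removed; every other mention proceeds to
    normalization and the primary canonical variant is returned.
    """
    result = normalize_mention(mention, cfg=cfg)
    if result is DROPPED or not result:
        return DROPPED
    return result[0]


# --- equivalence -------------------------------------------------------------

_DEL_RE = re.compile(
    r"^c\.(\d+(?:[+-]\d+)?(?:_\d+(?:[+-]\d+)?)?)del([ACGT]+|\d+)$"
)


def _del_parts(hgvs: str) -> tuple[str, str] | None:
    m = _DEL_RE.match(hgvs)
    return (m.group(1), m.group(2)) if m else None


def variant_equivalent(
    a: NormalizedVariant, b: NormalizedVariant, cfg: MatchConfig | None = None
) -> bool:
    """Decide whether two canonical variants denote the same change.

    True when the identity sets (canonical string plus codon/RSID
    alternates) intersect, or — with ``del_length_equivalence`` — when one
    side writes a deletion by its base string and the other by its length
    at the same position or range (``c.482_483delGA`` ≡ ``c.482_483del2``).
    A level mismatch is ``False``, not an error. With all flags off the
    relation reduces to string equality.
    """
    cfg = cfg or MatchConfig()
    if a.level != b.level:
        return False
    if a.identity_set & b.identity_set:
        return True
    if cfg.del_length_equivalence and a.level == "dna":
        for x in a.identity_set:
            px = _del_parts(x)
            if px is None:
                continue
            for y in b.identity_set:
                py = _del_parts(y)
                if py is None or px[0] != py[0]:
                    continue
                bx, by = px[1], py[1]
                if bx.isdigit() != by.isdigit():
                    count = int(bx) if bx.isdigit() else int(by)
                    bases = by if bx.isdigit() else bx
                    if len(bases) == count:
                        return True
    return False
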