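"""Variant and gene mention recognition over plain-text sections.

The scanner is a rule-based pattern engine covering the surface forms a
curation-recall study encounters: canonical HGVS substitutions and indels,
legacy forms without the ``c.`` prefix or the dot, compact ``C676T`` style,
dbSNP rs-numbers, natural-language substitutions ("C > T mutation at
nucleotide 2131"), protein indels (``p.Glu554_Val559del``) and imprecise
exon/intron mentions ("Del exon 3"). Each class is individually toggleable
through :class:`PatternConfig`.

Whitespace inside patterns is restricted to literal spaces, never ``\\s``,
so tab-linearized tables can never bridge two cells into one mention.

Overlapping candidates are resolved leftmost start first, then longest
match, then a fixed class priority (canonical beats legacy beats compact).
Compact mentions like ``C676T`` whose two letters are both nucleotides are
classified as DNA substitutions (the reading under which ``C676T`` means
``c.676C>T``); a ``p.`` prefix forces the protein reading.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from varlit.ingest import DocumentSection

NUCLEOTIDES = set("ACGT")
AA1_CODES = set("ACDEFGHIKLMNPQRSTVWY")

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|"
    "Trp|Tyr|Val"
)
_STOP3 = "Ter|Stop"

MENTION_CLASSES = (
    "protein_sub",
    "dna_sub",
    "dna_indel",
    "protein_indel",
    "rsid",
    "nl_sub",
)


@dataclass(frozen=True)
class PatternConfig:
    """Which mention classes and tolerant surface forms are enabled.

    ``legacy_dna`` admits DNA substitutions without the dot or the prefix
    (``c580G > T``, ``676C>T``, ``C676T``); ``codon_position`` admits
    natural-language substitutions located by codon rather than nucleotide;
    ``exon_intron`` admits imprecise exon/intron deletion mentions, which
    are recognized but later dropped at normalization because no precise
    coordinate can be derived from them.
    """

    protein_sub: bool = True
    dna_sub: bool = True
    dna_indel: bool = True
    protein_indel: bool = True
    rsid: bool = True
    nl_sub: bool = True
    legacy_dna: bool = True
    codon_position: bool = True
    exon_intron: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PatternConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown pattern flags: {sorted(unknown)}")
        return cls(**mapping)

    def enabled_classes(self) -> set[str]:
        return {c for c in MENTION_CLASSES if getattr(self, c)}


@dataclass(frozen=True)
class Components:
    """Parsed fields of a mention; unused fields stay ``None``."""

    wt: str | None = None
    mut: str | None = None
    pos: str | None = None
    pos_end: str | None = None
    op: str | None = None          # del / ins / dup / delins
    payload: str | None = None     # deleted/inserted bases, or a count
    codon: bool = False            # position given at codon granularity
    exon_intron: bool = False      # position given as exon/intron number
    has_prefix: bool = False       # explicit c. / p. prefix in the text


@dataclass(frozen=True)
class MutationMention:
    mention_class: str
    raw: str
    span: tuple[int, int]
    components: Components

    def __post_init__(self):
        if self.mention_class not in MENTION_CLASSES:
            raise ValueError(f"unknown mention class: {self.mention_class!r}")


@dataclass(frozen=True)
class GeneMention:
    raw: str
    symbol: str
    hgnc_id: str | None
    span: tuple[int, int]


# --- pattern table -----------------------------------------------------------
# (name, compiled regex, priority, guard attribute(s) on PatternConfig)

_DNA_CANON = re.compile(
    r"\bc\.(\d+(?:[+-]\d+)?)([ACGT]) ?> ?([ACGT])(?![A-Za-z0-9])"
)
_DNA_NODOT = re.compile(
    r"\bc ?(\d+)([ACGT]) ?> ?([ACGT])(?![A-Za-z0-9])"
)
_DNA_BARE = re.compile(
    r"\b(\d+(?:[+-]\d+)?)([ACGT]) ?> ?([ACGT])(?![A-Za-z0-9])"
)
_PROT1 = re.compile(
    r"(?:\b(p\.)|\b)([ACDEFGHIKLMNPQRSTVWY])(\d{1,6})"
    r"([ACDEFGHIKLMNPQRSTVWY*X])(?![A-Za-z0-9])"
)
_PROT3 = re.compile(
    rf"\b(p\.)?({_AA3})(\d{{1,6}})({_AA3}|{_STOP3}|X)(?![A-Za-z0-9])",
    re.IGNORECASE,
)
# Indel positions are plain integers; a hyphen between two numbers is a
# range separator (c.597-598delGA), never an intronic offset.
_DNA_INDEL = re.compile(
    r"\b(?:(c\.) ?)?(\d+)(?:[_\-](\d+))? ?"
    r"(delins|del|ins|dup) ?([ACGT]+|\d+)?(?![A-Za-z0-9])"
)
_PROT_INDEL = re.compile(
    rf"\b(p\.)?({_AA3})(\d+)(?:_({_AA3})(\d+))?"
    rf"(delins(?:{_AA3})*|del|dup)(?![A-Za-z0-9])",
    re.IGNORECASE,
)
_RSID = re.compile(r"\brs\d+\b")
_NL_SUB = re.compile(
    r"\b([ACGT]) ?(?:>|→|-+>|to) ?([ACGT]) "
    r"(?:mutation|substitution|change) at (nucleotide|position|codon) (\d+)\b"
)
_EXON_INTRON = re.compile(
    r"\b[Dd]el(?:etion)?(?: of)? (?:exon|intron)s? \d+(?: ?[-–] ?\d+)?\b"
    r"|\b(?:exon|intron) \d+ deletion\b"
    r"|\bentire gene deletion\b"
)


def _parse_dna_sub(m: re.Match, has_prefix: bool, has_dot: bool) -> tuple[str, Components]:
    pos, wt, mut = m.group(1), m.group(2), m.group(3)
    return "dna_sub", Components(wt=wt, mut=mut, pos=pos, has_prefix=has_prefix)


_Candidate = tuple[int, int, int, str, Components]  # start, end, priority, class, comps


def _candidates(text: str, cfg: PatternConfig) -> list[_Candidate]:
    out: list[_Candidate] = []

    if cfg.dna_sub:
        for m in _DNA_CANON.finditer(text):
            _, c = _parse_dna_sub(m, True, True)
            out.append((m.start(), m.end(), 0, "dna_sub", c))
        if cfg.legacy_dna:
            for m in _DNA_NODOT.finditer(text):
                _, c = _parse_dna_sub(m, True, False)
                out.append((m.start(), m.end(), 1, "dna_sub", c))
            for m in _DNA_BARE.finditer(text):
                _, c = _parse_dna_sub(m, False, False)
                out.append((m.start(), m.end(), 2, "dna_sub", c))

    if cfg.nl_sub:
        for m in _NL_SUB.finditer(text):
            is_codon = m.group(3) == "codon"
            if is_codon and not cfg.codon_position:
                continue
            out.append((
                m.start(), m.end(), 0, "nl_sub",
                Components(wt=m.group(1), mut=m.group(2), pos=m.group(4), codon=is_codon),
            ))

    if cfg.dna_indel:
        for m in _DNA_INDEL.finditer(text):
            out.append((
                m.start(), m.end(), 0, "dna_indel",
                Components(
                    pos=m.group(2), pos_end=m.group(3), op=m.group(4),
                    payload=m.group(5), has_prefix=m.group(1) is not None,
                ),
            ))
        if cfg.exon_intron:
            for m in _EXON_INTRON.finditer(text):
                out.append((
                    m.start(), m.end(), 1, "dna_indel",
                    Components(op="del", exon_intron=True),
                ))

    if cfg.protein_indel:
        for m in _PROT_INDEL.finditer(text):
            op = m.group(6)
            payload = op[6:] if op.lower().startswith("delins") else None
            out.append((
                m.start(), m.end(), 0, "protein_indel",
                Components(
                    wt=m.group(2), pos=m.group(3), mut=m.group(4),
                    pos_end=m.group(5),
                    op="delins" if payload is not None else op.lower(),
                    payload=payload or None,
                    has_prefix=m.group(1) is not None,
                ),
            ))

    if cfg.protein_sub:
        for m in _PROT3.finditer(text):
            out.append((
                m.start(), m.end(), 1, "protein_sub",
                Components(
                    wt=m.group(2), pos=m.group(3), mut=m.group(4),
                    has_prefix=m.group(1) is not None,
                ),
            ))
    # Compact one-letter form: classified DNA when both letters are
    # nucleotides and no p. prefix forces the protein reading.
    if cfg.protein_sub or (cfg.dna_sub and cfg.legacy_dna):
        for m in _PROT1.finditer(text):
            prefixed = m.group(1) is not None
            wt, pos, mut = m.group(2), m.group(3), m.group(4)
            dna_like = wt in NUCLEOTIDES and mut in NUCLEOTIDES
            if not prefixed and dna_like:
                if cfg.dna_sub and cfg.legacy_dna:
                    out.append((
                        m.start(), m.end(), 2, "dna_sub",
                        Components(wt=wt, mut=mut, pos=pos),
                    ))
            elif cfg.protein_sub:
                out.append((
                    m.start(), m.end(), 2, "protein_sub",
                    Components(wt=wt, pos=pos, mut=mut, has_prefix=prefixed),
                ))

    if cfg.rsid:
        for m in _RSID.finditer(text):
            out.append((m.start(), m.end(), 0, "rsid", Components()))

    return out


def scan_mentions(section: DocumentSection, patterns: PatternConfig | None = None) -> list[MutationMention]:
    """Return all non-overlapping variant mentions in a section.

    Ties between overlapping candidates are broken leftmost start, then
    longest match, then class priority. Returns an empty list when nothing
    matches.
    """
    patterns = patterns or PatternConfig()
    text = section.text
    cands = sorted(
        _candidates(text, patterns), key=lambda c: (c[0], -(c[1] - c[0]), c[2])
    )
    mentions: list[MutationMention] = []
    last_end = -1
    for start, end, _prio, klass, comps in cands:
        if start < last_end:
            continue
        mentions.append(
            MutationMention(
                mention_class=klass,
                raw=text[start:end],
                span=(start, end),
                components=comps,
            )
        )
        last_end = end
    return mentions


# --- gene dictionary ---------------------------------------------------------

@dataclass
class GeneDictionary:
    """Surface form → (symbol, HGNC id) lookup with a collision stop list.

    ``apply_curation_adjustments`` reproduces the standard dictionary fixes
    for this task: surface forms identical to three-letter codon (amino
    acid) names are moved to the stop list, and the alias ``P53`` — absent
    from the source dictionaries — is added for TP53.
    """

    entries: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    stop_list: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.entries = {k.upper(): v for k, v in self.entries.items()}
        self.stop_list = {s.upper() for s in self.stop_list}
        for form in self.stop_list:
            self.entries.pop(form, None)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneDictionary":
        entries = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            surface, symbol = fields[0], fields[1]
            hgnc = fields[2] if len(fields) > 2 and fields[2] else None
            entries[surface] = (symbol, hgnc)
        return cls(entries=entries)

    def apply_curation_adjustments(self) -> "GeneDictionary":
        codon_names = {c.upper() for c in _AA3.split("|")}
        colliding = {k for k in self.entries if k in codon_names}
        entries = {k: v for k, v in self.entries.items() if k not in colliding}
        if "P53" not in entries:
            target = entries.get("TP53", ("TP53", None))
            entries["P53"] = target
        return GeneDictionary(entries=entries, stop_list=self.stop_list | colliding)

    def lookup(self, token: str, strip_h_prefix: bool = False) -> tuple[str, str | None] | None:
        key = token.upper()
        if key in self.stop_list:
            return None
        if key in self.entries:
            return self.entries[key]
        if strip_h_prefix and token[:1] in ("h", "H"):
            rest = token[1:].upper()
            if rest and rest not in self.stop_list and rest in self.entries:
                return self.entries[rest]
        return None


_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z0-9-]*")


def scan_genes(
    section: DocumentSection,
    dictionary: GeneDictionary,
    strip_h_prefix: bool = False,
) -> list[GeneMention]:
    """Case-insensitive dictionary lookup over word-boundary tokens.

    With ``strip_h_prefix`` a token ``hX`` resolves to entry ``X``
    (hMLH1 → MLH1), mirroring the historical h-prefixed gene names.
    """
    out = []
    for m in _TOKEN_RE.finditer(section.text):
        hit = dictionary.lookup(m.group(0), strip_h_prefix=strip_h_prefix)
        if hit is not None:
            out.append(
                GeneMention(raw=m.group(0), symbol=hit[0], hgnc_id=hit[1], span=m.span())
            )
    return out


_SENT_SPLIT = re.compile(r"[.!?](?=\s)")


def _sentence_index(text: str) -> list[int]:
    """Sentence id per character offset (naive terminal-punctuation split)."""
    ids = [0] * (len(text) + 1)
    sent = 0
    last = 0
    for m in _SENT_SPLIT.finditer(text):
        for i in range(last, m.end()):
            ids[i] = sent
        last = m.end()
        sent += 1
    for i in range(last, len(text) + 1):
        ids[i] = sent
    return ids


def associate(
    mentions: list[MutationMention],
    genes: list[GeneMention],
    scope: str = "document",
    text: str | None = None,
) -> list[tuple[MutationMention, str | None]]:
    """Pair mutation mentions with gene symbols by co-occurrence.

    ``document`` scope pairs every mention with every distinct gene symbol
    seen in the same source set, so one mutation may yield several pairs;
    mentions with no co-occurring gene pair with ``None`` (ABSENT).
    ``sentence`` scope restricts pairing to the same sentence and requires
    the section text.
    """
    if scope == "document":
        symbols = sorted({g.symbol for g in genes})
        pairs = []
        for m in mentions:
            if symbols:
                pairs.extend((m, s) for s in symbols)
            else:
                pairs.append((m, None))
        return pairs
    if scope == "sentence":
        if text is None:
            raise ValueError("sentence scope requires the section text")
        ids = _sentence_index(text)
        pairs = []
        for m in mentions:
            sid = ids[m.span[0]]
            symbols = sorted({g.symbol for g in genes if ids[g.span[0]] == sid})
            if symbols:
                pairs.extend((m, s) for s in symbols)
            else:
                pairs.append((m, None))
        return pairs
    raise ValueError(f"unknown scope: {scope!r}")
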