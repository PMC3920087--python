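"""Synthetic corpus and curated-database generator with a truth manifest.

The generator emulates the study conditions of a curation-recall analysis:

* heavy-tailed per-article mutation counts — a small high-throughput (HT)
  fraction of articles drawn from a log-normal law carries most of the
  curated mutations, while ordinary (NHT) articles follow a low-mean
  Poisson;
* per-source placement of mentions — most curated variants live in
  supplementary files, then narrative body, then abstracts and tables;
* a mix of mention formats, from canonical HGVS through legacy and
  natural-language forms down to formats that are unrecoverable by design
  (exon/intron mentions, variants split across spreadsheet columns).

Every planted mention is recorded in a :class:`TruthManifest`, which makes
every downstream metric analytically checkable: :func:`expected_recall`
computes, without running the extractor, exactly which curated records are
recoverable under a given pattern/match configuration. DNA/protein
consistency comes from a synthetic CDS per gene and the standard codon
table, so each record's DNA and protein variants describe the same change.

All outputs are pure functions of the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from xml.sax.saxutils import escape

import numpy as np
from Bio.Data import CodonTable

from varlit.evaluate import (
    SOURCE_SETS,
    CuratedRecord,
    RecallReport,
    dedupe_records,
    write_curated_db,
)
from varlit.hgvs import MatchConfig, NormalizedVariant
from varlit.ingest import (
    DocumentBundle,
    linearize_table,
    parse_abstract_xml,
    parse_fulltext_xml,
    read_delimited_supplement,
    read_pdf_text,
)
from varlit.mentions import GeneDictionary, PatternConfig
from varlit.mesh import MeSHDescriptor, label_article

SOURCES = ("abstract", "body", "table", "supplement", "pdf_text")
FORMATS = (
    "canonical_hgvs",
    "legacy_nodot",
    "natural_language",
    "codon_position",
    "exon_intron",
    "split_fields",
    "del_count",
)

#: Fixed pool of human gene symbols (with synthetic HGNC ids). Symbols are
#: chosen so no token collides with a variant mention pattern, and none
#: equals a three-letter amino-acid code (e.g. MET), which the
#: dictionary's codon-collision stop list would make unrecognizable.
GENE_POOL: tuple[tuple[str, str], ...] = tuple(
    (sym, f"HGNC:{1000 + i}")
    for i, sym in enumerate([
        "KRAS", "TP53", "MLH1", "MSH2", "MSH6", "PMS2", "BRAF", "EGFR",
        "BRCA1", "BRCA2", "APC", "PTEN", "PIK3CA", "ALK", "RET", "FLT3",
        "KIT", "ATM", "CHEK2", "CDH1", "STK11", "SMAD4", "VHL", "RB1",
        "NF1", "NF2", "TSC1", "TSC2", "MUTYH", "POLE", "POLD1", "AXIN2",
        "BMPR1A", "GREM1", "CDK4", "CDKN2A", "ERBB2", "FGFR2", "FGFR3",
        "HRAS", "NRAS", "IDH1", "IDH2", "JAK2", "KDR", "NOTCH1", "PDGFRA",
        "SMO", "TERT", "WT1",
    ])
)

_HT_HEADINGS = (
    ("Genome-wide screening", "E05.393.420"),
    ("Proteome analysis", "D12.776.817.150"),
    ("Sequence analysis", "L01.453.245.667.550"),
    ("Computational biology", "H01.158.273.180"),
)
_NHT_HEADINGS = (
    ("Case reports", "V03.150"),
    ("Immunohistochemistry", "E05.200.750"),
    ("Middle aged", "M01.060.116.630"),
    ("Pedigree", "E05.318.740.600"),
)

_FOOTNOTE_MARKS = ("ᵉ", "ᵇ")  # superscript e, superscript b

# The synthetic CDS must offer comfortably more codons than the largest
# per-article mutation count so unique-position sampling never saturates.
_CDS_CODONS = 5000

_table = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_table.forward_table)
_CODON_TO_AA.update({c: "*" for c in _table.stop_codons})
_NONSTOP_CODONS = sorted(_table.forward_table)


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _check_dist(name: str, dist: dict, keys: tuple[str, ...]) -> None:
    unknown = set(dist) - set(keys)
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    if any(v < 0 for v in dist.values()):
        raise ConfigError(f"{name}: negative probability")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities must sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Per-article mutation counts follow a mixture: NHT articles are
    Poisson(``lambda_nht``); HT articles (fraction ``ht_fraction``) draw
    from a log-normal with parameters ``ht_log_mean``/``ht_log_sigma``,
    giving the heavy tail in which a minority of articles carries the large
    majority of curated mutations. Placement and format distributions apply
    per mutation; ``ht_placement``/``ht_format_mix`` optionally override
    them for HT articles. ``abstract_echo_in_body`` is the probability that
    an abstract-placed mention is repeated in the body, reflecting that
    abstract content is almost always restated in the full text.
    """

    n_articles: int = 500
    gene_pool_size: int = 40
    ht_fraction: float = 0.2
    lambda_nht: float = 5.0
    ht_log_mean: float = 4.0
    ht_log_sigma: float = 1.2
    max_mut_per_article: int = 2000
    placement: dict = field(default_factory=lambda: {
        "abstract": 0.15, "body": 0.25, "table": 0.10,
        "supplement": 0.50, "pdf_text": 0.0,
    })
    format_mix: dict = field(default_factory=lambda: {"canonical_hgvs": 1.0})
    ht_placement: dict | None = None
    ht_format_mix: dict | None = None
    abstract_echo_in_body: float = 0.95
    noise_footnote_marks: bool = False
    noise_h_prefix_rate: float = 0.0
    noise_drop_c_prefix_rate: float = 0.0
    distractor_rate: float = 0.0
    unplanted_fraction: float = 0.0
    unindexed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_articles < 0:
            raise ConfigError("n_articles must be >= 0")
        if not 1 <= self.gene_pool_size <= len(GENE_POOL):
            raise ConfigError(f"gene_pool_size must be in 1..{len(GENE_POOL)}")
        for name in ("ht_fraction", "abstract_echo_in_body",
                     "noise_h_prefix_rate", "noise_drop_c_prefix_rate",
                     "unplanted_fraction", "unindexed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.lambda_nht < 0 or self.distractor_rate < 0:
            raise ConfigError("rates must be >= 0")
        if not 1 <= self.max_mut_per_article <= _CDS_CODONS // 2:
            raise ConfigError(
                f"max_mut_per_article must be in 1..{_CDS_CODONS // 2}"
            )
        _check_dist("placement", self.placement, SOURCES)
        _check_dist("format_mix", self.format_mix, FORMATS)
        if self.ht_placement is not None:
            _check_dist("ht_placement", self.ht_placement, SOURCES)
        if self.ht_format_mix is not None:
            _check_dist("ht_format_mix", self.ht_format_mix, FORMATS)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PlantedMention:
    """One manifest row: a mention rendered into a document source.

    ``record_index`` links back to the curated record (None for
    distractors, which are true mentions the database never curated).
    ``fmt`` may differ from the drawn format when noise rewrites the
    surface form (dropping the ``c.`` prefix turns canonical into
    ``legacy_bare``).
    """

    doc_id: str
    record_index: int | None
    gene: str
    hgnc_id: str
    source_kind: str
    fmt: str
    curated: bool
    h_prefixed: bool = False
    footnote_marked: bool = False
    echo: bool = False
    # rendering fields
    kind: str = "sub"          # sub | del | exon
    pos: int | None = None
    wt: str | None = None
    mut: str | None = None
    codon: int | None = None
    del_start: int | None = None
    del_end: int | None = None
    del_bases: str | None = None
    exon_num: int | None = None
    dna_hgvs: str | None = None
    protein_hgvs: str | None = None


@dataclass
class DocInfo:
    doc_id: str
    is_ht: bool
    headings: tuple[tuple[str, str], ...]  # (heading, tree code)
    unindexed: bool


@dataclass
class TruthManifest:
    rows: list[PlantedMention]
    docs: list[DocInfo]
    n_unplanted: int

    def to_json(self) -> str:
        payload = {
            "n_unplanted": self.n_unplanted,
            "docs": [dataclasses.asdict(d) for d in self.docs],
            "rows": [dataclasses.asdict(r) for r in self.rows],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _gene_cds(seed: int, gene_index: int) -> str:
    rng = np.random.default_rng([seed, 977, gene_index])
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=_CDS_CODONS)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _draw(rng: np.random.Generator, dist: dict, keys: tuple[str, ...]) -> str:
    names = [k for k in keys if dist.get(k, 0.0) > 0]
    probs = np.array([dist[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def generate_curated_db(
    cfg: GeneratorConfig,
) -> tuple[list[CuratedRecord], TruthManifest]:
    """Draw the curated database and the truth-manifest skeleton.

    Deterministic given ``cfg.seed``. Counts come from the NHT/HT mixture;
    each record gets a gene from the pool, a DNA variant placed on that
    gene's synthetic CDS and — for substitutions — the consistent protein
    variant under the standard codon table. Codon positions are unique
    within an article, so no two records of one article have equivalent
    variants even under codon expansion.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = GENE_POOL[: cfg.gene_pool_size]
    cds = {gi: _gene_cds(cfg.seed, gi) for gi in range(len(pool))}

    records: list[CuratedRecord] = []
    rows: list[PlantedMention] = []
    docs: list[DocInfo] = []
    n_unplanted = 0

    for i in range(cfg.n_articles):
        doc_id = f"PM{100000 + i}"
        is_ht = bool(rng.random() < cfg.ht_fraction)
        if is_ht:
            count = int(rng.lognormal(cfg.ht_log_mean, cfg.ht_log_sigma))
            count = max(1, min(count, cfg.max_mut_per_article))
        else:
            count = int(rng.poisson(cfg.lambda_nht))
            count = min(count, cfg.max_mut_per_article)
        unindexed = bool(rng.random() < cfg.unindexed_fraction)
        if unindexed:
            headings: tuple[tuple[str, str], ...] = ()
        elif is_ht:
            ht_h = _HT_HEADINGS[int(rng.integers(len(_HT_HEADINGS)))]
            nht_h = _NHT_HEADINGS[int(rng.integers(len(_NHT_HEADINGS)))]
            headings = (nht_h, ht_h)
        else:
            picks = rng.choice(len(_NHT_HEADINGS), size=2, replace=False)
            headings = tuple(_NHT_HEADINGS[int(p)] for p in picks)
        docs.append(DocInfo(doc_id, is_ht, headings, unindexed))

        placement = cfg.ht_placement if (is_ht and cfg.ht_placement) else cfg.placement
        format_mix = cfg.ht_format_mix if (is_ht and cfg.ht_format_mix) else cfg.format_mix

        used_codons: set[int] = set()
        used_exons: set[int] = set()

        def fresh_codon() -> int:
            while True:
                c = int(rng.integers(1, _CDS_CODONS + 1))
                if c not in used_codons:
                    used_codons.add(c)
                    return c

        for _ in range(count):
            gi = int(rng.integers(len(pool)))
            symbol, hgnc = pool[gi]
            fmt = _draw(rng, format_mix, FORMATS)
            src = _draw(rng, placement, SOURCES)
            if fmt == "split_fields":
                src = "supplement"

            row = PlantedMention(
                doc_id=doc_id, record_index=len(records), gene=symbol,
                hgnc_id=hgnc, source_kind=src, fmt=fmt, curated=True,
            )
            if fmt == "del_count":
                codon = fresh_codon()
                p = 3 * (codon - 1) + 1
                bases = cds[gi][p - 1 : p + 1]
                dna = f"c.{p}_{p + 1}del{bases}"
                record = CuratedRecord(
                    doc_id=doc_id, gene_symbol=symbol, hgnc_id=hgnc,
                    dna_variant=NormalizedVariant("dna", dna),
                )
                row.kind = "del"
                row.del_start, row.del_end, row.del_bases = p, p + 1, bases
                row.dna_hgvs = dna
            elif fmt == "exon_intron":
                while True:
                    k = int(rng.integers(2, 2 * cfg.max_mut_per_article + 2))
                    if k not in used_exons:
                        used_exons.add(k)
                        break
                dna = f"c.{100 * k + 1}-?_{100 * k + 99}+?del"
                record = CuratedRecord(
                    doc_id=doc_id, gene_symbol=symbol, hgnc_id=hgnc,
                    dna_variant=NormalizedVariant("dna", dna),
                )
                row.kind = "exon"
                row.exon_num = k
                row.dna_hgvs = dna
            else:
                codon = fresh_codon()
                offset = int(rng.integers(3))
                pos = 3 * (codon - 1) + offset + 1
                wt_codon = cds[gi][3 * (codon - 1) : 3 * codon]
                wt = wt_codon[offset]
                mut = str(rng.choice(sorted(set("ACGT") - {wt})))
                mut_codon = wt_codon[:offset] + mut + wt_codon[offset + 1 :]
                dna = f"c.{pos}{wt}>{mut}"
                prot = f"{_CODON_TO_AA[wt_codon]}{codon}{_CODON_TO_AA[mut_codon]}"
                record = CuratedRecord(
                    doc_id=doc_id, gene_symbol=symbol, hgnc_id=hgnc,
                    dna_variant=NormalizedVariant("dna", dna),
                    protein_variant=NormalizedVariant("protein", prot),
                )
                row.kind = "sub"
                row.pos, row.wt, row.mut, row.codon = pos, wt, mut, codon
                row.dna_hgvs, row.protein_hgvs = dna, prot
            records.append(record)

            if rng.random() < cfg.unplanted_fraction:
                n_unplanted += 1
                continue

            if fmt == "canonical_hgvs" and rng.random() < cfg.noise_drop_c_prefix_rate:
                row.fmt = "legacy_bare"
            row.h_prefixed = bool(rng.random() < cfg.noise_h_prefix_rate)
            row.footnote_marked = bool(cfg.noise_footnote_marks and src == "table")
            rows.append(row)
            if src == "abstract" and rng.random() < cfg.abstract_echo_in_body:
                echo = dataclasses.replace(
                    row, source_kind="body", echo=True, footnote_marked=False
                )
                rows.append(echo)

        # distractors: true mentions the database never curated
        n_d = int(rng.poisson(cfg.distractor_rate))
        for _ in range(n_d):
            gi = int(rng.integers(len(pool)))
            symbol, hgnc = pool[gi]
            codon = fresh_codon()
            offset = int(rng.integers(3))
            pos = 3 * (codon - 1) + offset + 1
            wt = cds[gi][3 * (codon - 1) + offset]
            mut = str(rng.choice(sorted(set("ACGT") - {wt})))
            src = _draw(rng, placement, SOURCES)
            rows.append(PlantedMention(
                doc_id=doc_id, record_index=None, gene=symbol, hgnc_id=hgnc,
                source_kind=src, fmt="canonical_hgvs", curated=False,
                kind="sub", pos=pos, wt=wt, mut=mut, codon=codon,
                dna_hgvs=f"c.{pos}{wt}>{mut}",
            ))

    manifest = TruthManifest(rows=rows, docs=docs, n_unplanted=n_unplanted)
    return records, manifest


# --- rendering ---------------------------------------------------------------

def _mention_text(row: PlantedMention) -> str:
    fmt = row.fmt
    if fmt == "canonical_hgvs":
        return row.dna_hgvs
    if fmt == "legacy_nodot":
        return f"c{row.pos}{row.wt} > {row.mut}"
    if fmt == "legacy_bare":
        return f"{row.pos}{row.wt}>{row.mut}"
    if fmt == "natural_language":
        return f"{row.wt} > {row.mut} mutation at nucleotide {row.pos}"
    if fmt == "codon_position":
        return f"{row.wt} > {row.mut} mutation at codon {row.codon}"
    if fmt == "del_count":
        return f"c.{row.del_start}_{row.del_end}del{len(row.del_bases)}"
    if fmt == "exon_intron":
        return f"Del exon {row.exon_num}"
    raise ValueError(f"no surface form for format {fmt!r}")


def _gene_text(row: PlantedMention) -> str:
    return f"h{row.gene}" if row.h_prefixed else row.gene


def _mark_cell(text: str) -> str:
    e, b = _FOOTNOTE_MARKS
    if "del" in text:
        i = text.index("del") + 3
        return text[:i] + e + text[i:] + b
    return text + e + b


def render_bundle(
    doc: DocInfo, rows: list[PlantedMention], cfg: GeneratorConfig
) -> dict[str, str]:
    """Render one article's sources as text files (name → content).

    Always emits an abstract and a full text (with a filler paragraph, so a
    body is never missing); tables, supplements and PDF text appear only
    when a mention is placed there. Mentions of ``split_fields`` format
    spread position, wild-type and mutant allele over separate spreadsheet
    columns, which no contiguous pattern can recognize.
    """
    by_src: dict[str, list[PlantedMention]] = {k: [] for k in SOURCES}
    for r in rows:
        by_src[r.source_kind].append(r)

    files: dict[str, str] = {}

    abs_sentences = [
        "We studied tumour samples from a clinical cohort and reviewed the"
        " molecular findings."
    ]
    for r in by_src["abstract"]:
        abs_sentences.append(
            f"In this cohort the {_gene_text(r)} variant {_mention_text(r)}"
            " was detected."
        )
    files["abstract.xml"] = (
        f"<PubmedArticle><PMID>{doc.doc_id}</PMID><Abstract>"
        f"{escape(' '.join(abs_sentences))}</Abstract></PubmedArticle>"
    )

    paras = [
        "<p>Specimens were processed following standard protocols and"
        " screened for recurrent alterations.</p>"
    ]
    for r in by_src["body"]:
        paras.append(
            f"<p>Sequencing of {escape(_gene_text(r))} revealed"
            f" {escape(_mention_text(r))} in the present series.</p>"
        )
    table_xml = ""
    table_rows = by_src["table"]
    if table_rows:
        marked = any(r.footnote_marked for r in table_rows)
        attr = f' footnote-marks="{"".join(_FOOTNOTE_MARKS)}"' if marked else ""
        cells = ["<tr><td>Gene</td><td>Variant</td></tr>"]
        for r in table_rows:
            var = _mention_text(r)
            if r.footnote_marked:
                var = _mark_cell(var)
            cells.append(
                f"<tr><td>{escape(_gene_text(r))}</td><td>{escape(var)}</td></tr>"
            )
        table_xml = (
            f'<table-wrap id="T1"{attr}><caption>Alterations identified in'
            f" the screened series.</caption><table>{''.join(cells)}</table>"
            "</table-wrap>"
        )
    files["fulltext.xml"] = (
        "<article><body><sec>"
        + "".join(paras)
        + "</sec>"
        + table_xml
        + "<back><ref-list><ref>Reference entry one.</ref></ref-list></back>"
        "</body></article>"
    )

    if by_src["pdf_text"]:
        lines = [
            f"Variant {_mention_text(r)} of {_gene_text(r)} (converted page)."
            for r in by_src["pdf_text"]
        ]
        files["pdf.txt"] = "\n".join(lines)

    supp = [r for r in by_src["supplement"] if r.fmt != "split_fields"]
    split = [r for r in by_src["supplement"] if r.fmt == "split_fields"]
    if supp:
        lines = ["gene\tvariant"]
        lines += [f"{_gene_text(r)}\t{_mention_text(r)}" for r in supp]
        files["supplement.tsv"] = "\n".join(lines)
    if split:
        lines = ["gene\tposition\twild_type\tmutant"]
        lines += [f"{_gene_text(r)}\t{r.pos}\t{r.wt}\t{r.mut}" for r in split]
        files["supplement_split.tsv"] = "\n".join(lines)
    return files


@dataclass
class SyntheticCorpus:
    """A generated corpus: curated records, truth manifest, rendered files."""

    cfg: GeneratorConfig
    records: list[CuratedRecord]
    manifest: TruthManifest
    files: dict[str, dict[str, str]]  # doc_id -> {filename: content}

    @property
    def doc_ids(self) -> set[str]:
        return {d.doc_id for d in self.manifest.docs}

    def gene_dictionary(self) -> GeneDictionary:
        pool = GENE_POOL[: self.cfg.gene_pool_size]
        entries = {sym: (sym, hgnc) for sym, hgnc in pool}
        return GeneDictionary(entries=entries).apply_curation_adjustments()

    def mesh_labels(self) -> dict[str, str]:
        return {
            d.doc_id: label_article(
                [MeSHDescriptor(h, frozenset({c})) for h, c in d.headings]
            )
            for d in self.manifest.docs
        }

    def bundles(self) -> list[DocumentBundle]:
        """Parse the rendered files through the document ingester."""
        out = []
        for d in self.manifest.docs:
            f = self.files[d.doc_id]
            bundle = DocumentBundle(doc_id=d.doc_id)
            bundle.sections.append(parse_abstract_xml(f["abstract.xml"]))
            secs, grids = parse_fulltext_xml(f["fulltext.xml"])
            bundle.sections.extend(secs)
            bundle.sections.extend(linearize_table(g) for g in grids)
            if "pdf.txt" in f:
                bundle.sections.append(read_pdf_text(f["pdf.txt"]))
            for name in ("supplement.tsv", "supplement_split.tsv"):
                if name in f:
                    bundle.sections.append(
                        read_delimited_supplement(f[name], "tsv", origin=name)
                    )
            out.append(bundle)
        return out

    def write(self, outdir: str | Path) -> Path:
        """Write bundles, manifest JSON, curated DB and lookup tables.

        Byte-identical across runs for a fixed configuration.
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kind_of = {
            "abstract.xml": "abstract",
            "fulltext.xml": "body",
            "pdf.txt": "pdf_text",
            "supplement.tsv": "supplement",
            "supplement_split.tsv": "supplement",
        }
        entries = []
        for d in self.manifest.docs:
            doc_dir = out / "docs" / d.doc_id
            doc_dir.mkdir(parents=True, exist_ok=True)
            sources = []
            for name, content in sorted(self.files[d.doc_id].items()):
                (doc_dir / name).write_text(content, encoding="utf-8")
                sources.append({
                    "path": f"docs/{d.doc_id}/{name}",
                    "source_kind": kind_of[name],
                })
            entries.append({"doc_id": d.doc_id, "sources": sources})
        (out / "manifest.json").write_text(
            json.dumps({"documents": entries}, indent=1, sort_keys=True),
            encoding="utf-8",
        )
        write_curated_db(self.records, out / "curated_db.tsv")
        gd = self.gene_dictionary()
        lines = [
            f"{surface}\t{sym}\t{hgnc or ''}"
            for surface, (sym, hgnc) in sorted(gd.entries.items())
        ]
        (out / "gene_dictionary.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
        headings_seen: dict[str, str] = {}
        art_lines = ["doc_id\theadings"]
        for d in self.manifest.docs:
            for h, c in d.headings:
                headings_seen[h] = c
            art_lines.append(
                d.doc_id + "\t" + ";".join(h for h, _ in d.headings)
            )
        mesh_lines = ["heading\ttree_codes"]
        mesh_lines += [f"{h}\t{c}" for h, c in sorted(headings_seen.items())]
        (out / "mesh_descriptors.tsv").write_text(
            "\n".join(mesh_lines) + "\n", encoding="utf-8"
        )
        (out / "article_headings.tsv").write_text(
            "\n".join(art_lines) + "\n", encoding="utf-8"
        )
        (out / "truth_manifest.json").write_text(
            self.manifest.to_json(), encoding="utf-8"
        )
        return out


def generate_corpus(cfg: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate the curated database and render every article bundle."""
    cfg = cfg or GeneratorConfig()
    records, manifest = generate_curated_db(cfg)
    rows_by_doc: dict[str, list[PlantedMention]] = {}
    for r in manifest.rows:
        rows_by_doc.setdefault(r.doc_id, []).append(r)
    files = {
        d.doc_id: render_bundle(d, rows_by_doc.get(d.doc_id, []), cfg)
        for d in manifest.docs
    }
    return SyntheticCorpus(cfg=cfg, records=records, manifest=manifest, files=files)


# --- analytic oracle ---------------------------------------------------------

def format_recognizable(fmt: str, patterns: PatternConfig, mcfg: MatchConfig) -> bool:
    """Whether a planted format can be recovered and matched to its record
    under the given pattern and match configuration. ``exon_intron`` and
    ``split_fields`` are unrecoverable by design."""
    if fmt == "canonical_hgvs":
        return patterns.dna_sub
    if fmt in ("legacy_nodot", "legacy_bare"):
        return patterns.dna_sub and patterns.legacy_dna
    if fmt == "natural_language":
        return patterns.nl_sub
    if fmt == "codon_position":
        return patterns.nl_sub and patterns.codon_position and mcfg.codon_expansion
    if fmt == "del_count":
        return patterns.dna_indel and mcfg.del_length_equivalence
    if fmt in ("exon_intron", "split_fields"):
        return False
    raise ValueError(f"unknown format {fmt!r}")


def format_yields_triple(fmt: str, patterns: PatternConfig, mcfg: MatchConfig) -> bool:
    """Whether a planted format produces an extracted triple at all.

    Differs from :func:`format_recognizable` for ``del_count``: the count
    form is scanned and normalized into a triple even when deletion-length
    equivalence is off — it merely fails to match its record. The
    distinction matters for the common-article denominator, which counts
    any positive extraction, matched or not.
    """
    if fmt == "del_count":
        return patterns.dna_indel
    return format_recognizable(fmt, patterns, mcfg)


def expected_recall(
    corpus: SyntheticCorpus,
    patterns: PatternConfig | None = None,
    mcfg: MatchConfig | None = None,
    strip_h_prefix: bool = False,
) -> dict[str, RecallReport]:
    """Analytic per-source recall from the truth manifest — no simulation.

    For each source set, a curated record counts as recoverable when it has
    a planted mention in that set whose format is recognizable under the
    configuration; the full (gene-matched) variant additionally requires
    its gene symbol to be recognizable somewhere in the same article and
    source kind (an h-prefixed rendering needs the prefix-stripping flag).
    Common-article denominators restrict to articles with curated records
    and at least one recognizable planted mention.
    """
    patterns = patterns or PatternConfig()
    mcfg = mcfg or MatchConfig()
    records = dedupe_records(corpus.records)
    n = len(records)
    index_of = {id(r): i for i, r in enumerate(corpus.records)}

    rows_by_record: dict[int, list[PlantedMention]] = {}
    genes_ok: dict[tuple[str, str], set[str]] = {}
    extracted_at: set[tuple[str, str]] = set()
    for row in corpus.manifest.rows:
        key = (row.doc_id, row.source_kind)
        if not row.h_prefixed or strip_h_prefix:
            genes_ok.setdefault(key, set()).add(row.gene)
        if format_yields_triple(row.fmt, patterns, mcfg):
            extracted_at.add(key)
        if row.record_index is not None:
            rows_by_record.setdefault(row.record_index, []).append(row)

    # map original record index -> deduped record index
    key_to_pos = {r.key(): i for i, r in enumerate(records)}
    curated_docs = {r.doc_id for r in records}
    docs_of_record = [r.doc_id for r in records]

    out: dict[str, RecallReport] = {}
    for label, kinds in SOURCE_SETS.items():
        matched: set[int] = set()
        matched_ng: set[int] = set()
        for orig_idx, rows in rows_by_record.items():
            pos = key_to_pos[corpus.records[orig_idx].key()]
            for row in rows:
                if row.source_kind not in kinds:
                    continue
                if not format_recognizable(row.fmt, patterns, mcfg):
                    continue
                matched_ng.add(pos)
                if row.gene in genes_ok.get((row.doc_id, row.source_kind), set()):
                    matched.add(pos)
        common = {
            d for d in curated_docs
            if any((d, k) in extracted_at for k in kinds)
        }
        common_idx = [i for i in range(n) if docs_of_record[i] in common]
        n_common = len(common_idx)
        m_common = sum(1 for i in matched if docs_of_record[i] in common)
        mng_common = sum(1 for i in matched_ng if docs_of_record[i] in common)
        out[label] = RecallReport(
            n_curated=n,
            n_common_curated=n_common,
            n_common_docs=len(common),
            matched=len(matched),
            matched_ng=len(matched_ng),
            recall=len(matched) / n if n else 0.0,
            recall_ng=len(matched_ng) / n if n else 0.0,
            recall_common=(m_common / n_common) if n_common else 0.0,
            recall_common_ng=(mng_common / n_common) if n_common else 0.0,
        )
    return out
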