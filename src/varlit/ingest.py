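"""Document ingestion: XML abstracts, simplified JATS full text, supplements.

Every parser emits :class:`DocumentSection` objects whose ``text`` is plain
unicode — no markup, no XML character entities — so the downstream pattern
engine sees exactly what a reader sees. Tables are kept as rectangular
:class:`TableGrid` objects until :func:`linearize_table` flattens them with
tab separators (a character that cannot occur inside any supported variant
mention, so linearization never creates or destroys mentions).
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

SOURCE_KINDS = ("abstract", "body", "table", "pdf_text", "supplement")

#: Elements of the simplified JATS subset understood by the full-text parser.
_KNOWN_TAGS = {
    "article", "front", "abstract", "body", "sec", "p", "title",
    "table-wrap", "caption", "table", "thead", "tbody", "tr", "td", "th",
    "row", "cell", "back", "ref-list", "ref", "supplementary-material",
}

_WS_RE = re.compile(r"\s+")


class IngestError(Exception):
    """Base class for ingestion failures."""


class ParseError(IngestError):
    """Malformed XML input."""


class MissingSectionError(IngestError):
    """An expected element (e.g. the abstract) is absent."""


class BodyMissingError(IngestError):
    """Full-text document carries a title/abstract but no body content.

    Mirrors the corpus filter that discards articles found to contain only
    a title and an abstract.
    """


class RaggedTableError(IngestError):
    """Table rows of unequal length."""


class EncodingError(IngestError):
    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


@dataclass(frozen=True)
class DocumentSection:
    """A single unit of searchable text from one article source.

    ``source_kind`` is one of :data:`SOURCE_KINDS`; ``origin`` is a
    provenance label such as a table id or supplement filename.
    """

    source_kind: str
    text: str
    origin: str = ""

    def __post_init__(self):
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source_kind: {self.source_kind!r}")


@dataclass
class TableGrid:
    """A rectangular table: caption, cells and declared footnote marks.

    Footnote marks are single characters (typically Unicode superscript
    letters) declared per table in the document metadata; they are removed
    from cell payloads at linearization time, never auto-detected.
    """

    caption: str
    cells: list[list[str]]
    footnote_marks: frozenset[str] = frozenset()
    origin: str = ""

    def validate(self) -> None:
        if self.cells:
            widths = {len(row) for row in self.cells}
            if len(widths) > 1:
                raise RaggedTableError(
                    f"table {self.origin or '<anonymous>'}: ragged rows, widths {sorted(widths)}"
                )


@dataclass
class DocumentBundle:
    """All searchable sources for one article."""

    doc_id: str
    sections: list[DocumentSection] = field(default_factory=list)

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def by_kind(self, kind: str) -> list[DocumentSection]:
        return [s for s in self.sections if s.source_kind == kind]


def _clean_text(raw: str) -> str:
    return _WS_RE.sub(" ", raw).strip()


def _parse_xml(xml_text: str) -> etree._Element:
    try:
        return etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc


def _local(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def parse_abstract_xml(xml_text: str) -> DocumentSection:
    """Parse a MEDLINE-style abstract XML into an abstract section.

    Character entities are decoded (``A-&gt;T`` becomes ``A->T``), inline
    tags are stripped while their character content is preserved, and
    whitespace is collapsed to single spaces.
    """
    root = _parse_xml(xml_text)
    nodes = [
        el for el in root.iter()
        if _local(el).lower() in ("abstract", "abstracttext")
    ]
    # Prefer AbstractText leaves when present, else the Abstract wrapper.
    leaves = [el for el in nodes if _local(el).lower() == "abstracttext"]
    chosen = leaves or nodes[:1]
    if not chosen:
        raise MissingSectionError("no abstract element in document")
    text = _clean_text(" ".join("".join(el.itertext()) for el in chosen))
    return DocumentSection(source_kind="abstract", text=text, origin="abstract")


def _grid_from_table_wrap(wrap) -> TableGrid:
    caption = ""
    cap = next((c for c in wrap.iter() if _local(c) == "caption"), None)
    if cap is not None:
        caption = _clean_text("".join(cap.itertext()))
    rows: list[list[str]] = []
    for tr in wrap.iter():
        if _local(tr) in ("tr", "row"):
            cells = [
                _clean_text("".join(td.itertext()))
                for td in tr
                if _local(td) in ("td", "th", "cell")
            ]
            if cells:
                rows.append(cells)
    marks = frozenset(wrap.get("footnote-marks", ""))
    return TableGrid(
        caption=caption,
        cells=rows,
        footnote_marks=marks,
        origin=wrap.get("id", "table"),
    )


def parse_fulltext_xml(xml_text: str) -> tuple[list[DocumentSection], list[TableGrid]]:
    """Parse simplified JATS full text into body sections and table grids.

    One body section is emitted per paragraph group (a ``<sec>`` element, or
    the run of loose ``<p>`` children of ``<body>``); one :class:`TableGrid`
    per ``<table-wrap>``. Reference lists and everything under ``<back>``
    are removed as irrelevant. A document whose body is absent or empty is
    rejected with :class:`BodyMissingError`, mirroring the filter on
    title-and-abstract-only articles.
    """
    root = _parse_xml(xml_text)
    for el in root.iter():
        name = _local(el)
        if name and name not in _KNOWN_TAGS:
            logger.warning("ignoring unknown element <%s>", name)
    body = next((el for el in root.iter() if _local(el) == "body"), None)
    if body is None:
        raise BodyMissingError("document has no body element")

    def in_back(el) -> bool:
        p = el
        while p is not None:
            if _local(p) in ("back", "ref-list"):
                return True
            p = p.getparent()
        return False

    sections: list[DocumentSection] = []
    grids: list[TableGrid] = []

    def paragraph_text(el) -> str:
        # Paragraph text excluding any nested table content.
        parts = []
        for node in el.iter():
            if _local(node) == "table-wrap":
                continue
            if node.text and not _under_table(node):
                parts.append(node.text)
            if node.tail and node is not el:
                parts.append(node.tail)
        return _clean_text(" ".join(parts))

    def _under_table(el) -> bool:
        p = el
        while p is not None:
            if _local(p) == "table-wrap":
                return True
            p = p.getparent()
        return False

    loose: list[str] = []
    n_sec = 0
    for child in body:
        name = _local(child)
        if in_back(child):
            continue
        if name == "sec":
            n_sec += 1
            paras = [
                paragraph_text(p)
                for p in child.iter()
                if _local(p) == "p" and not _under_table(p)
            ]
            text = _clean_text(" ".join(t for t in paras if t))
            if text:
                sections.append(
                    DocumentSection(source_kind="body", text=text, origin=f"sec{n_sec}")
                )
        elif name == "p":
            t = paragraph_text(child)
            if t:
                loose.append(t)
    if loose:
        sections.insert(
            0,
            DocumentSection(source_kind="body", text=" ".join(loose), origin="body"),
        )
    for wrap in body.iter():
        if _local(wrap) == "table-wrap" and not in_back(wrap):
            grids.append(_grid_from_table_wrap(wrap))

    if not sections and not grids:
        raise BodyMissingError("document body is empty (title and abstract only)")
    return sections, grids


def linearize_table(grid: TableGrid) -> DocumentSection:
    """Flatten a table to one scannable section: caption, then cells
    row-major, joined by tabs; declared footnote marks stripped from cells."""
    grid.validate()
    strip = {ord(m): None for m in grid.footnote_marks}
    parts = [grid.caption] if grid.caption else []
    for row in grid.cells:
        parts.extend(cell.translate(strip) for cell in row)
    return DocumentSection(
        source_kind="table", text="\t".join(parts), origin=grid.origin
    )


def read_delimited_supplement(
    data: str | bytes, dialect: str = "tsv", origin: str = "supplement"
) -> DocumentSection:
    """Read a TSV/CSV supplement into a section with tab field boundaries.

    Quoting follows the named dialect, so a quoted CSV field keeps its
    internal commas intact. An empty file yields an empty section.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if isinstance(data, bytes):
        try:
            data = data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise EncodingError(
                f"undecodable bytes at offset {exc.start}", offset=exc.start
            ) from exc
    delimiter = "\t" if dialect == "tsv" else ","
    reader = csv.reader(io.StringIO(data), delimiter=delimiter)
    lines = ["\t".join(fields) for fields in reader]
    return DocumentSection(
        source_kind="supplement", text="\n".join(lines), origin=origin
    )


def read_pdf_text(text: str, origin: str = "pdf") -> DocumentSection:
    """Wrap pre-extracted PDF text (the package never parses PDF bytes)."""
    return DocumentSection(source_kind="pdf_text", text=_clean_text(text), origin=origin)


def load_bundle(entry: dict, base_dir: str | Path) -> DocumentBundle:
    """Materialize one bundle from a manifest entry.

    The entry lists ``doc_id`` and ``sources`` with per-source ``path``,
    ``source_kind`` and, for supplements, an optional ``dialect``.
    """
    base = Path(base_dir)
    bundle = DocumentBundle(doc_id=entry["doc_id"])
    for src in entry.get("sources", []):
        kind = src["source_kind"]
        path = base / src["path"]
        text = path.read_text(encoding="utf-8")
        if kind == "abstract":
            bundle.sections.append(parse_abstract_xml(text))
        elif kind == "body":
            secs, grids = parse_fulltext_xml(text)
            bundle.sections.extend(secs)
            bundle.sections.extend(linearize_table(g) for g in grids)
        elif kind == "supplement":
            bundle.sections.append(
                read_delimited_supplement(
                    text, src.get("dialect", "tsv"), origin=path.name
                )
            )
        elif kind == "pdf_text":
            bundle.sections.append(read_pdf_text(text, origin=path.name))
        else:
            raise IngestError(f"unknown source_kind in manifest: {kind!r}")
    return bundle


def load_corpus(manifest_path: str | Path) -> tuple[list[DocumentBundle], list[str]]:
    """Load all bundles listed in a manifest JSON.

    Documents whose full text turns out to be body-missing keep their other
    sources; a warning is recorded per skipped source.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    base = manifest_path.parent
    bundles, warnings = [], []
    for entry in manifest["documents"]:
        try:
            bundles.append(load_bundle(entry, base))
        except BodyMissingError as exc:
            warnings.append(f"{entry['doc_id']}: {exc}")
            slim = dict(entry)
            slim["sources"] = [
                s for s in entry.get("sources", []) if s["source_kind"] != "body"
            ]
            bundles.append(load_bundle(slim, base))
    return bundles, warnings
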