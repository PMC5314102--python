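"""MEDLINE-style citation records: PubMed XML and JSONL readers/writers.

A :class:`Citation` is article metadata — title, journal, year, MeSH
headings, authors — plus the abstract text; full texts are out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import IO, Iterable

from lxml import etree

logger = logging.getLogger(__name__)

_JSONL_KEYS = ("pmid", "title", "abstract", "journal", "year", "mesh_terms", "authors")


@dataclass
class Citation:
    """One citation: document metadata plus abstract text."""

    pmid: int
    title: str
    abstract: str = ""
    journal: str = ""
    year: int | None = None
    mesh_terms: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)

    def field_texts(self) -> dict[str, list[str]]:
        """The four indexed text places: title, journal, mesh, abstract."""
        return {
            "title": [self.title],
            "journal": [self.journal] if self.journal else [],
            "mesh": list(self.mesh_terms),
            "abstract": [self.abstract] if self.abstract else [],
        }


def _text(node) -> str:
    return "".join(node.itertext()).strip() if node is not None else ""


def read_medline_xml(stream: IO) -> list[Citation]:
    """Parse PubMed/MEDLINE XML into citations.

    Multiple ``AbstractText`` segments (structured abstracts) are concatenated
    with single spaces; records without an abstract get ``abstract=""``.
    Records missing a PMID, or repeating one already seen, are skipped with a
    logged warning. Malformed XML raises ``lxml.etree.XMLSyntaxError``.
    """
    tree = etree.parse(stream)
    citations: list[Citation] = []
    seen: set[int] = set()
    for rec in tree.iter("MedlineCitation"):
        pmid_node = rec.find("PMID")
        pmid_text = _text(pmid_node)
        if not pmid_text.isdigit():
            logger.warning("skipping MedlineCitation without a PMID")
            continue
        pmid = int(pmid_text)
        if pmid in seen:
            logger.warning("skipping duplicate PMID %d", pmid)
            continue
        seen.add(pmid)
        article = rec.find("Article")
        title = _text(article.find("ArticleTitle")) if article is not None else ""
        abstract = ""
        if article is not None:
            segs = [_text(n) for n in article.findall("Abstract/AbstractText")]
            abstract = " ".join(s for s in segs if s)
        journal = (
            _text(article.find("Journal/Title")) if article is not None else ""
        )
        year = None
        if article is not None:
            ynode = article.find("Journal/JournalIssue/PubDate/Year")
            ytext = _text(ynode)
            if ytext.isdigit():
                year = int(ytext)
        mesh = [
            _text(n)
            for n in rec.findall("MeshHeadingList/MeshHeading/DescriptorName")
        ]
        authors = []
        if article is not None:
            for a in article.findall("AuthorList/Author"):
                last, inits = _text(a.find("LastName")), _text(a.find("Initials"))
                if last:
                    authors.append(f"{last} {inits}".strip())
        citations.append(
            Citation(
                pmid=pmid,
                title=title,
                abstract=abstract,
                journal=journal,
                year=year,
                mesh_terms=[m for m in mesh if m],
                authors=authors,
            )
        )
    return citations


def read_jsonl(stream: IO[str] | Iterable[str]) -> list[Citation]:
    """Read citations from line-delimited JSON (one object per line)."""
    citations = []
    seen: set[int] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        pmid = obj.get("pmid")
        if not isinstance(pmid, int) or pmid <= 0:
            logger.warning("line %d: skipping record without a valid pmid", lineno)
            continue
        if pmid in seen:
            logger.warning("line %d: skipping duplicate PMID %d", lineno, pmid)
            continue
        seen.add(pmid)
        citations.append(
            Citation(
                pmid=pmid,
                title=obj.get("title", ""),
                abstract=obj.get("abstract", ""),
                journal=obj.get("journal", ""),
                year=obj.get("year"),
                mesh_terms=list(obj.get("mesh_terms", [])),
                authors=list(obj.get("authors", [])),
            )
        )
    return citations


def write_jsonl(citations: Iterable[Citation], stream: IO[str]) -> None:
    """Write citations as line-delimited JSON with a stable key order."""
    for c in citations:
        d = asdict(c)
        stream.write(json.dumps({k: d[k] for k in _JSONL_KEYS}) + "\n")
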