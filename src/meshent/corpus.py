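"""Literature records and corpus I/O (JSONL canonical, MEDLINE import).

A :class:`Document` is one record — id, title, abstract, journal, publication
year and a gold set of MeSH term ids.  JSONL (one object per line) is the
canonical, lossless on-disk form; MEDLINE tagged plain text is supported as a
best-effort import via ``Bio.Medline``, with MH headings mapped onto term ids
through a supplied :class:`~meshent.tree.MeshTree`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

from .tree import MeshTree

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Corpus",
    "CorpusError",
    "read_jsonl",
    "write_jsonl",
    "read_medline",
]

_JSONL_KEYS = ("doc_id", "title", "abstract", "journal", "year", "annotations")


class CorpusError(ValueError):
    """Structured parse/validation error for corpus sources."""


@dataclass(frozen=True)
class Document:
    """One literature record with gold MeSH annotations (possibly empty)."""

    doc_id: str
    title: str
    abstract: str
    journal: str
    year: int
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not isinstance(self.year, int) or not 1000 <= self.year <= 9999:
            raise CorpusError(
                f"document {self.doc_id!r}: year must be a 4-digit integer, "
                f"got {self.year!r}"
            )
        object.__setattr__(self, "annotations", frozenset(self.annotations))


class Corpus:
    """Ordered collection of documents plus an inverted annotation index."""

    def __init__(self, documents):
        self.documents: list[Document] = list(documents)
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
        self._by_id = {doc.doc_id: doc for doc in self.documents}
        self._term_index: dict[str, frozenset[str]] | None = None

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __getitem__(self, doc_id: str) -> Document:
        try:
            return self._by_id[doc_id]
        except KeyError:
            raise CorpusError(f"unknown doc_id {doc_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return sorted(self.documents, key=lambda d: d.doc_id) == sorted(
            other.documents, key=lambda d: d.doc_id
        )

    @property
    def term_index(self) -> dict[str, frozenset[str]]:
        """term_id -> doc_ids annotated with it (exact inverse of annotations)."""
        if self._term_index is None:
            index: dict[str, set[str]] = {}
            for doc in self.documents:
                for term_id in doc.annotations:
                    index.setdefault(term_id, set()).add(doc.doc_id)
            self._term_index = {t: frozenset(ids) for t, ids in index.items()}
        return self._term_index

    def docs_for_term(self, term_id: str) -> frozenset[str]:
        return self.term_index.get(term_id, frozenset())


# -- JSONL ------------------------------------------------------------------

def read_jsonl(source) -> Corpus:
    """Read a corpus from line-delimited JSON records."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    documents = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusError(f"line {lineno}: invalid JSON ({exc})") from None
        missing = [k for k in _JSONL_KEYS if k not in obj]
        if missing:
            raise CorpusError(f"line {lineno}: missing keys {missing}")
        if not isinstance(obj["year"], int):
            raise CorpusError(
                f"line {lineno}: year must be an integer, got {obj['year']!r}"
            )
        try:
            documents.append(
                Document(
                    doc_id=str(obj["doc_id"]),
                    title=obj["title"],
                    abstract=obj["abstract"],
                    journal=obj["journal"],
                    year=obj["year"],
                    annotations=frozenset(obj["annotations"]),
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"line {lineno}: {exc}") from None
    return Corpus(documents)


def write_jsonl(corpus: Corpus, destination) -> None:
    """Write the JSONL form accepted by :func:`read_jsonl` (lossless)."""
    if hasattr(destination, "write"):
        handle = destination
        close = False
    else:
        handle = open(destination, "w", encoding="utf-8")
        close = True
    try:
        for doc in corpus:
            handle.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "journal": doc.journal,
                        "year": doc.year,
                        "annotations": sorted(doc.annotations),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# -- MEDLINE ----------------------------------------------------------------

_YEAR_RE = re.compile(r"(\d{4})")


def _strip_mh(heading: str) -> str:
    # drop qualifier ("/therapy") and major-topic marker ("*")
    return heading.split("/", 1)[0].replace("*", "").strip()


def read_medline(source, tree: MeshTree) -> Corpus:
    """Import MEDLINE tagged records (PMID/TI/AB/TA-JT/DP/MH fields).

    MH headings are matched case-insensitively against the tree's labels and
    synonyms (qualifiers and major-topic asterisks stripped); unmatched
    headings are dropped with a warning.  Records missing PMID, title or a
    parseable 4-digit year are skipped with a warning.
    """
    from Bio import Medline

    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source, "r", encoding="utf-8")
        close = True
    label_idx = tree.label_index()
    documents = []
    try:
        for offset, record in enumerate(Medline.parse(handle)):
            pmid = record.get("PMID")
            title = (record.get("TI") or "").strip()
            if not pmid or not title:
                logger.warning("skipping MEDLINE record %d: missing PMID or title", offset)
                continue
            date = record.get("DP", "")
            match = _YEAR_RE.search(date)
            if not match:
                logger.warning("skipping record PMID %s: unparseable date %r", pmid, date)
                continue
            annotations = set()
            for heading in record.get("MH", []):
                label = _strip_mh(heading).lower()
                term_id = label_idx.get(label)
                if term_id is None:
                    logger.warning(
                        "record PMID %s: MeSH heading %r not in tree, dropped",
                        pmid,
                        heading,
                    )
                else:
                    annotations.add(term_id)
            documents.append(
                Document(
                    doc_id=str(pmid),
                    title=title,
                    abstract=(record.get("AB") or "").strip(),
                    journal=(record.get("TA") or record.get("JT") or "").strip(),
                    year=int(match.group(1)),
                    annotations=frozenset(annotations),
                )
            )
    finally:
        if close:
            handle.close()
    return Corpus(documents)
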