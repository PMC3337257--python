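"""MeSH hierarchy: terms, dotted tree numbers, and tree-based semantic distance.

MeSH organises headings as a forest of dotted position codes ("tree numbers",
e.g. ``C01.252.400``); one heading may sit at several positions
(polyhierarchy).  The distance between two headings t1, t2 is

    d(t1, t2) = L(t1) + L(t2) - 2 * CP(t1, t2)

where ``L`` is the minimal depth of a heading over its tree numbers (a
top-level code such as ``A01`` has depth 1) and ``CP`` is the maximal number
of common parents, i.e. the longest shared dotted prefix over all pairs of
tree numbers.  On a monohierarchic tree this is the shortest-path edge count
through the (virtual) root.  A heading is *semantically distant* from a
document when the maximum distance to any of the document's gold headings
exceeds a depth threshold (default 6).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MeshTerm",
    "MeshTree",
    "MeshTreeError",
    "load_mesh_tree",
    "write_mesh_tree",
    "min_depth",
    "common_parents",
    "term_distance",
    "term_abstract_distance",
    "is_semantically_distant",
]

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")

DEFAULT_DEPTH_THRESHOLD = 6


class MeshTreeError(ValueError):
    """Structured error raised for malformed tree sources or unknown terms."""


@dataclass(frozen=True)
class MeshTerm:
    """One MeSH heading: identifier, labels, and its tree positions."""

    term_id: str
    preferred_label: str
    synonyms: frozenset[str] = frozenset()
    tree_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.preferred_label.strip():
            raise MeshTreeError(f"term {self.term_id!r}: empty preferred label")
        if not self.tree_numbers:
            raise MeshTreeError(f"term {self.term_id!r}: no tree numbers")
        for tn in self.tree_numbers:
            if not _TREE_NUMBER_RE.match(tn):
                raise MeshTreeError(
                    f"term {self.term_id!r}: malformed tree number {tn!r}"
                )


def _components(tree_number: str) -> list[str]:
    return tree_number.split(".")


def _depth(tree_number: str) -> int:
    return tree_number.count(".") + 1


def _parent(tree_number: str) -> str | None:
    head, _, _ = tree_number.rpartition(".")
    return head or None


class MeshTree:
    """Mapping of term ids to :class:`MeshTerm` plus a tree-number index.

    Invariants: every tree number maps to exactly one term, and the parent
    prefix of every non-root tree number is itself indexed.
    """

    def __init__(self, terms: Iterable[MeshTerm]):
        self.terms: dict[str, MeshTerm] = {}
        self.index: dict[str, str] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise MeshTreeError(f"duplicate term id {term.term_id!r}")
            self.terms[term.term_id] = term
            for tn in term.tree_numbers:
                if tn in self.index:
                    raise MeshTreeError(
                        f"tree number {tn!r} assigned to both "
                        f"{self.index[tn]!r} and {term.term_id!r}"
                    )
                self.index[tn] = term.term_id
        for tn in self.index:
            parent = _parent(tn)
            if parent is not None and parent not in self.index:
                raise MeshTreeError(
                    f"orphan tree number {tn!r}: parent {parent!r} missing"
                )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self):
        return iter(self.terms.values())

    def term(self, term_id: str) -> MeshTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise MeshTreeError(f"unknown term id {term_id!r}") from None

    # -- distance machinery -------------------------------------------------

    def min_depth(self, term_id: str) -> int:
        """Minimal number of dotted components over the term's tree numbers."""
        return min(_depth(tn) for tn in self.term(term_id).tree_numbers)

    def common_parents(self, t1: str, t2: str) -> int:
        """Maximal shared-prefix length (in components) over tree-number pairs."""
        best = 0
        numbers1 = [_components(tn) for tn in self.term(t1).tree_numbers]
        numbers2 = [_components(tn) for tn in self.term(t2).tree_numbers]
        for c1 in numbers1:
            for c2 in numbers2:
                shared = 0
                for a, b in zip(c1, c2):
                    if a != b:
                        break
                    shared += 1
                best = max(best, shared)
        return best

    def term_distance(self, t1: str, t2: str) -> int:
        """Depth/common-parent path distance between two headings."""
        return (
            self.min_depth(t1)
            + self.min_depth(t2)
            - 2 * self.common_parents(t1, t2)
        )

    def term_abstract_distance(
        self, term_id: str, abstract_terms: Iterable[str]
    ) -> int:
        """Maximum distance from ``term_id`` to any heading of the abstract."""
        abstract_terms = list(abstract_terms)
        if not abstract_terms:
            raise MeshTreeError(
                f"term {term_id!r}: distance to an abstract with no MeSH "
                "annotations is undefined"
            )
        return max(self.term_distance(term_id, a) for a in abstract_terms)

    def is_semantically_distant(
        self,
        term_id: str,
        abstract_terms: Iterable[str],
        depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    ) -> bool:
        """True iff the term-abstract distance is strictly above the threshold."""
        return self.term_abstract_distance(term_id, abstract_terms) > depth_threshold

    # -- label lookup (for MEDLINE import and exact matching) ---------------

    def label_index(self) -> dict[str, str]:
        """Case-insensitive label/synonym -> term_id map (first writer wins)."""
        idx: dict[str, str] = {}
        for term in sorted(self.terms.values(), key=lambda t: t.term_id):
            for label in (term.preferred_label, *sorted(term.synonyms)):
                idx.setdefault(label.strip().lower(), term.term_id)
        return idx


# -- module-level wrappers over the tree methods ----------------------------

def min_depth(tree: MeshTree, term_id: str) -> int:
    return tree.min_depth(term_id)


def common_parents(tree: MeshTree, t1: str, t2: str) -> int:
    return tree.common_parents(t1, t2)


def term_distance(tree: MeshTree, t1: str, t2: str) -> int:
    return tree.term_distance(t1, t2)


def term_abstract_distance(tree: MeshTree, term_id: str, abstract_terms) -> int:
    return tree.term_abstract_distance(term_id, abstract_terms)


def is_semantically_distant(
    tree: MeshTree,
    term_id: str,
    abstract_terms,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
) -> bool:
    return tree.is_semantically_distant(term_id, abstract_terms, depth_threshold)


# -- TSV I/O ----------------------------------------------------------------

_COLUMNS = ("term_id", "label", "synonyms", "tree_numbers")


def load_mesh_tree(source) -> MeshTree:
    """Read a MeSH tree from TSV (term_id, label, synonyms, tree_numbers).

    ``synonyms`` and ``tree_numbers`` are pipe-separated; a header row is
    required.  ``source`` may be a path or an open text handle.
    """
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source, "r", encoding="utf-8", newline="")
        close = True
    try:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MeshTreeError("empty MeSH tree source") from None
        if [h.strip() for h in header] != list(_COLUMNS):
            raise MeshTreeError(
                f"bad header {header!r}; expected {list(_COLUMNS)!r}"
            )
        terms = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(_COLUMNS):
                raise MeshTreeError(f"line {lineno}: expected 4 columns, got {len(row)}")
            term_id, label, syns, numbers = (c.strip() for c in row)
            terms.append(
                MeshTerm(
                    term_id=term_id,
                    preferred_label=label,
                    synonyms=frozenset(s for s in syns.split("|") if s),
                    tree_numbers=frozenset(n for n in numbers.split("|") if n),
                )
            )
        if not terms:
            raise MeshTreeError("MeSH tree source contains no terms")
        return MeshTree(terms)
    finally:
        if close:
            handle.close()


def write_mesh_tree(tree: MeshTree, destination) -> None:
    """Write the TSV form accepted by :func:`load_mesh_tree`."""
    if hasattr(destination, "write"):
        handle = destination
        close = False
    else:
        handle = open(destination, "w", encoding="utf-8", newline="")
        close = True
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for term in sorted(tree, key=lambda t: t.term_id):
            writer.writerow(
                [
                    term.term_id,
                    term.preferred_label,
                    "|".join(sorted(term.synonyms)),
                    "|".join(sorted(term.tree_numbers)),
                ]
            )
    finally:
        if close:
            handle.close()
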