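"""Per-term training sets: capped positives and the three negative strategies.

Positives are all documents gold-annotated with the term, down-sampled
uniformly to a cap (default 10,000).  Negatives, equal in number to the
positives, are drawn uniformly from a strategy-dependent pool that always
excludes the positives:

``random``
    any other document in the corpus;
``literal``
    documents whose stemmed title or abstract contains the term's stemmed
    label as a contiguous token run, yet are NOT gold-annotated with the term
    (emulating the PubMed query "term" NOT "term"[mh:noexp] on a local
    corpus);
``literal_distant``
    the subset of ``literal`` whose own gold headings are all far from the
    term in the MeSH tree — the maximum tree distance exceeds the depth
    threshold (default 6).  Documents without gold headings are skipped
    (their distance is undefined).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .corpus import Corpus, Document
from .features import tokenize_and_stem
from .tree import DEFAULT_DEPTH_THRESHOLD, MeshTerm, MeshTree

logger = logging.getLogger(__name__)

__all__ = [
    "STRATEGIES",
    "DEFAULT_POSITIVE_CAP",
    "TermTrainingSet",
    "TrainingSetError",
    "select_positives",
    "contains_term_literally",
    "select_negatives",
    "build_training_set",
    "write_training_sets",
    "read_training_sets",
]

STRATEGIES = ("random", "literal", "literal_distant")
DEFAULT_POSITIVE_CAP = 10000


class TrainingSetError(ValueError):
    """Raised when a training pool is empty or a strategy is misconfigured."""


@dataclass(frozen=True)
class TermTrainingSet:
    """Selected positive/negative doc ids for one term (reproducible)."""

    term_id: str
    positives: frozenset[str]
    negatives: frozenset[str]
    strategy: str
    seed: int
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise TrainingSetError(
                f"term {self.term_id!r}: positives and negatives overlap"
            )


def _sample(pool: set[str], n: int, seed: int) -> frozenset[str]:
    ordered = sorted(pool)
    if n >= len(ordered):
        return frozenset(ordered)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ordered), size=n, replace=False)
    return frozenset(ordered[i] for i in picked)


def select_positives(
    corpus: Corpus, term_id: str, cap: int = DEFAULT_POSITIVE_CAP, seed: int = 0
) -> frozenset[str]:
    """All docs annotated with the term, uniformly capped at ``cap``."""
    annotated = corpus.docs_for_term(term_id)
    if not annotated:
        logger.warning("term %r: no positive documents in corpus", term_id)
        return frozenset()
    if len(annotated) <= cap:
        return frozenset(annotated)
    return _sample(set(annotated), cap, seed)


@lru_cache(maxsize=65536)
def _doc_stems(doc: Document) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return tuple(tokenize_and_stem(doc.title)), tuple(tokenize_and_stem(doc.abstract))


def _contains_run(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    if not needle or len(needle) > len(haystack):
        return False
    k = len(needle)
    return any(haystack[i : i + k] == needle for i in range(len(haystack) - k + 1))


def contains_term_literally(
    doc: Document, term: MeshTerm, include_synonyms: bool = False
) -> bool:
    """True iff the term's stemmed label occurs contiguously in the stemmed
    title or abstract (synonyms optionally included)."""
    title, abstract = _doc_stems(doc)
    labels = [term.preferred_label]
    if include_synonyms:
        labels.extend(sorted(term.synonyms))
    for label in labels:
        needle = tuple(tokenize_and_stem(label))
        if _contains_run(title, needle) or _contains_run(abstract, needle):
            return True
    return False


def select_negatives(
    corpus: Corpus,
    term: MeshTerm,
    strategy: str,
    n: int,
    seed: int,
    tree: MeshTree | None = None,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    include_synonyms: bool = False,
) -> frozenset[str]:
    """Uniform sample of ``min(n, pool size)`` negatives under ``strategy``."""
    if strategy not in STRATEGIES:
        raise TrainingSetError(f"unknown negative strategy {strategy!r}")
    if n < 1:
        raise TrainingSetError("n must be >= 1")
    if strategy == "literal_distant" and tree is None:
        raise TrainingSetError("strategy literal_distant requires a MeSH tree")
    positives = corpus.docs_for_term(term.term_id)
    pool: set[str] = set()
    for doc in corpus:
        if doc.doc_id in positives or term.term_id in doc.annotations:
            continue
        if strategy == "random":
            pool.add(doc.doc_id)
            continue
        if not contains_term_literally(doc, term, include_synonyms):
            continue
        if strategy == "literal":
            pool.add(doc.doc_id)
            continue
        gold = [t for t in doc.annotations if t in tree]
        if not gold:
            logger.debug(
                "term %r: doc %r has no usable gold headings; skipped for "
                "literal_distant",
                term.term_id,
                doc.doc_id,
            )
            continue
        if tree.is_semantically_distant(term.term_id, gold, depth_threshold):
            pool.add(doc.doc_id)
    if not pool:
        raise TrainingSetError(
            f"term {term.term_id!r}: empty negative pool under strategy "
            f"{strategy!r}"
        )
    return _sample(pool, n, seed)


def build_training_set(
    corpus: Corpus,
    term: MeshTerm,
    strategy: str = "literal_distant",
    seed: int = 0,
    cap: int = DEFAULT_POSITIVE_CAP,
    tree: MeshTree | None = None,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    include_synonyms: bool = False,
) -> TermTrainingSet:
    """Positives (capped) plus an equal number of strategy negatives."""
    warnings: list[str] = []
    positives = select_positives(corpus, term.term_id, cap=cap, seed=seed)
    if not positives:
        raise TrainingSetError(f"term {term.term_id!r}: no positive documents")
    negatives = select_negatives(
        corpus,
        term,
        strategy,
        n=len(positives),
        seed=seed,
        tree=tree,
        depth_threshold=depth_threshold,
        include_synonyms=include_synonyms,
    )
    if len(negatives) < len(positives):
        message = (
            f"term {term.term_id}: negative pool smaller than positives "
            f"({len(negatives)} < {len(positives)})"
        )
        logger.warning(message)
        warnings.append(message)
    return TermTrainingSet(
        term_id=term.term_id,
        positives=positives,
        negatives=negatives,
        strategy=strategy,
        seed=seed,
        warnings=tuple(warnings),
    )


# -- JSONL persistence for exact reruns -------------------------------------

def write_training_sets(training_sets, destination) -> None:
    if hasattr(destination, "write"):
        handle, close = destination, False
    else:
        handle = open(destination, "w", encoding="utf-8")
        close = True
    try:
        for ts in training_sets:
            handle.write(
                json.dumps(
                    {
                        "term_id": ts.term_id,
                        "strategy": ts.strategy,
                        "seed": ts.seed,
                        "positives": sorted(ts.positives),
                        "negatives": sorted(ts.negatives),
                        "warnings": list(ts.warnings),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_training_sets(source) -> list[TermTrainingSet]:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    out = []
    for line in lines:
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(
            TermTrainingSet(
                term_id=obj["term_id"],
                positives=frozenset(obj["positives"]),
                negatives=frozenset(obj["negatives"]),
                strategy=obj["strategy"],
                seed=obj["seed"],
                warnings=tuple(obj.get("warnings", ())),
            )
        )
    return out
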