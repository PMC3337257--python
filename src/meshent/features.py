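"""Binary labeled features for one document: title/abstract/journal/year.

Every feature string is namespaced (``title:heart``, ``abstract:diseas``,
``journal:lancet``, ``year:after1990``) so identical surface tokens from
different fields stay distinct.  Title and abstract tokens are lowercased,
stopword-filtered and Porter-stemmed.  The publication year is encoded as a
block of before/after indicators over the configured range: for a document
published in year y (clamped strictly inside 1950-2010) the block contains
``after``\\ Y for Y in 1951..y and ``before``\\ Y for Y in y+1..2009 — always
exactly 59 features under the default range.  All features are binary
presence indicators.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

from .stem import porter_stem
from .stopwords import STOPWORDS

logger = logging.getLogger(__name__)

__all__ = [
    "NAMESPACES",
    "YEAR_RANGE_START",
    "YEAR_RANGE_END",
    "FeatureSet",
    "tokenize_and_stem",
    "year_features",
    "build_feature_set",
    "serialize_features",
]

NAMESPACES = ("title", "abstract", "journal", "year")
YEAR_RANGE_START = 1950
YEAR_RANGE_END = 2010

#: A feature set is simply a frozenset of namespaced feature strings.
FeatureSet = frozenset

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


def tokenize_and_stem(text: str) -> list[str]:
    """Lowercase, split on non-alphanumeric runs, drop stopwords, Porter-stem.

    Token order is preserved (contiguity matters for literal matching).
    """
    tokens = [t for t in _TOKEN_RE.split(text.lower()) if t]
    return [porter_stem(t) for t in tokens if t not in STOPWORDS]


def year_features(
    pub_year: int,
    range_start: int = YEAR_RANGE_START,
    range_end: int = YEAR_RANGE_END,
) -> frozenset[str]:
    """Before/after year indicator block; both range endpoints are excluded,
    so the block always holds ``range_end - range_start - 1`` features (59
    for the default range).  Out-of-range years are clamped with a warning.
    """
    clamped = min(max(pub_year, range_start + 1), range_end - 1)
    if clamped != pub_year:
        logger.warning(
            "publication year %d outside (%d, %d); clamped to %d",
            pub_year,
            range_start,
            range_end,
            clamped,
        )
    after = (f"year:after{y}" for y in range(range_start + 1, clamped + 1))
    before = (f"year:before{y}" for y in range(clamped + 1, range_end))
    return frozenset(after) | frozenset(before)


def _normalize_journal(name: str) -> str:
    return " ".join(name.lower().split())


def build_feature_set(doc, use: Iterable[str] = NAMESPACES) -> frozenset[str]:
    """Binary labeled feature set of a document, restricted to ``use``.

    ``use`` is any non-empty subset of :data:`NAMESPACES`; restricting it
    implements the single-feature-type ablations.
    """
    use = frozenset(use)
    unknown = use - frozenset(NAMESPACES)
    if unknown:
        raise ValueError(f"unknown feature namespaces {sorted(unknown)}")
    if not use:
        raise ValueError("at least one feature namespace is required")
    features: set[str] = set()
    if "title" in use:
        features.update(f"title:{t}" for t in tokenize_and_stem(doc.title))
    if "abstract" in use:
        features.update(f"abstract:{t}" for t in tokenize_and_stem(doc.abstract))
    if "journal" in use and doc.journal.strip():
        features.add(f"journal:{_normalize_journal(doc.journal)}")
    if "year" in use:
        features.update(year_features(doc.year))
    return frozenset(features)


def serialize_features(features: Iterable[str]) -> str:
    """Sorted newline-delimited form, for golden files and model dumps."""
    return "\n".join(sorted(features))
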