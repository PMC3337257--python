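"""Synthetic MeSH trees and annotated corpora for end-to-end testing.

The generator emulates the statistical structure the annotation method
exploits, with no attempt at realistic English or real MeSH topology:

* a complete branching tree of synthetic headings (dotted tree numbers),
  with a fraction of leaves given a second tree number to exercise
  polyhierarchy;
* every heading owns one surface "signal" token (its preferred label) plus a
  few context tokens; positive documents contain these with probability
  ``signal_strength`` in title and abstract;
* background noise tokens are drawn from a shared vocabulary that also
  includes every heading's signal token, so documents that mention a heading
  literally without being annotated with it exist (the pool the literal
  negative strategies need);
* optional journal affinity (a home journal per heading) and per-heading
  publication-year trends (Gaussian around a peak year), the mechanism that
  makes year features informative;
* an ``ambiguity_fraction`` of headings is paired up across different
  top-level branches to share one surface token while differing in context
  tokens, journal and year trend — ambiguous strings that exact matching
  cannot tell apart.

All vocabulary tokens are synthetic consonant-terminated strings, so the
stopword list never collides with them and Porter stemming leaves them
intact.  Generation is fully deterministic under ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document
from .tree import MeshTerm, MeshTree

__all__ = ["GeneratorSpec", "GenerationError", "generate_toy_tree", "generate_corpus"]


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic study conditions.

    The defaults are the desk-scale preset: a depth-4 binary tree (30
    headings) and 3,000 documents, strong vocabulary signal (0.9), journal
    affinity 0.8 and per-heading year trends — small enough for a full
    pipeline run on one CPU in minutes.
    """

    tree_depth: int = 4
    branching: int = 2
    n_docs: int = 3000
    vocab_size: int = 300
    signal_strength: float = 0.9
    background_rate: float = 0.9
    journal_affinity: float = 0.8
    year_trend: str | None = "auto"  # "auto", None, or {term_id: (peak, width)}
    year_trend_width: float = 8.0
    ambiguity_fraction: float = 0.0
    n_context_tokens: int = 2
    title_noise_slots: int = 5
    abstract_noise_slots: int = 45
    polyhierarchy_fraction: float = 0.1
    terms_per_doc: tuple[int, int] = (1, 3)
    year_range: tuple[int, int] = (1950, 2010)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "signal_strength",
            "background_rate",
            "journal_affinity",
            "ambiguity_fraction",
            "polyhierarchy_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GenerationError(f"{name} must lie in [0, 1], got {value}")
        if self.tree_depth < 2 or self.branching < 2:
            raise GenerationError("tree_depth and branching must both be >= 2")

    @property
    def n_terms(self) -> int:
        return sum(self.branching**d for d in range(1, self.tree_depth + 1))


def _signal_token(index: int) -> str:
    return f"sig{index:03d}tok"


def generate_toy_tree(spec: GeneratorSpec) -> MeshTree:
    """Complete ``branching``-ary tree of depth ``tree_depth``; a fraction of
    leaves receives a second tree number under another branch."""
    rng = np.random.default_rng(spec.seed)
    tree_numbers: list[str] = []
    level = [f"A{i + 1:02d}" for i in range(spec.branching)]
    tree_numbers.extend(level)
    for _ in range(spec.tree_depth - 1):
        level = [
            f"{parent}.{j + 1:03d}" for parent in level for j in range(spec.branching)
        ]
        tree_numbers.extend(level)
    terms = []
    leaf_numbers = [tn for tn in tree_numbers if tn.count(".") == spec.tree_depth - 1]
    n_poly = int(round(spec.polyhierarchy_fraction * len(leaf_numbers)))
    poly_leaves = set(
        rng.choice(len(leaf_numbers), size=n_poly, replace=False).tolist()
    )
    internal = [tn for tn in tree_numbers if tn.count(".") < spec.tree_depth - 1]
    labels = _ambiguous_labels(spec, tree_numbers, rng)
    for idx, tn in enumerate(tree_numbers):
        numbers = {tn}
        if tn.count(".") == spec.tree_depth - 1:
            leaf_idx = leaf_numbers.index(tn)
            if leaf_idx in poly_leaves:
                host = internal[int(rng.integers(len(internal)))]
                numbers.add(f"{host}.9{idx:02d}")
        terms.append(
            MeshTerm(
                term_id=f"T{idx:04d}",
                preferred_label=labels[idx],
                synonyms=frozenset({f"syn{idx:03d}tok"}),
                tree_numbers=frozenset(numbers),
            )
        )
    return MeshTree(terms)


def _ambiguous_labels(spec: GeneratorSpec, tree_numbers, rng) -> list[str]:
    """Assign signal tokens; ambiguous pairs of deepest-level headings in
    different top branches share one token."""
    labels = [_signal_token(i) for i in range(len(tree_numbers))]
    n_pairs = int(round(spec.ambiguity_fraction * len(tree_numbers) / 2))
    if n_pairs == 0:
        return labels
    deepest = [
        i for i, tn in enumerate(tree_numbers) if tn.count(".") == spec.tree_depth - 1
    ]
    first_branch = [i for i in deepest if tree_numbers[i].startswith("A01")]
    other_branch = [i for i in deepest if not tree_numbers[i].startswith("A01")]
    n_pairs = min(n_pairs, len(first_branch), len(other_branch))
    for k in range(n_pairs):
        shared = f"amb{k:03d}tok"
        labels[first_branch[k]] = shared
        labels[other_branch[k]] = shared
    return labels


def generate_corpus(tree: MeshTree, spec: GeneratorSpec) -> Corpus:
    """Draw ``n_docs`` documents with 1-3 gold headings each (see module
    docstring for the generative story)."""
    if spec.vocab_size < spec.n_terms:
        raise GenerationError(
            f"vocab_size {spec.vocab_size} smaller than the number of "
            f"headings {spec.n_terms}"
        )
    rng = np.random.default_rng(spec.seed + 1)
    term_ids = sorted(tree.terms)
    signal = {t: tree.term(t).preferred_label for t in term_ids}
    context = {
        t: [f"ctx{i:04d}c{j}" for j in range(spec.n_context_tokens)]
        for i, t in enumerate(term_ids)
    }
    home_journal = {t: f"jrnl{i:03d}" for i, t in enumerate(term_ids)}
    generic_journals = [f"genj{i}" for i in range(10)]
    lo, hi = spec.year_range[0] + 1, spec.year_range[1] - 1
    if spec.year_trend == "auto":
        peaks = {
            t: (float(rng.integers(lo + 10, hi - 10)), spec.year_trend_width)
            for t in term_ids
        }
    elif isinstance(spec.year_trend, dict):
        peaks = dict(spec.year_trend)
    else:
        peaks = {}
    # noise pool: background vocabulary plus every heading's surface tokens
    noise_vocab = [f"bg{i:04d}w" for i in range(spec.vocab_size)]
    noise_vocab += sorted(set(signal.values()))
    noise_vocab += [tok for toks in context.values() for tok in toks]
    noise_vocab = np.array(sorted(set(noise_vocab)))

    k_lo, k_hi = spec.terms_per_doc
    documents = []
    for i in range(spec.n_docs):
        k = int(rng.integers(k_lo, k_hi + 1))
        gold = [term_ids[j] for j in rng.choice(len(term_ids), size=k, replace=False)]
        primary = gold[0]
        title_tokens: list[str] = []
        abstract_tokens: list[str] = []
        for t in gold:
            if rng.random() < spec.signal_strength:
                title_tokens.append(signal[t])
            if rng.random() < spec.signal_strength:
                abstract_tokens.append(signal[t])
            for tok in context[t]:
                if rng.random() < spec.signal_strength:
                    abstract_tokens.append(tok)
        for _ in range(spec.title_noise_slots):
            if rng.random() < spec.background_rate:
                title_tokens.append(str(noise_vocab[rng.integers(len(noise_vocab))]))
        for _ in range(spec.abstract_noise_slots):
            if rng.random() < spec.background_rate:
                abstract_tokens.append(
                    str(noise_vocab[rng.integers(len(noise_vocab))])
                )
        if not title_tokens:
            title_tokens.append(str(noise_vocab[rng.integers(len(noise_vocab))]))
        rng.shuffle(title_tokens)
        rng.shuffle(abstract_tokens)
        if primary in peaks:
            peak, width = peaks[primary]
            year = int(np.clip(round(rng.normal(peak, width)), lo, hi))
        else:
            year = int(rng.integers(lo, hi + 1))
        if rng.random() < spec.journal_affinity:
            journal = home_journal[primary]
        else:
            journal = generic_journals[int(rng.integers(len(generic_journals)))]
        documents.append(
            Document(
                doc_id=f"D{i:05d}",
                title=" ".join(title_tokens),
                abstract=" ".join(abstract_tokens),
                journal=journal,
                year=year,
                annotations=frozenset(gold),
            )
        )
    return Corpus(documents)


def generate(spec: GeneratorSpec) -> tuple[MeshTree, Corpus]:
    """Convenience: tree and corpus from one spec."""
    tree = generate_toy_tree(spec)
    return tree, generate_corpus(tree, spec)
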