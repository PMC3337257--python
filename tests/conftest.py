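import io

import pytest

from meshent.corpus import Corpus, Document
from meshent.simulate import GeneratorSpec, generate
from meshent.tree import MeshTerm, MeshTree


@pytest.fixture
def toy_tree() -> MeshTree:
    """Hand-built polyhierarchy-free toy tree spanning two top branches."""
    return MeshTree(
        [
            MeshTerm("A", "alpha", frozenset(), frozenset({"A01"})),
            MeshTerm("AA", "alpha a", frozenset(), frozenset({"A01.001"})),
            MeshTerm("AB", "alpha b", frozenset(), frozenset({"A01.002"})),
            MeshTerm("AAA", "alpha a a", frozenset(), frozenset({"A01.001.001"})),
            MeshTerm("B", "beta", frozenset(), frozenset({"B02"})),
            MeshTerm("BA", "beta a", frozenset(), frozenset({"B02.003"})),
        ]
    )


@pytest.fixture
def tree14() -> MeshTree:
    """Monohierarchic complete binary tree of depth 3 (14 terms)."""
    from meshent.simulate import generate_toy_tree

    return generate_toy_tree(
        GeneratorSpec(tree_depth=3, branching=2, polyhierarchy_fraction=0.0, seed=7)
    )


@pytest.fixture
def small_doc() -> Document:
    return Document(
        doc_id="d1",
        title="Heart disease",
        abstract="",
        journal="Lancet",
        year=1990,
        annotations=frozenset({"A"}),
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Desk-scale-but-small synthetic study: depth-4 tree, 800 documents."""
    spec = GeneratorSpec(n_docs=800, seed=11)
    tree, corpus = generate(spec)
    return spec, tree, corpus


def deepest_mono_term(tree):
    """Last deepest-level heading with a single tree position (its distant
    negative pool is guaranteed non-degenerate)."""
    best = None
    for tid in sorted(tree.terms):
        term = tree.term(tid)
        if len(term.tree_numbers) == 1 and tree.min_depth(tid) == 4:
            best = term
    return best
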