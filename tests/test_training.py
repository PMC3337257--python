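"""Positive capping, literal matching, and the three negative strategies."""

import io

import pytest

from meshent.corpus import Corpus, Document
from meshent.simulate import GeneratorSpec, generate
from meshent.training import (
    STRATEGIES,
    TermTrainingSet,
    TrainingSetError,
    build_training_set,
    contains_term_literally,
    read_training_sets,
    select_negatives,
    select_positives,
    write_training_sets,
)
from meshent.tree import MeshTerm

from conftest import deepest_mono_term


def _corpus_with_term(term_id="AA", n_pos=4, n_other=6):
    docs = []
    for i in range(n_pos):
        docs.append(
            Document(f"p{i}", f"pos {i}", "", "j", 1990, frozenset({term_id}))
        )
    for i in range(n_other):
        docs.append(Document(f"o{i}", f"other {i}", "", "j", 1990, frozenset({"B"})))
    return Corpus(docs)


class TestSelectPositives:
    def test_below_cap_returns_all(self):
        corpus = _corpus_with_term(n_pos=12)
        assert len(select_positives(corpus, "AA", cap=10000, seed=0)) == 12

    def test_above_cap_samples_exactly_cap_reproducibly(self):
        corpus = _corpus_with_term(n_pos=30)
        first = select_positives(corpus, "AA", cap=5, seed=42)
        second = select_positives(corpus, "AA", cap=5, seed=42)
        assert len(first) == 5
        assert first == second
        assert first != select_positives(corpus, "AA", cap=5, seed=43)

    def test_zero_positives_is_empty_with_warning(self, caplog):
        corpus = _corpus_with_term(n_pos=0)
        with caplog.at_level("WARNING"):
            assert select_positives(corpus, "AA") == frozenset()
        assert any("no positive" in r.message for r in caplog.records)


class TestLiteralMatch:
    TERM = MeshTerm("T", "Tricuspid Atresia", frozenset(), frozenset({"C01"}))

    def _doc(self, title="", abstract=""):
        return Document("d", title, abstract, "j", 1990, frozenset())

    def test_contiguous_stemmed_match_in_title(self):
        doc = self._doc(title="Outcomes in tricuspid atresia patients")
        assert contains_term_literally(doc, self.TERM)

    def test_inflected_form_matches_via_stemming(self):
        doc = self._doc(abstract="multiple tricuspid atresias were observed")
        assert contains_term_literally(doc, self.TERM)

    def test_reordered_or_gapped_tokens_do_not_match(self):
        doc = self._doc(abstract="atresia of the tricuspid valve")
        assert not contains_term_literally(doc, self.TERM)

    def test_empty_document_does_not_match(self):
        assert not contains_term_literally(self._doc(), self.TERM)

    def test_synonyms_only_when_enabled(self):
        term = MeshTerm(
            "T", "Tricuspid Atresia", frozenset({"TA syndrome"}), frozenset({"C01"})
        )
        doc = self._doc(title="a case of ta syndrome")
        assert not contains_term_literally(doc, term)
        assert contains_term_literally(doc, term, include_synonyms=True)


class TestSelectNegatives:
    def test_random_strategy_pool_excludes_positives(self, toy_tree):
        corpus = _corpus_with_term(n_pos=4, n_other=6)
        negatives = select_negatives(
            corpus, toy_tree.term("AA"), "random", n=4, seed=0
        )
        assert len(negatives) == 4
        assert all(d.startswith("o") for d in negatives)

    def test_literal_requires_mention_without_annotation(self, toy_tree):
        term = toy_tree.term("AA")  # label "alpha a"
        docs = [
            # mentions the term literally AND is annotated with it -> excluded
            Document("ann", "alpha a study", "", "j", 1990, frozenset({"AA"})),
            # mentions literally, not annotated -> eligible
            Document("hit", "about alpha a", "", "j", 1990, frozenset({"B"})),
            # no literal mention -> ineligible
            Document("miss", "beta things", "", "j", 1990, frozenset({"B"})),
        ]
        negatives = select_negatives(Corpus(docs), term, "literal", n=5, seed=0)
        assert negatives == frozenset({"hit"})

    def test_literal_distant_filters_by_tree_distance(self, toy_tree):
        term = toy_tree.term("AA")
        docs = [
            Document("pos", "alpha a", "", "j", 1990, frozenset({"AA"})),
            # near neighbour (distance AA->AB is 2 <= 6) -> excluded
            Document("near", "alpha a near", "", "j", 1990, frozenset({"AB"})),
            # distant gold term under low threshold -> eligible
            Document("far", "alpha a far", "", "j", 1990, frozenset({"BA"})),
            # no gold headings -> skipped (distance undefined)
            Document("bare", "alpha a bare", "", "j", 1990, frozenset()),
        ]
        corpus = Corpus(docs)
        negatives = select_negatives(
            corpus, term, "literal_distant", n=5, seed=0, tree=toy_tree,
            depth_threshold=3,
        )
        assert negatives == frozenset({"far"})
        # AA->BA distance is 4: with the default threshold 6 nothing qualifies
        with pytest.raises(TrainingSetError, match="empty negative pool"):
            select_negatives(
                corpus, term, "literal_distant", n=5, seed=0, tree=toy_tree
            )

    def test_literal_distant_requires_tree(self, toy_tree):
        corpus = _corpus_with_term()
        with pytest.raises(TrainingSetError, match="tree"):
            select_negatives(corpus, toy_tree.term("AA"), "literal_distant", n=1, seed=0)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_pool_nesting_on_synthetic_corpus(self, seed):
        spec = GeneratorSpec(n_docs=400, seed=seed)
        tree, corpus = generate(spec)
        term = deepest_mono_term(tree)
        huge = 10**9
        random_pool = select_negatives(corpus, term, "random", huge, 0)
        literal_pool = select_negatives(corpus, term, "literal", huge, 0, tree)
        distant_pool = select_negatives(
            corpus, term, "literal_distant", huge, 0, tree
        )
        positives = corpus.docs_for_term(term.term_id)
        assert distant_pool <= literal_pool <= random_pool
        for pool in (random_pool, literal_pool, distant_pool):
            assert not pool & positives


class TestBuildTrainingSet:
    def test_equal_sizes_and_disjointness(self):
        spec = GeneratorSpec(n_docs=400, seed=3)
        tree, corpus = generate(spec)
        term = deepest_mono_term(tree)
        ts = build_training_set(corpus, term, strategy="random", seed=1)
        assert len(ts.negatives) == len(ts.positives)
        assert not ts.positives & ts.negatives

    def test_short_pool_records_warning(self, toy_tree):
        term = toy_tree.term("AA")
        docs = [
            Document(f"p{i}", "alpha a", "", "j", 1990, frozenset({"AA"}))
            for i in range(5)
        ] + [Document("neg", "alpha a only", "", "j", 1990, frozenset({"B"}))]
        ts = build_training_set(Corpus(docs), term, strategy="literal", seed=0)
        assert len(ts.negatives) == 1 < len(ts.positives)
        assert ts.warnings

    def test_reproducible_under_seed(self):
        spec = GeneratorSpec(n_docs=400, seed=3)
        tree, corpus = generate(spec)
        term = deepest_mono_term(tree)
        kwargs = dict(strategy="literal_distant", seed=9, tree=tree)
        assert build_training_set(corpus, term, **kwargs) == build_training_set(
            corpus, term, **kwargs
        )

    def test_overlapping_sets_rejected(self):
        with pytest.raises(TrainingSetError, match="overlap"):
            TermTrainingSet(
                "T", frozenset({"a"}), frozenset({"a"}), "random", 0
            )

    def test_jsonl_round_trip(self):
        ts = TermTrainingSet(
            "T", frozenset({"a", "b"}), frozenset({"c"}), "literal", 4, ("w",)
        )
        buffer = io.StringIO()
        write_training_sets([ts], buffer)
        assert read_training_sets(io.StringIO(buffer.getvalue())) == [ts]
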