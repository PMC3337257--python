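"""Orchestration: per-term training, multi-label annotation, baselines, and
10-fold cross-validated macro evaluation.

Each MeSH term gets its own binary MaxEnt model, trained on its capped
positives plus strategy-selected negatives and applied independently of all
other terms (the task is multi-label, so decisions never interact).
Evaluation is per term: the term's positive+negative instance set is split
into class-stratified folds, each fold is classified at threshold
t = 0.5 + delta by a model trained on the remaining folds, and tp/fp/fn are
accumulated across folds into per-term precision/recall/F.  The summary is
the unweighted (macro) mean across trainable terms.  Baselines share the
exact same instance sets and folds: Bernoulli Naive Bayes (add-one
smoothing, maximum-posterior decision) and Exact Matching (annotate iff the
stemmed term string occurs in title or abstract).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB

from .corpus import Corpus, Document
from .features import NAMESPACES, build_feature_set
from .maxent import MaxEntClassifier, TrainingError, _vectorize
from .training import (
    DEFAULT_POSITIVE_CAP,
    TermTrainingSet,
    TrainingSetError,
    build_training_set,
    contains_term_literally,
)
from .tree import DEFAULT_DEPTH_THRESHOLD, MeshTerm, MeshTree

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationConfig",
    "TermScore",
    "EvalReport",
    "MeshAnnotator",
    "precision_recall_f",
    "train_term_model",
    "annotate",
    "exact_match_annotate",
    "naive_bayes_baseline",
    "tune_delta",
    "cross_validate",
]

METHODS = ("maxent", "naive_bayes", "exact_match")


@dataclass(frozen=True)
class AnnotationConfig:
    """Knobs of the annotation pipeline (defaults follow the study setup)."""

    delta: float = 0.1
    delta_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4)
    validation_fraction: float = 0.1
    folds: int = 10
    negative_strategy: str = "literal_distant"
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD
    positive_cap: int = DEFAULT_POSITIVE_CAP
    feature_namespaces: tuple[str, ...] = NAMESPACES
    prior_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 0.4:
            raise ValueError("delta must lie in [0, 0.4]")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.feature_namespaces:
            raise ValueError("at least one feature namespace is required")

    @classmethod
    def from_json(cls, source) -> "AnnotationConfig":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            with open(source, "r", encoding="utf-8") as handle:
                obj = json.load(handle)
        for key in ("delta_grid", "feature_namespaces"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["delta_grid"] = list(self.delta_grid)
        out["feature_namespaces"] = list(self.feature_namespaces)
        return out


def _term_seed(master_seed: int, term_id: str) -> int:
    """Stable per-term seed fan-out (kept below 2**31)."""
    return (zlib.crc32(term_id.encode("utf-8")) ^ (master_seed * 2654435761)) % (
        2**31 - 1
    )


class _FeatureCache:
    """Memoizes per-document feature sets for a fixed namespace selection."""

    def __init__(self, corpus: Corpus, namespaces):
        self._corpus = corpus
        self._namespaces = tuple(namespaces)
        self._cache: dict[str, frozenset[str]] = {}

    def __call__(self, doc_id: str) -> frozenset[str]:
        fs = self._cache.get(doc_id)
        if fs is None:
            fs = build_feature_set(self._corpus[doc_id], self._namespaces)
            self._cache[doc_id] = fs
        return fs


# -- metrics ----------------------------------------------------------------

def precision_recall_f(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P, R, F1 with the zero-denominator convention (0 when undefined)."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


@dataclass(frozen=True)
class TermScore:
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int


@dataclass
class EvalReport:
    """Per-term and macro precision/recall/F over cross-validation folds."""

    per_term: dict[str, TermScore]
    skipped: dict[str, str]
    config: AnnotationConfig
    method: str = "maxent"

    @property
    def macro(self) -> tuple[float, float, float]:
        if not self.per_term:
            return (0.0, 0.0, 0.0)
        scores = list(self.per_term.values())
        return (
            float(np.mean([s.precision for s in scores])),
            float(np.mean([s.recall for s in scores])),
            float(np.mean([s.f_measure for s in scores])),
        )

    def to_tsv(self) -> str:
        """Deterministic TSV: term table, then a summary block."""
        lines = ["term_id\tprecision\trecall\tf_measure\ttp\tfp\tfn"]
        for term_id in sorted(self.per_term):
            s = self.per_term[term_id]
            lines.append(
                f"{term_id}\t{s.precision:.6f}\t{s.recall:.6f}\t"
                f"{s.f_measure:.6f}\t{s.tp}\t{s.fp}\t{s.fn}"
            )
        p, r, f = self.macro
        lines.append("")
        lines.append(f"# method\t{self.method}")
        lines.append(f"# n_terms\t{len(self.per_term)}")
        lines.append(f"# macro_precision\t{p:.6f}")
        lines.append(f"# macro_recall\t{r:.6f}")
        lines.append(f"# macro_f\t{f:.6f}")
        for term_id in sorted(self.skipped):
            lines.append(f"# skipped\t{term_id}\t{self.skipped[term_id]}")
        lines.append(f"# config\t{json.dumps(self.config.to_dict(), sort_keys=True)}")
        return "\n".join(lines) + "\n"


# -- per-term training ------------------------------------------------------

def _training_instances(training_set: TermTrainingSet, featurize):
    doc_ids = sorted(training_set.positives) + sorted(training_set.negatives)
    labels = [1] * len(training_set.positives) + [0] * len(training_set.negatives)
    return doc_ids, np.array(labels)


def train_term_model(
    corpus: Corpus,
    term: MeshTerm,
    tree: MeshTree,
    config: AnnotationConfig,
    featurize=None,
) -> MaxEntClassifier:
    """Build the term's training set and fit its MaxEnt model.

    Raises :class:`~meshent.training.TrainingSetError` for terms with fewer
    than two positives or an empty negative pool (callers report them as
    untrainable), and :class:`~meshent.maxent.TrainingError` for degenerate
    fits.
    """
    if len(corpus.docs_for_term(term.term_id)) < 2:
        raise TrainingSetError(
            f"term {term.term_id!r}: fewer than 2 positive documents"
        )
    training_set = build_training_set(
        corpus,
        term,
        strategy=config.negative_strategy,
        seed=_term_seed(config.seed, term.term_id),
        cap=config.positive_cap,
        tree=tree,
        depth_threshold=config.depth_threshold,
    )
    featurize = featurize or _FeatureCache(corpus, config.feature_namespaces)
    doc_ids, labels = _training_instances(training_set, featurize)
    model = MaxEntClassifier(
        prior_variance=config.prior_variance, term_id=term.term_id
    )
    model.fit([featurize(d) for d in doc_ids], labels)
    model.training_set_hash_ = format(
        zlib.crc32("\n".join(doc_ids).encode("utf-8")), "08x"
    )
    return model


# -- multi-label annotation -------------------------------------------------

def annotate(models, doc: Document, delta: float = 0.1) -> frozenset[str]:
    """Apply every term model independently; return term ids decided positive."""
    out = set()
    for model in models:
        fs = build_feature_set(doc)
        if int(model.predict([fs], delta=delta)[0]):
            out.add(model.term_id)
    return frozenset(out)


def exact_match_annotate(doc: Document, terms) -> frozenset[str]:
    """Exact Matching baseline: every term whose stemmed string occurs in the
    title or abstract."""
    return frozenset(
        term.term_id for term in terms if contains_term_literally(doc, term)
    )


class MeshAnnotator(BaseEstimator):
    """Multi-label annotator: one MaxEnt model per MeSH term.

    ``fit`` trains a model for every term of the tree present in the corpus
    (or an explicit term list); ``predict`` returns a set of term ids per
    document.  Untrainable terms are recorded in ``skipped_``.
    """

    def __init__(self, config: AnnotationConfig | None = None):
        self.config = config

    def fit(self, corpus: Corpus, tree: MeshTree, terms=None):
        config = self.config or AnnotationConfig()
        if terms is None:
            terms = [t for t in sorted(tree, key=lambda t: t.term_id)
                     if corpus.docs_for_term(t.term_id)]
        featurize = _FeatureCache(corpus, config.feature_namespaces)
        self.models_: dict[str, MaxEntClassifier] = {}
        self.skipped_: dict[str, str] = {}
        for term in terms:
            try:
                self.models_[term.term_id] = train_term_model(
                    corpus, term, tree, config, featurize=featurize
                )
            except (TrainingSetError, TrainingError) as exc:
                logger.warning("term %s untrainable: %s", term.term_id, exc)
                self.skipped_[term.term_id] = str(exc)
        return self

    def predict(self, docs, delta: float | None = None) -> list[frozenset[str]]:
        config = self.config or AnnotationConfig()
        delta = config.delta if delta is None else delta
        out = []
        for doc in docs:
            fs = build_feature_set(doc, config.feature_namespaces)
            labels = {
                term_id
                for term_id, model in self.models_.items()
                if int(model.predict([fs], delta=delta)[0])
            }
            out.append(frozenset(labels))
        return out


# -- Naive Bayes baseline ---------------------------------------------------

def naive_bayes_baseline(
    train_instances, test_feature_sets, return_proba: bool = False
) -> np.ndarray:
    """Bernoulli NB (add-one smoothing) over the training vocabulary;
    maximum-posterior decisions (or class posteriors) for the test sets."""
    train_instances = list(train_instances)
    feature_sets = [fs for fs, _ in train_instances]
    labels = np.array([int(lab) for _, lab in train_instances])
    if np.unique(labels).size < 2:
        raise TrainingError("Naive Bayes training requires both classes")
    vocabulary = sorted(set().union(*map(set, feature_sets)))
    vocab = {f: i for i, f in enumerate(vocabulary)}
    X = _vectorize(feature_sets, vocab)
    nb = BernoulliNB(alpha=1.0)
    nb.fit(X, labels)
    X_test = _vectorize(list(test_feature_sets), vocab)
    if return_proba:
        return nb.predict_proba(X_test)
    return nb.predict(X_test)


# -- delta tuning -----------------------------------------------------------

def tune_delta(
    corpus: Corpus, term: MeshTerm, tree: MeshTree, config: AnnotationConfig
) -> float:
    """Grid-search delta on a stratified held-out validation split of the
    term's training set; ties break toward the smaller delta."""
    if not config.delta_grid:
        raise ValueError("delta_grid must be non-empty")
    seed = _term_seed(config.seed, term.term_id)
    training_set = build_training_set(
        corpus,
        term,
        strategy=config.negative_strategy,
        seed=seed,
        cap=config.positive_cap,
        tree=tree,
        depth_threshold=config.depth_threshold,
    )
    featurize = _FeatureCache(corpus, config.feature_namespaces)
    doc_ids, labels = _training_instances(training_set, featurize)
    train_ids, val_ids, y_train, y_val = train_test_split(
        doc_ids,
        labels,
        test_size=config.validation_fraction,
        stratify=labels,
        random_state=seed % (2**32 - 1),
    )
    if np.unique(y_val).size < 2 or np.unique(y_train).size < 2:
        raise TrainingSetError(
            f"term {term.term_id!r}: validation split lacks a class"
        )
    model = MaxEntClassifier(
        prior_variance=config.prior_variance, term_id=term.term_id
    )
    model.fit([featurize(d) for d in train_ids], y_train)
    proba = model.predict_proba([featurize(d) for d in val_ids])[:, 1]
    best_delta, best_f = None, -1.0
    for delta in sorted(config.delta_grid):
        predicted = proba > 0.5 + delta
        tp = int(np.sum(predicted & (y_val == 1)))
        fp = int(np.sum(predicted & (y_val == 0)))
        fn = int(np.sum(~predicted & (y_val == 1)))
        _, _, f = precision_recall_f(tp, fp, fn)
        if f > best_f:
            best_delta, best_f = delta, f
    return float(best_delta)


# -- cross-validated evaluation ---------------------------------------------

def _fold_predictions(
    method, train_fs, y_train, test_fs, test_docs, term, delta, prior_variance
):
    if method == "maxent":
        model = MaxEntClassifier(prior_variance=prior_variance, term_id=term.term_id)
        model.fit(train_fs, y_train)
        return model.predict(test_fs, delta=delta)
    if method == "naive_bayes":
        return naive_bayes_baseline(zip(train_fs, y_train), test_fs)
    if method == "exact_match":
        return np.array(
            [int(contains_term_literally(doc, term)) for doc in test_docs]
        )
    raise ValueError(f"unknown method {method!r}")


def cross_validate(
    corpus: Corpus,
    terms,
    tree: MeshTree,
    config: AnnotationConfig,
    method: str = "maxent",
) -> EvalReport:
    """Per-term stratified k-fold CV; macro averages over trainable terms.

    Negative sets are drawn once per term (before folding); every method is
    evaluated on identical instance sets and fold partitions.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    featurize = _FeatureCache(corpus, config.feature_namespaces)
    per_term: dict[str, TermScore] = {}
    skipped: dict[str, str] = {}
    for term in sorted(terms, key=lambda t: t.term_id):
        seed = _term_seed(config.seed, term.term_id)
        try:
            if len(corpus.docs_for_term(term.term_id)) < 2:
                raise TrainingSetError("fewer than 2 positive documents")
            training_set = build_training_set(
                corpus,
                term,
                strategy=config.negative_strategy,
                seed=seed,
                cap=config.positive_cap,
                tree=tree,
                depth_threshold=config.depth_threshold,
            )
            doc_ids, labels = _training_instances(training_set, featurize)
            n_minority = int(np.bincount(labels).min())
            if config.folds > n_minority:
                raise TrainingSetError(
                    f"{config.folds} folds exceed minority class size "
                    f"{n_minority}"
                )
            splitter = StratifiedKFold(
                n_splits=config.folds, shuffle=True, random_state=seed % (2**32 - 1)
            )
            feature_sets = [featurize(d) for d in doc_ids]
            tp = fp = fn = 0
            for train_idx, test_idx in splitter.split(feature_sets, labels):
                predicted = _fold_predictions(
                    method,
                    [feature_sets[i] for i in train_idx],
                    labels[train_idx],
                    [feature_sets[i] for i in test_idx],
                    [corpus[doc_ids[i]] for i in test_idx],
                    term,
                    config.delta,
                    config.prior_variance,
                )
                actual = labels[test_idx]
                predicted = np.asarray(predicted).astype(bool)
                tp += int(np.sum(predicted & (actual == 1)))
                fp += int(np.sum(predicted & (actual == 0)))
                fn += int(np.sum(~predicted & (actual == 1)))
            precision, recall, f = precision_recall_f(tp, fp, fn)
            per_term[term.term_id] = TermScore(precision, recall, f, tp, fp, fn)
        except (TrainingSetError, TrainingError) as exc:
            logger.warning("term %s skipped: %s", term.term_id, exc)
            skipped[term.term_id] = str(exc)
    return EvalReport(per_term=per_term, skipped=skipped, config=config, method=method)
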