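"""Per-term binary Maximum-Entropy classifier trained by penalized IRLS.

The model is a two-class conditional exponential model over binary labeled
features: each class c in {0, 1} carries a weight vector beta_c (plus an
unpenalized intercept) and

    p(c | x) = exp(s_c) / (exp(s_1) + exp(s_0)),
    s_c = intercept_c + sum of beta_c over features present in x.

Training maximizes the conditional log-likelihood penalized by a zero-mean
Gaussian prior with variance ``prior_variance`` on both feature-weight
vectors (intercepts unpenalized).  Because the likelihood depends only on
the difference d = beta_1 - beta_0 while the symmetric prior is minimized at
beta_1 = -beta_0 = d/2, the optimum is found by Newton/IRLS iterations on the
equivalent ridge-penalized logistic problem in d (penalty ||d||^2 / (4
sigma^2)), with step halving so the penalized objective is non-decreasing at
every iteration.  The fitted per-class vectors are recovered as +/- d/2.

Decisions use the threshold t = 0.5 + delta: a document is annotated with the
term iff p(positive | x) > t (strict).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "MaxEntClassifier",
    "TrainingError",
    "train_maxent",
    "predict_proba",
    "classify",
    "ranked_features",
    "save_model",
    "load_model",
]

MODEL_FORMAT_HEADER = "meshent-maxent-model v1"


class TrainingError(ValueError):
    """Raised for degenerate training inputs (single class, divergence)."""


def _vectorize(feature_sets, vocabulary: dict[str, int]) -> sp.csr_matrix:
    """CSR indicator matrix of the feature sets over a fixed vocabulary.

    Features absent from the vocabulary are ignored (contribute nothing).
    """
    indptr = [0]
    indices: list[int] = []
    for fs in feature_sets:
        cols = sorted({vocabulary[f] for f in fs if f in vocabulary})
        indices.extend(cols)
        indptr.append(len(indices))
    data = np.ones(len(indices))
    return sp.csr_matrix(
        (data, indices, indptr), shape=(len(indptr) - 1, len(vocabulary))
    )


class MaxEntClassifier(BaseEstimator, ClassifierMixin):
    """Binary MaxEnt (penalized-IRLS) classifier for one MeSH term.

    Parameters
    ----------
    prior_variance : float, default 1.0
        Variance sigma^2 of the zero-mean Gaussian prior on each per-class
        feature-weight vector.  Larger values penalize less.
    max_iter : int, default 100
        Maximum number of Newton/IRLS iterations.
    tol : float, default 1e-6
        Convergence threshold on the relative change of the penalized
        objective between iterations.
    term_id : str or None
        Optional term identifier carried as model metadata.

    Attributes
    ----------
    vocabulary_ : list of str
        Ordered feature strings seen during fit.
    weights_pos_, weights_neg_ : ndarray of shape (n_features + 1,)
        Per-class weights beta_1 and beta_0, intercept last.
    converged_ : bool
    n_iter_ : int
    objective_path_ : ndarray
        Penalized log-likelihood after each iteration (non-decreasing).
    """

    def __init__(
        self,
        prior_variance: float = 1.0,
        max_iter: int = 100,
        tol: float = 1e-6,
        term_id: str | None = None,
    ):
        self.prior_variance = prior_variance
        self.max_iter = max_iter
        self.tol = tol
        self.term_id = term_id

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Fit on feature sets (collections of feature strings) or a binary
        matrix.  ``y`` holds class labels in {0, 1}, both present."""
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")
        y = np.asarray(y)
        if y.ndim != 1 or len(set(np.unique(y)) - {0, 1}) > 0:
            raise TrainingError("labels must be 0/1")
        if np.unique(y).size < 2:
            raise TrainingError(
                "training requires both a positive and a negative class"
            )
        if sp.issparse(X) or isinstance(X, np.ndarray):
            Xs = sp.csr_matrix(X, dtype=float)
            self.vocabulary_ = [f"f{i}" for i in range(Xs.shape[1])]
        else:
            self.vocabulary_ = sorted(set().union(*map(set, X)) or set())
            vocab = {f: i for i, f in enumerate(self.vocabulary_)}
            Xs = _vectorize(X, vocab)
        if Xs.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")

        d = self._irls(Xs, y.astype(float))
        self.weights_pos_ = d / 2.0
        self.weights_neg_ = -d / 2.0
        self.classes_ = np.array([0, 1])
        if not np.all(np.isfinite(self.weights_pos_)):
            raise TrainingError("non-finite weights after optimization")
        return self

    def _penalty(self) -> float:
        # ||d||^2/(4 sigma^2)  ==  (||d/2||^2 + ||-d/2||^2) / (2 sigma^2)
        return 1.0 / (4.0 * self.prior_variance)

    def _objective(self, Xs, y, d_feat, d_int) -> float:
        eta = Xs @ d_feat + d_int
        # log-likelihood of logistic in the difference parameterization
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll - self._penalty() * float(d_feat @ d_feat)

    def _irls(self, Xs, y) -> np.ndarray:
        n, p = Xs.shape
        d = np.zeros(p + 1)  # feature differences + intercept (last)
        lam = 2.0 * self._penalty()  # second derivative of the penalty
        obj = self._objective(Xs, y, d[:p], d[p])
        path = []
        self.converged_ = False
        self.n_iter_ = 0
        for iteration in range(1, self.max_iter + 1):
            eta = Xs @ d[:p] + d[p]
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = np.empty(p + 1)
            residual = y - mu
            grad[:p] = Xs.T @ residual - lam * d[:p]
            grad[p] = residual.sum()
            Xw = Xs.multiply(w[:, None])
            H = np.empty((p + 1, p + 1))
            H[:p, :p] = (Xw.T @ Xs).toarray()
            H[:p, :p][np.diag_indices(p)] += lam
            cross = np.asarray(Xw.sum(axis=0)).ravel()
            H[:p, p] = cross
            H[p, :p] = cross
            H[p, p] = w.sum()
            step = solve(H, grad, assume_a="pos")
            # step halving keeps the penalized objective non-decreasing
            scale = 1.0
            for _ in range(30):
                cand = d + scale * step
                cand_obj = self._objective(Xs, y, cand[:p], cand[p])
                if cand_obj >= obj:
                    break
                scale *= 0.5
            else:
                cand, cand_obj = d, obj
            d, prev_obj, obj = cand, obj, cand_obj
            path.append(obj)
            self.n_iter_ = iteration
            if not np.isfinite(obj):
                raise TrainingError("non-finite training objective")
            if abs(obj - prev_obj) <= self.tol * (abs(prev_obj) + 1e-12):
                self.converged_ = True
                break
        self.objective_path_ = np.array(path)
        return d

    # -- prediction ---------------------------------------------------------

    def _difference(self) -> np.ndarray:
        return self.weights_pos_ - self.weights_neg_

    def decision_function(self, X) -> np.ndarray:
        """Log-odds s_1 - s_0 for each row/feature set."""
        d = self._difference()
        p = len(self.vocabulary_)
        if sp.issparse(X) or isinstance(X, np.ndarray):
            Xs = sp.csr_matrix(X, dtype=float)
        else:
            vocab = {f: i for i, f in enumerate(self.vocabulary_)}
            Xs = _vectorize(X, vocab)
        return Xs @ d[:p] + d[p]

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, delta: float = 0.0) -> np.ndarray:
        if not 0.0 <= delta <= 0.5:
            raise ValueError(f"delta must lie in [0, 0.5], got {delta}")
        return (self.predict_proba(X)[:, 1] > 0.5 + delta).astype(int)


# -- spec-surface wrappers --------------------------------------------------

def train_maxent(
    instances,
    prior_variance: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    term_id: str | None = None,
) -> MaxEntClassifier:
    """Train from (features, label) pairs; labels must cover both classes."""
    instances = list(instances)
    feature_sets = [fs for fs, _ in instances]
    labels = [int(lab) for _, lab in instances]
    model = MaxEntClassifier(
        prior_variance=prior_variance, max_iter=max_iter, tol=tol, term_id=term_id
    )
    return model.fit(feature_sets, labels)


def predict_proba(model: MaxEntClassifier, feature_set) -> float:
    """p(positive | feature_set); unseen features are ignored."""
    return float(model.predict_proba([feature_set])[0, 1])


def classify(model: MaxEntClassifier, feature_set, delta: float = 0.0) -> int:
    """1 iff p(positive) > 0.5 + delta (strict), else 0."""
    return int(model.predict([feature_set], delta=delta)[0])


def ranked_features(model: MaxEntClassifier, k: int):
    """Top-k positive and top-k negative features by weight difference.

    Positive list descends in beta_1 - beta_0; negative list ascends; ties
    break lexicographically.  Lists are truncated to the vocabulary size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    diff = model._difference()[: len(model.vocabulary_)]
    items = list(zip(model.vocabulary_, diff))
    positive = sorted(items, key=lambda it: (-it[1], it[0]))[:k]
    negative = sorted(items, key=lambda it: (it[1], it[0]))[:k]
    return [f for f, _ in positive], [f for f, _ in negative]


# -- persistence ------------------------------------------------------------

def save_model(model: MaxEntClassifier, destination) -> None:
    """Versioned, diffable text dump: metadata then per-feature weights."""
    if hasattr(destination, "write"):
        handle, close = destination, False
    else:
        handle = open(destination, "w", encoding="utf-8")
        close = True
    try:
        handle.write(MODEL_FORMAT_HEADER + "\n")
        handle.write(f"term_id\t{model.term_id or ''}\n")
        handle.write(f"prior_variance\t{model.prior_variance!r}\n")
        handle.write(f"converged\t{int(model.converged_)}\n")
        handle.write(f"n_iter\t{model.n_iter_}\n")
        handle.write(
            f"intercept\t{float(model.weights_pos_[-1])!r}\t"
            f"{float(model.weights_neg_[-1])!r}\n"
        )
        handle.write(f"n_features\t{len(model.vocabulary_)}\n")
        for i, feature in enumerate(model.vocabulary_):
            handle.write(
                f"{feature}\t{float(model.weights_pos_[i])!r}\t"
                f"{float(model.weights_neg_[i])!r}\n"
            )
    finally:
        if close:
            handle.close()


def load_model(source) -> MaxEntClassifier:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    if not lines or lines[0] != MODEL_FORMAT_HEADER:
        raise ValueError("not a meshent model file (bad header)")
    meta = {}
    i = 1
    while i < len(lines):
        key = lines[i].split("\t", 1)[0]
        meta[key] = lines[i].split("\t")[1:]
        i += 1
        if key == "n_features":
            break
    n = int(meta["n_features"][0])
    vocabulary, wpos, wneg = [], [], []
    for line in lines[i : i + n]:
        feature, a, b = line.split("\t")
        vocabulary.append(feature)
        wpos.append(float(a))
        wneg.append(float(b))
    model = MaxEntClassifier(
        prior_variance=float(meta["prior_variance"][0]),
        term_id=meta["term_id"][0] or None,
    )
    model.vocabulary_ = vocabulary
    model.weights_pos_ = np.array(wpos + [float(meta["intercept"][0])])
    model.weights_neg_ = np.array(wneg + [float(meta["intercept"][1])])
    model.converged_ = bool(int(meta["converged"][0]))
    model.n_iter_ = int(meta["n_iter"][0])
    model.classes_ = np.array([0, 1])
    return model
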