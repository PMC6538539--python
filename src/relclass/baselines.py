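"""Conventional learners for comparison, behind one train/predict surface.

The six comparison models — linear-kernel SVM, SGD-trained linear model,
multinomial naive Bayes, logistic regression, random forest and k-nearest
neighbours — consume the same group texts as the convolutional model,
vectorized as TF-IDF (or raw-count) unigram bags of words using the package
tokenizer, so the comparison isolates the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .embeddings import tokenize

BASELINE_NAMES = (
    "svm",
    "sgd",
    "naive_bayes",
    "logistic_regression",
    "random_forest",
    "knn",
)


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline learner to build, how to vectorize, and with what
    hyperparameters (an open key-value map passed to the estimator)."""

    name: str
    vectorizer: str = "tfidf"
    params: Mapping[str, object] = field(default_factory=dict)
    ngram_range: tuple[int, int] = (1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; expected one of {BASELINE_NAMES}"
            )
        if self.vectorizer not in ("tfidf", "counts"):
            raise ValueError("vectorizer must be 'tfidf' or 'counts'")


def _estimator(spec: BaselineSpec):
    p = dict(spec.params)
    if spec.name == "svm":
        return SVC(kernel="linear", random_state=spec.seed, **p)
    if spec.name == "sgd":
        return SGDClassifier(random_state=spec.seed, **p)
    if spec.name == "naive_bayes":
        return MultinomialNB(**p)
    if spec.name == "logistic_regression":
        return LogisticRegression(max_iter=1000, **p)
    if spec.name == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.name == "knn":
        return KNeighborsClassifier(**p)
    raise AssertionError(spec.name)


def make_baseline(spec: BaselineSpec) -> Pipeline:
    """A scikit-learn pipeline: bag-of-words vectorizer + the named learner."""
    vec_cls = TfidfVectorizer if spec.vectorizer == "tfidf" else CountVectorizer
    vectorizer = vec_cls(
        tokenizer=tokenize,
        preprocessor=None,
        lowercase=False,  # tokenize already lowercases
        token_pattern=None,
        ngram_range=spec.ngram_range,
    )
    return Pipeline([("vectorize", vectorizer), ("classify", _estimator(spec))])


def _texts(texts: Sequence) -> list[str]:
    return [getattr(t, "text", t) for t in texts]


def fit_baseline(texts: Sequence, labels: Sequence[str], spec: BaselineSpec) -> Pipeline:
    """Fit one baseline on group texts; deterministic given ``spec.seed``.

    The vectorizer vocabulary is fit on the training texts only.  Raises on
    empty input or a single-class label set.
    """
    texts = _texts(texts)
    if not texts:
        raise ValueError("cannot fit a baseline on an empty text list")
    if len(np.unique(np.asarray(labels))) < 2:
        raise ValueError("training data contains a single class; need at least 2")
    model = make_baseline(spec)
    model.fit(texts, np.asarray(labels))
    return model


def predict_baseline(model: Pipeline, texts: Sequence) -> np.ndarray:
    """Predict one label per text; labels come from the training classes."""
    return model.predict(_texts(texts))
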