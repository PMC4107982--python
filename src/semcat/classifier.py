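"""Probabilistic span classification with confidence-thresholded suggestion.

The model is an L2-regularised multinomial logistic regression over sparse
binary feature vectors.  Its probabilistic outputs serve two modes:

* ``classify`` — the single most confident category;
* ``suggest`` — the smallest set of categories, taken highest-confidence
  first, whose cumulative confidence reaches a threshold.  The threshold
  governs the trade-off between ambiguity (suggestion-set size) and recall
  (gold category present among suggestions).

For confidences [Protein 0.90, Chemical 0.06, Organism 0.04] and threshold
0.95 the suggestion set is {Protein, Chemical}: 0.90 falls short, 0.96
reaches the threshold, and Organism is not needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .annotation_io import AnnotatedSpan, Corpus
from .features import FeatureConfig, FeatureExtractor
from .lexicon import LexicalResource

__all__ = [
    "TrainedModel",
    "ConfidenceDistribution",
    "SuggestionSet",
    "train",
    "predict_confidences",
    "suggest",
    "classify",
    "save_model",
    "load_model",
]

# Guard so a distribution summing to 1 - eps still yields the full
# inventory at threshold 1.0.
_CUM_TOL = 1e-12


@dataclass(frozen=True)
class ConfidenceDistribution:
    """Per-category probabilities for one span, in inventory order."""

    confidences: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.confidences)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"confidences sum to {total}, expected 1")
        if any(not (0 <= c <= 1) for _, c in self.confidences):
            raise ValueError("confidences must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(self.confidences)


@dataclass(frozen=True)
class SuggestionSet:
    """Ordered (category, confidence) suggestions, highest first."""

    suggestions: tuple[tuple[str, float], ...]
    threshold: float

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.suggestions)

    @property
    def ambiguity(self) -> int:
        return len(self.suggestions)


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature extractor it was trained with."""

    categories: tuple[str, ...]
    vectorizer: DictVectorizer
    estimator: LogisticRegression
    extractor: FeatureExtractor

    @property
    def config(self) -> FeatureConfig:
        return self.extractor.config


def train(train_corpus: Corpus, config: FeatureConfig,
          resources: Mapping[str, LexicalResource] | None = None,
          C: float = 1.0, seed: int = 0,
          extractor: FeatureExtractor | None = None) -> TrainedModel:
    """Fit the model on a training corpus.

    The category inventory is the ordered subset of the corpus inventory
    actually present in the training spans; a category without training
    evidence can never be suggested.  Deterministic given ``seed``.
    """
    if not train_corpus.spans:
        raise ValueError("cannot train on an empty corpus")
    present = {sp.category for sp in train_corpus.spans}
    categories = tuple(c for c in train_corpus.categories if c in present)
    if len(categories) < 2:
        raise ValueError(
            f"training data covers {len(categories)} category; need >= 2"
        )
    if extractor is None:
        extractor = FeatureExtractor(config, resources)
    elif extractor.config != config:
        raise ValueError("extractor config differs from the requested config")

    cat_index = {c: i for i, c in enumerate(categories)}
    X_dicts = [extractor.extract(sp.surface) for sp in train_corpus.spans]
    y = np.array([cat_index[sp.category] for sp in train_corpus.spans])
    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform(X_dicts)
    estimator = LogisticRegression(
        C=C, max_iter=2000, solver="lbfgs", random_state=seed
    )
    estimator.fit(X, y)
    return TrainedModel(categories=categories, vectorizer=vectorizer,
                        estimator=estimator, extractor=extractor)


def predict_confidences(model: TrainedModel, span: AnnotatedSpan | str) -> ConfidenceDistribution:
    """Softmax-normalised distribution over the model's category inventory."""
    surface = span if isinstance(span, str) else span.surface
    if not surface:
        raise ValueError("cannot classify an empty span")
    X = model.vectorizer.transform([model.extractor.extract(surface)])
    proba = model.estimator.predict_proba(X)[0]
    # classes_ are inventory indices 0..k-1, already sorted
    confs = tuple(
        (model.categories[int(cls)], float(p))
        for cls, p in zip(model.estimator.classes_, proba)
    )
    return ConfidenceDistribution(confidences=confs)


def suggest(dist: ConfidenceDistribution, threshold: float) -> SuggestionSet:
    """Smallest highest-confidence-first category set reaching the threshold.

    Categories are ordered by descending confidence, ties broken by
    inventory order; the returned set is the shortest prefix of that order
    whose cumulative confidence is >= the threshold.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ranked = sorted(
        enumerate(dist.confidences), key=lambda ic: (-ic[1][1], ic[0])
    )
    picked: list[tuple[str, float]] = []
    cum = 0.0
    for _idx, (cat, conf) in ranked:
        picked.append((cat, conf))
        cum += conf
        if cum >= threshold - _CUM_TOL:
            break
    return SuggestionSet(suggestions=tuple(picked), threshold=threshold)


def classify(dist: ConfidenceDistribution) -> str:
    """Single most confident category, ties broken by inventory order."""
    ranked = sorted(
        enumerate(dist.confidences), key=lambda ic: (-ic[1][1], ic[0])
    )
    return ranked[0][1][0]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise the model (inventory, weights, extractor state) to disk."""
    joblib.dump(
        {
            "format": "semcat-model",
            "version": 1,
            "categories": model.categories,
            "vectorizer": model.vectorizer,
            "estimator": model.estimator,
            "extractor": model.extractor,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if not (isinstance(payload, dict) and payload.get("format") == "semcat-model"):
        raise ValueError(f"{path} is not a semcat model archive")
    return TrainedModel(
        categories=payload["categories"],
        vectorizer=payload["vectorizer"],
        estimator=payload["estimator"],
        extractor=payload["extractor"],
    )
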