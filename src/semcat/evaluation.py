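"""Evaluation metrics and protocols for category suggestion.

Metrics:

* **accuracy** — fraction of spans whose single-label prediction is gold;
* **recall** — fraction of spans whose gold category appears in the
  suggestion set;
* **mean ambiguity** — mean suggestion-set size;
* **ambiguity reduction** — (|C| - ambiguity) / (|C| - 1), where |C| is the
  corpus category inventory size.  Subtracting one in the denominator gives
  the metric the same [0, 1] range as recall: 1 means every span got a
  single suggestion, 0 means the full inventory was always returned;
* **harmonic mean** — H(ambiguity reduction, recall) = 2ab / (a + b), the
  headline trade-off number.

The learning-curve protocol trains on repeated random subsamples at a grid
of training fractions (5%..100% by default), averages each point over the
repeats, and summarises a curve by the mean over its points, approximating
the area under the curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Corpus, subsample
from .classifier import TrainedModel, classify, predict_confidences, suggest, train
from .features import FeatureConfig
from .lexicon import LexicalResource

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSummary",
    "LearningCurve",
    "ambiguity_reduction",
    "harmonic_mean",
    "evaluate",
    "threshold_sweep",
    "learning_curve",
    "DEFAULT_FRACTIONS",
    "summaries_to_frame",
]

DEFAULT_FRACTIONS = tuple(round(0.05 * i, 2) for i in range(1, 21))


def ambiguity_reduction(n_categories: int, mean_ambiguity: float) -> float:
    """Normalised reduction of suggestion-set size over the inventory.

    (|C| - ambiguity) / (|C| - 1); equals 1 at ambiguity 1 (perfect
    disambiguation) and 0 at ambiguity |C| (no reduction).
    """
    if n_categories < 2:
        raise ValueError(f"need >= 2 categories, got {n_categories}")
    if not (1.0 - 1e-9 <= mean_ambiguity <= n_categories + 1e-9):
        raise ValueError(
            f"mean ambiguity {mean_ambiguity} outside [1, {n_categories}]"
        )
    return (n_categories - mean_ambiguity) / (n_categories - 1)


def harmonic_mean(amb_red: float, recall: float) -> float:
    """2ab / (a + b); 0 when both are 0.  Scale-consistent: accepts either
    the [0, 1] scale or the x100 percentage scale, as long as both
    arguments use the same one."""
    if amb_red < 0 or recall < 0:
        raise ValueError("harmonic mean arguments must be non-negative")
    if amb_red + recall == 0:
        return 0.0
    return 2 * amb_red * recall / (amb_red + recall)


@dataclass(frozen=True)
class EvalSummary:
    """Metrics of one evaluation run, stored on the [0, 1] scale."""

    accuracy: float
    recall: float
    mean_ambiguity: float
    ambiguity_reduction: float
    harmonic_mean: float
    n_categories: int
    n_spans: int
    threshold: float

    def as_row(self) -> dict[str, float | int]:
        return {
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "mean_ambiguity": self.mean_ambiguity,
            "ambiguity_reduction": self.ambiguity_reduction,
            "harmonic_mean": self.harmonic_mean,
            "n_spans": self.n_spans,
            "n_categories": self.n_categories,
        }


@dataclass(frozen=True)
class LearningCurve:
    """Per-fraction mean metrics plus their over-points summary."""

    fractions: tuple[float, ...]
    points: tuple[EvalSummary, ...]
    summary: EvalSummary
    samples_per_point: int
    seed: int


def evaluate(model: TrainedModel, test: Corpus, threshold: float,
             return_details: bool = False):
    """Score a model on a test corpus at one confidence threshold.

    Ambiguity reduction is normalised by the test corpus's full category
    inventory.  A span whose gold category is unknown to the model counts
    as both a classification miss and a recall miss.
    """
    if not test.spans:
        raise ValueError("cannot evaluate on an empty corpus")
    known = set(model.categories)
    unknown = sorted({sp.category for sp in test.spans} - known)
    if unknown:
        logger.warning("gold categories unknown to the model (counted as "
                       "misses): %s", unknown)

    n_correct = 0
    n_recalled = 0
    ambiguities = []
    details = []
    for sp in test.spans:
        dist = predict_confidences(model, sp)
        top = classify(dist)
        sugg = suggest(dist, threshold)
        correct = top == sp.category
        recalled = sp.category in sugg.categories
        n_correct += correct
        n_recalled += recalled
        ambiguities.append(sugg.ambiguity)
        if return_details:
            details.append((sp, sugg, correct, recalled))

    n = len(test.spans)
    mean_amb = float(np.mean(ambiguities))
    amb_red = ambiguity_reduction(len(test.categories), mean_amb)
    recall = n_recalled / n
    summary = EvalSummary(
        accuracy=n_correct / n,
        recall=recall,
        mean_ambiguity=mean_amb,
        ambiguity_reduction=amb_red,
        harmonic_mean=harmonic_mean(amb_red, recall),
        n_categories=len(test.categories),
        n_spans=n,
        threshold=threshold,
    )
    if return_details:
        return summary, details
    return summary


def threshold_sweep(model: TrainedModel, test: Corpus,
                    thresholds: Sequence[float]) -> list[EvalSummary]:
    """One EvalSummary per threshold on a fixed model and test set."""
    for t in thresholds:
        if not (0 < t <= 1):
            raise ValueError(f"threshold must be in (0, 1], got {t}")
    return [evaluate(model, test, t) for t in thresholds]


def _mean_summary(summaries: Sequence[EvalSummary], threshold: float) -> EvalSummary:
    mean = lambda attr: float(np.mean([getattr(s, attr) for s in summaries]))
    amb_red = mean("ambiguity_reduction")
    recall = mean("recall")
    return EvalSummary(
        accuracy=mean("accuracy"),
        recall=recall,
        mean_ambiguity=mean("mean_ambiguity"),
        ambiguity_reduction=amb_red,
        harmonic_mean=harmonic_mean(amb_red, recall),
        n_categories=summaries[0].n_categories,
        n_spans=int(round(mean("n_spans"))),
        threshold=threshold,
    )


def learning_curve(train_corpus: Corpus, test: Corpus, config: FeatureConfig,
                   threshold: float,
                   fractions: Sequence[float] = DEFAULT_FRACTIONS,
                   samples_per_point: int = 5, seed: int = 0,
                   resources: dict[str, LexicalResource] | None = None,
                   C: float = 1.0) -> LearningCurve:
    """Train/evaluate on repeated random subsamples at each training fraction.

    Each point's metrics are means over ``samples_per_point`` independent
    subsamples (seeds derived from the master seed and point index); the
    curve summary is the mean over points.  Fractions whose subsample does
    not cover at least two categories are skipped with a log entry.
    """
    points: list[EvalSummary] = []
    kept_fracs: list[float] = []
    for i, frac in enumerate(fractions):
        reps: list[EvalSummary] = []
        for j in range(samples_per_point):
            sub_seed = (seed * 100003 + i * 1009 + j) % (2**31)
            sub = subsample(train_corpus, frac, seed=sub_seed)
            if len({sp.category for sp in sub.spans}) < 2:
                continue
            model = train(sub, config, resources=resources, C=C, seed=sub_seed)
            reps.append(evaluate(model, test, threshold))
        if not reps:
            logger.warning("skipping fraction %.2f: subsamples cover < 2 "
                           "categories", frac)
            continue
        points.append(_mean_summary(reps, threshold))
        kept_fracs.append(frac)
    if not points:
        raise ValueError("no usable learning-curve points")
    return LearningCurve(
        fractions=tuple(kept_fracs),
        points=tuple(points),
        summary=_mean_summary(points, threshold),
        samples_per_point=samples_per_point,
        seed=seed,
    )


def summaries_to_frame(summaries: Iterable[EvalSummary],
                       dataset: str = "", model_variant: str = "",
                       scale100: bool = True) -> pd.DataFrame:
    """Tabulate summaries; metrics reported x100 to mirror printed tables."""
    rows = []
    for s in summaries:
        row = {"dataset": dataset, "model_variant": model_variant, **s.as_row()}
        if scale100:
            for k in ("accuracy", "recall", "ambiguity_reduction", "harmonic_mean"):
                row[k] = round(100 * row[k], 2)
            row["mean_ambiguity"] = round(row["mean_ambiguity"], 2)
        rows.append(row)
    return pd.DataFrame(rows)
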