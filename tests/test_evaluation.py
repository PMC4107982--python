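"""Ambiguity-reduction arithmetic, harmonic means, and evaluation protocols."""

import numpy as np
import pytest

from semcat.annotation_io import AnnotatedSpan, Corpus, Document
from semcat.classifier import train
from semcat.evaluation import (DEFAULT_FRACTIONS, ambiguity_reduction,
                               evaluate, harmonic_mean, learning_curve,
                               summaries_to_frame, threshold_sweep)
from semcat.features import FeatureConfig
from semcat.synthetic import GeneratorSpec, make_corpus, make_lexicons


class TestAmbiguityReduction:
    def test_perfect_disambiguation(self):
        assert ambiguity_reduction(10, 1.0) == pytest.approx(1.0)

    def test_no_reduction(self):
        assert ambiguity_reduction(10, 10.0) == pytest.approx(0.0)

    def test_direct_substitution(self):
        assert ambiguity_reduction(17, 2.5) == pytest.approx(14.5 / 16)

    def test_range_and_endpoints_over_grid(self):
        for n in range(2, 30):
            for amb in np.linspace(1.0, n, 17):
                v = ambiguity_reduction(n, float(amb))
                assert 0.0 <= v <= 1.0

    def test_fewer_than_two_categories_rejected(self):
        for n in (0, 1):
            with pytest.raises(ValueError):
                ambiguity_reduction(n, 1.0)

    def test_out_of_range_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            ambiguity_reduction(5, 0.5)
        with pytest.raises(ValueError):
            ambiguity_reduction(5, 6.0)


class TestHarmonicMean:
    @pytest.mark.parametrize("a,b,expected", [
        (78.00, 99.54, 87.46),
        (88.50, 99.99, 93.89),
        (77.60, 98.14, 86.67),
        (78.00, 99.79, 87.56),
    ])
    def test_printed_percentage_pairs(self, a, b, expected):
        assert harmonic_mean(a, b) == pytest.approx(expected, abs=0.005)

    def test_idempotent_on_equal_arguments(self):
        for x in (0.0, 0.3, 1.0):
            assert harmonic_mean(x, x) == pytest.approx(x)

    def test_zero_sum_returns_zero(self):
        assert harmonic_mean(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean(-0.1, 0.5)


class _FixedModel:
    """Stub model emitting predetermined confidence distributions."""

    def __init__(self, table, categories):
        from semcat.classifier import ConfidenceDistribution
        self.categories = tuple(categories)
        self._table = {
            surface: ConfidenceDistribution(tuple(zip(categories, probs)))
            for surface, probs in table.items()
        }

    # duck-typed: evaluate() only calls predict_confidences via module fn,
    # so expose the pieces it needs
    class _Extractor:
        config = None

        def extract(self, surface):
            return {}

    extractor = _Extractor()


def _manual_eval_fixture():
    """Three spans over three categories with hand-chosen confidences."""
    from semcat import classifier as clf

    cats = ("A", "B", "C")
    text = "sa sb sc"
    doc = Document("d", text)
    spans = [AnnotatedSpan("d", 0, 2, "A", "sa"),
             AnnotatedSpan("d", 3, 5, "B", "sb"),
             AnnotatedSpan("d", 6, 8, "C", "sc")]
    corpus = Corpus({"d": doc}, spans, cats)
    table = {
        "sa": (0.97, 0.02, 0.01),   # singleton at 0.95; correct
        "sb": (0.60, 0.30, 0.10),   # argmax wrong; {A,B} at 0.90 -> recalled
        "sc": (0.50, 0.30, 0.20),   # argmax wrong; {A,B} misses C
    }
    model = _FixedModel(table, cats)
    return corpus, model, table


class TestEvaluateHandEnumerated:
    def test_metrics_match_hand_computation(self, monkeypatch):
        corpus, model, _table = _manual_eval_fixture()
        from semcat import evaluation as ev

        monkeypatch.setattr(ev, "predict_confidences",
                            lambda m, sp: m._table[sp.surface])
        s = ev.evaluate(model, corpus, 0.90)
        # hand enumeration at threshold 0.90:
        # sa -> {A} (0.97) correct+recalled, amb 1
        # sb -> {A,B} (0.90) wrong argmax, recalled, amb 2
        # sc -> {A,B} (0.80 < 0.90 -> add C) amb 3, recalled
        assert s.accuracy == pytest.approx(1 / 3)
        assert s.recall == pytest.approx(1.0)
        assert s.mean_ambiguity == pytest.approx(2.0)
        assert s.ambiguity_reduction == pytest.approx((3 - 2.0) / (3 - 1))
        assert s.harmonic_mean == pytest.approx(harmonic_mean(0.5, 1.0))

    def test_sweep_monotone_in_threshold(self, monkeypatch):
        corpus, model, _table = _manual_eval_fixture()
        from semcat import evaluation as ev

        monkeypatch.setattr(ev, "predict_confidences",
                            lambda m, sp: m._table[sp.surface])
        lo, hi = ev.threshold_sweep(model, corpus, [0.5, 0.99])
        assert hi.recall >= lo.recall
        assert hi.mean_ambiguity >= lo.mean_ambiguity
        assert hi.ambiguity_reduction <= lo.ambiguity_reduction

    def test_recall_at_threshold_one_is_total(self, monkeypatch):
        corpus, model, _table = _manual_eval_fixture()
        from semcat import evaluation as ev

        monkeypatch.setattr(ev, "predict_confidences",
                            lambda m, sp: m._table[sp.surface])
        s = ev.evaluate(model, corpus, 1.0)
        assert s.recall == 1.0
        assert s.ambiguity_reduction == pytest.approx(0.0)

    def test_recall_never_below_accuracy(self, monkeypatch):
        corpus, model, _table = _manual_eval_fixture()
        from semcat import evaluation as ev

        monkeypatch.setattr(ev, "predict_confidences",
                            lambda m, sp: m._table[sp.surface])
        for t in (0.3, 0.6, 0.9, 1.0):
            s = ev.evaluate(model, corpus, t)
            assert s.recall >= s.accuracy


@pytest.fixture(scope="module")
def small_synthetic():
    spec = GeneratorSpec(n_categories=3, lexicon_size=60, n_spans=240,
                         noise_rate=0.05, seed=21)
    lexicons = make_lexicons(spec)
    corpus = make_corpus(spec, lexicons)
    train_c = corpus.with_spans(corpus.spans[:160])
    test_c = corpus.with_spans(corpus.spans[160:])
    return train_c, test_c, lexicons


class TestLearningCurve:
    def test_single_full_fraction_equals_evaluate(self, small_synthetic):
        train_c, test_c, lexicons = small_synthetic
        config = FeatureConfig.from_variant("INT.SIM", resources=tuple(lexicons))
        curve = learning_curve(train_c, test_c, config, 0.995,
                               fractions=[1.0], samples_per_point=1, seed=0,
                               resources=lexicons)
        model = train(train_c, config, resources=lexicons,
                      seed=(0 * 100003 + 0 * 1009 + 0) % 2**31)
        direct = evaluate(model, test_c, 0.995)
        point = curve.points[0]
        assert point.accuracy == pytest.approx(direct.accuracy)
        assert point.mean_ambiguity == pytest.approx(direct.mean_ambiguity)
        assert curve.summary.accuracy == pytest.approx(point.accuracy)

    def test_more_data_helps(self, small_synthetic):
        train_c, test_c, lexicons = small_synthetic
        config = FeatureConfig.from_variant("INT.SIM", resources=tuple(lexicons))
        curve = learning_curve(train_c, test_c, config, 0.995,
                               fractions=[0.1, 1.0], samples_per_point=3,
                               seed=1, resources=lexicons)
        accs = {f: p.accuracy for f, p in zip(curve.fractions, curve.points)}
        assert accs[1.0] >= accs[0.1]

    def test_default_fraction_grid(self):
        assert DEFAULT_FRACTIONS[0] == 0.05
        assert DEFAULT_FRACTIONS[-1] == 1.0
        assert len(DEFAULT_FRACTIONS) == 20
        assert all(b > a for a, b in zip(DEFAULT_FRACTIONS, DEFAULT_FRACTIONS[1:]))

    def test_report_frame_layout(self, small_synthetic):
        train_c, test_c, lexicons = small_synthetic
        config = FeatureConfig.from_variant("INT", resources=())
        model = train(train_c, config, seed=0)
        frame = summaries_to_frame(threshold_sweep(model, test_c, [0.995, 0.95]),
                                   dataset="synthetic", model_variant="INT")
        assert list(frame.columns) == [
            "dataset", "model_variant", "threshold", "accuracy", "recall",
            "mean_ambiguity", "ambiguity_reduction", "harmonic_mean",
            "n_spans", "n_categories",
        ]
        assert len(frame) == 2
        assert frame["accuracy"].between(0, 100).all()
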