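import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from cdrscreen.evaluation import (
    ConfusionCounts,
    confusion,
    metrics,
    per_class_report,
    relative_drop,
    relative_improvement,
    roc_auc,
)


class TestConfusion:
    def test_perfect_predictions(self):
        truth = [1] * 10 + [0] * 10
        counts = confusion(truth, truth)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (10, 10, 0, 0)

    def test_all_positive_predictor(self):
        truth = [1] * 4 + [0] * 6
        counts = confusion([1] * 10, truth)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (4, 6, 0, 0)

    def test_class_swap_exchanges_counts(self, rng):
        pred = rng.integers(0, 2, 50)
        truth = rng.integers(0, 2, 50)
        c1 = confusion(pred, truth, positive_class=1)
        c0 = confusion(pred, truth, positive_class=0)
        assert (c0.tp, c0.fp, c0.tn, c0.fn) == (c1.tn, c1.fn, c1.tp, c1.fp)

    def test_matches_pairwise_tally(self, rng):
        pred = rng.integers(0, 2, 30)
        truth = rng.integers(0, 2, 30)
        counts = confusion(pred, truth)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, truth):
            key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert tally == {
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn
        }

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        report = metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert report.acc == report.pre == report.sen == report.f_measure == 1.0
        assert report.mcc == 1.0

    def test_chance_classifier(self):
        report = metrics(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert report.acc == 0.5
        assert report.mcc == 0.0

    def test_f_is_harmonic_mean_of_pre_and_sen(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 21, 4)
            report = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            harmonic = 2 / (1 / report.pre + 1 / report.sen)
            assert report.f_measure == pytest.approx(harmonic)

    def test_zero_denominator_reported_as_nan(self):
        report = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert math.isnan(report.pre)
        assert math.isnan(report.sen)
        assert report.acc == 1.0

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 15, 4))
            a = metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
            b = metrics(ConfusionCounts(tn, fn, tp, fp)).mcc
            assert a == pytest.approx(b)

    def test_legacy_variant_differs_from_standard(self):
        counts = ConfusionCounts(tp=8, fp=2, tn=7, fn=3)
        standard = metrics(counts).mcc
        legacy = metrics(counts, legacy_mcc=True).mcc
        assert standard != legacy
        denom = math.sqrt((8 + 2) * (8 + 3) * (7 + 2) * (7 + 3))
        assert standard == pytest.approx((8 * 7 - 2 * 3) / denom)

    def test_per_class_zero_equals_label_flip(self, rng):
        pred = rng.integers(0, 2, 40)
        truth = rng.integers(0, 2, 40)
        reports = per_class_report(pred, truth)
        flipped = metrics(confusion(1 - pred, 1 - truth, positive_class=1))
        assert reports[0].as_dict()["sen"] == pytest.approx(flipped.sen)
        assert reports[0].as_dict()["pre"] == pytest.approx(flipped.pre)


class TestROC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc([0.5] * 8, [1, 0] * 4)
        assert auc == 0.5

    def test_matches_mann_whitney_pair_count(self, rng):
        for _ in range(30):
            scores = rng.choice([0.1, 0.4, 0.7, 0.9], size=8)
            truth = rng.integers(0, 2, 8)
            if truth.min() == truth.max():
                continue
            auc, _ = roc_auc(scores, truth)
            pos = scores[truth == 1]
            neg = scores[truth == 0]
            wins = sum(
                1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos
                for n in neg
            )
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_agrees_with_sklearn(self, rng):
        scores = rng.random(100)
        truth = rng.integers(0, 2, 100)
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        truth = rng.integers(0, 2, 50)
        a1, _ = roc_auc(scores, truth)
        a2, _ = roc_auc(np.exp(3 * scores), truth)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_curve_endpoints(self, rng):
        auc, points = roc_auc(rng.random(20), rng.integers(0, 2, 20))
        assert points[0][:2].tolist() == [0.0, 0.0]
        assert points[-1][:2].tolist() == [1.0, 1.0]


class TestComparisonCalculators:
    @pytest.mark.parametrize(
        "new,baseline,expected",
        [
            (0.956, 0.933, 2.465),   # sensitivity, two-model comparison
            (0.920, 0.839, 9.654),   # MCC
            (0.960, 0.919, 4.461),   # accuracy
            (0.5, 0.5, 0.0),
        ],
    )
    def test_relative_improvement(self, new, baseline, expected):
        assert relative_improvement(new, baseline) == expected

    @pytest.mark.parametrize(
        "original,new,expected",
        [
            (0.960, 0.909, 5.312),   # accuracy, disease-held-out regime
            (0.964, 0.948, 1.660),   # AUC, compound-held-out regime
            (0.7, 0.7, 0.0),
        ],
    )
    def test_relative_drop(self, original, new, expected):
        assert relative_drop(original, new) == expected

    def test_nonpositive_baselines_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.5, 0.0)
        with pytest.raises(ValueError):
            relative_drop(-1.0, 0.5)


class TestReportIO:
    def test_metric_report_json_and_table(self, tmp_path, rng):
        import json

        from cdrscreen.evaluation import format_metric_table, write_metric_report

        report = metrics(ConfusionCounts(tp=8, fp=2, tn=7, fn=3))
        path = tmp_path / "report.json"
        write_metric_report(report, path)
        payload = json.loads(path.read_text())
        assert payload["acc"] == report.acc
        assert payload["counts"]["tp"] == 8
        table = format_metric_table({"tiny": report})
        assert "tiny" in table and "NA" in table  # auc not computed -> NA

    def test_roc_points_csv(self, tmp_path, rng):
        import pandas as pd

        from cdrscreen.evaluation import write_roc_points

        _, points = roc_auc(rng.random(20), rng.integers(0, 2, 20))
        path = tmp_path / "roc.csv"
        write_roc_points(points, path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["fpr", "tpr", "threshold"]
        assert len(frame) == len(points)
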