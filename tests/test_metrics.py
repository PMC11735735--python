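import json

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import hashdemux as hd
from hashdemux.io_formats import ValidationError


def _labels(mapping):
    return pd.DataFrame(
        {"barcode": list(mapping), "label": list(mapping.values()), "confidence": 1.0}
    )


class TestFScore:
    def test_perfect_prediction(self):
        truth = _labels({"c1": "A", "c2": "B", "c3": "Doublet"})
        per_tag, avg = hd.f_score(truth, truth)
        assert per_tag == {"A": 1.0, "B": 1.0}
        assert avg == 1.0

    def test_hand_contingency_table(self):
        # 4 true A cells; 3 called A, 1 Negative -> P=1, R=0.75, F=6/7
        truth = _labels({f"c{i}": "A" for i in range(4)} | {"c9": "B"})
        pred = _labels(
            {"c0": "A", "c1": "A", "c2": "A", "c3": "Negative", "c9": "B"}
        )
        per_tag, _ = hd.f_score(pred, truth)
        assert per_tag["A"] == pytest.approx(6 / 7)

    def test_never_predicted_tag_scores_zero(self):
        truth = _labels({"c1": "A", "c2": "B"})
        pred = _labels({"c1": "A", "c2": "A"})
        per_tag, avg = hd.f_score(pred, truth)
        assert per_tag["B"] == 0.0
        assert avg == pytest.approx(np.mean(list(per_tag.values())))

    def test_doublet_negative_not_averaged_classes(self):
        truth = _labels({"c1": "A", "c2": "Doublet", "c3": "Negative"})
        pred = _labels({"c1": "A", "c2": "Doublet", "c3": "Negative"})
        per_tag, _ = hd.f_score(pred, truth)
        assert set(per_tag) == {"A"}

    def test_barcode_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            hd.f_score(_labels({"c1": "A"}), _labels({"c2": "A"}))


class TestDoubletMisclassification:
    def test_counting(self):
        truth = {f"d{i}": "Doublet" for i in range(98)}
        pred = {f"d{i}": ("A" if i < 49 else "Negative") for i in range(98)}
        rate = hd.doublet_misclassification(_labels(pred), _labels(truth))
        assert rate == pytest.approx(0.5)

    def test_doublet_or_negative_calls_not_counted(self):
        truth = _labels({"d1": "Doublet", "d2": "Doublet"})
        pred = _labels({"d1": "Doublet", "d2": "Negative"})
        assert hd.doublet_misclassification(pred, truth) == 0.0

    def test_no_doublets_warns_and_returns_zero(self):
        truth = _labels({"c1": "A"})
        pred = _labels({"c1": "A"})
        with pytest.warns(UserWarning):
            assert hd.doublet_misclassification(pred, truth) == 0.0


def brute_force_aucpr(scores, positive):
    """Independent oracle: enumerate all (P, R) operating points by direct
    counting, then integrate the precision-recall interpolation numerically.

    For each distinct threshold t, TP = #{positives with score > t} and
    FP = #{negatives with score > t} (counted with explicit loops). The first
    attainable point contributes a rectangle from recall 0; each later
    recall-increasing segment contributes the numerically integrated
    Davis-Goadrich interpolated precision.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    thresholds = sorted(set(scores), reverse=True)
    points = []
    for t in thresholds:
        tp = sum(1 for s, p in zip(scores, positive) if s >= t and p)
        fp = sum(1 for s, p in zip(scores, positive) if s >= t and not p)
        points.append((tp, fp))
    area = 0.0
    prev = None
    for tp, fp in points:
        if tp == 0:
            prev = (tp, fp)
            continue
        if prev is None or prev[0] == 0:
            area += (tp / n_pos) * (tp / (tp + fp))
        else:
            a, b = prev
            delta = tp - a
            if delta > 0:
                s = (fp - b) / delta

                def precision(x):
                    return (a + x) / (a + x + b + s * x)

                val, _ = quad(precision, 0, delta, epsabs=1e-13, epsrel=1e-13)
                area += val / n_pos
        prev = (tp, fp)
    return area


class TestAucprSeparability:
    def _run(self, scores, positive):
        scores = np.asarray(scores, dtype=float)
        n = len(scores)
        values = np.vstack([scores, np.zeros(n)])
        m = hd.NormalizedTagMatrix(
            values, ["T", "other"], [f"c{i}" for i in range(n)], "rc"
        )
        truth = _labels(
            {f"c{i}": ("T" if positive[i] else "Negative") for i in range(n)}
        )
        return hd.aucpr_separability(m, truth, "T")

    def test_perfect_separation(self):
        scores = [10, 9, 8, 3, 2, 1]
        positive = [True, True, True, False, False, False]
        assert self._run(scores, positive) == pytest.approx(1.0)

    def test_worst_ranking_single_recall_point(self):
        # pos={1}, neg={2,3}: only attainable point is (R=1, P=1/3)
        assert self._run([1, 2, 3], [True, False, False]) == pytest.approx(1 / 3)

    def test_constant_scores_give_prevalence(self):
        scores = [5] * 10
        positive = [True] * 3 + [False] * 7
        assert self._run(scores, positive) == pytest.approx(0.3)

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 21)
            scores = rng.integers(0, 8, size=n)  # small range forces ties
            positive = rng.random(n) < 0.4
            if positive.all() or not positive.any():
                continue
            got = self._run(scores, positive)
            expected = brute_force_aucpr(scores, positive)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 50, size=40)
        positive = rng.random(40) < 0.3
        raw = self._run(scores, positive)
        transformed = self._run(np.log1p(scores) * 7 + 2, positive)
        assert raw == transformed

    def test_doublets_excluded(self):
        counts = np.array([[9, 8, 7, 1], [0, 0, 0, 0]])
        m = hd.TagCountMatrix(counts, ["T", "o"], ["c1", "c2", "c3", "c4"])
        truth = _labels({"c1": "T", "c2": "Doublet", "c3": "Negative", "c4": "Negative"})
        # with c2 excluded, the single positive outranks both negatives
        assert hd.aucpr_separability(m, truth, "T") == pytest.approx(1.0)

    def test_no_positives_is_missing(self):
        counts = np.array([[1, 2], [3, 4]])
        m = hd.TagCountMatrix(counts, ["T", "o"], ["c1", "c2"])
        truth = _labels({"c1": "Negative", "c2": "Negative"})
        with pytest.warns(UserWarning):
            assert hd.aucpr_separability(m, truth, "T") is None


class TestNoiseStatistics:
    def _matrix(self, counts):
        counts = np.asarray(counts)
        return hd.TagCountMatrix(
            counts,
            [f"t{i}" for i in range(counts.shape[0])],
            [f"c{j}" for j in range(counts.shape[1])],
        )

    def test_baseline_variability_identical_tags_zero(self):
        m = self._matrix(np.tile([3, 7, 11, 2], (4, 1)))
        assert hd.baseline_expression_variability(m) == 0.0

    def test_baseline_variability_hand_value(self):
        # medians {ln 9, 0}: CV with sample sd = sqrt(2)
        m = self._matrix([[8] * 6, [0] * 6])
        assert hd.baseline_expression_variability(m) == pytest.approx(
            np.sqrt(2), abs=1e-9
        )

    def test_baseline_variability_permutation_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, size=(3, 30))
        m = self._matrix(counts)
        perm = self._matrix(counts[:, rng.permutation(30)])
        assert hd.baseline_expression_variability(m) == pytest.approx(
            hd.baseline_expression_variability(perm)
        )

    def test_all_zero_matrix_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(hd.baseline_expression_variability(
                self._matrix(np.zeros((2, 4), dtype=int))
            ))

    def test_depth_variability_equal_totals(self):
        m = self._matrix([[5, 5, 5], [3, 3, 3]])
        assert hd.sequencing_depth_variability(m) == 1.0

    def test_depth_variability_two_orders_of_magnitude(self):
        totals = np.linspace(100, 10000, 200).astype(int)
        counts = np.vstack([totals, np.zeros_like(totals)])
        m = self._matrix(counts)
        ratio = hd.sequencing_depth_variability(m)
        # direct percentile computation on the constructed vector:
        # p1 ~ 199, p99 ~ 9901, ratio ~ 49.8 for a 100..10000 uniform span
        expected = np.percentile(totals, 99) / np.percentile(totals, 1)
        assert ratio == pytest.approx(expected)
        assert ratio > 10

    def test_depth_variability_scale_invariant(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 50, size=(3, 40))
        assert hd.sequencing_depth_variability(
            self._matrix(counts)
        ) == pytest.approx(
            hd.sequencing_depth_variability(self._matrix(counts * 3))
        )

    def test_zero_first_percentile_infinite(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, 50:] = 10
        with pytest.warns(UserWarning):
            assert hd.sequencing_depth_variability(self._matrix(counts)) == float("inf")


class TestEvaluate:
    def test_perfect_prediction_report(self, small_dataset):
        ds = small_dataset
        truth = ds.truth_labels()
        report = hd.evaluate(truth, truth, ds.matrix)
        assert report.average_f == 1.0
        assert report.doublet_to_singlet_rate == 0.0
        assert report.average_f == pytest.approx(
            np.mean(list(report.per_tag_f.values()))
        )
        for v in report.per_tag_aucpr.values():
            assert v is None or 0.0 <= v <= 1.0

    def test_report_round_trips_through_json(self, small_dataset, tmp_path):
        ds = small_dataset
        truth = ds.truth_labels()
        report = hd.evaluate(truth, truth, ds.matrix)
        report.to_json(tmp_path / "r.json")
        with open(tmp_path / "r.json") as fh:
            back = hd.EvaluationReport.from_dict(json.load(fh))
        assert back.to_dict() == report.to_dict()

    def test_missing_aucpr_encoded_as_null(self):
        counts = np.array([[5, 1], [2, 3]])
        m = hd.TagCountMatrix(counts, ["A", "B"], ["c1", "c2"])
        truth = _labels({"c1": "A", "c2": "A"})  # B never present
        pred = _labels({"c1": "A", "c2": "A"})
        with pytest.warns(UserWarning):
            report = hd.evaluate(pred, truth, m)
        assert report.to_dict()["per_tag_aucpr"]["B"] is None
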