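import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sorsbone import (
    ConfusionMatrix,
    RankError,
    RocError,
    SubjectRecord,
    WHORule,
    class_metrics,
    classify_who,
    confusion,
    fit_tscore_loso,
    pairwise_roc,
)

# the unique 3x3 matrix with row sums (6, 4, 11) reproducing the reported
# per-class precision and sensitivity of the cadaveric classifier
REFERENCE_CM = np.array([[5, 0, 1], [1, 1, 2], [1, 0, 10]])


class TestWHORule:
    @pytest.mark.parametrize(
        "t, cls",
        [(0.05, "Normal"), (-0.999, "Normal"), (-1.0, "Osteopenia"),
         (-1.63, "Osteopenia"), (-2.499, "Osteopenia"),
         (-2.5, "Osteoporosis"), (-4.19, "Osteoporosis")],
    )
    def test_boundaries(self, t, cls):
        assert classify_who(t) == cls

    def test_band_width_is_one_and_a_half(self):
        assert WHORule().band_width == pytest.approx(1.5)

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            classify_who(float("nan"))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-10, 5, allow_nan=False))
    def test_partition_and_monotonicity(self, t):
        order = {"Osteoporosis": 0, "Osteopenia": 1, "Normal": 2}
        cls = classify_who(t)
        assert cls in order
        # a lower T-score never maps to a healthier class
        assert order[classify_who(t - 0.5)] <= order[cls]


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        true = ["Normal"] * 6 + ["Osteopenia"] * 4 + ["Osteoporosis"] * 11
        cm = confusion(true, true)
        assert np.array_equal(np.diag(cm.counts), [6, 4, 11])
        assert cm.counts.sum() == 21

    def test_degenerate_all_normal_predictor(self):
        true = ["Normal"] * 6 + ["Osteopenia"] * 4 + ["Osteoporosis"] * 11
        cm = confusion(true, ["Normal"] * 21)
        assert np.array_equal(cm.counts[:, 0], [6, 4, 11])
        assert cm.counts[:, 1:].sum() == 0

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            cm = confusion([], [])
        assert cm.counts.sum() == 0

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            confusion(["Normal"], ["Severe"])


class TestClassMetrics:
    def test_reference_matrix_normal_metrics(self):
        m = class_metrics(ConfusionMatrix(REFERENCE_CM)).per_class["Normal"]
        assert m["precision"] == pytest.approx(5 / 7)
        assert m["sensitivity"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(13 / 15)
        assert m["accuracy"] == pytest.approx(18 / 21)

    def test_reference_matrix_osteoporosis_metrics(self):
        m = class_metrics(ConfusionMatrix(REFERENCE_CM)).per_class["Osteoporosis"]
        assert m["specificity"] == pytest.approx(7 / 10)
        assert m["accuracy"] == pytest.approx(17 / 21)

    def test_diagonal_matrix_all_ones(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]))
        for cls, m in class_metrics(cm).per_class.items():
            assert all(v == 1.0 for v in m.values())

    def test_undefined_precision_reported_none(self):
        # Osteopenia never predicted: precision 0/0
        cm = ConfusionMatrix(np.array([[6, 0, 0], [2, 0, 2], [0, 0, 11]]))
        with pytest.warns(UserWarning, match="precision undefined"):
            m = class_metrics(cm)
        assert m.per_class["Osteopenia"]["precision"] is None

    def test_micro_average_identity(self):
        """Accuracy identities: per-class accuracy == (TP+TN)/N exactly,
        and micro-averaged sensitivity equals the overall fraction
        correct."""
        cm = ConfusionMatrix(REFERENCE_CM)
        metrics = class_metrics(cm)
        tp_total = 0
        for cls in cm.classes:
            tp, fp, tn, fn = cm.one_vs_rest(cls)
            assert metrics.per_class[cls]["accuracy"] == (tp + tn) / cm.total
            tp_total += tp
        assert tp_total / cm.total == np.trace(cm.counts) / cm.counts.sum()


def _records_from_scores(labels):
    t_by_class = {"Normal": 0.0, "Osteopenia": -1.5, "Osteoporosis": -3.0}
    return [
        SubjectRecord(f"s{i}", t_by_class[c], c) for i, c in enumerate(labels)
    ]


class TestROC:
    def test_perfect_separation(self):
        recs = _records_from_scores(["Normal"] * 3 + ["Osteoporosis"] * 3)
        scores = {"s0": 0.1, "s1": 0.2, "s2": 0.3, "s3": 1.1, "s4": 1.2,
                  "s5": 1.3}
        _, auc = pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))
        assert auc == 1.0

    def test_tied_pairs_half_credit(self):
        # positives {2,3,4}, negatives {1,2,3}: 6 wins + 2 ties of 9 pairs
        recs = _records_from_scores(["Normal"] * 3 + ["Osteoporosis"] * 3)
        scores = {"s0": 1.0, "s1": 2.0, "s2": 3.0, "s3": 2.0, "s4": 3.0,
                  "s5": 4.0}
        _, auc = pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))
        assert auc == pytest.approx(7 / 9)

    def test_uninformative_scores(self):
        recs = _records_from_scores(["Normal"] * 3 + ["Osteoporosis"] * 4)
        scores = {f"s{i}": 5.0 for i in range(7)}
        _, auc = pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))
        assert auc == 0.5

    def test_empty_class_raises(self):
        recs = _records_from_scores(["Normal"] * 3)
        scores = {f"s{i}": float(i) for i in range(3)}
        with pytest.raises(RocError):
            pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 3), min_size=1, max_size=6),
        neg=st.lists(st.integers(0, 3), min_size=1, max_size=6),
    )
    def test_auc_equals_pair_enumeration(self, pos, neg):
        """AUC == brute-force count over all (pos, neg) score pairs with
        half credit for ties."""
        labels = ["Normal"] * len(neg) + ["Osteoporosis"] * len(pos)
        recs = _records_from_scores(labels)
        scores = {
            f"s{i}": float(v) for i, v in enumerate(list(neg) + list(pos))
        }
        _, auc = pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        neg = rng.normal(size=8)
        pos = rng.normal(loc=0.7, size=9)
        labels = ["Normal"] * 8 + ["Osteoporosis"] * 9
        recs = _records_from_scores(labels)
        scores = {
            f"s{i}": float(v)
            for i, v in enumerate(np.concatenate([neg, pos]))
        }
        _, auc = pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))
        ref = roc_auc_score([0] * 8 + [1] * 9, np.concatenate([neg, pos]))
        assert auc == pytest.approx(float(ref))

    def test_curve_endpoints(self):
        recs = _records_from_scores(["Normal"] * 3 + ["Osteoporosis"] * 3)
        scores = {f"s{i}": float(i) for i in range(6)}
        curve, _ = pairwise_roc(scores, recs, ("Normal", "Osteoporosis"))
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)


class TestTScoreLOSO:
    @staticmethod
    def _linear_cohort(n=12, p=60, seed=43, noise=0.0):
        # spectra-like rows: the T-score is exactly linear in the
        # amplitude of one band, the other band is constant
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, p)
        peak1 = np.exp(-0.5 * ((grid - 0.3) / 0.05) ** 2)
        peak2 = np.exp(-0.5 * ((grid - 0.7) / 0.05) ** 2)
        amp = rng.uniform(0.2, 2.0, size=n)
        X = amp[:, None] * peak1 + peak2
        t = amp * 1.5 - 2.0 + noise * rng.normal(size=n)
        records = [
            SubjectRecord(f"s{i}", float(ti), classify_who(float(ti)))
            for i, ti in enumerate(t)
        ]
        return X, records

    def test_exact_linear_signal(self):
        X, records = self._linear_cohort()
        result = fit_tscore_loso(X, records, ranks=range(1, 6))
        t = np.array([r.tscore for r in records])
        assert result.pearson_r > 0.999
        assert result.rmse_cv < 1e-3 * np.ptp(t)

    def test_tie_break_prefers_smaller_rank(self):
        X, records = self._linear_cohort()
        result = fit_tscore_loso(X, records, ranks=range(1, 6))
        near_min = [
            r for r, v in result.rmse_by_rank.items()
            if v <= result.rmse_cv + 1e-12
        ]
        assert result.chosen_rank == min(near_min)

    def test_one_prediction_per_subject(self):
        X, records = self._linear_cohort(noise=0.3)
        result = fit_tscore_loso(X, records, ranks=[2, 3])
        assert len(result.predicted_tscores) == len(records)
        assert result.subject_ids == [r.subject_id for r in records]

    def test_too_few_subjects(self):
        X, records = self._linear_cohort(n=3)
        with pytest.raises(RankError):
            fit_tscore_loso(X, records)

    def test_permuted_labels_destroy_signal(self, default_cohort):
        """Permutation null: shuffling the T-scores across subjects leaves
        no exploitable signal, so the mean |r| over permutations is small."""
        data, gt, records = default_cohort
        subjects = np.asarray(data.subjects)
        positions = np.asarray([s[1] for s in data.sites])
        X = np.vstack([
            data.Y[(subjects == r.subject_id) & (positions == 0.0)][0]
            for r in records
        ])
        rng = np.random.default_rng(51)
        rs = []
        for _ in range(50):
            perm = rng.permutation(len(records))
            shuffled = [
                SubjectRecord(
                    records[i].subject_id,
                    records[perm[i]].tscore,
                    records[perm[i]].who_class,
                )
                for i in range(len(records))
            ]
            res = fit_tscore_loso(X, shuffled)
            rs.append(abs(res.pearson_r))
        assert np.mean(rs) < 0.3
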