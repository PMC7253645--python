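import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

from cardiochain.chain import PredictionSet
from cardiochain.datamodel import (
    ConfigValidationError,
    LABEL_GROUPS,
    LabelMatrix,
    UndefinedMetricError,
)
from cardiochain.evaluation import (
    ConfusionCounts,
    accuracy_f1,
    auc,
    cohen_kappa,
    evaluate,
    kappa_frobenius_distance,
    kappa_matrix,
    lhs_sample,
    lhs_tune,
    make_folds,
    matthews_cc,
    relationship_preservation,
    smote_oversample,
)


def vectors_from_counts(c: ConfusionCounts):
    truth = [1] * c.tp + [0] * c.tn + [0] * c.fp + [1] * c.fn
    pred = [1] * c.tp + [0] * c.tn + [1] * c.fp + [0] * c.fn
    return np.array(truth), np.array(pred)


class TestMatthews:
    def test_perfect_prediction_is_one(self):
        assert matthews_cc(ConfusionCounts(tp=3, tn=4, fp=0, fn=0)) == 1.0

    def test_total_disagreement_is_minus_one(self):
        assert matthews_cc(ConfusionCounts(tp=0, tn=0, fp=2, fn=3)) == -1.0

    def test_hand_example(self):
        assert matthews_cc(ConfusionCounts(3, 2, 1, 1)) == pytest.approx(5 / 12)

    def test_zero_denominator_convention(self):
        assert matthews_cc(ConfusionCounts(tp=0, tn=3, fp=0, fn=2)) == 0.0

    def test_exhaustive_small_vs_sklearn(self):
        # brute-force oracle over all tables with total <= 7
        for tp, tn, fp, fn in itertools.product(range(8), repeat=4):
            if not 0 < tp + tn + fp + fn <= 7:
                continue
            counts = ConfusionCounts(tp, tn, fp, fn)
            truth, pred = vectors_from_counts(counts)
            assert matthews_cc(counts) == pytest.approx(
                matthews_corrcoef(truth, pred), abs=1e-12
            )


class TestAccuracyF1:
    def test_hand_example(self):
        accuracy, precision, recall, f1 = accuracy_f1(ConfusionCounts(3, 2, 1, 1))
        assert accuracy == pytest.approx(5 / 7)
        assert precision == pytest.approx(3 / 4)
        assert recall == pytest.approx(3 / 4)
        assert f1 == pytest.approx(0.75)

    def test_all_correct(self):
        accuracy, _, _, f1 = accuracy_f1(ConfusionCounts(2, 3, 0, 0))
        assert accuracy == 1.0 and f1 == 1.0

    def test_empty_denominator_convention(self):
        accuracy, precision, recall, f1 = accuracy_f1(ConfusionCounts(0, 4, 0, 1))
        assert precision == 0.0 and f1 == 0.0


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_half(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_pair_counting_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_one_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.2, 0.4], [1, 1])

    @given(
        scores=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=8
        ),
        data=st.data(),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_pair_counting_oracle(self, scores, data):
        truth = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(truth)) < 2:
            return
        scores = np.array(scores)
        truth = np.array(truth)
        # independent oracle: count ordered pairs, ties worth 1/2
        wins = 0.0
        pairs = 0
        for i in range(len(truth)):
            for j in range(len(truth)):
                if truth[i] == 1 and truth[j] == 0:
                    pairs += 1
                    if scores[i] > scores[j]:
                        wins += 1.0
                    elif scores[i] == scores[j]:
                        wins += 0.5
        assert auc(scores, truth) == pytest.approx(wins / pairs, abs=1e-12)


class TestCohenKappa:
    def test_identity(self):
        assert cohen_kappa([1, 0, 1, 1, 0], [1, 0, 1, 1, 0]).kappa == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        result = cohen_kappa([1, 1, 0, 0], [0, 0, 1, 1])
        assert result.kappa == pytest.approx(-1.0)
        assert result.p_o == 0.0
        assert result.p_e == pytest.approx(0.5)

    def test_hand_evaluation(self):
        # p_o = 0.8, marginals (0.6, 0.4) x (0.4, 0.6) -> p_e = 0.48
        result = cohen_kappa([1, 1, 0, 0, 1], [1, 0, 0, 0, 1])
        assert result.p_o == pytest.approx(0.8)
        assert result.p_e == pytest.approx(0.48)
        assert result.kappa == pytest.approx(1 - 0.2 / 0.52)
        assert result.kappa == pytest.approx(
            cohen_kappa_score([1, 1, 0, 0, 1], [1, 0, 0, 0, 1])
        )

    def test_kappa_identity_invariant(self):
        result = cohen_kappa([1, 0, 0, 1, 1, 0], [0, 0, 1, 1, 1, 0])
        assert result.kappa == pytest.approx(1 - (1 - result.p_o) / (1 - result.p_e))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 0], [1, 0, 1])

    def test_undefined_when_expected_agreement_one(self):
        with pytest.raises(UndefinedMetricError):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_exhaustive_vs_sklearn(self):
        # all binary vector pairs of length 4..5
        for n in (4, 5):
            for bits in itertools.product((0, 1), repeat=2 * n):
                a, b = np.array(bits[:n]), np.array(bits[n:])
                pa, pb = a.mean(), b.mean()
                p_e = pa * pb + (1 - pa) * (1 - pb)
                if p_e >= 1.0:
                    continue
                assert cohen_kappa(a, b).kappa == pytest.approx(
                    cohen_kappa_score(a, b), abs=1e-12
                )

    def test_z_test_significance_direction(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 500)
        b = a.copy()
        flip = rng.random(500) < 0.1
        b[flip] = 1 - b[flip]
        strong = cohen_kappa(a, b)
        weak = cohen_kappa(a, rng.integers(0, 2, 500))
        assert strong.p_value < 0.001
        assert strong.z > weak.z


class TestMakeFolds:
    def meta(self, n_drugs=10, reps=3):
        return pd.DataFrame(
            {
                "drug_id": [f"D{i}" for i in range(n_drugs) for _ in range(reps)],
                "cell_line": "A",
                "time_h": 6.0,
                "concentration": 1.0,
            }
        )

    def test_leave_drug_out_counts(self):
        plan = make_folds(self.meta(), k=5, strategy="leave_drug_out", seed=0)
        meta = self.meta()
        for tr, va in plan.folds:
            assert len(va) == 6  # 2 drugs x 3 replicates
            tr_drugs = set(meta["drug_id"].iloc[list(tr)])
            va_drugs = set(meta["drug_id"].iloc[list(va)])
            assert not tr_drugs & va_drugs
            assert len(va_drugs) == 2

    def test_random_strategy_leaks_drugs(self):
        leaked = 0
        for seed in range(20):
            plan = make_folds(self.meta(), k=5, strategy="random", seed=seed)
            meta = self.meta()
            for tr, va in plan.folds:
                tr_drugs = set(meta["drug_id"].iloc[list(tr)])
                va_drugs = set(meta["drug_id"].iloc[list(va)])
                if tr_drugs & va_drugs:
                    leaked += 1
                    break
        assert leaked == 20  # with 3 replicates per drug leakage is near-certain

    def test_determinism(self):
        a = make_folds(self.meta(), 4, "leave_drug_out", seed=9)
        b = make_folds(self.meta(), 4, "leave_drug_out", seed=9)
        assert a == b

    def test_partition_property(self):
        for strategy in ("leave_drug_out", "random"):
            for seed in range(10):
                plan = make_folds(self.meta(), 3, strategy, seed=seed)
                plan.validate_partition(30)

    def test_too_few_drugs(self):
        with pytest.raises(ConfigValidationError):
            make_folds(self.meta(n_drugs=3), k=5, strategy="leave_drug_out", seed=0)


class TestSmote:
    def test_two_minority_points_interpolate_on_segment(self, rng):
        design = np.vstack(
            [rng.normal(5, 1, size=(20, 2)), np.array([[0.0, 0.0], [1.0, 2.0]])]
        )
        label = np.array([0] * 20 + [1] * 2)
        augmented, y = smote_oversample(design, label, 1.0, k_neighbors=5, seed=0)
        synthetic = augmented[22:]
        # every synthetic point is a + u*(b-a) for the only two minority points
        direction = np.array([1.0, 2.0])
        for point in synthetic:
            u = point[0]  # since a=(0,0), b=(1,2): x = u, y = 2u
            assert point[1] == pytest.approx(2 * u, abs=1e-9)
            assert 0 <= u <= 1

    def test_count_arithmetic(self, rng):
        design = rng.normal(size=(50, 3))
        label = np.array([1] * 10 + [0] * 40)
        augmented, y = smote_oversample(design, label, 1.0, 3, seed=1)
        assert (y == 1).sum() >= 40
        assert len(augmented) - len(design) >= 30

    def test_originals_untouched(self, rng):
        design = rng.normal(size=(30, 4))
        label = np.array([1] * 5 + [0] * 25)
        original = design.copy()
        augmented, y = smote_oversample(design, label, 1.0, 3, seed=2)
        np.testing.assert_array_equal(augmented[:30], original)
        np.testing.assert_array_equal(y[:30], label)

    def test_tiny_minority_skipped(self, rng, caplog):
        design = rng.normal(size=(10, 2))
        label = np.array([1] + [0] * 9)
        with caplog.at_level("WARNING"):
            augmented, y = smote_oversample(design, label, 1.0, 5, seed=3)
        assert len(augmented) == 10
        assert "skipped" in caplog.text

    def test_binary_columns_rethresholded(self, rng):
        design = np.column_stack(
            [rng.normal(size=40), rng.integers(0, 2, 40).astype(float)]
        )
        label = np.array([1] * 8 + [0] * 32)
        augmented, _ = smote_oversample(
            design, label, 1.0, 3, seed=4, binary_columns=[1]
        )
        assert np.isin(augmented[:, 1], (0.0, 1.0)).all()


class TestLhs:
    def test_margin_stratification(self):
        points = lhs_sample({"x": (0.0, 1.0), "y": (0.0, 1.0)}, 4, seed=0)
        for name in ("x", "y"):
            values = sorted(p[name] for p in points)
            for i, v in enumerate(values):
                assert i / 4 <= v < (i + 1) / 4  # one point per quartile bin

    def test_integer_rounding(self):
        points = lhs_sample({"n": (1, 10)}, 5, seed=1)
        assert all(isinstance(p["n"], int) for p in points)

    def test_determinism(self):
        a = lhs_sample({"x": (0.0, 1.0)}, 6, seed=3)
        b = lhs_sample({"x": (0.0, 1.0)}, 6, seed=3)
        assert a == b

    def test_unbounded_range_rejected(self):
        with pytest.raises(ConfigValidationError):
            lhs_sample({"x": (0.0, math.inf)}, 3, seed=0)

    def test_unimodal_objective_near_optimum(self):
        def objective(params):
            return 2.0 - (params["x"] - 0.5) ** 2 - (params["y"] - 0.5) ** 2

        for seed in range(5):
            best, history = lhs_tune(
                {"x": (0.0, 1.0), "y": (0.0, 1.0)}, 10, objective, seed=seed
            )
            assert objective(best) >= 0.95 * 2.0
            assert len(history) == 10

    def test_tie_break_first_encountered(self):
        best, history = lhs_tune({"x": (0.0, 1.0)}, 5, lambda p: 1.0, seed=2)
        assert best == history[0][0]


def prediction_set(drug_ids, labels, probabilities):
    meta = pd.DataFrame(
        {"drug_id": drug_ids, "cell_line": "A", "time_h": 6.0, "concentration": 1.0}
    )
    return PredictionSet(meta, list(labels), np.asarray(probabilities, float))


class TestEvaluate:
    def full_label_matrix(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 2, size=(n, 7))
        values[0] = 0
        values[1] = 1  # avoid constant columns
        return LabelMatrix([f"D{i}" for i in range(n)], list(LABEL_GROUPS), values)

    def test_perfect_predictions(self):
        labels = self.full_label_matrix()
        probabilities = labels.values.astype(float)
        predictions = prediction_set(labels.drug_ids, labels.labels, probabilities)
        report = evaluate(predictions, labels)
        assert report.aggregate["mean_auc"] == 1.0
        assert report.aggregate["mean_mcc"] == 1.0
        assert report.aggregate["half_sd_auc"] == 0.0

    def test_constant_probabilities_auc_half(self):
        labels = self.full_label_matrix()
        predictions = prediction_set(
            labels.drug_ids, labels.labels, np.full((8, 7), 0.5)
        )
        report = evaluate(predictions, labels)
        for name in LABEL_GROUPS:
            assert report.per_label[name].auc == pytest.approx(0.5)

    def test_vascular_excluded_from_aggregate(self):
        labels = self.full_label_matrix()
        probabilities = labels.values.astype(float)
        # corrupt vascular predictions only: aggregates must stay perfect
        probabilities[:, 0] = 1 - probabilities[:, 0]
        predictions = prediction_set(labels.drug_ids, labels.labels, probabilities)
        report = evaluate(predictions, labels)
        assert report.aggregate["mean_auc"] == 1.0
        assert report.per_label["vascular_disorders"].auc == 0.0

    def test_hand_built_confusion_tables(self):
        labels = LabelMatrix(
            ["D0", "D1", "D2", "D3", "D4", "D5", "D6"],
            list(LABEL_GROUPS),
            np.array(
                [
                    [0, 1, 0, 1, 0, 1, 0],
                    [1, 1, 0, 0, 1, 0, 1],
                    [0, 0, 1, 1, 0, 0, 0],
                    [1, 1, 1, 0, 0, 1, 1],
                    [0, 0, 0, 1, 1, 0, 0],
                    [1, 1, 1, 1, 1, 1, 1],
                    [0, 0, 0, 0, 0, 0, 0],
                ]
            ),
        )
        rng = np.random.default_rng(5)
        probabilities = rng.uniform(size=(7, 7))
        predictions = prediction_set(labels.drug_ids, labels.labels, probabilities)
        report = evaluate(predictions, labels)
        hard = (probabilities >= 0.5).astype(int)
        for j, name in enumerate(LABEL_GROUPS):
            y = labels.values[:, j]
            c = report.per_label[name].counts
            assert c.tp == ((y == 1) & (hard[:, j] == 1)).sum()
            assert c.tn == ((y == 0) & (hard[:, j] == 0)).sum()
            assert report.per_label[name].mcc == pytest.approx(
                matthews_corrcoef(y, hard[:, j]) if len(set(y)) > 1 else 0.0, abs=1e-9
            )
            assert report.per_label[name].auc == pytest.approx(
                roc_auc_score(y, probabilities[:, j])
            )

    def test_mean_half_sd_convention(self):
        labels = self.full_label_matrix(n=30, seed=2)
        rng = np.random.default_rng(3)
        predictions = prediction_set(
            labels.drug_ids, labels.labels, rng.uniform(size=(30, 7))
        )
        report = evaluate(predictions, labels)
        aucs = [report.per_label[n].auc for n in LABEL_GROUPS[1:]]
        assert report.aggregate["mean_auc"] == pytest.approx(np.mean(aucs))
        assert report.aggregate["half_sd_auc"] == pytest.approx(
            0.5 * np.std(aucs, ddof=1)
        )


class TestRelationshipPreservation:
    def test_identical_predictions_zero_difference(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 2, size=(40, 7))
        labels = LabelMatrix([f"D{i}" for i in range(40)], list(LABEL_GROUPS), values)
        predictions = prediction_set(labels.drug_ids, labels.labels, values.astype(float))
        kappa_pred, kappa_true, diff = relationship_preservation(predictions, labels)
        np.testing.assert_allclose(diff.to_numpy(), 0.0, atol=1e-12)
        assert kappa_frobenius_distance(kappa_pred, kappa_true) == pytest.approx(0.0)

    def test_noise_predictions_flat_kappa(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 2, 300)
        values = np.column_stack(
            [rng.integers(0, 2, 300)]
            + [np.where(rng.random(300) < 0.85, base, 1 - base) for _ in range(6)]
        )  # strongly associated cardiac labels
        labels = LabelMatrix([f"D{i}" for i in range(300)], list(LABEL_GROUPS), values)
        noise = rng.uniform(size=(300, 7))
        predictions = prediction_set(labels.drug_ids, labels.labels, noise)
        kappa_pred, kappa_true, _ = relationship_preservation(predictions, labels)
        off_pred = kappa_pred.to_numpy()[~np.eye(6, dtype=bool)]
        off_true = kappa_true.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.nanmean(np.abs(off_pred)) < 0.15
        assert np.nanmean(off_true) > 0.4

    def test_kappa_matrix_masks_undefined_pairs(self):
        # two identical constant columns -> p_e = 1 -> masked as NaN
        values = np.column_stack([np.ones(10), np.ones(10), np.arange(10) % 2])
        grid = kappa_matrix(values.astype(int), ["a", "b", "c"])
        assert math.isnan(grid.loc["a", "b"])
        assert grid.loc["a", "c"] == pytest.approx(0.0)
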