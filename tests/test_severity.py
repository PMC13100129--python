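"""Label handling, ordinal decomposition, LOSO evaluation and metrics."""

import numpy as np
import pytest

from fingertap import (
    SeverityDataset,
    SeverityLabel,
    ValidationError,
    compute_metrics,
    frank_hall_probabilities,
    loso_evaluate,
    majority_vote,
    merge_scores,
    ordinal_fit_predict,
    simulate_cohort,
)


class TestMergeScores:
    @pytest.mark.parametrize(
        "score, label",
        [
            (0, SeverityLabel.MILD),
            (1, SeverityLabel.MILD),
            (2, SeverityLabel.MODERATE),
            (3, SeverityLabel.SEVERE),
            (4, SeverityLabel.SEVERE),
        ],
    )
    def test_mapping(self, score, label):
        assert merge_scores(score) is label

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            merge_scores(5)

    def test_group_counts(self):
        per_score = {0: 355, 1: 1070, 2: 1380, 3: 1196, 4: 72}
        groups = {lbl: 0 for lbl in SeverityLabel}
        for score, n in per_score.items():
            groups[merge_scores(score)] += n
        assert groups[SeverityLabel.MILD] == 1425
        assert groups[SeverityLabel.MODERATE] == 1380
        assert groups[SeverityLabel.SEVERE] == 1268


class TestMajorityVote:
    @pytest.mark.parametrize(
        "ratings, expected",
        [([2, 2, 3], 2), ([1], 1), ([1, 2], 1), ([3, 3, 1, 1, 0], 1)],
    )
    def test_vote(self, ratings, expected):
        assert majority_vote(ratings) == expected

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            majority_vote([])


class TestFrankHall:
    def test_arithmetic(self):
        probs = frank_hall_probabilities(np.array([0.9]), np.array([0.2]))
        np.testing.assert_allclose(probs, [[0.1, 0.7, 0.2]])
        assert probs.argmax(axis=1)[0] == SeverityLabel.MODERATE

    def test_certain_mild(self):
        probs = frank_hall_probabilities(np.array([0.0]), np.array([0.0]))
        np.testing.assert_allclose(probs, [[1.0, 0.0, 0.0]])

    def test_monotonicity_violation_clipped(self):
        probs = frank_hall_probabilities(np.array([0.3]), np.array([0.6]))
        np.testing.assert_allclose(probs, [[0.7 / 1.3, 0.0, 0.6 / 1.3]])
        assert probs.argmax(axis=1)[0] == SeverityLabel.MILD

    def test_probabilities_normalised(self):
        rng = np.random.default_rng(0)
        q1, q2 = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        probs = frank_hall_probabilities(q1, q2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()

    def test_degenerate_binary_task(self):
        # only Mild and Moderate in training: the y > Moderate task is
        # single-class and must fall back to a constant probability
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = np.array([0, 1] * 15)
        preds, probs = ordinal_fit_predict(X, y, X, "logistic", seed=0)
        np.testing.assert_allclose(probs[:, 2], 0.0, atol=1e-12)
        assert set(preds) <= {0, 1}


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        rep = compute_metrics(y, y)
        assert rep.accuracy == rep.balanced_accuracy == 100.0
        assert rep.macro_precision == rep.macro_f1 == 100.0

    def test_constant_predictor_balanced_accuracy(self):
        y = np.array([0] * 10 + [1] * 5 + [2] * 25)
        rep = compute_metrics(y, np.full_like(y, 2))
        assert rep.balanced_accuracy == pytest.approx(100 / 3)

    def test_majority_baseline_row(self):
        # majority prevalence 34.84 %: the constant predictor's macro
        # precision is p/3 and macro F1 is (2p/(1+p))/3
        y = np.array([0] * 3484 + [1] * 3258 + [2] * 3258)
        rep = compute_metrics(y, np.zeros_like(y))
        assert rep.accuracy == pytest.approx(34.84, abs=0.005)
        assert rep.balanced_accuracy == pytest.approx(33.33, abs=0.005)
        assert rep.macro_precision == pytest.approx(11.61, abs=0.005)
        assert rep.macro_f1 == pytest.approx(17.23, abs=0.005)

    def test_confusion_row_sums_are_supports(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 100)
        y_pred = rng.integers(0, 3, 100)
        rep = compute_metrics(y_true, y_pred)
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1), np.bincount(y_true, minlength=3)
        )

    def test_fuzz_against_brute_force_tally(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            y_true = rng.integers(0, 3, n)
            y_pred = rng.integers(0, 3, n)
            rep = compute_metrics(y_true, y_pred)
            # independent tally
            acc = 100 * sum(t == p for t, p in zip(y_true, y_pred)) / n
            present = sorted(set(y_true.tolist()))
            recalls, precisions, f1s = [], [], []
            for c in present:
                tp = sum((t == c) and (p == c) for t, p in zip(y_true, y_pred))
                sup = sum(t == c for t in y_true)
                pred = sum(p == c for p in y_pred)
                r = tp / sup
                pr = tp / pred if pred else 0.0
                recalls.append(r)
                precisions.append(pr)
                f1s.append(2 * pr * r / (pr + r) if pr + r else 0.0)
            assert rep.accuracy == pytest.approx(acc)
            assert rep.balanced_accuracy == pytest.approx(100 * np.mean(recalls))
            assert rep.macro_precision == pytest.approx(100 * np.mean(precisions))
            assert rep.macro_f1 == pytest.approx(100 * np.mean(f1s))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            compute_metrics([0, 1], [0])


def toy_dataset(n_subjects=6, per_subject=3, seed=0) -> SeverityDataset:
    rng = np.random.default_rng(seed)
    means = {0: [0.0, 0.0], 1: [4.0, 0.0], 2: [8.0, 0.0]}
    X, y, subs = [], [], []
    for s in range(n_subjects):
        label = s % 3
        for r in range(per_subject):
            X.append(rng.normal(means[label], 0.5))
            y.append(label)
            subs.append(f"S{s}")
    return SeverityDataset(
        X=np.asarray(X), y=np.asarray(y), subject_ids=np.asarray(subs)
    )


class TestLoso:
    def test_constant_rule_learner(self):
        # Mild dominates every training fold, so the majority-rule learner
        # must predict Mild for every pooled recording
        rng = np.random.default_rng(8)
        labels = [0, 0, 0, 0, 1, 2]
        X, y, subs = [], [], []
        for s, lbl in enumerate(labels):
            for r in range(3):
                X.append(rng.normal(size=2))
                y.append(lbl)
                subs.append(f"S{s}")
        data = SeverityDataset(
            X=np.asarray(X), y=np.asarray(y), subject_ids=np.asarray(subs)
        )
        rep, preds = loso_evaluate(data, model="majority", seed=0)
        assert set(preds["predicted"]) == {0}
        assert rep.balanced_accuracy == pytest.approx(100 / 3)

    def test_no_subject_leaks_into_own_training(self):
        # two-subject dataset: each subject is predicted by a model that, by
        # construction, never saw any of its recordings
        data = toy_dataset(n_subjects=2)
        rep, preds = loso_evaluate(data, model="logistic", seed=0)
        assert set(preds["subject_id"]) == {"S0", "S1"}
        assert len(preds) == len(data)

    def test_separable_classes_high_balanced_accuracy(self):
        data = toy_dataset(n_subjects=12, per_subject=2, seed=1)
        rep, _ = loso_evaluate(data, model="logistic", seed=1)
        assert rep.balanced_accuracy >= 90.0

    def test_missing_class_in_training_still_predicts(self):
        # single Severe subject: its outer fold trains without class 2
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 2))
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        subs = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        data = SeverityDataset(X=X, y=y, subject_ids=subs)
        rep, preds = loso_evaluate(data, model="logistic", seed=0)
        assert len(preds) == 9

    def test_single_subject_errors(self):
        data = toy_dataset(n_subjects=1)
        with pytest.raises(ValidationError):
            loso_evaluate(data, model="logistic")

    def test_seed_reproducibility_with_tuning(self):
        data = toy_dataset(n_subjects=6, per_subject=2, seed=5)
        r1, p1 = loso_evaluate(data, model="logistic", tuning_budget=3, seed=9)
        r2, p2 = loso_evaluate(data, model="logistic", tuning_budget=3, seed=9)
        assert r1.accuracy == r2.accuracy
        assert p1.equals(p2)

    def test_ordinal_mode_on_cohort(self):
        data, _ = simulate_cohort(n_subjects=12, recordings_per_subject=1, seed=6)
        rep, preds = loso_evaluate(data, model="logistic", mode="ordinal", seed=6)
        probs = preds[["p_mild", "p_moderate", "p_severe"]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
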