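"""OSR classifier: splitting, SMOTE, forest training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from swarmkin import (
    ClassifierConfig,
    evaluate,
    run_classifier,
    smote_oversample,
    split_train_test,
    train_forest,
)
from swarmkin.classify import FEATURES, LABEL, _digest, feature_importance
from swarmkin.errors import TrackDataError

CODES = [0, 50, 100, 150, 200]


def _table(rng, n_per_class=200, separation=5.0, n_tracks_per_class=20):
    """Synthetic kinematics: one Gaussian cloud per OSR code."""
    frames = []
    for i, code in enumerate(CODES):
        X = rng.normal(loc=i * separation, scale=1.0, size=(n_per_class, 5))
        df = pd.DataFrame(X, columns=FEATURES)
        df[LABEL] = code
        df["track_id"] = [
            f"c{code}_t{j % n_tracks_per_class}" for j in range(n_per_class)
        ]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestSplit:
    def test_80_20_row_counts(self, rng):
        table = _table(rng, 100)
        train, test = split_train_test(table, ClassifierConfig(random_seed=1))
        assert len(train) == 400 and len(test) == 100

    def test_track_unit_no_id_overlap(self, rng):
        table = _table(rng, 100)
        cfg = ClassifierConfig(split_unit="track", random_seed=1)
        train, test = split_train_test(table, cfg)
        assert set(train["track_id"]).isdisjoint(set(test["track_id"]))
        assert len(train) + len(test) == len(table)

    def test_same_seed_identical_partition(self, rng):
        table = _table(rng, 60)
        cfg = ClassifierConfig(random_seed=9)
        t1, s1 = split_train_test(table, cfg)
        t2, s2 = split_train_test(table, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        table = _table(rng, 50)
        table[LABEL] = 0
        with pytest.raises(TrackDataError):
            split_train_test(table, ClassifierConfig())


class TestSmote:
    def test_counts_equalized(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(5, 1, (40, 3))])
        y = np.array([0] * 100 + [1] * 40)
        Xo, yo = smote_oversample(X, y, seed=2)
        assert dict(zip(*np.unique(yo, return_counts=True))) == {0: 100, 1: 100}

    def test_synthetic_point_on_parent_segment(self, rng):
        # two-sample minority class: every synthetic point must lie on the
        # segment between the only possible parent pair
        X = np.vstack([rng.normal(0, 1, (10, 2)), [[0.0, 0.0], [1.0, 2.0]]])
        y = np.array([0] * 10 + [1] * 2)
        Xo, yo = smote_oversample(X, y, k_neighbors=5, seed=0)
        synth = Xo[12:][yo[12:] == 1]
        assert len(synth) == 8
        p, q = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        for s in synth:
            lam = np.dot(s - p, q - p) / np.dot(q - p, q - p)
            assert -1e-9 <= lam <= 1 + 1e-9
            np.testing.assert_allclose(s, p + lam * (q - p), atol=1e-9)

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.repeat([0, 1, 2], 20)
        Xo, yo = smote_oversample(X, y, seed=3)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_singleton_class_duplicated_with_warning(self, rng, caplog):
        X = np.vstack([rng.normal(0, 1, (5, 2)), [[9.0, 9.0]]])
        y = np.array([0] * 5 + [1])
        with caplog.at_level("WARNING"):
            Xo, yo = smote_oversample(X, y, seed=0)
        assert (yo == 1).sum() == 5
        np.testing.assert_array_equal(Xo[yo == 1], np.tile([9.0, 9.0], (5, 1)))

    def test_test_partition_untouched(self, rng):
        table = _table(rng, 80)
        # unbalance the classes
        table = table[~((table[LABEL] == 200) & (table.index % 3 == 0))]
        cfg = ClassifierConfig(random_seed=4)
        train, test = split_train_test(table, cfg)
        before = _digest(test)
        smote_oversample(train[FEATURES].to_numpy(), train[LABEL].to_numpy(), seed=4)
        assert _digest(test) == before


class TestForest:
    def test_unanimous_prediction(self, rng):
        table = _table(rng, 100, separation=50.0)
        cfg = ClassifierConfig(random_seed=0)
        forest = train_forest(table[FEATURES].to_numpy(), table[LABEL].to_numpy(), cfg)
        proba = forest.predict_proba(np.full((1, 5), 0.0))
        assert proba[0, 0] == 1.0  # all 30 trees vote class 0

    def test_separable_clouds_high_accuracy(self, rng):
        table = _table(rng, 500)
        report = run_classifier(table, ClassifierConfig(random_seed=0))
        assert report.accuracy >= 0.95

    def test_label_permutation_chance_accuracy(self, rng):
        table = _table(rng, 300)
        table[LABEL] = rng.permutation(table[LABEL].to_numpy())
        report = run_classifier(table, ClassifierConfig(random_seed=0))
        # binomial CI around 0.2 with n = 300 test rows
        n_test = report.n_test
        half_width = 4 * np.sqrt(0.2 * 0.8 / n_test)
        assert abs(report.accuracy - 0.2) < half_width

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(50, 5))
        with pytest.raises(TrackDataError):
            train_forest(X, np.zeros(50), ClassifierConfig())


class TestImportances:
    def test_sum_to_one(self, rng):
        table = _table(rng, 200)
        report = run_classifier(table, ClassifierConfig(random_seed=0))
        assert sum(report.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in report.importances.values())

    def test_uninformative_features_near_uniform(self, rng):
        X = rng.normal(size=(2000, 5))
        y = rng.integers(0, 2, 2000) * 50
        cfg = ClassifierConfig(n_trees=50, random_seed=0)
        forest = train_forest(X, y, cfg)
        imp = np.array(list(feature_importance(forest).values()))
        assert np.all(np.abs(imp - 0.2) < 0.1)

    def test_single_informative_feature_dominates(self, rng):
        X = rng.normal(size=(1500, 5))
        y = (X[:, 0] > 0).astype(int) * 50
        forest = train_forest(X, y, ClassifierConfig(random_seed=0))
        assert feature_importance(forest)["speed_mps"] > 0.9


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        table = _table(rng, 200, separation=50.0)
        report = run_classifier(table, ClassifierConfig(random_seed=0))
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(np.diag(report.confusion), report.confusion.sum(axis=1))
        for c in CODES:
            assert report.f1[c] == 1.0
            assert report.auc[c] == 1.0

    def test_confusion_row_sums_equal_test_counts(self, rng):
        table = _table(rng, 150, separation=1.0)
        cfg = ClassifierConfig(random_seed=2)
        report = run_classifier(table, cfg)
        _, test = split_train_test(table, cfg)
        counts = test.groupby(LABEL).size()
        for i, c in enumerate(report.classes):
            assert report.confusion[i].sum() == counts[c]

    def test_hand_built_two_class_confusion(self):
        """TP=3, FP=1, FN=2, TN=4 gives precision 0.75 and recall 0.6."""
        from sklearn.ensemble import RandomForestClassifier

        forest = RandomForestClassifier(n_estimators=1, random_state=0)
        # craft train/test so the tree reproduces the desired confusion
        X_tr = np.array([[0.0], [1.0]])
        forest.fit(X_tr, [0, 1])
        # class 1 is "positive": 3 TP, 1 FP, 2 FN, 4 TN
        X_te = np.array([[1.0]] * 3 + [[1.0]] + [[0.0]] * 2 + [[0.0]] * 4)
        y_te = np.array([1] * 3 + [0] + [1] * 2 + [0] * 4)
        rep = evaluate(forest, X_te, y_te, ClassifierConfig(), feature_names=["f"])
        assert rep.precision[1] == pytest.approx(0.75)
        assert rep.recall[1] == pytest.approx(0.6)

    def test_random_scores_auc_near_half(self, rng):
        X = rng.normal(size=(3000, 5))
        y = rng.integers(0, 2, 3000) * 50
        table = pd.DataFrame(X, columns=FEATURES)
        table[LABEL] = y
        table["track_id"] = np.arange(len(table))
        report = run_classifier(table, ClassifierConfig(random_seed=1))
        for c in (0, 50):
            assert report.auc[c] == pytest.approx(0.5, abs=0.08)

    def test_absent_test_class_flagged_not_zero_filled(self, rng):
        table = _table(rng, 100, separation=50.0)
        cfg = ClassifierConfig(random_seed=0)
        train, test = split_train_test(table, cfg)
        forest = train_forest(train[FEATURES].to_numpy(), train[LABEL].to_numpy(), cfg)
        test2 = test[test[LABEL] != 200]
        rep = evaluate(forest, test2[FEATURES].to_numpy(), test2[LABEL].to_numpy(), cfg)
        assert 200 in rep.undefined_classes
        assert np.isnan(rep.recall[200]) and np.isnan(rep.auc[200])

    def test_fixed_seed_byte_identical_report(self, rng):
        table = _table(rng, 150)
        r1 = run_classifier(table, ClassifierConfig(random_seed=5))
        r2 = run_classifier(table, ClassifierConfig(random_seed=5))
        assert r1.to_json() == r2.to_json()


def test_generated_swarms_beat_chance_with_spatial_signal():
    """Groups generated with the study's qualitative structure (male-rich:
    compact and slow; female-rich: loose and fast) are classified far above
    chance, with spatial features among the top importances."""
    from swarmkin import apply_filters, build_feature_table, generate_study

    tracks, _ = generate_study(
        np.random.default_rng(17),
        tracks_by_group={c: 5 for c in (0, 50, 100, 150, 200)},
        n_noise_tracks=0,
        n_replicates=1,
        track_duration_range=(27.0, 29.0),
    )
    table = build_feature_table(apply_filters(tracks))
    report = run_classifier(table, ClassifierConfig(random_seed=0))
    assert report.accuracy > 0.5  # chance is 0.2 for five classes
    spatial = {"x_cm", "y_cm", "z_cm", "d_cm"}
    top3 = sorted(report.importances, key=report.importances.get, reverse=True)[:3]
    assert len(spatial & set(top3)) >= 2
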