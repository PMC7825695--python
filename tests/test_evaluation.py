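"""Hyperparameter grid, AUC/PRAUC kernels, repeated CV, ROC averaging,
and the negative-control path."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_auc
from radsig.evaluation import (
    HyperGrid,
    build_grid,
    compute_auc,
    compute_prauc,
    cross_validate,
    average_roc,
    fit_gbm,
    negative_control,
)
from radsig.selection import SelectionConfig
from radsig.synthetic import TableSpec, generate_feature_table


class TestGrid:
    def test_default_grid_size(self):
        grid = build_grid()
        assert len(grid) == 8 * 4 * 3 * 3 * 3 * 3 == 2592
        assert len({tuple(sorted(g.items())) for g in grid}) == 2592

    def test_level_counts(self):
        g = HyperGrid()
        assert tuple(
            len(x)
            for x in (g.n_top_features, g.n_trees, g.shrinkage,
                      g.interaction_depth, g.min_node_size, g.bag_fraction)
        ) == (8, 4, 3, 3, 3, 3)

    def test_singleton_grid(self):
        g = HyperGrid(n_top_features=(5,), n_trees=(100,), shrinkage=(0.1,),
                      interaction_depth=(2,), min_node_size=(5,), bag_fraction=(1.0,))
        assert len(build_grid(g)) == 1

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="n_trees"):
            build_grid(HyperGrid(n_trees=()))


class TestAUC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0], 1.0),
            ([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0], 0.75),  # 3 of 4 pairs concordant
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),  # all ties
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert compute_auc(np.array(scores), np.array(labels)) == expected

    def test_exact_pair_counting_on_random_cases(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = int(rng.integers(4, 16))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert compute_auc(scores, labels) == pytest.approx(
                oracle_auc(scores, labels), abs=1e-14
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestPRAUC:
    def test_perfect_ranking(self):
        assert compute_prauc(np.array([0.9, 0.8, 0.2, 0.1]),
                             np.array([1, 1, 0, 0])) == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        assert compute_prauc(np.full(10, 0.3), labels) == pytest.approx(0.2)

    def test_hand_enumerated_four_samples(self):
        # descending scores: 0.9(+), 0.8(-), 0.2(+), 0.1(-)
        # recall steps at the positives: P=1 at R=1/2, P=2/3 at R=1
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        got = compute_prauc(np.array([0.9, 0.2, 0.8, 0.1]), np.array([1, 1, 0, 0]))
        assert got == pytest.approx(expected)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_prauc(np.array([0.1, 0.2]), np.array([0, 0]))


class TestFitGBM:
    def test_separable_data_high_training_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 1))
        y = (X[:, 0] > 0).astype(int)
        model = fit_gbm(X, y, {"n_trees": 50, "shrinkage": 0.3}, seed=0)
        assert compute_auc(model.predict_proba(X), y) > 0.99

    def test_refit_same_seed_identical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = {"n_trees": 60, "bag_fraction": 0.6}
        p1 = fit_gbm(X, y, s, seed=9).predict_proba(X)
        p2 = fit_gbm(X, y, s, seed=9).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_gbm(np.zeros((5, 2)), np.ones(5), {})

    def test_null_features_near_chance_on_heldout(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(30):
            X = rng.normal(size=(60, 3))
            y = np.array([0, 1] * 30)
            model = fit_gbm(X[:40], y[:40], {"n_trees": 40}, seed=0)
            aucs.append(compute_auc(model.predict_proba(X[40:]), y[40:]))
        assert abs(np.mean(aucs) - 0.5) < 0.07


@pytest.fixture(scope="module")
def planted_table():
    return generate_feature_table(
        TableSpec(n_patients=60, n_features=40, n_informative=3,
                  effect=1.5, prevalence=0.45, seed=21)
    )


class TestCrossValidate:
    def test_record_count_is_rounds_times_folds(self, planted_table):
        t = planted_table
        ranked = list(t.informative) + list(t.features.columns[:7])
        res = cross_validate(t.features, t.labels("statin"), ranked[:10],
                             rounds=4, folds=3, seed=0, search_budget=4)
        assert len(res.records) == 12
        assert res.records["auc"].between(0, 1).all()
        assert res.records["prauc"].between(0, 1).all()

    def test_deterministic(self, planted_table):
        t = planted_table
        ranked = list(t.informative) + list(t.features.columns[:7])
        kw = dict(rounds=2, folds=3, seed=5, search_budget=4)
        a = cross_validate(t.features, t.labels("statin"), ranked[:10], **kw)
        b = cross_validate(t.features, t.labels("statin"), ranked[:10], **kw)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_planted_signal_beats_chance(self, planted_table):
        t = planted_table
        ranked = list(t.informative) + list(t.features.columns[:7])
        res = cross_validate(t.features, t.labels("statin"), ranked[:10],
                             rounds=10, folds=3, seed=1, search_budget=6)
        assert res.auc_mean > 0.65

    def test_too_few_positives_for_folds_rejected(self):
        synth = generate_feature_table(
            TableSpec(n_patients=20, n_features=12, n_informative=2,
                      effect=1.0, prevalence=2, seed=0)
        )
        with pytest.raises(ValueError, match="per class"):
            cross_validate(synth.features, synth.labels("statin"),
                           list(synth.features.columns[:10]), rounds=1, folds=3)

    def test_permuted_labels_near_chance(self, planted_table):
        """Leakage guard: evaluating with labels permuted independently of
        the features yields mean AUC within 0.05 of 0.5."""
        t = planted_table
        rng = np.random.default_rng(17)
        y_perm = rng.permutation(np.asarray(t.labels("statin")))
        ranked = list(t.features.columns[:10])
        res = cross_validate(t.features, y_perm, ranked,
                             rounds=34, folds=3, seed=3, search_budget=4)
        assert len(res.records) == 102
        assert abs(res.auc_mean - 0.5) < 0.05

    def test_summary_matches_records(self, planted_table):
        t = planted_table
        ranked = list(t.features.columns[:10])
        res = cross_validate(t.features, t.labels("statin"), ranked,
                             rounds=3, folds=3, seed=2, search_budget=4)
        s = res.summary_dict()
        assert s["auc_mean"] == pytest.approx(res.records["auc"].mean())
        assert s["auc_sd"] == pytest.approx(res.records["auc"].std(ddof=1))
        assert s["n_tests"] == 9


class TestAverageROC:
    def test_perfect_test_hits_corner(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        fpr, tpr = average_roc([(scores, labels)])
        assert tpr[0] == 0.0 and tpr[-1] == 1.0
        assert np.interp(0.01, fpr, tpr) == 1.0  # hugs (0, 1)
        assert np.trapezoid(tpr, fpr) == pytest.approx(1.0, abs=0.01)

    def test_idempotent_averaging(self):
        rng = np.random.default_rng(4)
        scores, labels = rng.random(20), rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        single = average_roc([(scores, labels)])
        double = average_roc([(scores, labels), (scores, labels)])
        np.testing.assert_allclose(single[1], double[1])

    def test_pointwise_mean_of_two_toy_curves(self):
        perfect = (np.array([0.9, 0.1]), np.array([1, 0]))
        inverted = (np.array([0.1, 0.9]), np.array([1, 0]))
        fpr, tpr = average_roc([perfect, inverted])
        t1 = average_roc([perfect])[1]
        t2 = average_roc([inverted])[1]
        np.testing.assert_allclose(tpr, (t1 + t2) / 2)

    def test_monotone(self):
        rng = np.random.default_rng(5)
        tests = []
        for _ in range(5):
            s, l = rng.random(30), rng.integers(0, 2, 30)
            l[:2] = [0, 1]
            tests.append((s, l))
        _, tpr = average_roc(tests)
        assert np.all(np.diff(tpr) >= -1e-12)


class TestNegativeControl:
    def test_positive_control_label_equals_feature_threshold(self, planted_table):
        t = planted_table
        y = (t.features.iloc[:, 0] > t.features.iloc[:, 0].median()).astype(int)
        sel_cfg = SelectionConfig(rounds=3, seed=0)
        _, val = negative_control(t.features, y, selection_config=sel_cfg,
                                  rounds=3, seed=0, search_budget=4)
        assert val.auc_mean > 0.9

    def test_degenerate_prevalence_rejected(self, planted_table):
        t = planted_table
        with pytest.raises(ValueError, match="both classes"):
            negative_control(t.features, np.zeros(len(t.features)), rounds=2)
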