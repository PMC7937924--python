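import copy

import numpy as np
import pandas as pd
import pytest

from stabmark import stability_cv as scv
from stabmark.io_config import RunConfig


def labels_series(n_pos, n_neg):
    ids = [f"P{i:03d}" for i in range(n_pos + n_neg)]
    vals = ["complicated"] * n_pos + ["uncomplicated"] * n_neg
    return pd.Series(vals, index=ids)


class TestFoldPlans:
    def test_fifty_plans(self):
        plans = scv.make_fold_plans(labels_series(52, 176), K=5, R=10, seed=0)
        assert len(plans) == 50

    def test_each_sample_in_r_test_sets(self):
        labels = labels_series(20, 60)
        plans = scv.make_fold_plans(labels, K=5, R=10, seed=1)
        counts = {}
        for plan in plans:
            for sid in plan.test_ids:
                counts[sid] = counts.get(sid, 0) + 1
        assert set(counts.values()) == {10}

    def test_test_sets_partition_each_repeat(self):
        labels = labels_series(12, 48)
        plans = scv.make_fold_plans(labels, K=5, R=3, seed=2)
        for r in (1, 2, 3):
            test_ids = [sid for p in plans if p.repeat == r for sid in p.test_ids]
            assert sorted(test_ids) == sorted(labels.index)

    def test_stratification_52_of_228(self):
        labels = labels_series(52, 176)
        plans = scv.make_fold_plans(labels, K=5, R=10, seed=3)
        for plan in plans:
            n_pos = sum(labels[s] == "complicated" for s in plan.test_ids)
            assert n_pos in (10, 11)

    def test_deterministic(self):
        a = scv.make_fold_plans(labels_series(10, 30), seed=9)
        b = scv.make_fold_plans(labels_series(10, 30), seed=9)
        assert a == b

    def test_train_test_disjoint(self):
        for plan in scv.make_fold_plans(labels_series(10, 30), K=4, R=2, seed=5):
            assert not set(plan.train_ids) & set(plan.test_ids)


class TestGridExpansion:
    def test_preserves_insertion_order(self):
        grid = {"b": [1, 2], "a": [3]}
        out = scv.expand_grid(grid)
        assert out == [{"b": 1, "a": 3}, {"b": 2, "a": 3}]

    def test_empty_grid(self):
        assert scv.expand_grid({}) == [{}]


class TestTuning:
    @pytest.fixture()
    def data(self, rng):
        X = np.vstack([rng.normal(1, 1, (25, 3)), rng.normal(-1, 1, (25, 3))])
        y = np.array([True] * 25 + [False] * 25)
        return X, y

    def test_single_point_grid(self, data):
        X, y = data
        params, results = scv.tune_hyperparameters(
            X, y, "extra_trees", {"n_estimators": [13]}, inner_cv=3, seed=0
        )
        assert params == {"n_estimators": 13}
        assert len(results) == 1

    def test_duplicated_rows_first_wins(self, data):
        X, y = data
        params, results = scv.tune_hyperparameters(
            X, y, "extra_trees", {"n_estimators": [20, 20]}, inner_cv=3, seed=0
        )
        assert results[0]["mean_auroc"] == results[1]["mean_auroc"]
        assert params == results[0]["params"]

    def test_deterministic(self, data):
        X, y = data
        a = scv.tune_hyperparameters(X, y, "logit", {"C": [0.1, 1.0]}, inner_cv=3, seed=4)
        b = scv.tune_hyperparameters(X, y, "logit", {"C": [0.1, 1.0]}, inner_cv=3, seed=4)
        assert a == b


class TestStabilitySummary:
    def test_score_formula(self):
        rep = scv.summarize_stability({"RETN": 50, "OLAH": 42, "X": 0}, R=10, K=5)
        scores = rep.scores.set_index("feature")["normalized_score"]
        assert scores["RETN"] == 100.0
        assert scores["OLAH"] == 84.0
        assert scores["X"] == 0.0

    def test_zero_count_excluded_from_shortlist(self):
        rep = scv.summarize_stability({"a": 0, "b": 40}, R=10, K=5, threshold_pct=60)
        assert rep.shortlist == ["b"]

    def test_scores_bounded(self):
        rep = scv.summarize_stability({"a": 50}, R=10, K=5)
        assert rep.scores["normalized_score"].between(0, 100).all()


@pytest.fixture(scope="module")
def tiny_discovery(small_discovery_inputs):
    mat, pheno, truth, config = small_discovery_inputs
    cv, stab = scv.run_discovery(mat, pheno, config)
    return cv, stab, truth, config


@pytest.fixture(scope="module")
def small_discovery_inputs():
    from stabmark import preprocess, synthetic_data as sd

    spec = sd.SyntheticSpec(
        n_samples=60, prevalence=14 / 60, n_genes=120, n_strong=4, n_weak=4, seed=23
    )
    mat, pheno, truth = sd.generate_cohort(spec)
    adj = preprocess.combat_adjust(
        mat, pheno["batch"].to_numpy(), covariates=pheno["outcome"].to_numpy()
    )
    config = RunConfig(
        seed=2, n_repeats=1, rfe_target=8, rf_trees=80, mrmr_k=8,
        lasso_cs=[0.1, 1.0], grids={"brf": {"n_estimators": [40]}},
    )
    return adj, pheno, truth, config


class TestRunDiscovery:
    def test_iteration_count(self, tiny_discovery):
        cv, stab, _, config = tiny_discovery
        assert len(cv.iterations) == config.n_folds * config.n_repeats
        assert stab.n_iterations == config.n_folds * config.n_repeats

    def test_counts_sum_to_rfe_output_sizes(self, tiny_discovery):
        cv, stab, _, _ = tiny_discovery
        total_selected = sum(it["n_selected"] for it in cv.iterations)
        assert stab.scores["times_selected"].sum() == total_selected

    def test_planted_genes_recovered(self, tiny_discovery):
        cv, stab, truth, _ = tiny_discovery
        scores = stab.scores.set_index("feature")["normalized_score"]
        for g in truth.strong_genes:
            assert scores.get(g, 0.0) >= 80.0
        assert cv.summary["auroc"]["mean"] >= 0.8

    def test_deterministic_reruns(self, small_discovery_inputs):
        mat, pheno, _, config = small_discovery_inputs
        cv1, stab1 = scv.run_discovery(mat, pheno, copy.deepcopy(config))
        cv2, stab2 = scv.run_discovery(mat, pheno, copy.deepcopy(config))
        assert cv1.iterations == cv2.iterations
        assert stab1.scores.equals(stab2.scores)

    def test_single_class_training_fold_aborts(self, small_discovery_inputs):
        mat, pheno, _, config = small_discovery_inputs
        plan = scv.FoldPlan(
            repeat=1, fold=1,
            train_ids=list(pheno.loc[pheno["outcome"] == "uncomplicated", "sample_id"][:20]),
            test_ids=list(pheno["sample_id"][:5]),
        )
        with pytest.raises(RuntimeError, match="single class"):
            scv.fit_fold(mat, pheno, plan, config)


class TestLeakageGuard:
    def test_poisoned_test_labels_leave_model_unchanged(self, small_discovery_inputs):
        mat, pheno, _, config = small_discovery_inputs
        labels = pheno.set_index("sample_id")["outcome"]
        plan = scv.make_fold_plans(labels, K=5, R=1, seed=config.seed)[0]

        poisoned = pheno.copy()
        flip = poisoned["sample_id"].isin(plan.test_ids)
        poisoned.loc[flip, "outcome"] = np.where(
            poisoned.loc[flip, "outcome"] == "complicated", "uncomplicated", "complicated"
        )

        fm_clean = scv.fit_fold(mat, pheno, plan, config)
        fm_poisoned = scv.fit_fold(mat, poisoned, plan, config)

        assert fm_clean.features == fm_poisoned.features
        assert fm_clean.params == fm_poisoned.params
        X_test = mat.to_frame().T.loc[plan.test_ids, [f for f in fm_clean.features
                                                      if f in mat.gene_ids]]
        # score on gene features only (clinical column unaffected by outcome poisoning)
        from stabmark.stability_cv import _feature_frame

        Xf = _feature_frame(mat, pheno, config.clinical_features)
        a = fm_clean.model.predict_proba(Xf.loc[plan.test_ids, fm_clean.features].to_numpy())
        b = fm_poisoned.model.predict_proba(
            Xf.loc[plan.test_ids, fm_poisoned.features].to_numpy()
        )
        np.testing.assert_array_equal(a, b)


def test_cv_report_serialization(tiny_discovery, tmp_path):
    cv, stab, _, _ = tiny_discovery
    cv.to_json(tmp_path / "cv.json")
    table = cv.to_table()
    assert "sampler_classifier" in table.columns
    assert (tmp_path / "cv.json").exists()
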