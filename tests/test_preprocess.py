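import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stabmark import preprocess as pp
from stabmark import synthetic_data as sd
from stabmark.io_config import ExpressionMatrix


def em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, samples)


class TestQuantileNormalize:
    def test_two_columns_by_hand(self):
        # sorted columns [1,2,3] and [4,5,6] -> mean order statistics [2.5,3.5,4.5]
        mat = em(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = pp.quantile_normalize(mat)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        mat = em(np.column_stack([col, col]))
        out = pp.quantile_normalize(mat)
        np.testing.assert_allclose(out.values, mat.values)

    def test_rank_based_respects_row_order(self):
        # permuting the rows of one column permutes its output identically
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 40.0, 20.0, 30.0])
        out = pp.quantile_normalize(em(np.column_stack([a, b])))
        ref = np.sort(out.values[:, 1])
        expected_b = ref[stats.rankdata(b).astype(int) - 1]
        np.testing.assert_allclose(out.values[:, 1], expected_b)

    def test_tie_handling_averages_reference(self):
        mat = em(np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0]]))
        out = pp.quantile_normalize(mat)
        ref = np.sort(mat.values, axis=0).mean(axis=1)
        assert out.values[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.values[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_idempotent(self, rng):
        mat = em(rng.normal(size=(40, 6)))
        once = pp.quantile_normalize(mat)
        twice = pp.quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_single_sample_identity_with_warning(self):
        mat = em(np.array([[1.0], [2.0]]))
        with pytest.warns(UserWarning):
            out = pp.quantile_normalize(mat)
        np.testing.assert_array_equal(out.values, mat.values)


class TestSurrogates:
    def test_planted_batch_detected(self):
        spec = sd.SyntheticSpec(n_samples=80, n_genes=300, n_strong=3, n_weak=0, seed=17)
        mat, pheno, _ = sd.generate_cohort(spec)
        sv = pp.estimate_surrogates(
            mat, pheno["outcome"].to_numpy(), k=2, batch=pheno["batch"].to_numpy()
        )
        assert sv.association_stats["p_value"].min() < 0.01

    def test_null_association_uniform(self):
        # no batch effect planted: ANOVA p of component 1 vs a random batch ~ U[0,1]
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 24))
            y = np.array(["a", "b"] * 12)
            batch = np.array(["x"] * 12 + ["y"] * 12)
            mat = em(X)
            sv = pp.estimate_surrogates(mat, y, k=1, batch=batch)
            pvals.append(sv.association_stats["p_value"].iloc[0])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_components_orthonormal(self, small_cohort):
        mat, pheno, _ = small_cohort
        sv = pp.estimate_surrogates(mat, pheno["outcome"].to_numpy(), k=3)
        gram = sv.components.T @ sv.components
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_rank_limits_nonzero_singular_values(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 12))  # rank 2
        y = np.array(["a"] * 6 + ["b"] * 6)
        sv = pp.estimate_surrogates(em(base), y, k=5)
        assert np.sum(sv.singular_values > 1e-8) <= 2

    def test_k_validation(self, small_cohort):
        mat, pheno, _ = small_cohort
        with pytest.raises(ValueError):
            pp.estimate_surrogates(mat, pheno["outcome"].to_numpy(), k=0)
        with pytest.raises(ValueError):
            pp.estimate_surrogates(mat, pheno["outcome"].to_numpy(), k=mat.n_samples)


class TestCombat:
    def test_planted_shift_removed(self):
        # per-gene additive shifts ~ N(0, 0.5) between two batches
        rng = np.random.default_rng(5)
        n_genes, n = 500, 200
        batch = np.array(["b1"] * 100 + ["b2"] * 100)
        y = np.tile(["c", "u"], 100)
        gamma = rng.normal(0, 0.5, size=n_genes)
        X = rng.normal(7, 0.5, size=(n_genes, n)) + gamma[:, None] * (batch == "b2")
        out = pp.combat_adjust(em(X), batch, covariates=y)
        pre = X[:, batch == "b1"].mean(axis=1) - X[:, batch == "b2"].mean(axis=1)
        diff = out.values[:, batch == "b1"].mean(axis=1) - out.values[:, batch == "b2"].mean(axis=1)
        assert np.mean(np.abs(diff) < 0.05) >= 0.95
        assert np.abs(diff).mean() < np.abs(pre).mean()

    def test_single_batch_identity(self, small_cohort):
        mat, pheno, _ = small_cohort
        out = pp.combat_adjust(mat, np.array(["one"] * mat.n_samples))
        np.testing.assert_array_equal(out.values, mat.values)

    def test_confounded_design_refused(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        batch = np.array(["b1"] * 5 + ["b2"] * 5)
        y = np.array(["c"] * 5 + ["u"] * 5)  # each batch one class
        with pytest.raises(ValueError, match="confounded"):
            pp.combat_adjust(em(X), batch, covariates=y)

    def test_singleton_batch_named(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        batch = np.array(["b1", "b1", "b1", "b1", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            pp.combat_adjust(em(X), batch)

    def test_global_mean_preserved_balanced(self):
        rng = np.random.default_rng(7)
        X = rng.normal(7, 1, size=(100, 40)) + np.where(np.arange(40) < 20, 0.0, 1.5)
        batch = np.array(["b1"] * 20 + ["b2"] * 20)
        out = pp.combat_adjust(em(X), batch)
        assert abs(out.values.mean() - X.mean()) < 1e-6


class TestCollapseProbes:
    def test_mean_of_probes(self):
        mat = em(np.array([[2.0, 4.0], [4.0, 6.0]]), genes=["p1", "p2"])
        mapping = pd.DataFrame({"probe": ["p1", "p2"], "symbol": ["geneA", "geneA"]})
        out = pp.collapse_probes(mat, mapping)
        assert out.gene_ids == ["geneA"]
        np.testing.assert_allclose(out.values[0], [3.0, 5.0])

    def test_one_to_one_renames(self):
        mat = em(np.array([[1.0, 2.0], [3.0, 4.0]]), genes=["p1", "p2"])
        mapping = pd.DataFrame({"probe": ["p1", "p2"], "symbol": ["A", "B"]})
        out = pp.collapse_probes(mat, mapping)
        assert out.gene_ids == ["A", "B"]
        np.testing.assert_array_equal(out.values, mat.values)

    def test_probe_mapped_to_two_genes(self):
        mat = em(np.array([[1.0], [5.0], [9.0]]), genes=["p1", "p2", "p3"])
        mapping = pd.DataFrame(
            {"probe": ["p1", "p1", "p2"], "symbol": ["A", "B", "B"]}
        )
        out = pp.collapse_probes(mat, mapping)
        frame = out.to_frame()
        assert frame.loc["A"].iloc[0] == 1.0
        assert frame.loc["B"].iloc[0] == 3.0  # mean of p1=1 and p2=5

    def test_row_count_equals_distinct_symbols(self, small_cohort, rng):
        mat, _, _ = small_cohort
        symbols = [f"SYM{i % 40}" for i in range(mat.n_genes)]
        mapping = pd.DataFrame({"probe": mat.gene_ids, "symbol": symbols})
        out = pp.collapse_probes(mat, mapping)
        assert out.n_genes == 40

    def test_empty_intersection_errors(self):
        mat = em(np.zeros((2, 2)), genes=["p1", "p2"])
        mapping = pd.DataFrame({"probe": ["q1"], "symbol": ["A"]})
        with pytest.raises(ValueError, match="no probes"):
            pp.collapse_probes(mat, mapping)

    def test_blank_symbols_dropped(self):
        mat = em(np.array([[1.0], [2.0]]), genes=["p1", "p2"])
        mapping = pd.DataFrame({"probe": ["p1", "p2"], "symbol": ["A", "  "]})
        out = pp.collapse_probes(mat, mapping)
        assert out.gene_ids == ["A"]
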