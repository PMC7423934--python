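import numpy as np
import pandas as pd
import pytest

from lepinet import (
    LepinetError,
    ModuleSpec,
    SimSpec,
    adjacency,
    aggregate_replicates,
    dynamic_tree_cut,
    eigen_protein,
    fit_coexpression,
    hclust_average,
    module_trait_correlation,
    normalize,
    pearson_matrix,
    simulate_counts,
    soft_threshold_fit,
    tom,
)
from lepinet.coexpression import scale_free_fit
from lepinet.preprocess import NormalizedMatrix
from lepinet.simulate import planted_module_ari, recovered_module_of


def _nm(values: np.ndarray, prefix: str = "p") -> NormalizedMatrix:
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return NormalizedMatrix(df - df.min().min() + 0.1, "none")


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        nm = _nm(np.array([[1.0, 2, 3], [2, 4, 6], [3, 2, 1]]))
        corr = pearson_matrix(nm)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(0)
        corr = pearson_matrix(_nm(rng.normal(size=(40, 1000))))
        off = corr.to_numpy()[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 0.01 and np.abs(off).max() < 0.2

    def test_zero_variance_rejected(self):
        nm = _nm(np.array([[1.0, 1, 1], [1, 2, 3]]))
        with pytest.raises(LepinetError, match="p0"):
            pearson_matrix(nm)


class TestAdjacency:
    @pytest.mark.parametrize(
        "r,mode,beta,expected",
        [
            (1.0, "signed", 10, 1.0),
            (-1.0, "signed", 10, 0.0),
            (0.8, "unsigned", 10, 0.8**10),
            (1.0, "dissim_literal", 10, 0.0),
        ],
    )
    def test_transforms(self, r, mode, beta, expected):
        corr = pd.DataFrame([[1.0, r], [r, 1.0]], index=list("ab"), columns=list("ab"))
        a = adjacency(corr, beta=beta, mode=mode)
        assert a.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert a.iloc[0, 0] == 1.0

    def test_unknown_mode(self):
        corr = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(LepinetError, match="mode"):
            adjacency(corr, mode="bogus")


class TestTOM:
    def test_complete_unit_graph_is_all_ones(self):
        a = pd.DataFrame(np.ones((5, 5)), index=list("abcde"), columns=list("abcde"))
        assert np.allclose(tom(a).to_numpy(), 1.0)

    def test_star_closed_form(self):
        a = pd.DataFrame(
            [[1, 0.5, 0.5], [0.5, 1, 0], [0.5, 0, 1]],
            index=list("abc"), columns=list("abc"),
        )
        t = tom(a)
        assert t.loc["a", "b"] == pytest.approx(0.5)

    def test_isolated_pair_zero(self):
        a = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        assert tom(a).loc["a", "b"] == 0.0

    def test_range_and_symmetry_on_random_adjacency(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (30, 30))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"p{i}" for i in range(30)]
        t = tom(pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
        assert np.allclose(t, t.T)
        assert t.min() >= 0 and t.max() <= 1

    def test_asymmetric_rejected(self):
        a = pd.DataFrame([[1, 0.2], [0.6, 1]], index=list("ab"), columns=list("ab"))
        with pytest.raises(LepinetError, match="symmetric"):
            tom(a)


class TestSoftThreshold:
    def test_power_law_degrees_fit_near_one(self):
        ks = []
        for k in range(1, 51):
            ks += [float(k)] * max(1, round(2000 * k**-2.0))
        r2, _ = scale_free_fit(np.array(ks))
        assert r2 >= 0.99

    def test_equal_connectivities_degenerate(self):
        r2, _ = scale_free_fit(np.full(30, 7.0))
        assert np.isnan(r2)

    def test_recommendation_on_modular_input(self):
        spec = SimSpec(seed=4, n_proteins=150,
                       modules=tuple(ModuleSpec(25, None, 0.9) for _ in range(4)))
        m, design, _ = simulate_counts(spec)
        nm = normalize(aggregate_replicates(m, "sum"), "log2_mor")
        from lepinet.coexpression import drop_zero_variance

        table = soft_threshold_fit(drop_zero_variance(nm)[0], powers=(2, 4, 6, 8, 10, 12))
        assert table["recommended"].sum() == 1
        rec = int(table.loc[table["recommended"], "power"].iloc[0])
        assert rec in (2, 4, 6, 8, 10, 12)


class TestTreeCut:
    @staticmethod
    def _pipeline_diss(x: np.ndarray) -> pd.DataFrame:
        nm = _nm(x)
        return 1.0 - tom(adjacency(pearson_matrix(nm), beta=10, mode="signed"))

    def test_three_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        blocks = [0.9 * rng.normal(0, 1, 14)[None, :] + 0.3 * rng.normal(0, 1, (30, 14))
                  for _ in range(3)]
        diss = self._pipeline_diss(np.vstack(blocks))
        labels = dynamic_tree_cut(hclust_average(diss), diss, deep_split=4, min_module_size=10)
        truth = np.repeat([1, 2, 3], 30)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_two_block_dendrogram_merges_within_blocks_first(self):
        rng = np.random.default_rng(8)
        x = np.vstack([
            np.tile(rng.normal(0, 1, 14), (5, 1)) + 1e-6 * rng.normal(0, 1, (5, 14)),
            np.tile(rng.normal(0, 1, 14), (5, 1)) + 1e-6 * rng.normal(0, 1, (5, 14)),
        ])
        diss = self._pipeline_diss(x)
        Z = hclust_average(diss)
        assert np.all(Z[:8, 2] < 0.01)  # 8 within-block merges come first

    def test_single_tight_cluster_one_module(self):
        rng = np.random.default_rng(5)
        x = 0.9 * rng.normal(0, 1, 14)[None, :] + 0.3 * rng.normal(0, 1, (40, 14))
        diss = self._pipeline_diss(x)
        labels = dynamic_tree_cut(hclust_average(diss), diss, deep_split=4, min_module_size=10)
        top = labels.value_counts()
        assert set(top.index) - {0} == {1}
        assert top[1] >= 0.9 * len(labels)

    def test_fewer_leaves_than_min_size_all_unassigned(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.2, 0.8, (5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = list("abcde")
        diss = pd.DataFrame(d, index=ids, columns=ids)
        labels = dynamic_tree_cut(hclust_average(diss), diss, min_module_size=10)
        assert (labels == 0).all()

    def test_determinism_with_duplicate_distances(self):
        m = pd.DataFrame(0.5, index=[f"q{i}" for i in range(20)], columns=[f"q{i}" for i in range(20)])
        np.fill_diagonal(m.values, 0)
        runs = [dynamic_tree_cut(hclust_average(m), m, min_module_size=10) for _ in range(2)]
        pd.testing.assert_series_equal(runs[0], runs[1])


class TestEigenProtein:
    def test_dominant_and_tied(self):
        ids = list("abcd")
        a = pd.DataFrame(0.1, index=ids, columns=ids)
        a.loc["a"] = 1.0
        a["a"] = 1.0
        np.fill_diagonal(a.values, 1.0)
        labels = pd.Series([1, 1, 1, 1], index=ids)
        assert eigen_protein(a, labels) == {1: "a"}

    def test_tie_broken_lexicographically(self):
        ids = list("xy")
        a = pd.DataFrame([[1, 0.4], [0.4, 1]], index=ids, columns=ids)
        labels = pd.Series([1, 1], index=ids)
        assert eigen_protein(a, labels) == {1: "x"}

    def test_singleton_module(self):
        a = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        labels = pd.Series([1, 0], index=list("ab"))
        assert eigen_protein(a, labels) == {1: "a"}


class TestModuleTrait:
    def test_profile_equal_to_trait(self, cohort_design):
        vals = pd.DataFrame(
            [cohort_design.trait_vectors["LPA"].astype(float)], index=["P0"]
        )
        nm = NormalizedMatrix(vals, "none")
        stats_ = module_trait_correlation(nm, {1: "P0"}, cohort_design)
        row = stats_[(stats_["module"] == 1) & (stats_["trait"] == "LPA")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-6

    def test_constant_profile_is_na(self, cohort_design):
        nm = NormalizedMatrix(
            pd.DataFrame([[1.0] * 14], index=["P0"], columns=cohort_design.sample_ids),
            "none",
        )
        stats_ = module_trait_correlation(nm, {1: "P0"}, cohort_design)
        assert stats_["r"].isna().all()


class TestEndToEnd:
    def test_pipeline_determinism(self):
        spec = SimSpec(seed=9, n_proteins=150, modules=(ModuleSpec(30, "LPA"),))
        m, design, _ = simulate_counts(spec)
        nm = normalize(aggregate_replicates(m, "sum"), "log2_mor")
        a = fit_coexpression(nm, design)
        b = fit_coexpression(nm, design)
        pd.testing.assert_series_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.trait_stats, b.trait_stats)

    def test_trait_linked_module_detected(self):
        spec = SimSpec(
            seed=21, n_proteins=500,
            modules=(ModuleSpec(30, "LPA", 0.9), ModuleSpec(30, None, 0.9)),
        )
        m, design, truth = simulate_counts(spec)
        nm = normalize(aggregate_replicates(m, "sum"), "log2_mor")
        model = fit_coexpression(nm, design)
        assert planted_module_ari(model.labels, truth) >= 0.8
        linked = recovered_module_of(model.labels, truth, 1)
        assert linked is not None
        ts = model.trait_stats
        row = ts[(ts["module"] == linked) & (ts["trait"] == "LPA")].iloc[0]
        assert abs(row["r"]) > 0.5 and row["bh_q"] < 0.05
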