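import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aabnet.networks import (
    build_network,
    compare_networks,
    correlation_matrix,
    family_correlogram,
    write_graphml,
)
from aabnet.simulate import PerturbationSpec, apply_perturbation, generate_cohort
from .conftest import make_table
from .test_simulate import two_analyte_truth


def naive_pairwise_corr(values: pd.DataFrame, method: str) -> pd.DataFrame:
    """O(n p^2) double-loop oracle with pairwise-complete deletion."""
    cols = list(values.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = values[[a, b]].dropna()
            if method == "spearman":
                r = stats.spearmanr(sub[a], sub[b]).statistic
            else:
                r = stats.pearsonr(sub[a], sub[b]).statistic
            out.loc[a, b] = out.loc[b, a] = r
    return out


class TestCorrelationMatrix:
    def test_rank_formula_example(self):
        # x=(1,2,3) vs y=(3,1,2): rho = 1 - 6*sum(d^2)/(n(n^2-1)) = -0.5
        table = make_table(np.array([[1, 3], [2, 1], [3, 2]], float), analytes=["x", "y"])
        corr = correlation_matrix(table, min_n=2)
        assert corr.values.loc["x", "y"] == pytest.approx(-0.5, abs=1e-12)

    def test_unit_diagonal_and_symmetry(self, rng):
        table = make_table(rng.lognormal(size=(30, 6)))
        corr = correlation_matrix(table)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_matches_double_loop_oracle(self, rng, method):
        values = rng.lognormal(size=(20, 8))
        values[rng.random((20, 8)) < 0.1] = np.nan
        table = make_table(values)
        corr = correlation_matrix(table, method=method, min_n=5)
        oracle = naive_pairwise_corr(table.values, method)
        mask = corr.values.notna()
        np.testing.assert_allclose(
            corr.values.values[mask.values], oracle.values[mask.values], atol=1e-12
        )

    def test_spearman_invariant_to_monotone_transform(self, rng):
        values = rng.lognormal(size=(40, 5))
        t1 = make_table(values)
        t2 = make_table(np.exp(values))
        c1 = correlation_matrix(t1).values
        c2 = correlation_matrix(t2).values
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_min_n_masks_sparse_pairs(self, rng):
        values = rng.lognormal(size=(15, 3))
        values[:10, 0] = np.nan  # only 5 complete pairs with column 0
        table = make_table(values)
        corr = correlation_matrix(table, min_n=10)
        assert np.isnan(corr.values.iloc[0, 1])
        assert corr.n_pairs.iloc[0, 1] == 5

    def test_too_few_subjects_rejected(self, rng):
        table = make_table(rng.lognormal(size=(5, 3)))
        with pytest.raises(ValueError, match="min_n"):
            correlation_matrix(table, min_n=10)


class TestBuildNetwork:
    def _corr(self, rho):
        table = make_table(np.random.default_rng(0).lognormal(size=(30, 3)))
        corr = correlation_matrix(table)
        v = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
        corr.values.iloc[:, :] = v
        return corr

    def test_strict_threshold_semantics(self):
        net = build_network(self._corr(0.61), threshold=0.6)
        assert frozenset(("A0", "A1")) in net.edges
        net = build_network(self._corr(0.59), threshold=0.6)
        assert not net.edges
        net = build_network(self._corr(0.60), threshold=0.6)
        assert not net.edges  # strictly greater, per the > 0.6 rule

    def test_complete_graph_edge_count(self):
        p = 5
        values = pd.DataFrame(np.ones((p, p)), index=[f"A{i}" for i in range(p)],
                              columns=[f"A{i}" for i in range(p)])
        corr = correlation_matrix(make_table(np.random.default_rng(1).lognormal(size=(20, p))))
        corr.values.iloc[:, :] = values.values
        net = build_network(corr, threshold=0.6)
        assert len(net.edges) == p * (p - 1) // 2

    def test_signed_subset_of_absolute(self, rng):
        values = rng.normal(size=(50, 6))
        values[:, 1] = -values[:, 0] + rng.normal(scale=0.3, size=50)
        corr = correlation_matrix(make_table(values + 10))
        signed = build_network(corr, threshold=0.4, rule="signed")
        absolute = build_network(corr, threshold=0.4, rule="absolute")
        assert signed.edges <= absolute.edges
        assert frozenset(("A0", "A1")) in absolute.edges - signed.edges

    def test_isolated_nodes_retained(self):
        net = build_network(self._corr(0.3), threshold=0.6)
        assert set(net.nodes) == {"A0", "A1", "A2"}

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_network(self._corr(0.5), threshold=1.0)

    def test_graphml_roundtrip(self, tmp_path):
        import networkx as nx

        net = build_network(self._corr(0.9), threshold=0.6)
        path = write_graphml(net, tmp_path / "net.graphml")
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert back.number_of_edges() == len(net.edges)


class TestFamilyCorrelogram:
    def test_single_member_family(self, rng):
        corr = correlation_matrix(make_table(rng.lognormal(size=(20, 3))))
        out = family_correlogram(corr, {"solo": ["A1"]})
        assert out["solo"].shape == (1, 1)
        assert out["solo"].iloc[0, 0] == 1.0

    def test_full_panel_family(self, rng):
        corr = correlation_matrix(make_table(rng.lognormal(size=(20, 4))))
        out = family_correlogram(corr, {"all": ["A0", "A1", "A2", "A3"]})
        pd.testing.assert_frame_equal(out["all"], corr.values)

    def test_unknown_member_rejected(self, rng):
        corr = correlation_matrix(make_table(rng.lognormal(size=(20, 3))))
        with pytest.raises(ValueError, match="unknown analyte"):
            family_correlogram(corr, {"bad": ["A0", "ZZ"]})

    def test_broken_pair_visible_in_family_block(self):
        truth = two_analyte_truth(lam=2.0, psi=1.0, transform="exponential")
        truth = apply_perturbation(
            truth, PerturbationSpec("D", "break_pair", ("A0", "A1"), 0.0)
        )
        table = generate_cohort(truth, {"HD": 800, "D": 800}, seed=8)
        fam = {"pair": ["A0", "A1"]}
        hd = family_correlogram(correlation_matrix(table.select_groups(["HD"])), fam)
        dd = family_correlogram(correlation_matrix(table.select_groups(["D"])), fam)
        assert hd["pair"].iloc[0, 1] > 0.6
        assert abs(dd["pair"].iloc[0, 1]) < 0.2


class TestCompareNetworks:
    def _net_from(self, rho_map, analytes=("A0", "A1", "A2")):
        table = make_table(np.random.default_rng(2).lognormal(size=(30, len(analytes))),
                           analytes=list(analytes))
        corr = correlation_matrix(table)
        corr.values.iloc[:, :] = np.eye(len(analytes))
        for (a, b), rho in rho_map.items():
            corr.values.loc[a, b] = corr.values.loc[b, a] = rho
        return build_network(corr, threshold=0.6)

    def test_identical_networks(self):
        a = self._net_from({("A0", "A1"): 0.9})
        b = self._net_from({("A0", "A1"): 0.9})
        res = compare_networks(a, b)
        assert res == {"jaccard": 1.0, "lost": [], "gained": []}

    def test_disjoint_edge_sets(self):
        a = self._net_from({("A0", "A1"): 0.9})
        b = self._net_from({("A1", "A2"): 0.9})
        res = compare_networks(a, b)
        assert res["jaccard"] == 0.0
        assert res["lost"] == [("A0", "A1")]
        assert res["gained"] == [("A1", "A2")]

    def test_both_empty_jaccard_one(self):
        a = self._net_from({})
        b = self._net_from({})
        assert compare_networks(a, b)["jaccard"] == 1.0

    def test_node_mismatch_rejected(self):
        a = self._net_from({})
        b = self._net_from({}, analytes=("A0", "A1", "A9"))
        with pytest.raises(ValueError, match="node set"):
            compare_networks(a, b)
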