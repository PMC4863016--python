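"""Node dating, cophenetic distances, and the mixed-trait Gower dissimilarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import assemblage as A
from assemblage.data import DataError

from conftest import random_trait_table


class TestBladj:
    def test_single_interior_node_halfway(self):
        t = A.read_tree("((T)v)root;")
        dated = A.bladj_date(t, {"root": 10.0})
        assert dated.ages["v"] == pytest.approx(5.0)

    def test_two_interior_nodes_evenly_spaced(self):
        t = A.read_tree("(((T)v)u)root;")
        dated = A.bladj_date(t, {"root": 10.0})
        assert dated.ages["u"] == pytest.approx(20.0 / 3.0)
        assert dated.ages["v"] == pytest.approx(10.0 / 3.0)

    def test_all_nodes_fixed_gives_exact_age_differences(self):
        t = A.read_tree("((A,B)n1,C)root;")
        dated = A.bladj_date(t, {"root": 3.0, "n1": 1.0})
        dm = A.cophenetic_distance(dated)
        assert dm[("A", "B")] == pytest.approx(2.0)
        assert dm[("A", "C")] == pytest.approx(6.0)

    def test_idempotent_on_fully_dated_tree(self):
        t = A.read_tree("(((A,B)n2,C)n1,D)root;")
        first = A.bladj_date(t, {"root": 8.0})
        again = A.bladj_date(first, {k: v for k, v in first.ages.items() if v > 0})
        for label, age in first.ages.items():
            assert again.ages[label] == pytest.approx(age)

    def test_inconsistent_fixed_ages_rejected(self):
        t = A.read_tree("(((A,B)n2,C)n1,D)root;")
        with pytest.raises(DataError):
            A.bladj_date(t, {"root": 5.0, "n1": 2.0, "n2": 3.0})

    def test_missing_root_age_rejected(self):
        t = A.read_tree("((A,B)n1,C)root;")
        with pytest.raises(DataError, match="root"):
            A.bladj_date(t, {"n1": 1.0})


def _graph_distance(ptree):
    """Independent oracle: all-pairs shortest path on the edge graph."""
    import networkx as nx

    g = nx.Graph()
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is not None:
            u = id(node.parent_node)
            v = id(node)
            g.add_edge(u, v, weight=node.edge.length)
    tips = {
        leaf.taxon.label: id(leaf) for leaf in ptree.tree.leaf_node_iter()
    }
    labels = sorted(tips)
    paths = dict(nx.all_pairs_dijkstra_path_length(g))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = paths[tips[labels[i]]][tips[labels[j]]]
    return labels, d


class TestCophenetic:
    def test_path_sum_example(self, small_tree):
        dm = A.cophenetic_distance(small_tree)
        assert dm[("A", "C")] == pytest.approx(4.0)

    def test_ultrametric_equals_twice_mrca_age(self):
        t = A.read_tree("((A,B)n1,C)root;")
        dated = A.bladj_date(t, {"root": 5.0, "n1": 3.0})
        dm = A.cophenetic_distance(dated)
        assert dm[("A", "B")] == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_graph_search_oracle(self, seed):
        t = A.simulate_tree(8, seed=seed, polytomy_fraction=0.2 if seed % 2 else 0.0)
        labels, expected = _graph_distance(t)
        dm = A.cophenetic_distance(t).filter(labels)
        np.testing.assert_allclose(dm.data, expected, atol=1e-12)

    def test_triangle_inequality(self, sim_phylo_dist):
        d = sim_phylo_dist.data
        n = d.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(n, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_ultrametric_inequality(self, sim_phylo_dist):
        d = sim_phylo_dist.data
        rng = np.random.default_rng(1)
        for _ in range(200):
            i, j, k = rng.choice(d.shape[0], 3, replace=False)
            a, b, c = sorted([d[i, j], d[i, k], d[j, k]])
            assert b == pytest.approx(c, abs=1e-9)

    def test_undated_tree_rejected(self):
        t = A.read_tree("((A,B),C);")
        with pytest.raises(DataError):
            A.cophenetic_distance(t)


def _gower_oracle(table: A.TraitTable, subset):
    """Naive per-pair reimplementation of the per-trait contribution rules."""
    taxa = table.taxa
    n = len(taxa)
    ranges, ranks, ties, ord_denom = {}, {}, {}, {}
    for trait in subset:
        kind = table.kinds[trait]
        col = table.data[trait]
        if kind == "quantitative":
            vals = col.astype(float)
            ranges[trait] = np.nanmax(vals) - np.nanmin(vals)
        elif kind == "ordinal":
            vals = col.astype(float).to_numpy()
            mask = ~np.isnan(vals)
            r = np.full(len(vals), np.nan)
            r[mask] = rankdata(vals[mask])
            ranks[trait] = r
            t = np.full(len(vals), np.nan)
            for v in np.unique(vals[mask]):
                t[mask & (vals == v)] = np.sum(vals[mask] == v)
            ties[trait] = t
            if mask.any() and np.nanmax(vals) > np.nanmin(vals):
                imax, imin = np.nanargmax(r), np.nanargmin(r)
                ord_denom[trait] = (
                    r[imax] - r[imin] - (t[imax] - 1) / 2 - (t[imin] - 1) / 2
                )
            else:
                ord_denom[trait] = 0.0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for trait in subset:
                kind = table.kinds[trait]
                xi, xj = table.data[trait].iloc[i], table.data[trait].iloc[j]
                if pd.isna(xi) or pd.isna(xj):
                    continue
                if kind == "nominal":
                    c = 0.0 if xi == xj else 1.0
                elif kind == "quantitative":
                    c = 0.0 if ranges[trait] == 0 else abs(xi - xj) / ranges[trait]
                else:
                    if xi == xj or ord_denom[trait] <= 0:
                        c = 0.0
                    else:
                        r, t = ranks[trait], ties[trait]
                        c = (
                            abs(r[i] - r[j]) - (t[i] - 1) / 2 - (t[j] - 1) / 2
                        ) / ord_denom[trait]
                        c = min(max(c, 0.0), 1.0)
                num += c
                den += 1.0
            d[i, j] = d[j, i] = num / den
    return d


class TestModifiedGower:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame({"a": ["x", "x"], "q": [1.0, 1.0]}, index=["T1", "T2"])
        tt = A.TraitTable(
            data=df,
            kinds=pd.Series({"a": "nominal", "q": "quantitative"}),
            groups=pd.Series({"a": "other", "q": "other"}),
        )
        with pytest.warns(UserWarning, match="zero range"):
            dm = A.modified_gower(tt)
        assert dm[("T1", "T2")] == 0.0

    def test_single_nominal_difference_is_one(self):
        df = pd.DataFrame({"a": ["x", "y"]}, index=["T1", "T2"])
        tt = A.TraitTable(
            data=df, kinds=pd.Series({"a": "nominal"}), groups=pd.Series({"a": "other"})
        )
        assert A.modified_gower(tt)[("T1", "T2")] == 1.0

    def test_mixed_pair_hand_arithmetic(self):
        # nominal differing (1) + quantitative half the range (0.5) -> 0.75
        df = pd.DataFrame(
            {"a": ["x", "y", "x"], "q": [0.0, 5.0, 10.0]}, index=["T1", "T2", "T3"]
        )
        tt = A.TraitTable(
            data=df,
            kinds=pd.Series({"a": "nominal", "q": "quantitative"}),
            groups=pd.Series({"a": "other", "q": "other"}),
        )
        dm = A.modified_gower(tt)
        assert dm[("T1", "T2")] == pytest.approx(0.75)
        assert dm[("T1", "T3")] == pytest.approx(0.5)

    def test_podani_ordinal_ties_hand_example(self):
        # values 1,1,2,3: ranks 1.5,1.5,3,4; denominator 4-1.5-0.5-0 = 2
        df = pd.DataFrame({"o": [1.0, 1.0, 2.0, 3.0]}, index=list("WXYZ"))
        tt = A.TraitTable(
            data=df, kinds=pd.Series({"o": "ordinal"}), groups=pd.Series({"o": "other"})
        )
        dm = A.modified_gower(tt)
        assert dm[("W", "X")] == 0.0
        assert dm[("W", "Y")] == pytest.approx(0.5)
        assert dm[("W", "Z")] == pytest.approx(1.0)
        assert dm[("Y", "Z")] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed,missing", [(0, 0.0), (1, 0.0), (2, 0.2), (3, 0.3)])
    def test_matches_naive_oracle_with_and_without_missing(self, seed, missing):
        rng = np.random.default_rng(seed)
        tt = random_trait_table(rng, n_taxa=12, n_traits=6, missing_rate=missing)
        dm = A.modified_gower(tt)
        expected = _gower_oracle(tt, tt.traits)
        np.testing.assert_allclose(dm.data, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_symmetry_zero_diagonal(self, seed):
        rng = np.random.default_rng(100 + seed)
        tt = random_trait_table(rng, n_taxa=15, n_traits=7, missing_rate=0.1)
        dm = A.modified_gower(tt)
        d = dm.data
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_adding_identical_trait_moves_toward_its_contribution(self):
        # the new distance is an average including a 0 contribution, so it
        # cannot exceed the old distance
        rng = np.random.default_rng(7)
        tt = random_trait_table(rng, n_taxa=10, n_traits=4)
        base = A.modified_gower(tt).data
        tt.data["same"] = "k"
        tt2 = A.TraitTable(
            data=tt.data,
            kinds=pd.concat([tt.kinds, pd.Series({"same": "nominal"})]),
            groups=pd.concat([tt.groups, pd.Series({"same": "other"})]),
        )
        wider = A.modified_gower(tt2).data
        assert (wider <= base + 1e-12).all()

    def test_pair_without_shared_traits_rejected(self):
        df = pd.DataFrame(
            {"a": ["x", None], "b": [None, "y"]}, index=["T1", "T2"]
        )
        tt = A.TraitTable(
            data=df,
            kinds=pd.Series({"a": "nominal", "b": "nominal"}),
            groups=pd.Series({"a": "other", "b": "other"}),
        )
        with pytest.raises(DataError, match="T1"):
            A.modified_gower(tt)

    def test_empty_subset_rejected(self, trait_table_12):
        with pytest.raises(DataError, match="nonempty"):
            A.modified_gower(trait_table_12, [])

    def test_distance_csv_round_trip(self, sim_phylo_dist):
        from assemblage.distances import distance_from_csv, distance_to_csv

        again = distance_from_csv(distance_to_csv(sim_phylo_dist))
        assert list(again.ids) == list(sim_phylo_dist.ids)
        np.testing.assert_allclose(again.data, sim_phylo_dist.data, atol=1e-9)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    values=st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=3,
        max_size=10,
    ),
    states=st.data(),
)
def test_gower_bounds_hold_for_arbitrary_mixed_tables(values, states):
    """Output stays in [0, 1], symmetric, zero-diagonal for any input."""
    n = len(values)
    nominal = states.draw(
        st.lists(st.sampled_from("pqr"), min_size=n, max_size=n)
    )
    df = pd.DataFrame(
        {"q": values, "nom": nominal}, index=[f"t{i}" for i in range(n)]
    )
    tt = A.TraitTable(
        data=df,
        kinds=pd.Series({"q": "quantitative", "nom": "nominal"}),
        groups=pd.Series({"q": "other", "nom": "other"}),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = A.modified_gower(tt).data
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    np.testing.assert_allclose(d, d.T)
    assert np.all(np.diag(d) == 0)
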