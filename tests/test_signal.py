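"""Mantel tests, correlograms, parsimony change counts, and the K family."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import assemblage as A
from assemblage.data import DataError
from assemblage.signal import _hartigan_batch, _postorder_structure


def _random_distance(rng, labels):
    n = len(labels)
    m = rng.random((n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=labels)


class TestMantel:
    def test_self_correlation_is_one(self):
        dm = _random_distance(np.random.default_rng(0), list("abcde"))
        res = A.mantel_test(dm, dm, n_perm=99, rng=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_affine_transform_gives_r_one(self):
        rng = np.random.default_rng(1)
        dm = _random_distance(rng, list("abcde"))
        dm2 = DistanceMatrix(3.0 * dm.data + 0.0, ids=list(dm.ids))
        res = A.mantel_test(dm, dm2, n_perm=99, rng=0)
        assert res.statistic == pytest.approx(1.0)

    def test_sqrt_first_transforms_first_matrix(self):
        rng = np.random.default_rng(2)
        dm = _random_distance(rng, list("abcdef"))
        dm_sqrt = DistanceMatrix(np.sqrt(dm.data), ids=list(dm.ids))
        other = _random_distance(rng, list("abcdef"))
        direct = A.mantel_test(dm_sqrt, other, n_perm=9, rng=0).statistic
        flagged = A.mantel_test(dm, other, n_perm=9, rng=0, sqrt_first=True).statistic
        assert direct == pytest.approx(flagged)

    @pytest.mark.parametrize("seed", range(3))
    def test_p_matches_full_enumeration_on_four_taxa(self, seed):
        """The sampled permutation p converges to exhaustive enumeration."""
        rng = np.random.default_rng(10 + seed)
        labels = list("wxyz")
        dA = _random_distance(rng, labels)
        dB = _random_distance(rng, labels)
        iu = np.triu_indices(4, 1)
        a = dA.data[iu]
        r_obs = np.corrcoef(a, dB.data[iu])[0, 1]
        null = []
        for perm in itertools.permutations(range(4)):
            Bp = dB.data[np.ix_(perm, perm)]
            null.append(np.corrcoef(a, Bp[iu])[0, 1])
        exact = np.mean(np.asarray(null) >= r_obs - 1e-12)
        res = A.mantel_test(dA, dB, n_perm=1999, rng=seed)
        assert res.p_value == pytest.approx(exact, abs=0.06)

    @pytest.mark.parametrize("seed", range(3))
    def test_statistic_agrees_with_reference_library(self, seed):
        """Cross-check the Mantel r against scikit-bio's implementation."""
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(40 + seed)
        dA = _random_distance(rng, [f"t{i}" for i in range(10)])
        dB = _random_distance(rng, [f"t{i}" for i in range(10)])
        ours = A.mantel_test(dA, dB, n_perm=9, rng=0).statistic
        theirs = skbio_mantel(dA, dB, permutations=0)[0]
        assert ours == pytest.approx(float(theirs), abs=1e-12)

    def test_statistic_symmetric_in_matrix_roles(self):
        rng = np.random.default_rng(3)
        dA = _random_distance(rng, list("abcdefg"))
        dB = _random_distance(rng, list("abcdefg"))
        r1 = A.mantel_test(dA, dB, n_perm=99, rng=0).statistic
        r2 = A.mantel_test(dB, dA, n_perm=99, rng=0).statistic
        assert r1 == pytest.approx(r2)

    def test_zero_variance_flagged(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        other = _random_distance(np.random.default_rng(4), list("abcd"))
        with pytest.warns(UserWarning, match="zero variance"):
            res = A.mantel_test(dm, other, n_perm=9, rng=0)
        assert res.undefined

    def test_label_mismatch_rejected(self):
        d1 = _random_distance(np.random.default_rng(0), list("abc"))
        d2 = _random_distance(np.random.default_rng(0), list("abd"))
        with pytest.raises(DataError):
            A.mantel_test(d1, d2, n_perm=9, rng=0)


class TestCorrelogram:
    def test_constant_trait_distance_flagged(self):
        labels = list("abcdef")
        d_tr = DistanceMatrix(np.ones((6, 6)) - np.eye(6), ids=labels)
        d_ph = _random_distance(np.random.default_rng(0), labels)
        res = A.mantel_correlogram(d_tr, d_ph, n_classes=2, n_perm=49, rng=0)
        assert res.table["empty"].all()

    def test_near_class_negative_when_trait_tracks_phylogeny(self):
        t = A.simulate_tree(25, seed=3)
        d_ph = A.cophenetic_distance(t)
        res = A.mantel_correlogram(d_ph, d_ph, n_classes=2, n_perm=49, rng=0)
        r = res.table["r"].to_numpy()
        assert r[0] < 0 < r[-1]

    def test_classes_partition_all_pairs(self):
        rng = np.random.default_rng(5)
        d_tr = _random_distance(rng, [f"t{i}" for i in range(12)])
        d_ph = _random_distance(rng, [f"t{i}" for i in range(12)])
        res = A.mantel_correlogram(d_tr, d_ph, n_classes=4, n_perm=49, rng=0)
        assert res.table["n_pairs"].sum() == 12 * 11 // 2
        assert res.table["p_holm"].dropna().ge(res.table["p"].dropna()).all()


def _random_small_tree(rng, n_tips, allow_polytomy=True):
    """Random rooted topology over labeled tips, optionally multifurcating."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        k = 2
        if allow_polytomy and len(nodes) > 2 and rng.random() < 0.3:
            k = 3
        picks = rng.choice(len(nodes), size=k, replace=False)
        merged = "(" + ",".join(nodes[i] for i in sorted(picks, reverse=True)) + ")"
        for i in sorted(picks, reverse=True):
            nodes.pop(i)
        nodes.append(merged)
    return A.read_tree(nodes[0] + ";")


def _fitch_oracle(ptree, states):
    """Exhaustive minimization over all internal-node state assignments."""
    tips, children = _postorder_structure(ptree)
    levels = sorted({states[t] for t in tips})
    lookup = {s: i for i, s in enumerate(levels)}
    tip_states = [lookup[states[t]] for t in tips]
    n_internal = len(children)
    best = None
    for assign in itertools.product(range(len(levels)), repeat=n_internal):
        full = tip_states + list(assign)
        changes = 0
        for i, kids in enumerate(children):
            parent_state = assign[i]
            changes += sum(full[c] != parent_state for c in kids)
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    def test_three_tip_example(self):
        t = A.read_tree("((A,B),C);")
        assert A.fitch_changes(t, {"A": "x", "B": "x", "C": "y"}) == 1

    def test_constant_states_no_changes(self):
        t = A.read_tree("((A,B),(C,D));")
        assert A.fitch_changes(t, {t: "x" for t in "ABCD"}) == 0

    def test_missing_state_rejected(self):
        t = A.read_tree("((A,B),C);")
        with pytest.raises(DataError, match="without a state"):
            A.fitch_changes(t, {"A": "x", "B": "x"})

    def test_polytomy_counts_exactly(self):
        t = A.read_tree("(A,B,C,D);")
        states = {"A": "x", "B": "x", "C": "y", "D": "z"}
        assert A.fitch_changes(t, states) == _fitch_oracle(t, states)

    @pytest.mark.parametrize("n_tips", [4, 5, 6])
    def test_matches_exhaustive_assignment_oracle(self, n_tips):
        """Random topologies (with polytomies) x random <=3-state vectors."""
        rng = np.random.default_rng(n_tips)
        for rep in range(60):
            t = _random_small_tree(rng, n_tips)
            states = {
                f"T{i}": "xyz"[rng.integers(3)] for i in range(n_tips)
            }
            assert A.fitch_changes(t, states) == _fitch_oracle(t, states)


class TestMaddisonSlatkin:
    def test_constant_trait_p_is_one(self):
        t = A.read_tree("((A,B),(C,D));")
        with pytest.warns(UserWarning, match="constant"):
            res = A.maddison_slatkin(t, {t_: "x" for t_ in "ABCD"}, n_perm=99, rng=0)
        assert res.p_value == 1.0
        assert res.statistic == 0.0

    def test_clade_sorted_binary_trait_is_significant(self):
        t = A.read_tree("((((A,B),(C,D)),((E,F),(G,H))));")
        states = {s: "x" for s in "ABCD"} | {s: "y" for s in "EFGH"}
        res = A.maddison_slatkin(t, states, n_perm=999, rng=0)
        assert res.statistic == 1.0
        assert res.p_value <= 0.05

    def test_parsimony_upper_bound(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            t = _random_small_tree(rng, 6)
            raw = ["xyz"[rng.integers(3)] for _ in range(6)]
            states = {f"T{i}": raw[i] for i in range(6)}
            counts = pd.Series(raw).value_counts()
            res = A.maddison_slatkin(t, states, n_perm=19, rng=rep)
            assert res.statistic <= 6 - counts.max()

    def test_p_value_floor(self):
        t = A.simulate_tree(16, seed=0)
        states = {tip: "xy"[i % 2] for i, tip in enumerate(t.tip_labels)}
        res = A.maddison_slatkin(t, states, n_perm=19, rng=0)
        assert res.p_value >= 1 / 20


class TestBlombergK:
    def test_star_tree_K_is_exactly_one(self):
        """On a star tree the Brownian expectation cancels: K = 1 always."""
        from assemblage.synthetic import _lambda_transform

        t = _lambda_transform(A.simulate_tree(20, seed=2), 0.0)
        rng = np.random.default_rng(0)
        vals = {tip: float(v) for tip, v in zip(t.tip_labels, rng.normal(size=20))}
        res = A.blomberg_k(t, vals, "K", n_perm=9, rng=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance_of_branch_lengths(self):
        t = A.simulate_tree(20, seed=5)
        rng = np.random.default_rng(1)
        vals = {tip: float(v) for tip, v in zip(t.tip_labels, rng.normal(size=20))}
        res1 = A.blomberg_k(t, vals, "K", n_perm=9, rng=0)
        scaled = t.copy()
        for node in scaled.tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= 7.5
        res2 = A.blomberg_k(scaled, vals, "K", n_perm=9, rng=0)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-9)

    def test_k_star_equals_kw_with_equal_weights(self):
        t = A.simulate_tree(25, seed=6)
        rng = np.random.default_rng(2)
        vals = {tip: float(v) for tip, v in zip(t.tip_labels, rng.normal(size=25))}
        w = {tip: 2.0 for tip in t.tip_labels}
        r_star = A.blomberg_k(t, vals, "K_star", n_perm=49, rng=0)
        r_w = A.blomberg_k(t, vals, "Kw", n_perm=49, rng=0, weights=w)
        assert r_star.statistic == pytest.approx(r_w.statistic, rel=1e-9)
        assert r_star.p_value == pytest.approx(r_w.p_value)

    def test_kw_without_weights_rejected(self):
        t = A.simulate_tree(10, seed=7)
        vals = {tip: float(i) for i, tip in enumerate(t.tip_labels)}
        with pytest.raises(DataError, match="weights"):
            A.blomberg_k(t, vals, "Kw", n_perm=9, rng=0)

    def test_zero_variance_flagged(self):
        t = A.simulate_tree(10, seed=8)
        with pytest.warns(UserWarning, match="zero trait variance"):
            res = A.blomberg_k(t, {tip: 1.0 for tip in t.tip_labels}, "K", n_perm=9, rng=0)
        assert res.undefined

    def test_brownian_traits_give_high_k_and_significance(self):
        t = A.simulate_tree(64, seed=9)
        x = A.simulate_traits(
            t, [A.TraitModel("x", "quantitative", "other", "brownian")], seed=3
        )
        res = A.blomberg_k(t, x.data["x"].to_dict(), "K", n_perm=199, rng=0)
        assert res.p_value <= 0.05


def test_signal_table_shape_and_columns(sim_tree, sim_traits, sim_phylo_dist):
    tab = A.signal_table(sim_tree, sim_traits, d_phylo=sim_phylo_dist, n_perm=49, seed=0)
    # 3 group rows (all/alpha/beta) + 12 traits
    assert len(tab) == 15
    assert set(tab.columns) >= {"trait", "kind", "mantel_r", "mantel_p", "kind_p"}
    nominal = tab[tab["kind"] == "nominal"]
    assert nominal["kind_p"].notna().all()
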