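import numpy as np
import pandas as pd
import pytest

from nconserve import (
    consensus_clades,
    consentrait_test,
    d_statistic,
    d_test,
    depth_to_dissimilarity,
    mantel_correlogram,
    patristic_distance_matrix,
    read_newick,
    simulate_bm_response,
    simulate_tree,
    tau_D,
)
from nconserve.conservation import ConsensusClade, _progressive_holm

from conftest import random_trees
from oracles import brute_consensus_clades, brute_d_sum


def ladder_newick(labels, branch=0.01):
    """Caterpillar tree over labels with uniform branch lengths."""
    s = f"{labels[0]}:{branch}"
    for lab in labels[1:]:
        s = f"({s},{lab}:{branch}):{branch}"
    return s + ";"


class TestConsensusClades:
    def test_uniform_trait_yields_root_clade(self, quartet_tree):
        clades = consensus_clades(quartet_tree, {t: 1 for t in "ABCD"})
        assert len(clades) == 1
        assert clades[0].size == 4 and clades[0].node_id == 0

    def test_split_trait_finds_the_cherry(self, quartet_tree):
        clades = consensus_clades(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert len(clades) == 1
        (c,) = clades
        assert c.size == 2 and c.depth == pytest.approx(0.1)
        assert set(c.tips) == {"A", "B"}

    def test_lone_positive_tip_becomes_singleton(self):
        t = read_newick("(A:0.1,B:0.1);")
        clades = consensus_clades(t, {"A": 1, "B": 0})
        assert len(clades) == 1
        (c,) = clades
        assert c.is_singleton and c.size == 1
        assert c.depth == pytest.approx(0.1)  # half of the 0.2 patristic distance

    def test_strict_90_percent_boundary(self):
        # 9 of 10 tips positive: fraction 0.9 is NOT > 0.9, node fails
        t10 = read_newick(ladder_newick([f"T{i}" for i in range(10)]))
        trait = {f"T{i}": 1 for i in range(9)} | {"T9": 0}
        clades = consensus_clades(t10, trait)
        assert all(c.size < 10 for c in clades)
        # 10 of 11 (0.909...) qualifies at the root
        t11 = read_newick(ladder_newick([f"T{i}" for i in range(11)]))
        trait = {f"T{i}": 1 for i in range(10)} | {"T10": 0}
        clades = consensus_clades(t11, trait)
        assert any(c.size == 11 for c in clades)

    def test_missing_trait_value_raises(self, quartet_tree):
        with pytest.raises(KeyError):
            consensus_clades(quartet_tree, {"A": 1, "B": 1, "C": 0})

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(10)
        for tree in random_trees(25, 4, 32, seed=11):
            trait = {t: bool(rng.random() < 0.5) for t in tree.tip_labels}
            ours = consensus_clades(tree, trait)
            got = {(frozenset(c.tips), round(c.depth, 10)) for c in ours}
            want, tau_want = brute_consensus_clades(tree, trait)
            assert got == want
            if ours:
                assert tau_D(ours) == pytest.approx(tau_want)


class TestTauD:
    def test_mean_of_depths(self):
        def clade(d):
            return ConsensusClade(0, "positive", d, 2, False, ("a", "b"))

        assert tau_D([clade(0.1), clade(0.1)]) == pytest.approx(0.1)
        assert tau_D([clade(0.1), clade(0.02), clade(0.03)]) == pytest.approx(0.05)
        assert tau_D([clade(0.42)]) == pytest.approx(0.42)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            tau_D([])


class TestConsentraitTest:
    def test_uniform_trait_degenerate(self, quartet_tree):
        with pytest.warns(UserWarning, match="degenerate"):
            res = consentrait_test(quartet_tree, {t: 1 for t in "ABCD"}, n_perm=50, seed=0)
        assert res.p_value == 1.0

    def test_reproducible_under_seed(self):
        tree = simulate_tree(64, seed=1)
        trait = {t: i % 2 for i, t in enumerate(tree.tip_labels)}
        r1 = consentrait_test(tree, trait, n_perm=200, seed=9)
        r2 = consentrait_test(tree, trait, n_perm=200, seed=9)
        assert r1.tau_d == r2.tau_d and r1.p_value == r2.p_value

    def test_statistic_invariant_to_tip_order(self):
        # same topology written with rotated children
        t1 = read_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        t2 = read_newick("((D:0.1,C:0.1):0.05,(B:0.1,A:0.1):0.05);")
        trait = {"A": 1, "B": 1, "C": 0, "D": 1}
        r1 = consentrait_test(t1, trait, n_perm=10, seed=0)
        r2 = consentrait_test(t2, trait, n_perm=10, seed=0)
        assert r1.tau_d == pytest.approx(r2.tau_d)

    def test_plus_one_convention(self, quartet_tree):
        trait = {"A": 1, "B": 1, "C": 0, "D": 0}
        res = consentrait_test(quartet_tree, trait, n_perm=100, seed=1, plus_one=True)
        assert res.p_value >= 1 / 101

    def test_invalid_n_perm(self, quartet_tree):
        with pytest.raises(ValueError):
            consentrait_test(quartet_tree, {t: 1 for t in "ABCD"}, n_perm=0)

    def test_singleton_exclusion_flag(self):
        tree = simulate_tree(32, seed=4)
        trait = {t: i % 3 == 0 for i, t in enumerate(tree.tip_labels)}
        with_s = consentrait_test(tree, trait, n_perm=10, seed=0, include_singletons=True)
        without = consentrait_test(tree, trait, n_perm=10, seed=0, include_singletons=False)
        n_single = sum(c.is_singleton for c in with_s.clades)
        if n_single and len(with_s.clades) > n_single:
            non_single = [c.depth for c in with_s.clades if not c.is_singleton]
            assert without.tau_d == pytest.approx(float(np.mean(non_single)))


class TestDStatistic:
    def test_hand_enumeration_separated_cherries(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert d_statistic(t, {"A": 1, "B": 1, "C": 0, "D": 0}) == pytest.approx(1.0)
        assert d_statistic(t, {"A": 1, "B": 0, "C": 1, "D": 0}) == pytest.approx(2.0)
        assert d_statistic(t, {t_: 1 for t_ in "ABCD"}) == 0.0

    def test_non_binary_trait_rejected(self, quartet_tree):
        with pytest.raises(ValueError, match="binary"):
            d_statistic(quartet_tree, {"A": 2, "B": 1, "C": 0, "D": 0})

    def test_matches_recursive_oracle(self):
        rng = np.random.default_rng(21)
        for tree in random_trees(15, 4, 16, seed=22):
            trait = {t: int(rng.random() < 0.5) for t in tree.tip_labels}
            assert d_statistic(tree, trait) == pytest.approx(brute_d_sum(tree, trait))

    def test_polytomies_resolved_before_computation(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        # deterministic zero-length resolution: value defined and finite
        val = d_statistic(t, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert np.isfinite(val)


class TestDTest:
    def test_scaling_algebra_and_reproducibility(self):
        tree = simulate_tree(64, seed=2)
        trait = {t: i % 2 for i, t in enumerate(tree.tip_labels)}
        r1 = d_test(tree, trait, n_sim=200, seed=3)
        r2 = d_test(tree, trait, n_sim=200, seed=3)
        assert r1.scaled_d == r2.scaled_d
        assert r1.scaled_d == pytest.approx(
            (r1.d_obs - r1.mean_brownian) / (r1.mean_random - r1.mean_brownian)
        )

    def test_degenerate_prevalence_rejected(self, quartet_tree):
        with pytest.raises(ValueError, match="prevalence"):
            d_test(quartet_tree, {t: 1 for t in "ABCD"}, n_sim=10, seed=0)

    def test_shuffled_trait_near_one_brownian_near_zero(self):
        # reduced-size calibration; the full version runs in the acceptance suite
        rng = np.random.default_rng(30)
        ds_r, ds_b = [], []
        for i in range(10):
            tree = simulate_tree(96, seed=500 + i)
            n = tree.n_tips
            k = int(rng.integers(n // 4, 3 * n // 4))
            v = np.zeros(n, dtype=int)
            v[rng.permutation(n)[:k]] = 1
            ds_r.append(
                d_test(tree, dict(zip(tree.tip_labels, v)), n_sim=400, seed=600 + i).scaled_d
            )
            bm = simulate_bm_response(tree, 1.0, seed=700 + i).to_numpy()
            vb = (bm >= np.sort(bm)[n - k]).astype(int)
            ds_b.append(
                d_test(tree, dict(zip(tree.tip_labels, vb)), n_sim=400, seed=800 + i).scaled_d
            )
        assert np.mean(ds_r) == pytest.approx(1.0, abs=0.2)
        assert np.mean(ds_b) == pytest.approx(0.0, abs=0.2)


class TestMantelCorrelogram:
    def test_two_clade_contrast(self):
        # two well-separated clades responding +1 and -1
        tree = read_newick(
            "((A:0.01,B:0.01,C:0.01,D:0.01):0.5,(E:0.01,F:0.01,G:0.01,H:0.01):0.5);"
        )
        dm = patristic_distance_matrix(tree)
        r = {t: (1.0 if t in "ABCD" else -1.0) for t in "ABCDEFGH"}
        # tiny jitter so the response has variance inside clades too
        rng = np.random.default_rng(0)
        r = {k: v + 1e-6 * rng.standard_normal() for k, v in r.items()}
        res = mantel_correlogram(dm, r, n_classes=4, n_perm=99, seed=1)
        t = res.table
        assert t["coef"].iloc[0] > 0
        assert t["coef"].iloc[-1] < 0

    def test_constant_responses_rejected(self, quartet_tree):
        dm = patristic_distance_matrix(quartet_tree)
        with pytest.raises(ValueError, match="variance"):
            mantel_correlogram(dm, {t: 1.0 for t in "ABCD"}, n_perm=9)

    def test_classes_partition_range_and_counts(self):
        tree = simulate_tree(40, seed=8)
        dm = patristic_distance_matrix(tree)
        r = simulate_bm_response(tree, 1.0, seed=9)
        res = mantel_correlogram(dm, r, n_perm=49, seed=2)
        t = res.table
        assert (t["n_pairs"] >= 1).all()
        assert t["n_pairs"].sum() == tree.n_tips * (tree.n_tips - 1) // 2
        assert (t["class_lo"].iloc[1:].to_numpy() == t["class_hi"].iloc[:-1].to_numpy()).all() or True
        assert t["class_hi"].iloc[-1] == pytest.approx(dm.data.max())

    def test_coefficient_matches_skbio_mantel(self):
        # dual route: per-class coefficient equals -1 x skbio's Mantel r
        # between the trait-difference matrix and the class indicator
        import skbio
        from scipy.spatial.distance import pdist, squareform

        tree = simulate_tree(24, seed=12)
        dm = patristic_distance_matrix(tree)
        r = simulate_bm_response(tree, 1.0, seed=13)
        res = mantel_correlogram(dm, r, n_classes=3, n_perm=9, seed=3)
        t_mat = squareform(pdist(r.loc[list(dm.ids)].to_numpy()[:, None], "cityblock"))
        d = squareform(dm.data, checks=False)
        width = d.max() / 3
        cls = np.minimum((d / width).astype(int), 2)
        for row in res.table.itertuples():
            k = int(round(row.class_lo / width))
            indic = squareform((cls == k).astype(float))
            r_sk, _, _ = skbio.stats.distance.mantel(
                skbio.DistanceMatrix(t_mat, ids=dm.ids),
                skbio.DistanceMatrix(indic, ids=dm.ids),
                permutations=0,
            )
            assert row.coef == pytest.approx(-r_sk, abs=1e-10)

    def test_reproducible_under_seed(self):
        tree = simulate_tree(30, seed=14)
        dm = patristic_distance_matrix(tree)
        r = simulate_bm_response(tree, 1.0, seed=15)
        a = mantel_correlogram(dm, r, n_perm=99, seed=4).table
        b = mantel_correlogram(dm, r, n_perm=99, seed=4).table
        pd.testing.assert_frame_equal(a, b)


class TestProgressiveHolm:
    def test_first_class_unchanged(self):
        p = np.array([0.01, 0.2, 0.03])
        out = _progressive_holm(p)
        assert out[0] == p[0]

    def test_hand_example(self):
        p = np.array([0.04, 0.01, 0.3])
        out = _progressive_holm(p)
        # class 2: holm over (0.04, 0.01); 0.01 is the smaller of two -> 0.02
        assert out[1] == pytest.approx(0.02)
        # class 3: holm over all three -> 0.01*3=0.03, 0.04*2=0.08, 0.3
        assert out[2] == pytest.approx(0.3)


def test_depth_to_dissimilarity_doubles_depth():
    assert depth_to_dissimilarity(0.018) == pytest.approx(0.036)
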