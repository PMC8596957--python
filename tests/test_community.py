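"""Tests for rarefaction, diversity indices, ordination and group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import permanova as skbio_permanova

from fermbal.community import (
    bray_curtis,
    chao1,
    faith_pd,
    family_profile,
    group_difference,
    nmds,
    observed_species,
    permanova,
    rarefy,
    shannon,
)


class TestRarefy:
    def make_table(self):
        return pd.DataFrame(
            [[50, 30, 20, 0], [10, 10, 10, 70], [1, 1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=list("abcd"),
        )

    def test_sums_equal_depth_and_shallow_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            out = rarefy(self.make_table(), depth=50, seed=0)
        assert list(out.index) == ["s1", "s2"]
        assert (out.sum(axis=1) == 50).all()

    def test_full_depth_returns_same_multiset(self):
        table = self.make_table().iloc[:1]
        out = rarefy(table, depth=100, seed=1)
        assert (out == table).all().all()

    def test_reproducible_under_seed(self):
        t = self.make_table().iloc[:2]
        a = rarefy(t, 40, seed=7)
        b = rarefy(t, 40, seed=7)
        assert (a == b).all().all()

    def test_expected_proportions_match_hypergeometric_mean(self):
        # E[draws of taxon i] = depth * n_i / N for sampling w/o replacement
        row = np.array([500, 300, 150, 50])
        table = pd.DataFrame([row], index=["s"], columns=list("abcd"))
        depth = 200
        acc = np.zeros(4)
        for seed in range(500):
            acc += rarefy(table, depth, seed=seed).to_numpy()[0]
        mean = acc / 500
        expected = depth * row / row.sum()
        assert np.allclose(mean, expected, rtol=0.05, atol=1.5)

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            rarefy(self.make_table(), 0, seed=0)


class TestAlphaDiversity:
    def test_shannon_examples(self):
        assert shannon([5, 5, 5, 5], base=2) == pytest.approx(2.0)
        assert shannon([42], base=2) == 0.0
        # direct summation oracle for counts (1, 2, 3), natural log
        p = np.array([1, 2, 3]) / 6
        assert shannon([1, 2, 3], base=np.e) == pytest.approx(-(p * np.log(p)).sum())
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_chao1_hand_formula(self):
        # S_obs 10, F1 = 4 singletons, F2 = 2 doubletons -> 10 + 4*3/(2*3) = 12
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert chao1(counts) == pytest.approx(12.0)

    def test_chao1_without_singletons_is_richness(self):
        counts = [2, 3, 4, 5]
        assert chao1(counts) == pytest.approx(observed_species(counts))

    def test_chao1_at_least_observed(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 6, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= observed_species(counts) - 1e-9


def _pd_oracle(tree: TreeNode, present: list[str]) -> float:
    """Independent oracle: scikit-bio's Faith PD (root path included)."""
    from skbio.diversity.alpha import faith_pd as skbio_faith_pd

    return float(skbio_faith_pd(np.ones(len(present)), taxa=present, tree=tree))


class TestFaithPD:
    tree = TreeNode.read(["((a:1,b:2):0.5,((c:1,d:1):0.25,e:3):1):0;"])

    def test_all_leaves_is_total_branch_length(self):
        total = sum(n.length or 0.0 for n in self.tree.traverse() if n.parent is not None)
        assert faith_pd(self.tree, list("abcde")) == pytest.approx(total)

    def test_star_tree_unit_branches(self):
        star = TreeNode.read(["(a:1,b:1,c:1,d:1):0;"])
        assert faith_pd(star, ["a", "b", "c"]) == pytest.approx(3.0)

    def test_matches_union_of_root_paths_oracle(self):
        rng = np.random.default_rng(3)
        from fermbal.synthetic import _random_coalescent_tree

        taxa = [f"t{i}" for i in range(8)]
        tree = _random_coalescent_tree(taxa, rng, rate=1.0)
        for _ in range(10):
            k = rng.integers(1, 9)
            present = list(rng.choice(taxa, size=k, replace=False))
            assert faith_pd(tree, present) == pytest.approx(_pd_oracle(tree, present))

    def test_monotone_in_taxa(self):
        assert faith_pd(self.tree, ["a"]) <= faith_pd(self.tree, ["a", "c"])
        assert faith_pd(self.tree, ["a", "c"]) <= faith_pd(self.tree, ["a", "c", "e"])

    def test_root_path_toggle(self):
        with_root = faith_pd(self.tree, ["c", "d"], include_root=True)
        without = faith_pd(self.tree, ["c", "d"], include_root=False)
        # c,d crown sits 1 + 0.25 below the root
        assert with_root - without == pytest.approx(1.25)

    def test_unknown_taxon_rejected(self):
        with pytest.raises(KeyError):
            faith_pd(self.tree, ["a", "zz"])
        with pytest.raises(ValueError):
            faith_pd(self.tree, [])


class TestBrayCurtis:
    def test_hand_formula_cases(self):
        table = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]],
            index=["x", "y", "x2", "z"],
            columns=list("abc"),
        )
        d = bray_curtis(table)
        assert d.loc["x", "y"] == pytest.approx(0.5)  # 1 - 2*1/(2+2)
        assert d.loc["x", "x2"] == 0.0
        assert d.loc["y", "z"] == pytest.approx(1.0)  # disjoint
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()

    def test_zero_sample_rejected(self):
        table = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"], columns=["t1", "t2"])
        with pytest.raises(ValueError):
            bray_curtis(table)


class TestNMDS:
    def embeddable_distances(self, n=8, seed=4):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(pts))

    def test_exact_2d_configuration_has_near_zero_stress(self):
        res = nmds(self.embeddable_distances(), k=2, seed=0, n_restarts=10)
        assert res.stress < 0.01

    def test_three_points_embed_exactly(self):
        d = np.array([[0, 1, 2.0], [1, 0, 1.5], [2, 1.5, 0]])
        res = nmds(d, k=2, seed=0, n_restarts=5)
        assert res.stress == pytest.approx(0.0, abs=1e-4)

    def test_stress_trace_non_increasing(self):
        res = nmds(self.embeddable_distances(n=10, seed=9), k=2, seed=3, n_restarts=3)
        assert np.all(np.diff(res.stress_trace) <= 1e-9)

    def test_bit_reproducible_under_seed(self):
        d = self.embeddable_distances()
        a = nmds(d, k=2, seed=12, n_restarts=4)
        b = nmds(d, k=2, seed=12, n_restarts=4)
        assert a.stress == b.stress
        assert (a.coordinates.to_numpy() == b.coordinates.to_numpy()).all()

    def test_coordinates_centered(self):
        res = nmds(self.embeddable_distances(), k=2, seed=1, n_restarts=3)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)

    def test_stress_competitive_with_sklearn_smacof(self):
        # independent route: sklearn's non-metric MDS on the same distances
        from sklearn.manifold import MDS

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(9, 4))  # 4-D cloud: not exactly 2-D embeddable
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ours = nmds(d, k=2, seed=0, n_restarts=10)
        theirs = MDS(
            n_components=2,
            metric=False,
            dissimilarity="precomputed",
            n_init=10,
            normalized_stress=True,
            random_state=0,
        ).fit(d)
        assert ours.stress <= theirs.stress_ + 0.02

    def test_k_bounds(self):
        d = self.embeddable_distances(n=4)
        with pytest.raises(ValueError):
            nmds(d, k=4, seed=0)
        with pytest.raises(ValueError):
            nmds(d, k=0, seed=0)


class TestPermanova:
    def toy(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, size=(3, 4))
        b = rng.normal(3, 1, size=(2, 4))
        pts = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(pts)), np.array(["g1"] * 3 + ["g2"] * 2)

    def test_r2_matches_brute_force_partition(self):
        d, labels = self.toy()
        n = d.shape[0]
        d2 = d**2
        sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in ("g1", "g2"):
            idx = [i for i, l in enumerate(labels) if l == g]
            ssw += sum(
                d2[i, j] for k, i in enumerate(idx) for j in idx[k + 1 :]
            ) / len(idx)
        res = permanova(d, labels, n_permutations=99, seed=0)
        assert res.r2 == pytest.approx((sst - ssw) / sst)
        assert 0.0 <= res.r2 <= 1.0

    def test_pseudo_f_matches_skbio(self):
        d, labels = self.toy()
        ours = permanova(d, labels, n_permutations=999, seed=1)
        theirs = skbio_permanova(
            DistanceMatrix(d, ids=[str(i) for i in range(5)]),
            list(labels),
            permutations=999,
            seed=1,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_minimal_p_for_separated_clusters(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 0.1, size=(13, 3)), rng.normal(5, 0.1, size=(13, 3))]
        )
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        labels = np.array(["a"] * 13 + ["b"] * 13)
        res = permanova(d, labels, n_permutations=999, seed=3)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_floor_invariant(self):
        d, labels = self.toy()
        res = permanova(d, labels, n_permutations=49, seed=5)
        assert res.p_value >= 1 / 50

    def test_single_group_rejected(self):
        d, _ = self.toy()
        with pytest.raises(ValueError):
            permanova(d, ["g"] * 5, n_permutations=9, seed=0)


class TestFamilyLevel:
    def make_profile(self):
        counts = pd.DataFrame(
            [[10, 20, 30, 40], [40, 30, 20, 10], [25, 25, 25, 25], [5, 5, 45, 45]],
            index=["a1", "a2", "b1", "b2"],
            columns=["t1", "t2", "t3", "t4"],
        )
        taxonomy = {"t1": "F1", "t2": "F1", "t3": "F2"}  # t4 unclassified
        return counts, taxonomy

    def test_aggregation_matches_hand_computation(self):
        counts, taxonomy = self.make_profile()
        prof = family_profile(counts, taxonomy)
        assert prof.loc["a1", "F1"] == pytest.approx(0.30)
        assert prof.loc["a1", "F2"] == pytest.approx(0.30)
        assert prof.loc["a1", "Other"] == pytest.approx(0.40)
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_single_family_is_everything(self):
        counts = pd.DataFrame([[3, 7]], index=["s"], columns=["t1", "t2"])
        prof = family_profile(counts, {"t1": "F", "t2": "F"})
        assert prof.loc["s", "F"] == pytest.approx(1.0)

    def test_empty_taxonomy_rejected(self):
        counts, _ = self.make_profile()
        with pytest.raises(ValueError):
            family_profile(counts, {})

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        base = rng.random((6, 2))
        prof = pd.DataFrame(
            base / base.sum(axis=1, keepdims=True),
            index=[f"s{i}" for i in range(6)],
            columns=["F1", "F2"],
        )
        groups = pd.Series(
            ["a", "a", "a", "b", "b", "b"], index=prof.index
        )
        out = group_difference(prof, groups, "a", "b")
        x = prof.loc[["s0", "s1", "s2"], "F1"].to_numpy()
        y = prof.loc[["s3", "s4", "s5"], "F1"].to_numpy()
        # textbook Welch: t, df, and CI from the unpooled variances
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_stat = (y.mean() - x.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        half = stats.t.ppf(0.975, df) * np.sqrt(vx + vy)
        assert out.loc["F1", "t"] == pytest.approx(t_stat)
        assert out.loc["F1", "ci_low"] == pytest.approx(y.mean() - x.mean() - half)
        assert out.loc["F1", "ci_high"] == pytest.approx(y.mean() - x.mean() + half)

    def test_identical_groups_ci_spans_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.random(3)
        prof = pd.DataFrame(
            {"F1": np.tile(vals, 2)}, index=[f"s{i}" for i in range(6)]
        )
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=prof.index)
        out = group_difference(prof, groups, "a", "b")
        assert out.loc["F1", "mean_diff"] == pytest.approx(0.0)
        assert out.loc["F1", "ci_low"] <= 0.0 <= out.loc["F1", "ci_high"]

    def test_constant_shift_tight_ci(self):
        rng = np.random.default_rng(2)
        a = 0.3 + rng.normal(0, 1e-9, 4)
        prof = pd.DataFrame({"F1": np.concatenate([a, a + 0.2])},
                            index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=prof.index)
        out = group_difference(prof, groups, "a", "b")
        assert out.loc["F1", "ci_low"] == pytest.approx(0.2, abs=1e-6)
        assert out.loc["F1", "ci_high"] == pytest.approx(0.2, abs=1e-6)

    def test_small_group_rejected(self):
        prof = pd.DataFrame({"F1": [0.1, 0.2, 0.3]}, index=["s0", "s1", "s2"])
        groups = pd.Series(["a", "b", "b"], index=prof.index)
        with pytest.raises(ValueError):
            group_difference(prof, groups, "a", "b")
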