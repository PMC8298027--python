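"""Population structure: divergence, diversity, NJ trees, F_ST, sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oystergs.popgen import (DistanceMatrix, cut_tree_clusters,
                             fst_from_diversity, neighbor_joining,
                             nucleotide_diversity, pairwise_divergence,
                             population_structure, select_unrelated,
                             weight_categories)
from oystergs.qc import GenotypeMatrix
from oystergs.simulate import SimulationConfig, TraitSpec, make_pedigree

nan = np.nan


def gm_from(calls, ids=None):
    calls = np.asarray(calls, float)
    n, m = calls.shape
    return GenotypeMatrix(ids or [f"s{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)], calls)


def patristic(tree):
    """Leaf-to-leaf path lengths of a TreeNode tree."""
    leaves = sorted(tree.leaves(), key=lambda v: v.name)
    paths = {}

    def walk(node, ancestors):
        here = ancestors + [node]
        if node.is_leaf():
            paths[node.name] = here
        for c in node.children:
            walk(c, here)

    walk(tree, [])
    names = [v.name for v in leaves]
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            pa, pb = paths[a], paths[b]
            common = 0
            for x, y in zip(pa, pb):
                if x is y:
                    common += 1
                else:
                    break
            d = sum(v.length for v in pa[common:]) + \
                sum(v.length for v in pb[common:])
            D[i, j] = D[j, i] = d
    return names, D


class TestDivergence:
    def test_identical_and_opposite(self):
        gm = gm_from([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        D = pairwise_divergence(gm).values
        assert D[0, 1] == 0.0
        gm2 = gm_from([[0, 0], [2, 2]])
        assert pairwise_divergence(gm2).values[0, 1] == 1.0

    def test_brute_force_oracle_with_missing(self, rng):
        calls = rng.choice([0.0, 1.0, 2.0, nan], size=(6, 30),
                           p=[0.3, 0.25, 0.25, 0.2])
        gm = gm_from(calls)
        D = pairwise_divergence(gm).values
        for i, j in itertools.combinations(range(6), 2):
            num, den = 0.0, 0
            for k in range(30):
                a, b = calls[i, k], calls[j, k]
                if not (np.isnan(a) or np.isnan(b)):
                    num += abs(a - b) / 2.0
                    den += 1
            assert D[i, j] == pytest.approx(num / den)

    def test_no_shared_markers_rejected(self):
        gm = gm_from([[0.0, nan], [nan, 2.0]])
        with pytest.raises(ValueError, match="share no genotyped marker"):
            pairwise_divergence(gm)

    def test_invariant_to_orderings(self, rng):
        calls = rng.choice([0.0, 1.0, 2.0], size=(5, 20))
        gm = gm_from(calls)
        D = pairwise_divergence(gm)
        mperm = rng.permutation(20)
        gm_m = gm_from(calls[:, mperm])
        np.testing.assert_allclose(pairwise_divergence(gm_m).values, D.values)
        sperm = rng.permutation(5)
        gm_s = gm_from(calls[sperm], ids=[f"s{i}" for i in sperm])
        idx = np.argsort(sperm)
        np.testing.assert_allclose(
            pairwise_divergence(gm_s).values[np.ix_(idx, idx)], D.values)


class TestDiversity:
    def test_identical_population_zero(self):
        gm = gm_from([[1, 0, 2]] * 4)
        assert nucleotide_diversity(gm) == 0.0

    def test_two_individuals_equals_their_distance(self):
        gm = gm_from([[0, 1], [2, 1]])
        d = pairwise_divergence(gm).values[0, 1]
        assert nucleotide_diversity(gm) == pytest.approx(d)

    def test_mean_of_all_pairs(self, rng):
        calls = rng.choice([0.0, 1.0, 2.0], size=(5, 25))
        gm = gm_from(calls)
        D = pairwise_divergence(gm).values
        pairs = [D[i, j] for i, j in itertools.combinations(range(5), 2)]
        assert nucleotide_diversity(gm) == pytest.approx(np.mean(pairs))

    def test_differentiated_clusters_give_positive_fst(self, rng):
        """With genuinely diverged subpopulations the total diversity
        exceeds the size-weighted within diversity, so F_ST > 0."""
        p1 = rng.uniform(0.05, 0.35, 40)
        p2 = np.clip(p1 + rng.uniform(0.3, 0.5, 40), 0.0, 0.95)
        calls = np.vstack([rng.binomial(2, p1, size=(5, 40)),
                           rng.binomial(2, p2, size=(5, 40))]).astype(float)
        gm = gm_from(calls)
        clusters = pd.Series(["x"] * 5 + ["y"] * 5, index=gm.sample_ids)
        res = population_structure(gm, clusters)
        pi_s = np.average(list(res.pi_within.values()),
                          weights=list(res.cluster_sizes.values()))
        assert res.pi_total > pi_s
        assert 0.0 < res.fst <= 1.0


class TestFst:
    def test_identical_subpopulations_zero(self):
        assert fst_from_diversity(0.2, [0.2, 0.2], [5, 5]) == 0.0

    def test_fixed_opposite_alleles_one(self):
        gm = gm_from([[0, 0], [0, 0], [2, 2], [2, 2]])
        clusters = pd.Series(["a", "a", "b", "b"], index=gm.sample_ids)
        res = population_structure(gm, clusters)
        assert res.fst == pytest.approx(1.0)
        assert all(v == 0.0 for v in res.pi_within.values())

    def test_toy_two_cluster_hand_computation(self):
        # cluster A: {0,0} and {0,2}; cluster B: {2,2} and {2,0}
        gm = gm_from([[0, 0], [0, 2], [2, 2], [2, 0]])
        clusters = pd.Series(["A", "A", "B", "B"], index=gm.sample_ids)
        res = population_structure(gm, clusters)
        # within A: |0-0|+|0-2| over 2 sites /2 -> 0.5; same within B
        # pi_T: pairs (0,1)=.5 (0,2)=1 (0,3)=.5 (1,2)=.5 (1,3)=1 (2,3)=.5 -> 2/3
        assert res.pi_within["A"] == pytest.approx(0.5)
        assert res.pi_within["B"] == pytest.approx(0.5)
        assert res.pi_total == pytest.approx(4.0 / 6.0)
        assert res.fst == pytest.approx((4 / 6 - 0.5) / (4 / 6))

    def test_zero_total_diversity_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(fst_from_diversity(0.0, [0.0], [2]))


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) with the C-D split via a length-1 edge
        names = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(D, names))
        got_names, P = patristic(tree)
        assert got_names == names
        np.testing.assert_allclose(P, D, atol=1e-9)

    def test_three_taxon_point_formulas(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(D, ["A", "B", "C"]))
        lengths = {v.name: v.length for v in tree.children}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_ultrametric_pairs_join_first(self):
        # two clear cherries (A,B) and (C,D)
        D = np.array([[0, 2, 8, 8],
                      [2, 0, 8, 8],
                      [8, 8, 0, 2],
                      [8, 8, 2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(D, list("ABCD")))
        cherries = [{v.name for v in c.leaves()}
                    for c in tree.children if not c.is_leaf()]
        assert {"A", "B"} in cherries or {"C", "D"} in cherries

    def test_matches_scikit_bio_on_random_additive_matrix(self, rng):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        names, D = _random_additive_matrix(rng, n=8)
        tree = neighbor_joining(DistanceMatrix(D, names))
        _, P = patristic(tree)
        np.testing.assert_allclose(P, D, atol=1e-9)
        sk_tree = sk_nj(SkDM(D, ids=names))
        sk_P = np.array([[sk_tree.find(a).distance(sk_tree.find(b))
                          for b in names] for a in names])
        np.testing.assert_allclose(P, sk_P, atol=1e-6)

    def test_newick_round_trip_parses(self):
        pytest.importorskip("skbio")
        from skbio import TreeNode as SkNode
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(D, list("ABCD")))
        import io
        sk = SkNode.read(io.StringIO(tree.newick()))
        assert {t.name for t in sk.tips()} == set("ABCD")

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    def test_cluster_cutting_partitions_leaves(self, rng):
        names, D = _random_additive_matrix(rng, n=10)
        tree = neighbor_joining(DistanceMatrix(D, names))
        clusters = cut_tree_clusters(tree, 4)
        assert set(clusters.index) == set(names)
        assert clusters.nunique() <= 4


def _random_additive_matrix(rng, n=8):
    """Distance matrix induced by a random binary tree with positive lengths.

    Clusters are merged in random order; each cluster tracks its leaves'
    distances to the cluster root, and cross-cluster leaf pairs get their
    path length recorded at merge time.
    """
    D = np.zeros((n, n))
    clusters = [{i: 0.0} for i in range(n)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        da, db = clusters[i], clusters[j]
        la, lb = rng.uniform(0.5, 2.0, 2)
        for a, xa in da.items():
            for b, xb in db.items():
                D[a, b] = D[b, a] = xa + la + xb + lb
        merged = {k: v + la for k, v in da.items()}
        merged.update({k: v + lb for k, v in db.items()})
        clusters = [clusters[k] for k in range(len(clusters))
                    if k not in (i, j)] + [merged]
    return [f"L{i}" for i in range(n)], D


@pytest.fixture(scope="module")
def default_ped():
    return make_pedigree(SimulationConfig(seed=8))


class TestStudyHelpers:
    def test_select_unrelated_distinct_families(self, default_ped):
        ids = select_unrelated(default_ped, n=50, generation=1, seed=0)
        assert len(ids) == 50
        fams = default_ped.families(generation=1)
        fam_of = {str(k): key for key, kids in fams.items() for k in kids}
        assert len({fam_of[i] for i in ids}) == 50

    def test_select_single(self, default_ped):
        assert len(select_unrelated(default_ped, n=1, generation=1)) == 1

    def test_select_deterministic(self, default_ped):
        a = select_unrelated(default_ped, n=20, generation=1, seed=5)
        b = select_unrelated(default_ped, n=20, generation=1, seed=5)
        assert a == b

    def test_select_too_many_reports_maximum(self, default_ped):
        with pytest.raises(ValueError, match="57 families"):
            select_unrelated(default_ped, n=60, generation=1)

    @pytest.mark.parametrize("weight, label", [
        (45.0, "II"), (71.0, "V"), (40.0, "II"), (30.0, "I"),
        (69.9, "IV"), (70.0, "V"), (15.7, "unbinned"),
    ])
    def test_weight_categories(self, weight, label):
        assert weight_categories([weight])[0] == label
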