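"""Cophenetic distances, MPD, MPD_ses and random polytomy resolution."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_path_distance, random_ultrametric_tree
from mzosim.phylodiv import (
    DistanceMatrix,
    cophenetic_matrix,
    mpd,
    mpd_ses,
    resolve_polytomies,
)
from mzosim.trees import Phylogeny


class TestCophenetic:
    def test_two_tip_tree(self, two_tip_tree):
        dm = cophenetic_matrix(two_tip_tree)
        i, j = dm.positions(["A", "B"])
        assert dm.values[i, j] == pytest.approx(10.0)
        assert dm.values[i, i] == 0.0

    def test_ultrametric_geometry(self):
        tree = random_ultrametric_tree(12, seed=3)
        h = tree.height()
        dm = cophenetic_matrix(tree)
        assert dm.values.max() <= 2 * h + 1e-9
        # tips on opposite sides of the root are exactly 2h apart
        children = tree.children()
        sides = []
        for c in children[0]:
            stack, tips = [c], []
            while stack:
                x = stack.pop()
                if not children[x]:
                    tips.append(tree.labels[x])
                stack.extend(children[x])
            sides.append(tips)
        i = dm.positions([sides[0][0]])[0]
        j = dm.positions([sides[1][0]])[0]
        assert dm.values[i, j] == pytest.approx(2 * h)

    def test_matches_brute_force_path_walk_oracle(self):
        for seed in (1, 2, 3):
            tree = random_ultrametric_tree(20, seed=seed)
            dm = cophenetic_matrix(tree)
            tips = tree.tip_indices()
            labels = [tree.labels[i] for i in tips]
            for a, b in itertools.combinations(range(len(tips)), 2):
                expected = brute_force_path_distance(tree, int(tips[a]), int(tips[b]))
                ia, ib = dm.positions([labels[a], labels[b]])
                assert dm.values[ia, ib] == pytest.approx(expected, abs=1e-12)

    def test_matches_dendropy_distance_matrix(self):
        """Independent library cross-check on a nonultrametric tree."""
        newick = "((A:1.5,B:2.5):0.5,(C:0.7,(D:0.2,E:0.9):0.3):1.1);"
        tree = Phylogeny.from_newick(newick)
        dm = cophenetic_matrix(tree)
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        for a, b in itertools.combinations("ABCDE", 2):
            ia, ib = dm.positions([a, b])
            assert dm.values[ia, ib] == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-12
            )

    def test_triangle_inequality(self):
        tree = random_ultrametric_tree(15, seed=9)
        d = cophenetic_matrix(tree).values
        n = d.shape[0]
        for a, b, c in itertools.combinations(range(n), 3):
            assert d[a, b] <= d[a, c] + d[c, b] + 1e-9


class TestMPD:
    def test_pair_community(self, two_tip_tree):
        dm = cophenetic_matrix(two_tip_tree)
        assert mpd(["A", "B"], dm) == pytest.approx(10.0)

    def test_three_species_mean_of_pairs(self):
        dm = DistanceMatrix(
            np.array([[0.0, 4.0, 6.0], [4.0, 0.0, 8.0], [6.0, 8.0, 0.0]]),
            ["a", "b", "c"],
        )
        assert mpd(["a", "b", "c"], dm) == pytest.approx(6.0)

    def test_missing_species_named_in_error(self, two_tip_tree):
        dm = cophenetic_matrix(two_tip_tree)
        with pytest.raises(KeyError, match="ghost"):
            mpd(["A", "ghost"], dm)

    def test_fuzz_against_brute_force_pair_mean(self, rng):
        """1,000 random communities: MPD equals the explicit double loop."""
        tree = random_ultrametric_tree(30, seed=17)
        dm = cophenetic_matrix(tree)
        labels = np.array(dm.labels)
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            comm = list(labels[rng.choice(len(labels), size=k, replace=False)])
            idx = dm.positions(comm)
            expected = np.mean(
                [dm.values[a, b] for a, b in itertools.combinations(idx, 2)]
            )
            assert mpd(comm, dm) == pytest.approx(expected, rel=1e-12)


class TestMPDSes:
    def test_community_equal_to_pool_is_degenerate(self):
        tree = random_ultrametric_tree(8, seed=2)
        dm = cophenetic_matrix(tree)
        pool = dm.labels
        res = mpd_ses(pool, dm, pool, n_null=99, seed_or_rng=1)
        assert res.degenerate
        assert res.ses == 0.0
        assert res.null_sd == 0.0

    def test_mean_ses_near_zero_for_random_communities(self, rng):
        """Null self-consistency: random communities from the pool give
        mean ses within 3 SE of 0 over 500 communities."""
        tree = random_ultrametric_tree(120, seed=4)
        dm = cophenetic_matrix(tree)
        pool = dm.labels
        ses = []
        for _ in range(500):
            comm = list(
                np.array(pool)[rng.choice(len(pool), size=12, replace=False)]
            )
            ses.append(mpd_ses(comm, dm, pool, n_null=199, seed_or_rng=rng).ses)
        ses = np.array(ses)
        se = ses.std(ddof=1) / np.sqrt(ses.size)
        assert abs(ses.mean()) < 3 * se

    def test_most_distant_pair_is_extreme(self):
        """The two most distantly related tips: ses > 0 and rank_p <= 0.05,
        cross-checked by exhaustive enumeration of all 45 pairs."""
        newick = (
            "(((a:9.0,b:1.0):1.0,(c:2.0,d:2.5):1.5):1.0,"
            "((e:3.0,f:4.0):2.0,((g:6.5,h:2.0):1.0,(i:1.2,j:0.7):4.0):0.5):3.0);"
        )
        dm = cophenetic_matrix(Phylogeny.from_newick(newick))
        pairs = list(itertools.combinations(dm.labels, 2))
        pair_mpds = {p: mpd(list(p), dm) for p in pairs}
        best = max(pair_mpds, key=pair_mpds.get)
        # exhaustive: fraction of pairs at least as distant
        exceed = np.mean([pair_mpds[p] >= pair_mpds[best] for p in pairs])
        assert exceed <= 0.05  # ties at the maximum are rare in a random tree
        res = mpd_ses(list(best), dm, dm.labels, n_null=999, seed_or_rng=0)
        assert res.ses > 0
        assert res.rank_p <= 0.05

    def test_ses_invariant_to_branch_length_scaling(self, rng):
        tree = random_ultrametric_tree(40, seed=6)
        scaled = Phylogeny(tree.parent, tree.edge_length * 7.3, tree.labels)
        dm1, dm2 = cophenetic_matrix(tree), cophenetic_matrix(scaled)
        pool = dm1.labels
        comm = list(np.array(pool)[rng.choice(len(pool), size=8, replace=False)])
        a = mpd_ses(comm, dm1, pool, n_null=199, seed_or_rng=42)
        b = mpd_ses(comm, dm2, pool, n_null=199, seed_or_rng=42)
        assert a.ses == pytest.approx(b.ses, rel=1e-9)
        assert a.rank_p == b.rank_p

    def test_community_not_in_pool_rejected(self, balanced_tree_10):
        dm = cophenetic_matrix(balanced_tree_10)
        with pytest.raises(ValueError, match="not in pool"):
            mpd_ses(dm.labels[:3], dm, dm.labels[3:], n_null=99, seed_or_rng=0)


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self):
        tree = random_ultrametric_tree(10, seed=1)
        out = resolve_polytomies(tree, 0)
        assert out.n_nodes == tree.n_nodes
        assert np.allclose(
            cophenetic_matrix(out).values, cophenetic_matrix(tree).values
        )

    def test_trifurcation_uniform_over_three_resolutions(self):
        """(a,b,c) polytomy: the three labelled resolutions appear with
        equal frequency (chi-square over 3,000 draws)."""
        tree = Phylogeny([-1, 0, 0, 0], [0, 1.0, 1.0, 1.0], [None, "a", "b", "c"])
        counts = {"a": 0, "b": 0, "c": 0}  # keyed by the odd tip out
        rng = np.random.default_rng(123)
        for _ in range(3000):
            out = resolve_polytomies(tree, rng)
            assert out.is_binary()
            children = out.children()
            root_kids = children[0]
            # odd one out = the tip that is a direct child of the root
            solo = [out.labels[c] for c in root_kids if not children[c]]
            assert len(solo) == 1
            counts[solo[0]] += 1
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 0.001

    def test_distances_preserved_by_zero_length_insertion(self):
        newick = "((a:1,b:1,c:1,d:1):1,(e:2,f:2,g:2):0.5);"
        tree = Phylogeny.from_newick(newick)
        assert tree.has_polytomies()
        before = cophenetic_matrix(tree)
        out = resolve_polytomies(tree, 7)
        assert out.is_binary()
        after = cophenetic_matrix(out)
        order = [after.positions([l])[0] for l in before.labels]
        assert np.allclose(before.values, after.values[np.ix_(order, order)])

    def test_mpd_identical_across_resolutions(self):
        tree = Phylogeny.from_newick("((a:1,b:1,c:1,d:1):1,(e:2,f:2,g:2):0.5);")
        comm = ["a", "c", "e", "g"]
        vals = {
            round(mpd(comm, cophenetic_matrix(resolve_polytomies(tree, s))), 12)
            for s in range(20)
        }
        assert len(vals) == 1
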