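"""p-distance computation and neighbor-joining reconstruction."""

import dendropy
import numpy as np
import pytest

from mitochar.distance_phylo import (
    AlignmentMatrix,
    PDistanceMatrix,
    UndefinedDistanceError,
    neighbor_joining,
    p_distance,
)
from mitochar.synth_data import (
    expected_p_distance,
    random_additive_tree,
    simulate_alignment,
)


def topo_equal(nwk_a: str, nwk_b: str) -> bool:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=nwk_a, schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=nwk_b, schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGTAC", "ACGTAC"])
        assert p_distance(aln).d[0, 1] == 0.0

    def test_one_in_four_differs(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGT", "ACGA"])
        assert p_distance(aln).d[0, 1] == pytest.approx(0.25)

    def test_complete_deletion_hand_count(self):
        aln = AlignmentMatrix(["r1", "r2", "r3"], ["AC-T", "ACGT", "ACGA"])
        dm = p_distance(aln, mode="complete")
        assert dm.get("r1", "r2") == pytest.approx(0.0)
        assert dm.get("r1", "r3") == pytest.approx(1 / 3)
        assert dm.get("r2", "r3") == pytest.approx(1 / 3)

    def test_pairwise_deletion_hand_count(self):
        aln = AlignmentMatrix(["r1", "r2", "r3"], ["AC-T", "ACGT", "ACGA"])
        dm = p_distance(aln, mode="pairwise")
        assert dm.get("r1", "r2") == pytest.approx(0.0)
        assert dm.get("r2", "r3") == pytest.approx(0.25)
        assert dm.get("r1", "r3") == pytest.approx(1 / 3)

    def test_modes_agree_without_missing_data(self):
        rng = np.random.default_rng(0)
        aln, _ = simulate_alignment("((a:1,b:1):1,(c:1,d:1));", 500, 0.1, 3)
        d1 = p_distance(aln, "complete").d
        d2 = p_distance(aln, "pairwise").d
        assert np.allclose(d1, d2)

    def test_symmetry_and_zero_diagonal(self):
        aln, _ = simulate_alignment("((a:1,b:1):1,(c:1,d:1));", 300, 0.2, 5)
        d = p_distance(aln).d
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_ambiguity_treated_as_missing(self):
        aln = AlignmentMatrix(["a", "b"], ["ARGT", "AAGT"])
        # column 2 excluded: 0 differences over 3 sites
        assert p_distance(aln, "pairwise").d[0, 1] == 0.0

    def test_no_comparable_sites_raises(self):
        aln = AlignmentMatrix(["a", "b"], ["NN", "AC"])
        with pytest.raises(UndefinedDistanceError, match="a and b"):
            p_distance(aln, mode="pairwise")


class TestNeighborJoining:
    def test_four_taxon_additive_split_recovered(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:1))
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        dm = PDistanceMatrix(["A", "B", "C", "D"], D, "complete")
        out = neighbor_joining(dm)
        assert topo_equal(out, "((A:1,B:2):1,(C:3,D:1));")

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        out = neighbor_joining(PDistanceMatrix(["a", "b", "c"], D, "complete"))
        t = dendropy.Tree.get(data=out, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["c"] == pytest.approx((0.4 + 0.5 - 0.3) / 2)

    def test_equal_distances_deterministic(self):
        D = np.full((5, 5), 0.5)
        np.fill_diagonal(D, 0)
        dm = PDistanceMatrix(list("abcde"), D, "complete")
        assert neighbor_joining(dm) == neighbor_joining(dm)

    def test_additive_matrices_recover_topology(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            nwk, D, taxa = random_additive_tree(n, rng)
            dm = PDistanceMatrix(taxa, D, "complete")
            assert topo_equal(neighbor_joining(dm), nwk)

    def test_agrees_with_skbio_on_additive_matrix(self):
        """Independent cross-check against another NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(3)
        nwk, D, taxa = random_additive_tree(6, rng)
        D = (D + D.T) / 2  # exact symmetry for skbio's validator
        ours = neighbor_joining(PDistanceMatrix(taxa, D, "complete"))
        theirs = sk_nj(SkDM(D, ids=taxa))
        assert topo_equal(ours, str(theirs))

    def test_non_finite_distance_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(PDistanceMatrix(["a", "b"], D, "complete"))


class TestSimulatedAlignments:
    def test_zero_substitution_probability_identical_rows(self):
        aln, _ = simulate_alignment("((a:1,b:1):1,(c:1,d:1));", 200, 0.0, 1)
        assert len(set(aln.rows)) == 1
        assert np.allclose(p_distance(aln).d, 0)

    def test_two_taxon_closed_form_within_three_se(self):
        q, sites = 0.08, 10000
        aln, _ = simulate_alignment("(a:1,b:1);", sites, q, 17)
        observed = p_distance(aln).d[0, 1]
        expected = expected_p_distance(q, 2)
        se = np.sqrt(expected * (1 - expected) / sites)
        assert abs(observed - expected) <= 3 * se

    def test_six_taxon_topology_recovery_rate(self):
        """NJ on simulated matrices recovers the generating topology in at
        least 95 of 100 seeds at moderate divergence."""
        tree = "((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);"
        wins = 0
        for seed in range(100):
            aln, _ = simulate_alignment(tree, 2000, 0.05, seed)
            out = neighbor_joining(p_distance(aln))
            wins += topo_equal(out, tree)
        assert wins >= 95
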