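"""Distances, neighbor joining, bootstrap, and Newick round-trips."""

import math

import dendropy
import numpy as np
import pytest

from fadskit.phylo import (
    DistanceMatrix,
    NewickParseError,
    NoComparableColumnsError,
    ProteinAlignment,
    SaturationError,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
    parse_newick,
    read_phylip_dm,
    reroot_at_leaf,
    robinson_foulds,
    to_newick,
    tree_path_distances,
    write_phylip_dm,
)
from fadskit.synth import random_tree, two_clade_alignment


class TestDistances:
    def test_p_distance_one_in_four(self):
        dm = pairwise_distance(ProteinAlignment(["a", "b"], ["AAAA", "AAAT"]), "p")
        assert dm[("a", "b")] == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        dm = pairwise_distance(ProteinAlignment(["a", "b"], ["AA-A", "AATA"]), "p")
        assert dm[("a", "b")] == 0.0

    def test_poisson_closed_form(self):
        dm_p = pairwise_distance(ProteinAlignment(["a", "b"], ["AAAA", "AAAT"]), "p")
        dm_c = pairwise_distance(
            ProteinAlignment(["a", "b"], ["AAAA", "AAAT"]), "poisson"
        )
        assert dm_c[("a", "b")] == pytest.approx(-math.log(0.75))
        assert dm_c[("a", "b")] >= dm_p[("a", "b")]

    def test_poisson_dominates_p(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = ["".join(rng.choice(list(aa), 120)) for _ in range(5)]
        ids = [f"s{i}" for i in range(5)]
        p = pairwise_distance(ProteinAlignment(ids, rows), "p").values
        c = pairwise_distance(ProteinAlignment(ids, rows), "poisson").values
        assert np.all(c >= p)
        assert np.allclose(np.diagonal(c), 0)
        assert np.allclose(c, c.T)

    def test_no_comparable_columns_names_the_pair(self):
        with pytest.raises(NoComparableColumnsError, match="a.*b"):
            pairwise_distance(ProteinAlignment(["a", "b"], ["A-", "-A"]), "p")

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            pairwise_distance(
                ProteinAlignment(["a", "b"], ["AAAA", "TTTT"]), "poisson"
            )

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        )
        tree = neighbor_joining(dm)
        limbs = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert limbs == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})
        assert to_newick(tree) == "(A:0.5,B:1.5,C:2.5);"

    def test_four_taxon_additive(self):
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert {frozenset(s) for s in tree.bipartitions()} in (
            {frozenset("AB")},
            {frozenset("CD")},
        )
        limbs = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert limbs == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})
        got = tree_path_distances(tree)
        idx = [got.labels.index(x) for x in "ABCD"]
        assert np.allclose(got.values[np.ix_(idx, idx)], d, atol=1e-12)

    def test_all_zero_distances_gives_zero_limbs(self):
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), np.zeros((4, 4))))
        for node in tree.root.walk():
            if node is not tree.root:
                assert node.length == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_agrees_with_dendropy_on_random_additive_matrices(self):
        # independent implementation cross-check (topology only)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            true = random_tree(int(rng.integers(5, 11)), rng)
            dm = tree_path_distances(true)
            mine = neighbor_joining(dm)

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_dm_to_csv(dm), delimiter=","
            )
            theirs = pdm.nj_tree()
            tns = theirs.taxon_namespace
            mine_dp = dendropy.Tree.get(
                data=to_newick(mine), schema="newick", taxon_namespace=tns
            )
            mine_dp.encode_bipartitions()
            theirs.encode_bipartitions()
            assert (
                dendropy.calculate.treecompare.symmetric_difference(
                    mine_dp, theirs
                )
                == 0
            )

    def test_deterministic_tie_breaking(self):
        dm = DistanceMatrix(list("ABCD"), np.ones((4, 4)) - np.eye(4))
        assert to_newick(neighbor_joining(dm)) == to_newick(neighbor_joining(dm))


def _dm_to_csv(dm):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(dm.labels) + "\n")
    for lbl, row in zip(dm.labels, dm.values):
        buf.write(lbl + "," + ",".join(str(x) for x in row) + "\n")
    buf.seek(0)
    return buf


class TestNewick:
    def test_roundtrip_random_trees(self):
        for seed in range(20):
            tree = random_tree(20, seed)
            text = to_newick(tree)
            back = parse_newick(text)
            assert robinson_foulds(tree, back) == 0
            d1 = tree_path_distances(tree)
            d2 = tree_path_distances(back)
            idx = [d2.labels.index(x) for x in d1.labels]
            assert np.allclose(d1.values, d2.values[np.ix_(idx, idx)], atol=1e-9)
            assert to_newick(back) == text

    def test_two_leaf_degenerate_accepted(self):
        tree = parse_newick("(A:1,B:2);")
        assert tree.leaf_names() == ["A", "B"]

    def test_supports_roundtrip(self):
        text = "((A:1,B:1)97:0.5,(C:1,D:1)63:0.5,E:2);"
        tree = parse_newick(text)
        assert sorted(
            v for v in tree.bipartitions().values() if v is not None
        ) == [63, 97]
        assert to_newick(tree) == text

    @pytest.mark.parametrize("bad", ["(A,B", "(A:x,B:1);", "(A,B)", ";", "(,);"])
    def test_malformed_reports_offset(self, bad):
        with pytest.raises(NewickParseError) as err:
            parse_newick(bad)
        assert err.value.offset >= 0


class TestBootstrap:
    def test_two_clade_central_support_high(self):
        aln = two_clade_alignment(n_per_clade=4, n_columns=200, seed=11)
        tree = bootstrap_support(aln, iterations=100, seed=5)
        central = frozenset(name for name in aln.ids if name.startswith("B"))
        bips = tree.bipartitions()
        ref = min(aln.ids)
        key = central if ref not in central else frozenset(aln.ids) - central
        assert bips[key] >= 95

    def test_same_seed_identical(self):
        aln = two_clade_alignment(seed=2)
        t1 = bootstrap_support(aln, iterations=30, seed=9)
        t2 = bootstrap_support(aln, iterations=30, seed=9)
        assert t1.bipartitions() == t2.bipartitions()
        assert to_newick(t1) == to_newick(t2)

    def test_single_iteration_supports_binary(self):
        aln = two_clade_alignment(seed=3)
        tree = bootstrap_support(aln, iterations=1, seed=1)
        values = {v for v in tree.bipartitions().values() if v is not None}
        assert values <= {0, 100}

    def test_supports_cover_exactly_internal_edges(self):
        aln = two_clade_alignment(seed=4)
        point = neighbor_joining(pairwise_distance(aln))
        boot = bootstrap_support(aln, iterations=10, seed=0)
        assert set(boot.bipartitions()) == set(point.bipartitions())
        assert all(
            v is not None and 0 <= v <= 100
            for v in boot.bipartitions().values()
        )


class TestUtilities:
    def test_phylip_roundtrip(self, tmp_path):
        tree = random_tree(6, 1)
        dm = tree_path_distances(tree)
        path = tmp_path / "dm.phy"
        write_phylip_dm(dm, path)
        back = read_phylip_dm(path)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-8)

    def test_reroot_at_leaf_preserves_distances(self):
        tree = random_tree(8, 5)
        before = tree_path_distances(tree)
        rerooted = reroot_at_leaf(parse_newick(to_newick(tree)), "T03")
        after = tree_path_distances(rerooted)
        idx = [after.labels.index(x) for x in before.labels]
        assert np.allclose(before.values, after.values[np.ix_(idx, idx)], atol=1e-9)
        assert {c.name for c in rerooted.root.children if c.is_leaf} == {"T03"}
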