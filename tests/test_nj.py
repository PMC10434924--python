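import numpy as np
import pytest

from thripspop import distances, nj, simulate
from thripspop.distances import DistanceMatrix


def random_additive_tree(rng, n):
    """Random binary tree with uniform branch lengths; returns the leaf-path
    distance matrix and the set of non-trivial bipartitions (the oracle)."""
    nodes = [frozenset([i]) for i in range(n)]
    children: dict[frozenset, tuple] = {}
    lengths: dict[frozenset, float] = {s: rng.uniform(0.05, 1.0) for s in nodes}
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        children[merged] = (nodes[i], nodes[j])
        lengths[merged] = rng.uniform(0.05, 1.0)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    # join the last two with a single internal edge (its length is the sum)
    root_split = (nodes[0], nodes[1])

    def depth(leaf, clade):
        if clade == frozenset([leaf]):
            return lengths[clade]
        if leaf not in clade:
            return None
        a, b = children[clade]
        sub = depth(leaf, a if leaf in a else b)
        return sub + lengths[clade]

    dmat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            for top in root_split:
                if a in top and b in top:
                    clade = top
                    while True:
                        ca, cb = children[clade]
                        nxt = ca if (a in ca and b in ca) else (cb if (a in cb and b in cb) else None)
                        if nxt is None:
                            break
                        clade = nxt
                    ca, cb = children[clade]
                    d = depth(a, ca if a in ca else cb) + depth(b, ca if b in ca else cb)
                    break
            else:
                d = depth(a, root_split[0] if a in root_split[0] else root_split[1]) + \
                    depth(b, root_split[0] if b in root_split[0] else root_split[1])
            dmat[a, b] = dmat[b, a] = d
    splits = set()
    for clade in children:
        if 1 < len(clade) < n - 1:
            splits.add(min(clade, frozenset(range(n)) - clade, key=sorted))
    for top in root_split:
        if 1 < len(top) < n - 1:
            splits.add(min(top, frozenset(range(n)) - top, key=sorted))
    return dmat, splits


def tree_bipartitions(tree, labels):
    n = len(labels)
    idx = {lab: k for k, lab in enumerate(labels)}
    splits = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        clade = frozenset(idx[l.taxon.label] for l in node.leaf_iter())
        if 1 < len(clade) < n - 1:
            splits.add(min(clade, frozenset(range(n)) - clade, key=sorted))
    return splits


def patristic(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj.neighbor_joining(DistanceMatrix(["a", "b", "c"], d, "p"))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_additive_matrix_recovered(self):
        # hand-built tree: ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0.0],
        ])
        labels = ["a", "b", "c", "d"]
        tree = nj.neighbor_joining(DistanceMatrix(labels, d, "p"))
        assert tree_bipartitions(tree, labels) == {frozenset({0, 1})}
        assert np.allclose(patristic(tree, labels), d, atol=1e-9)

    def test_equidistant_taxa_equal_pendant_lengths(self):
        d = np.full((4, 4), 0.4) - 0.4 * np.eye(4)
        tree = nj.neighbor_joining(DistanceMatrix(list("abcd"), d, "p"))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert all(v == pytest.approx(0.2) for v in lengths.values())

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj.neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))

    def test_random_additive_trees_recovered(self):
        """NJ is consistent on additive distances: topology and path lengths
        of random trees (n <= 12) are reproduced exactly."""
        rng = np.random.default_rng(123)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            dmat, splits = random_additive_tree(rng, n)
            labels = [f"t{k}" for k in range(n)]
            tree = nj.neighbor_joining(DistanceMatrix(labels, dmat, "p"),
                                       clamp_negative=False)
            assert tree_bipartitions(tree, labels) == splits, f"trial {trial}"
            assert np.allclose(patristic(tree, labels), dmat, atol=1e-9)


class TestRooting:
    @pytest.fixture()
    def four_taxon_tree(self):
        d = np.array([
            [0, 3, 8, 9],
            [3, 0, 9, 10],
            [8, 9, 0, 9],
            [9, 10, 9, 0.0],
        ])
        return nj.neighbor_joining(DistanceMatrix(list("abcd"), d, "p"))

    def test_root_bipartition_isolates_outgroup(self, four_taxon_tree):
        rooted = nj.root_with_outgroup(four_taxon_tree, "d")
        kids = rooted.seed_node.child_nodes()
        sides = [sorted(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert ["d"] in sides
        assert sorted(sides, key=len)[-1] == ["a", "b", "c"]

    def test_rooting_is_idempotent(self, four_taxon_tree):
        r1 = nj.root_with_outgroup(four_taxon_tree, "d")
        r2 = nj.root_with_outgroup(r1, "d")
        def sides(t):
            return sorted(
                tuple(sorted(l.taxon.label for l in k.leaf_iter()))
                for k in t.seed_node.child_nodes())
        assert sides(r1) == sides(r2)

    def test_missing_outgroup_rejected(self, four_taxon_tree):
        with pytest.raises(KeyError):
            nj.root_with_outgroup(four_taxon_tree, "zz")

    def test_leafset_conserved_through_rooting(self, four_taxon_tree):
        rooted = nj.root_with_outgroup(four_taxon_tree, "a")
        assert {l.taxon.label for l in rooted.leaf_node_iter()} == set("abcd")


class TestGroupAssignment:
    def rooted_panel_tree(self, panel):
        tab = panel.haplotypes
        out_seq = simulate._mutate(np.random.default_rng(9), tab["H1"].sequence, 83)
        dm = distances.distance_matrix(
            tab.names + ["OUTGROUP"],
            [h.sequence for h in tab] + [out_seq], "p")
        return nj.root_with_outgroup(nj.neighbor_joining(dm), "OUTGROUP")

    def test_two_lineage_clades_recovered_on_panel(self, panel):
        """Anchored assignment splits the ingroup into two clades: one pure
        group-1 clade around H1, and one containing every group-2 haplotype.
        The handful of intermediate thelytokous-fragment haplotypes (the
        H6/H7 cluster) and HU58 sit on the group-2 side of the distance
        tree, between the two cores."""
        rooted = self.rooted_panel_tree(panel)
        asg = nj.assign_groups(rooted, {"group1": ["H1"], "group2": ["H8"]})
        g1 = {h for h, g in asg.items() if g == "group1"}
        g2 = {h for h, g in asg.items() if g == "group2"}
        true_g2 = {h for h, g in panel.groups.items() if g == "group2"}
        assert g1 and g1 <= {h for h, g in panel.groups.items() if g == "group1"}
        assert true_g2 <= g2
        assert "H2" in g1 and "H28" in g2
        assert asg["OUTGROUP"] == "ungrouped"

    def test_every_leaf_assigned_exactly_once(self, panel):
        rooted = self.rooted_panel_tree(panel)
        asg = nj.assign_groups(rooted, {"group1": ["H1"], "group2": ["H8"]})
        assert set(asg) == {h.name for h in panel.haplotypes} | {"OUTGROUP"}

    def test_single_group_anchors_leave_rest_ungrouped_or_grouped(self):
        d = np.array([
            [0, 0.1, 0.5, 0.5],
            [0.1, 0, 0.5, 0.5],
            [0.5, 0.5, 0, 0.1],
            [0.5, 0.5, 0.1, 0.0],
        ])
        tree = nj.neighbor_joining(DistanceMatrix(list("abcd"), d, "p"))
        rooted = nj.root_with_outgroup(tree, "d")
        asg = nj.assign_groups(rooted, {"group1": ["a"]})
        assert set(asg.values()) <= {"group1", "ungrouped"}
        assert asg["a"] == asg["b"] == "group1"

    def test_overlapping_anchor_clades_rejected(self, panel):
        rooted = self.rooted_panel_tree(panel)
        with pytest.raises((ValueError, KeyError)):
            nj.assign_groups(rooted, {"group1": ["H1", "H28"], "group2": ["H8"]})

    def test_missing_anchor_rejected(self, panel):
        rooted = self.rooted_panel_tree(panel)
        with pytest.raises(KeyError):
            nj.assign_groups(rooted, {"group1": ["nope"]})


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.7], [0.6, 0.7, 0.0]])
        tree = nj.neighbor_joining(DistanceMatrix(["a", "b", "c"], d, "p"))
        nj.write_newick(tree, tmp_path / "t.nwk")
        back = nj.read_newick(tmp_path / "t.nwk")
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"a", "b", "c"}
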