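"""Neighbor-Joining trees, outgroup rooting, and anchored group assignment.

The joining loop is the classic Saitou-Nei agglomeration: at each step the
pair minimising the Q criterion is joined, branch lengths to the new node are
computed from the row sums, and the distance matrix is reduced.  Ties in the
Q matrix are broken by the lowest (row, column) index pair so trees are
bit-reproducible for a fixed label order.  Trees are held as dendropy
objects, which also supply Newick reading/writing and rooting.

Group assignment mirrors how barcoding surveys delimit mitochondrial
lineages: each group is seeded with anchor haplotypes of known identity and
grows to the largest rooted clade that contains all of its anchors and none
of any other group's anchors; leaves caught in no such clade are left
ungrouped.
"""
from __future__ import annotations

import numpy as np
import dendropy

from .distances import DistanceMatrix


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> dendropy.Tree:
    """Build an unrooted NJ tree from a labeled symmetric distance matrix."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError(f"need at least 3 taxa, got {n}")
    d = np.array(dm.values, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("asymmetric distance matrix")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)

    def clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) tie-break in current active order
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        vi = clamp(0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = clamp(sub[i, j] - (0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = vi
        nodes[aj].edge.length = vj
        # reduce: reuse slot ai for the new node
        for k in active:
            if k in (ai, aj):
                continue
            dk = 0.5 * (d[ai, k] + d[aj, k] - d[ai, aj])
            d[ai, k] = d[k, ai] = dk
        nodes[ai] = parent
        active.remove(aj)

    # join the final three around a central node (closed form)
    a, b, c = active
    center = dendropy.Node()
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = ln
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root the tree on the outgroup's pendant edge (bisecting it)."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_label:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"outgroup label {outgroup_label!r} not found in tree")
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def assign_groups(tree: dendropy.Tree, anchors: dict[str, list[str]]) -> dict[str, str]:
    """Assign every leaf to a group keyed by anchor leaves, or 'ungrouped'.

    For each group the assigned clade is the largest rooted clade containing
    all of that group's anchors and none of any other group's anchors.
    Raises ValueError if the resulting clades overlap.
    """
    all_leaves = _leafset(tree.seed_node)
    for g, labs in anchors.items():
        missing = set(labs) - all_leaves
        if missing:
            raise KeyError(f"group {g!r}: anchor leaves {sorted(missing)} not in tree")
    clades: dict[str, frozenset[str]] = {}
    for g, labs in anchors.items():
        others = {lab for og, olabs in anchors.items() if og != g for lab in olabs}
        taxa = [tree.taxon_namespace.get_taxon(lab) for lab in labs]
        node = tree.mrca(taxa=taxa) if len(taxa) > 1 else next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == labs[0]
        )
        if _leafset(node) & others:
            raise ValueError(
                f"group {g!r}: smallest clade containing its anchors already "
                f"contains another group's anchors; anchor sets do not form "
                f"disjoint clades"
            )
        while node.parent_node is not None:
            parent_leaves = _leafset(node.parent_node)
            if parent_leaves & others or parent_leaves == all_leaves:
                break
            node = node.parent_node
        clades[g] = _leafset(node)
    groups = sorted(clades)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            shared = clades[g1] & clades[g2]
            if shared:
                raise ValueError(
                    f"groups {g1!r} and {g2!r} resolve to overlapping clades "
                    f"(shared leaves e.g. {sorted(shared)[:5]})"
                )
    assignment = {}
    for leaf in sorted(all_leaves):
        for g in groups:
            if leaf in clades[g]:
                assignment[leaf] = g
                break
        else:
            assignment[leaf] = "ungrouped"
    return assignment


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
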