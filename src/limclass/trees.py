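"""Newick I/O and the tree algorithms the classification pipeline needs.

The analysis works on three kinds of trees: gene trees whose leaves are
individual LIM domains (labelled ``<protein>.<ordinal>``, e.g.
``Hs_ABLIM2.B``), a human-only gene tree, and a small rooted species tree.
The operations here are the ones the homology-group construction requires:
pruning with path-length preservation, strict consensus (the tree containing
exactly the bipartitions shared by both inputs), midpoint rooting (with
either branch lengths or unit edge lengths, for cladograms), and extraction
of the clades radiating from the root.

Trees are :class:`dendropy.Tree` objects throughout; every function returns
a new tree and leaves its input untouched.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "read_newick",
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "nontrivial_bipartitions",
    "prune_to",
    "strict_consensus",
    "midpoint_root",
    "basal_clades",
    "leaf_path_distances",
    "tree_diameter",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree-operation inputs."""


def parse_newick(newick: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string into a tree.

    Duplicate leaf labels and unbalanced parentheses raise :class:`TreeError`
    carrying the parser's position information.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def read_newick(path: str, rooted: bool | None = None) -> dendropy.Tree:
    """Read a Newick file (single tree, lengths optional, multifurcations OK)."""
    with open(path) as handle:
        return parse_newick(handle.read(), rooted=rooted)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as handle:
        handle.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=False,
    )


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _clade_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial splits of the tree, read as unrooted.

    Each split is stored canonically as the side *not* containing the
    lexicographically smallest leaf label, so splits from different trees
    over the same leaf set compare directly.
    """
    leaves = leaf_labels(tree)
    n = len(leaves)
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = _clade_labels(node)
        if 1 < len(clade) < n - 1:
            side = clade if ref not in clade else leaves - clade
            if 1 < len(side) < n - 1:
                splits.add(side)
    return splits


def prune_to(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict the tree to ``keep``, contracting paths.

    Suppressed degree-2 nodes have their branch lengths summed, so pairwise
    path distances among the kept leaves are unchanged.
    """
    keep = frozenset(keep)
    leaves = leaf_labels(tree)
    missing = keep - leaves
    if missing:
        raise TreeError(
            "prune_to: labels not in tree: " + ", ".join(sorted(missing))
        )
    if len(keep) < 2:
        raise TreeError("prune_to: need at least 2 leaves to keep")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    pruned.purge_taxon_namespace()
    return pruned


def strict_consensus(t1: dendropy.Tree, t2: dendropy.Tree) -> dendropy.Tree:
    """Strict consensus of two trees over an identical leaf set.

    The result is an unrooted cladogram (no branch lengths) whose internal
    edges are exactly the bipartitions present in both inputs.
    """
    leaves1, leaves2 = leaf_labels(t1), leaf_labels(t2)
    if leaves1 != leaves2:
        raise TreeError(
            "strict_consensus: leaf sets differ "
            f"(only in first: {sorted(leaves1 - leaves2)}; "
            f"only in second: {sorted(leaves2 - leaves1)})"
        )
    shared = nontrivial_bipartitions(t1) & nontrivial_bipartitions(t2)
    return tree_from_splits(leaves1, shared)


def tree_from_splits(
    leaves: Iterable[str], splits: Iterable[frozenset[str]]
) -> dendropy.Tree:
    """Build an unrooted cladogram from pairwise-compatible canonical splits.

    ``splits`` must be stored on the side excluding the smallest leaf label
    (the convention of :func:`nontrivial_bipartitions`); viewed as rooted at
    that reference leaf they are simply clades, so the tree is assembled by
    nesting each clade under the smallest clade that strictly contains it.
    """
    leaves = frozenset(leaves)
    ref = min(leaves)
    rest = leaves - {ref}
    clades: set[frozenset[str]] = {frozenset({x}) for x in rest}
    clades.add(frozenset(rest))
    clades.update(frozenset(s) for s in splits)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[frozenset[str], dendropy.Node] = {}
    for clade in clades:
        node = dendropy.Node()
        if len(clade) == 1:
            node.taxon = taxa.require_taxon(label=next(iter(clade)))
        nodes[clade] = node
    ordered = sorted(clades, key=len)
    for clade in ordered:
        if clade == frozenset(rest):
            continue
        parent = min(
            (c for c in clades if len(c) > len(clade) and clade < c),
            key=len,
        )
        nodes[parent].add_child(nodes[clade])
    root = nodes[frozenset(rest)]
    ref_leaf = dendropy.Node()
    ref_leaf.taxon = taxa.require_taxon(label=ref)
    root.add_child(ref_leaf)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# path distances / midpoint rooting


def _adjacency(
    tree: dendropy.Tree, unit: bool
) -> dict[dendropy.Node, list[tuple[dendropy.Node, float]]]:
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            length = 1.0 if unit else child.edge.length
            if length is None:
                raise TreeError(
                    "midpoint_root(lengths='branch') requires branch lengths "
                    "on every edge"
                )
            if length < 0:
                raise TreeError("negative branch length")
            adj.setdefault(node, []).append((child, length))
            adj.setdefault(child, []).append((node, length))
    return adj


def _distances_from(
    start: dendropy.Node,
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]],
) -> tuple[dict[dendropy.Node, float], dict[dendropy.Node, dendropy.Node]]:
    dist = {start: 0.0}
    prev: dict[dendropy.Node, dendropy.Node] = {}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, length in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + length
                prev[nbr] = node
                stack.append(nbr)
    return dist, prev


def leaf_path_distances(
    tree: dendropy.Tree, unit: bool = False
) -> dict[tuple[str, str], float]:
    """All pairwise leaf-to-leaf path lengths (unordered label pairs)."""
    adj = _adjacency(tree, unit)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(leaves):
        dist, _ = _distances_from(a, adj)
        for b in leaves[i + 1 :]:
            out[(a.taxon.label, b.taxon.label)] = dist[b]
    return out


def tree_diameter(tree: dendropy.Tree, unit: bool = False) -> float:
    return max(leaf_path_distances(tree, unit=unit).values())


def midpoint_root(tree: dendropy.Tree, lengths: str = "branch") -> dendropy.Tree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    ``lengths='branch'`` uses the stored branch lengths (all must be
    present); ``lengths='unit'`` treats every edge as length 1, which is the
    mode used for consensus cladograms. When the midpoint falls exactly on a
    node the tree is rooted at that node (producing a root polytomy whose
    children are the clades radiating from the midpoint); when it falls
    inside an edge a new root node splits that edge. Ties between equally
    long paths are broken by the lexicographically smallest endpoint pair.
    """
    if lengths not in ("branch", "unit"):
        raise ValueError("lengths must be 'branch' or 'unit'")
    unit = lengths == "unit"
    work = tree.clone(depth=1)
    adj = _adjacency(work, unit)
    leaves = sorted(work.leaf_node_iter(), key=lambda l: l.taxon.label)
    if len(leaves) < 2:
        raise TreeError("midpoint_root: need at least 2 leaves")

    best: tuple[float, str, str] | None = None
    best_pair: tuple[dendropy.Node, dendropy.Node] | None = None
    best_prev = None
    for a in leaves:
        dist, prev = _distances_from(a, adj)
        for b in leaves:
            if b is a:
                continue
            lab = tuple(sorted((a.taxon.label, b.taxon.label)))
            key = (-dist[b], lab[0], lab[1])
            if best is None or key < best:
                # orient the path from the smaller-labelled endpoint
                if a.taxon.label == lab[0]:
                    best, best_pair, best_prev = key, (a, b), prev
                else:
                    d2, p2 = _distances_from(
                        next(l for l in leaves if l.taxon.label == lab[0]), adj
                    )
                    best, best_pair, best_prev = key, (
                        next(l for l in leaves if l.taxon.label == lab[0]),
                        next(l for l in leaves if l.taxon.label == lab[1]),
                    ), p2
    assert best is not None and best_pair is not None and best_prev is not None
    diameter = -best[0]
    u, v = best_pair
    # walk v -> u via predecessors computed from u, then reverse
    path = [v]
    while path[-1] is not u:
        path.append(best_prev[path[-1]])
    path.reverse()  # now u ... v

    half = diameter / 2.0
    tol = 1e-9
    acc = 0.0
    edge_len = {
        (min(id(a), id(b)), max(id(a), id(b))): l
        for a, nbrs in adj.items()
        for b, l in nbrs
    }

    def _len(a: dendropy.Node, b: dendropy.Node) -> float:
        return edge_len[(min(id(a), id(b)), max(id(a), id(b)))]

    work.is_rooted = True
    for a, b in itertools.pairwise(path):
        step = _len(a, b)
        if abs(acc + step - half) <= tol:
            # midpoint is exactly node b
            work.reroot_at_node(b, update_bipartitions=False)
            work.is_rooted = True
            return work
        if acc + step > half:
            # midpoint inside edge a-b, at (half - acc) from a
            from_a = half - acc
            child = b if b.parent_node is a else a
            parent_side = from_a if child is b else step - from_a
            if unit:
                length1 = length2 = None
            else:
                length1 = parent_side
                length2 = step - parent_side
            work.reroot_at_edge(
                child.edge,
                length1=length1,
                length2=length2,
                update_bipartitions=False,
            )
            work.is_rooted = True
            if unit:
                for c in work.seed_node.child_nodes():
                    c.edge.length = None
            return work
        acc += step
    raise AssertionError("midpoint not located on diameter path")


def basal_clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label sets of the clades radiating from the root.

    One set per child of the root; together they partition the leaf set.
    """
    if not tree.is_rooted:
        raise TreeError("basal_clades requires a rooted tree")
    clades = [_clade_labels(child) for child in tree.seed_node.child_nodes()]
    all_leaves = leaf_labels(tree)
    union: set[str] = set()
    for clade in clades:
        if union & clade:
            raise AssertionError("basal clades are not disjoint")
        union |= clade
    if union != all_leaves:
        raise AssertionError("basal clades do not cover the leaf set")
    return clades
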