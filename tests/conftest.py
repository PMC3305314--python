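import dendropy
import numpy as np
import pytest

from limclass.signatures import load_registry
from limclass.simulate import SyntheticConfig, generate_proteome


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_cfg():
    """Four classes covering LIM-count diversity; quick to generate."""
    return SyntheticConfig(seed=11, classes=("LHX", "LMO", "ABLIM", "PXN"))


@pytest.fixture(scope="session")
def small_proteome(small_cfg):
    return generate_proteome(small_cfg)


def random_binary_tree(rng, n_leaves, with_lengths=True, prefix="L"):
    """Random binary tree over labelled leaves; unrooted semantics."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_leaves):
        node = dendropy.Node()
        node.taxon = taxa.require_taxon(label=f"{prefix}{i}")
        nodes.append(node)
    while len(nodes) > 3:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    for node in nodes:
        tree.seed_node.add_child(node)
    if with_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = float(np.round(rng.uniform(0.05, 2.0), 6))
    tree.is_rooted = False
    return tree


def independent_splits(tree):
    """Nontrivial bipartitions via direct leafset recursion (test oracle,
    written independently of the library's bipartition code)."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    out = set()

    def clade(node):
        if node.is_leaf():
            return frozenset({node.taxon.label})
        acc = frozenset()
        for child in node.child_nodes():
            acc |= clade(child)
        return acc

    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = clade(node)
        if 1 < len(side) < len(leaves) - 1:
            out.add(side if ref not in side else leaves - side)
    return {s for s in out if 1 < len(s) < len(leaves) - 1}
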