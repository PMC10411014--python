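import dendropy
import numpy as np
import pytest

from pancore import phylo, simulate


@pytest.fixture
def three_leaf_tree():
    """((A,B),C) with unit branch lengths."""
    return phylo.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_leaf_tree():
    """((A,B),(C,D)) with all branch lengths 1."""
    return phylo.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_rooted_binary_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random binary topology with random positive branch lengths."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=f"L{i}")
        node.edge.length = float(rng.uniform(0.1, 1.0))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree
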