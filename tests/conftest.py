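import dendropy
import numpy as np
import pytest

from seqfunnel.seqio import parse_newick


def random_binary_tree(labels, rng, rooted=True, lengths=True):
    """Random binary tree over ``labels`` by repeated random joins."""
    taxa = dendropy.TaxonNamespace(list(labels))
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > (2 if rooted else 3):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = rooted
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(0.1, 2.0)) if lengths else 1.0
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quartet_trees():
    """The classic conflicting pair AB|CD vs AC|BD with unit lengths."""
    t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
    return t1, t2
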