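"""Shared test helpers: independent oracles built on networkx / dendropy."""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import pytest

from qfm.phylo_core import Quartet, QuartetSet, QuartetStatus, classify


def make_tree(newick: str,
              tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=tns, preserve_underscores=True)
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()
    tree.is_rooted = False
    return tree


def tree_to_nx(tree: dendropy.Tree):
    """Undirected graph view of a dendropy tree; leaves keyed by label."""
    G = nx.Graph()
    leafmap = {}
    for nd in tree.preorder_node_iter():
        G.add_node(id(nd))
        if nd.parent_node is not None:
            G.add_edge(id(nd.parent_node), id(nd))
        if nd.is_leaf():
            leafmap[nd.taxon.label] = id(nd)
    return G, leafmap


def consistent_by_paths(tree: dendropy.Tree, quartet: Quartet) -> bool:
    """Independent consistency oracle: ab|cd holds iff the a-b path and the
    c-d path share no vertex."""
    G, leafmap = tree_to_nx(tree)
    a, b = quartet.pair_one
    c, d = quartet.pair_two
    p1 = set(nx.shortest_path(G, leafmap[a], leafmap[b]))
    p2 = set(nx.shortest_path(G, leafmap[c], leafmap[d]))
    return not (p1 & p2)


def score_by_classify(quartets: QuartetSet, partition, fn) -> float:
    """Independent partition scorer: a plain Python loop over classify()."""
    s = v = d = 0.0
    for q, w in quartets.items():
        status = classify(q, partition)
        if status is QuartetStatus.SATISFIED:
            s += w
        elif status is QuartetStatus.VIOLATED:
            v += w
        else:
            d += w
    return float(fn(s, v, d))


def _nx_binary_trees(labels):
    """All unrooted binary topologies on the labels, as networkx graphs.

    Built by inserting each successive leaf into every edge of every
    smaller tree; yields (2n-5)!! graphs.
    """
    base = nx.Graph()
    root = ("internal", 0)
    base.add_edges_from((root, lab) for lab in labels[:3])
    trees = [base]
    counter = itertools.count(1)
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for u, v in list(t.edges()):
                t2 = t.copy()
                mid = ("internal", next(counter))
                t2.remove_edge(u, v)
                t2.add_edges_from([(u, mid), (mid, v), (mid, lab)])
                nxt.append(t2)
        trees = nxt
    return trees


def _nx_to_newick(G, labels) -> str:
    internal = next(n for n in G.nodes if isinstance(n, tuple))

    def sub(node, parent):
        nbrs = [n for n in G.neighbors(node) if n != parent]
        if not nbrs:
            return str(node)
        return "(" + ",".join(sub(n, node) for n in nbrs) + ")"

    return sub(internal, None) + ";"


def all_binary_trees(labels, tns: dendropy.TaxonNamespace | None = None):
    """All unrooted binary dendropy trees on the given labels."""
    labels = list(labels)
    tns = tns if tns is not None else dendropy.TaxonNamespace()
    return [make_tree(_nx_to_newick(G, labels), tns)
            for G in _nx_binary_trees(labels)]


@pytest.fixture
def tns():
    return dendropy.TaxonNamespace()
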