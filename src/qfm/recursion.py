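"""Divide-and-conquer quartet amalgamation (the full QFM method).

Divide: bipartition the working taxon set with the MFM search, drop the
quartets the split satisfies or violates, add one fresh dummy taxon to both
halves, and send each deferred quartet to the side holding three of its
taxa with the stray taxon renamed to that dummy.  Conquer: solve both
halves recursively, then delete the dummy leaf from each subtree and join
the two attachment nodes by a new internal edge.  Subproblems with no
quartets left, or at most BASE_CASE_SIZE taxa, return a star.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional, Tuple

import dendropy

from .mfm import DIFFERENCE, ScoreFunction, Seedlike, _as_rng, mfm_bipartition
from .phylo_core import Bipartition, Quartet, QuartetSet, QuartetStatus, classify

__all__ = [
    "BASE_CASE_SIZE",
    "DummyRegistry",
    "SubProblem",
    "split_quartets",
    "star_tree",
    "merge_on_dummy",
    "qfm_tree",
]

#: Recursion stops at taxon sets of this size: every topology on <= 3 taxa
#: is a star, so no quartet information is lost.  Configurable per call.
BASE_CASE_SIZE = 3

_DUMMY_PREFIX = "__qfm_dummy_"


class DummyRegistry:
    """Issues globally unique artificial taxon names for the divide step."""

    def __init__(self, prefix: str = _DUMMY_PREFIX) -> None:
        self.prefix = prefix
        self._counter = itertools.count()
        self.joins = {}  # dummy name -> (frozenset side_a, frozenset side_b)

    def new(self, side_a: Iterable[str], side_b: Iterable[str]) -> str:
        name = f"{self.prefix}{next(self._counter)}"
        self.joins[name] = (frozenset(side_a), frozenset(side_b))
        return name

    def is_dummy(self, taxon: str) -> bool:
        return taxon.startswith(self.prefix)

    def validate(self, taxa: Iterable[str]) -> None:
        clash = sorted(t for t in taxa if t.startswith(self.prefix))
        if clash:
            raise ValueError(
                f"taxon names collide with the dummy namespace: {clash}")


class SubProblem:
    """A (taxon set, quartet set) pair at one recursion depth."""

    def __init__(self, taxa: frozenset, quartets: QuartetSet,
                 depth: int = 0) -> None:
        extra = quartets.taxa - set(taxa)
        if extra:
            raise ValueError(f"quartet taxa outside subproblem: {sorted(extra)}")
        self.taxa = frozenset(taxa)
        self.quartets = quartets
        self.depth = depth


def split_quartets(quartets: QuartetSet, partition: Bipartition,
                   dummy_a: str, dummy_b: str) -> Tuple[QuartetSet, QuartetSet]:
    """Divide a quartet set across a bipartition.

    Satisfied and violated quartets are dropped; 4-0 quartets pass intact
    to their side; 3-1 quartets go to the majority side with the minority
    taxon renamed to that side's dummy.  Weights are preserved.
    """
    extra = quartets.taxa - partition.ground_set
    if extra:
        raise ValueError(f"quartet taxa outside partition: {sorted(extra)}")
    left = QuartetSet()
    right = QuartetSet()
    for q, w in quartets.items():
        if classify(q, partition) is not QuartetStatus.DEFERRED:
            continue
        in_a = [t for t in q.taxa if t in partition.side_a]
        if len(in_a) == 4:
            left.add(q, w)
        elif len(in_a) == 0:
            right.add(q, w)
        elif len(in_a) == 3:
            (stray,) = (t for t in q.taxa if t in partition.side_b)
            left.add(q.rename({stray: dummy_a}), w)
        else:
            (stray,) = (t for t in q.taxa if t in partition.side_a)
            right.add(q.rename({stray: dummy_b}), w)
    return left, right


def star_tree(taxa: Iterable[str],
              taxon_namespace: Optional[dendropy.TaxonNamespace] = None
              ) -> dendropy.Tree:
    """Depth-one tree: one internal node adjacent to every leaf."""
    tns = (taxon_namespace if taxon_namespace is not None
           else dendropy.TaxonNamespace())
    tree = dendropy.Tree(taxon_namespace=tns)
    for t in sorted(taxa):
        tree.seed_node.new_child(taxon=tns.require_taxon(t))
    tree.is_rooted = False
    return tree


def _dummy_leaf(tree: dendropy.Tree, dummy: str) -> dendropy.Node:
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == dummy:
            return lf
    raise ValueError(f"dummy taxon {dummy!r} is not a leaf of the tree")


def merge_on_dummy(left: dendropy.Tree, right: dendropy.Tree,
                   dummy: str) -> dendropy.Tree:
    """Join two subtrees sharing a dummy leaf into one tree without it.

    Each tree is rerooted at the dummy's attachment node, the dummy leaf is
    deleted, and the two attachment nodes are joined by a new internal
    edge; any degree-2 node this leaves behind is suppressed.
    """
    if left.taxon_namespace is not right.taxon_namespace:
        raise ValueError("trees must share a taxon namespace to merge")
    overlap = ({lf.taxon.label for lf in left.leaf_node_iter()}
               & {lf.taxon.label for lf in right.leaf_node_iter()}) - {dummy}
    if overlap:
        raise ValueError(f"non-dummy leaves shared by both trees: {sorted(overlap)}")
    attach = []
    for tree in (left, right):
        nd = _dummy_leaf(tree, dummy)
        p = nd.parent_node
        tree.reroot_at_node(p, suppress_unifurcations=False)
        p.remove_child(nd)
        attach.append(p)
    attach[0].add_child(attach[1])
    left.suppress_unifurcations()
    left.is_rooted = False
    return left


def qfm_tree(taxa: Iterable[str], quartets: QuartetSet,
             fn: ScoreFunction = DIFFERENCE, seed: Seedlike = None,
             base_case_size: int = BASE_CASE_SIZE,
             taxon_namespace: Optional[dendropy.TaxonNamespace] = None
             ) -> dendropy.Tree:
    """Amalgamate a quartet set into one unrooted tree over ``taxa``.

    Recursively bipartitions the taxon set with the MFM search; each
    accepted bipartition becomes an internal edge of the output.  The
    returned tree's leaf set is exactly ``taxa`` — dummy taxa never leak.
    """
    taxa = frozenset(taxa)
    extra = quartets.taxa - taxa
    if extra:
        raise ValueError(f"quartet taxa outside input taxa: {sorted(extra)}")
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    registry = DummyRegistry()
    registry.validate(taxa)
    rng = _as_rng(seed)
    tns = (taxon_namespace if taxon_namespace is not None
           else dendropy.TaxonNamespace())

    def solve(problem: SubProblem) -> dendropy.Tree:
        if len(problem.taxa) <= base_case_size or len(problem.quartets) == 0:
            return star_tree(problem.taxa, tns)
        part = mfm_bipartition(problem.taxa, problem.quartets, fn, rng)
        dummy = registry.new(part.side_a, part.side_b)
        q_left, q_right = split_quartets(problem.quartets, part, dummy, dummy)
        left = solve(SubProblem(part.side_a | {dummy}, q_left,
                                problem.depth + 1))
        right = solve(SubProblem(part.side_b | {dummy}, q_right,
                                 problem.depth + 1))
        return merge_on_dummy(left, right, dummy)

    tree = solve(SubProblem(taxa, quartets))
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assert leaves == set(taxa), "dummy taxa leaked into the result"
    return tree
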