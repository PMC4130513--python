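"""Foundational phylogenetic types and operations.

Quartets, taxon bipartitions, quartet--bipartition classification,
quartet--tree consistency, induced (embedded) quartet decomposition and the
Robinson-Foulds error rate.  Trees are :class:`dendropy.Tree` objects with
unrooted semantics: the root is an arbitrary basal node, polytomies are
allowed, and only internal (non-trivial) edges carry topological information.
"""

from __future__ import annotations

import enum
import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Optional, Sequence, Tuple

import dendropy

__all__ = [
    "Quartet",
    "QuartetSet",
    "Bipartition",
    "QuartetStatus",
    "classify",
    "is_consistent",
    "induced_quartets",
    "count_satisfied",
    "tree_bipartitions",
    "rf_rate",
    "leaf_labels",
    "quartet_topology",
    "topological_leaf_distances",
]


class QuartetStatus(enum.Enum):
    """Status of a quartet relative to a taxon bipartition.

    SATISFIED: the two pairs lie wholly on opposite sides.
    VIOLATED:  the four taxa split 2-2 but the pairs are crossed.
    DEFERRED:  the taxa split 3-1 or 4-0 (the bipartition is uninformative
    for this quartet and it is passed on unchanged by the divide step).
    """

    SATISFIED = "satisfied"
    VIOLATED = "violated"
    DEFERRED = "deferred"


@dataclass(frozen=True)
class Quartet:
    """An unrooted 4-taxon topology ``ab|cd`` with a multiplicity weight.

    The split is stored canonically: within each pair taxa are sorted, and
    the pair with the lexicographically smaller first element comes first.
    Equality and hashing ignore the weight, so quartets on the same four
    taxa with the same split compare equal however they were written.
    """

    pair_one: Tuple[str, str]
    pair_two: Tuple[str, str]
    weight: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        a = tuple(sorted(self.pair_one))
        b = tuple(sorted(self.pair_two))
        if a > b:
            a, b = b, a
        taxa = {*a, *b}
        if len(taxa) != 4:
            raise ValueError(
                f"quartet taxa must be pairwise distinct: {a} | {b}")
        if self.weight < 0:
            raise ValueError("quartet weight must be non-negative")
        object.__setattr__(self, "pair_one", a)
        object.__setattr__(self, "pair_two", b)

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(self.pair_one + self.pair_two)

    def with_weight(self, weight: float) -> "Quartet":
        return Quartet(self.pair_one, self.pair_two, weight)

    def alternatives(self) -> Tuple["Quartet", "Quartet"]:
        """The two other topologies on the same four taxa (weight preserved)."""
        a, b = self.pair_one
        c, d = self.pair_two
        return (Quartet((a, c), (b, d), self.weight),
                Quartet((a, d), (b, c), self.weight))

    def rename(self, mapping: Dict[str, str]) -> "Quartet":
        ren = lambda t: mapping.get(t, t)
        return Quartet(tuple(map(ren, self.pair_one)),
                       tuple(map(ren, self.pair_two)), self.weight)

    def __str__(self) -> str:
        return "{},{}|{},{}".format(*self.pair_one, *self.pair_two)

    @classmethod
    def parse(cls, text: str, weight: float = 1.0) -> "Quartet":
        """Parse ``a,b|c,d`` notation."""
        halves = text.split("|")
        if len(halves) != 2:
            raise ValueError(f"expected exactly one '|' in quartet {text!r}")
        pairs = []
        for half in halves:
            names = [t for t in half.split(",") if t]
            if len(names) != 2:
                raise ValueError(
                    f"each side of a quartet needs exactly 2 taxa: {text!r}")
            pairs.append(tuple(names))
        return cls(pairs[0], pairs[1], weight)


class QuartetSet:
    """A weighted multiset of quartets over a taxon set.

    Canonically equal quartets are aggregated; the weight of an unweighted
    quartet is its multiplicity.  Iteration yields :class:`Quartet` objects
    carrying their aggregated weight.
    """

    def __init__(self, quartets: Iterable[Quartet] = ()) -> None:
        self._weights: Dict[Quartet, float] = {}
        for q in quartets:
            self.add(q)

    def add(self, quartet: Quartet, weight: Optional[float] = None) -> None:
        w = quartet.weight if weight is None else weight
        if w < 0:
            raise ValueError("weight must be non-negative")
        key = quartet if quartet.weight == 1.0 else quartet.with_weight(1.0)
        self._weights[key] = self._weights.get(key, 0.0) + w

    def update(self, other: "QuartetSet") -> None:
        for q, w in other.items():
            self.add(q, w)

    def items(self) -> Iterator[Tuple[Quartet, float]]:
        return iter(self._weights.items())

    def __iter__(self) -> Iterator[Quartet]:
        for q, w in self._weights.items():
            yield q.with_weight(w)

    def __len__(self) -> int:
        """Number of distinct canonical quartets."""
        return len(self._weights)

    def __contains__(self, quartet: Quartet) -> bool:
        return quartet in self._weights

    def weight_of(self, quartet: Quartet) -> float:
        return self._weights.get(quartet, 0.0)

    @property
    def total_weight(self) -> float:
        return sum(self._weights.values())

    @property
    def taxa(self) -> FrozenSet[str]:
        out: set = set()
        for q in self._weights:
            out.update(q.taxa)
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuartetSet):
            return NotImplemented
        return self._weights == other._weights

    def __repr__(self) -> str:
        return (f"QuartetSet({len(self._weights)} distinct, "
                f"total weight {self.total_weight:g})")


class Bipartition:
    """An unordered split of a taxon set into two disjoint non-empty sides.

    Corresponds to one internal tree edge.  Orientation-free:
    ``Bipartition(A, B) == Bipartition(B, A)``.
    """

    __slots__ = ("side_a", "side_b", "_key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]) -> None:
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if a & b:
            raise ValueError(f"bipartition sides overlap: {sorted(a & b)}")
        self.side_a = a
        self.side_b = b
        self._key = frozenset((a, b))

    @property
    def ground_set(self) -> FrozenSet[str]:
        return self.side_a | self.side_b

    @property
    def is_singleton(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    def side_of(self, taxon: str) -> int:
        if taxon in self.side_a:
            return 0
        if taxon in self.side_b:
            return 1
        raise KeyError(f"taxon {taxon!r} not in bipartition ground set")

    def move(self, taxon: str) -> "Bipartition":
        """The bipartition with ``taxon`` transferred to the other side."""
        if taxon in self.side_a:
            return Bipartition(self.side_a - {taxon}, self.side_b | {taxon})
        if taxon in self.side_b:
            return Bipartition(self.side_a | {taxon}, self.side_b - {taxon})
        raise KeyError(f"taxon {taxon!r} not in bipartition ground set")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        fmt = lambda s: "{" + ",".join(sorted(s)) + "}"
        return f"Bipartition({fmt(self.side_a)} | {fmt(self.side_b)})"


def classify(quartet: Quartet, partition: Bipartition) -> QuartetStatus:
    """Classify a quartet as satisfied, violated or deferred by a bipartition."""
    a, b = quartet.pair_one
    c, d = quartet.pair_two
    sa, sb, sc, sd = (partition.side_of(t) for t in (a, b, c, d))
    if sa == sb and sc == sd:
        return QuartetStatus.SATISFIED if sa != sc else QuartetStatus.DEFERRED
    if sa + sb + sc + sd == 2:  # 2-2 split with crossed pairs
        return QuartetStatus.VIOLATED
    return QuartetStatus.DEFERRED


# ---------------------------------------------------------------------------
# tree operations


def leaf_labels(tree: dendropy.Tree) -> FrozenSet[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _adjacency(tree: dendropy.Tree):
    adj: Dict[object, list] = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        for ch in nd.child_nodes():
            adj[nd].append(ch)
            adj.setdefault(ch, []).append(nd)
    return adj


def topological_leaf_distances(tree: dendropy.Tree):
    """Unit-length path distances between all leaves.

    Returns ``(labels, D)`` with labels sorted and ``D`` a nested dict;
    the four-point rule on these distances resolves induced quartet
    topologies (every edge weighs 1, so the tightest pairing wins).
    """
    adj = _adjacency(tree)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    labels = sorted(leaves)
    D: Dict[str, Dict[str, int]] = {}
    for lab in labels:
        src = leaves[lab]
        dist = {src: 0}
        queue = deque([src])
        while queue:
            nd = queue.popleft()
            for nb in adj[nd]:
                if nb not in dist:
                    dist[nb] = dist[nd] + 1
                    queue.append(nb)
        D[lab] = {l2: dist[leaves[l2]] for l2 in labels}
    return labels, D


def quartet_topology(D, a: str, b: str, c: str, d: str) -> Optional[Quartet]:
    """Topology induced on four leaves given the distance table ``D``.

    Returns None when the restriction is unresolved (a polytomy spans the
    four taxa), which cannot happen in a binary tree.
    """
    sums = (
        (D[a][b] + D[c][d], (a, b), (c, d)),
        (D[a][c] + D[b][d], (a, c), (b, d)),
        (D[a][d] + D[b][c], (a, d), (b, c)),
    )
    best = min(s[0] for s in sums)
    winners = [s for s in sums if s[0] == best]
    if len(winners) != 1:
        return None
    _, p1, p2 = winners[0]
    return Quartet(p1, p2)


def is_consistent(quartet: Quartet, tree: dendropy.Tree) -> bool:
    """True iff the tree's restriction to the quartet's taxa equals it.

    An unresolved restriction (e.g. against a star tree) is consistent with
    nothing.
    """
    labs = leaf_labels(tree)
    missing = quartet.taxa - labs
    if missing:
        raise ValueError(f"quartet taxa not in tree: {sorted(missing)}")
    _, D = topological_leaf_distances(tree)
    topo = quartet_topology(D, *quartet.pair_one, *quartet.pair_two)
    return topo == quartet


def induced_quartets(tree: dendropy.Tree,
                     skip_unresolved: bool = False) -> QuartetSet:
    """All C(n,4) embedded quartets of a binary n-leaf tree, weight 1 each.

    A non-binary tree leaves some 4-subsets unresolved; that raises unless
    ``skip_unresolved`` is set, in which case those subsets are omitted.
    """
    labels, D = topological_leaf_distances(tree)
    if len(labels) < 4:
        raise ValueError("tree must have at least 4 leaves")
    out = QuartetSet()
    for a, b, c, d in itertools.combinations(labels, 4):
        topo = quartet_topology(D, a, b, c, d)
        if topo is None:
            if skip_unresolved:
                continue
            raise ValueError(
                f"tree is not binary: 4-subset {{{a},{b},{c},{d}}} unresolved")
        out.add(topo)
    return out


def count_satisfied(quartets: QuartetSet,
                    tree: dendropy.Tree) -> Tuple[float, float]:
    """Weight of quartets consistent with the tree, and the total weight."""
    labs = leaf_labels(tree)
    missing = quartets.taxa - labs
    if missing:
        raise ValueError(f"quartet taxa not in tree: {sorted(missing)}")
    _, D = topological_leaf_distances(tree)
    sat = 0.0
    total = 0.0
    for q, w in quartets.items():
        total += w
        if quartet_topology(D, *q.pair_one, *q.pair_two) == q:
            sat += w
    return sat, total


def tree_bipartitions(tree: dendropy.Tree) -> set:
    """The non-trivial bipartitions of a tree, one per internal edge.

    Trivial splits (a side of size < 2) are excluded; a binary tree on n
    leaves yields exactly n - 3.  Fewer than 4 leaves give the empty set.
    """
    all_leaves = leaf_labels(tree)
    n = len(all_leaves)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(below) <= n - 2:
            out.add(Bipartition(below, all_leaves - below))
    return out


def rf_rate(true_tree: dendropy.Tree, estimated_tree: dendropy.Tree) -> float:
    """Robinson-Foulds error rate (FP + FN) / (2(n-3)).

    FP: internal edges of the estimate absent from the true tree; FN: the
    converse.  Both trees must share the same leaf set of n >= 4 taxa.
    """
    lt = leaf_labels(true_tree)
    le = leaf_labels(estimated_tree)
    if lt != le:
        raise ValueError("trees must have identical leaf sets")
    n = len(lt)
    if n < 4:
        raise ValueError("RF rate needs at least 4 shared taxa")
    bt = tree_bipartitions(true_tree)
    be = tree_bipartitions(estimated_tree)
    fp = len(be - bt)
    fn = len(bt - be)
    return (fp + fn) / (2.0 * (n - 3))
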