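"""Simulation harness: model trees, quartet sampling, noise, replicates.

Emulates the study conditions used to benchmark quartet amalgamation:
random binary model trees on n taxa, q quartets drawn uniformly (with
replacement) from the model tree's induced quartets, an exact fraction
(1 - c) of the draws flipped to one of the two disagreeing topologies, and
Robinson-Foulds error rates averaged over replicates with a standard
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .mfm import DIFFERENCE, ScoreFunction, Seedlike, _as_rng
from .phylo_core import (Quartet, QuartetSet, count_satisfied,
                         induced_quartets, leaf_labels, quartet_topology,
                         rf_rate, topological_leaf_distances)
from .recursion import BASE_CASE_SIZE, qfm_tree

__all__ = [
    "ModelCondition",
    "ExperimentResult",
    "random_binary_tree",
    "sample_quartets",
    "apply_noise",
    "decompose_gene_trees",
    "run_experiment",
    "quartet_count_preset",
    "wilcoxon_comparison",
]


def random_binary_tree(n: int, seed: Seedlike = None,
                       taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
                       distribution: str = "uniform",
                       label_format: str = "t{}") -> dendropy.Tree:
    """Random unrooted binary topology on leaves t1..tn.

    ``uniform`` attaches each new leaf to an edge chosen uniformly among
    all current edges, which draws uniformly from the (2n-5)!! unrooted
    binary topologies; ``yule`` attaches to a uniformly chosen pendant
    edge instead.
    """
    if n < 4:
        raise ValueError("need at least 4 leaves for a binary tree")
    if distribution not in ("uniform", "yule"):
        raise ValueError("distribution must be 'uniform' or 'yule'")
    rng = _as_rng(seed)
    tns = (taxon_namespace if taxon_namespace is not None
           else dendropy.TaxonNamespace())
    labels = [label_format.format(i + 1) for i in range(n)]
    tree = dendropy.Tree(taxon_namespace=tns)
    for lab in labels[:3]:
        tree.seed_node.new_child(taxon=tns.require_taxon(lab))
    # every non-seed node identifies the edge above it
    edges: List[dendropy.Node] = list(tree.seed_node.child_nodes())
    for lab in labels[3:]:
        if distribution == "uniform":
            head = edges[int(rng.integers(len(edges)))]
        else:
            pendant = [nd for nd in edges if nd.is_leaf()]
            head = pendant[int(rng.integers(len(pendant)))]
        tail = head.parent_node
        mid = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(mid)
        mid.add_child(head)
        leaf = mid.new_child(taxon=tns.require_taxon(lab))
        edges.extend([mid, leaf])
    tree.is_rooted = False
    return tree


def sample_quartets(tree: dendropy.Tree, q: int,
                    seed: Seedlike = None) -> QuartetSet:
    """Draw q quartets uniformly (with replacement) from a binary tree.

    Each draw picks a uniformly random 4-subset of leaves and contributes
    the tree-induced topology with weight 1; the result is a multiset and
    every drawn quartet is consistent with the tree.
    """
    rng = _as_rng(seed)
    labels, D = topological_leaf_distances(tree)
    n = len(labels)
    if n < 4:
        raise ValueError("tree must have at least 4 leaves")
    out = QuartetSet()
    if q == 0:
        return out
    # uniform 4-subsets: the 4 smallest entries of a random row are a
    # uniformly random 4-subset of columns
    r = rng.random((q, n))
    picks = np.argpartition(r, 4, axis=1)[:, :4]
    for row in picks:
        a, b, c, d = (labels[i] for i in row)
        topo = quartet_topology(D, a, b, c, d)
        if topo is None:
            raise ValueError("tree is not binary: unresolved 4-subset")
        out.add(topo)
    return out


def apply_noise(quartets: QuartetSet, c: float,
                seed: Seedlike = None) -> QuartetSet:
    """Flip an exact fraction (1 - c) of quartet instances.

    Exactly round((1-c) * N) instances (N = total multiplicity, weights
    must be integral) are chosen without replacement and each replaced by
    one of its two alternative topologies, chosen uniformly.  c = 1 is the
    identity; the output always has the same total weight as the input.
    """
    if not (0 < c <= 1):
        raise ValueError("consistency level c must be in (0, 1]")
    rng = _as_rng(seed)
    instances: List[Quartet] = []
    for q, w in quartets.items():
        mult = int(round(w))
        if abs(w - mult) > 1e-9:
            raise ValueError("apply_noise needs integer multiplicities")
        instances.extend([q] * mult)
    n_inst = len(instances)
    n_flip = int(math.floor((1.0 - c) * n_inst + 0.5))  # round half-up
    flip_idx = set(rng.choice(n_inst, size=n_flip, replace=False).tolist()
                   ) if n_flip else set()
    out = QuartetSet()
    for i, q in enumerate(instances):
        if i in flip_idx:
            alt = q.alternatives()
            q = alt[int(rng.integers(2))].with_weight(1.0)
        out.add(q, 1.0)
    return out


def decompose_gene_trees(trees: Iterable[dendropy.Tree],
                         skip_unresolved: bool = False) -> QuartetSet:
    """Multiset union of the embedded quartets of every gene tree.

    Multiple copies of a quartet are retained (weights add), so the total
    weight is the sum of C(n_i, 4) over the input trees.
    """
    out = QuartetSet()
    for tree in trees:
        out.update(induced_quartets(tree, skip_unresolved=skip_unresolved))
    return out


#: Quartet-count presets as powers of the taxon count: sparse ~ n^1.5,
#: quadratic ~ n^2, dense ~ n^2.8 (dense sampling is empirically enough to
#: recover the model tree even under noise).
_PRESET_EXPONENTS = {"sparse": 1.5, "quadratic": 2.0, "dense": 2.8}


def quartet_count_preset(n: int, preset: str) -> int:
    try:
        expo = _PRESET_EXPONENTS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; options: {sorted(_PRESET_EXPONENTS)}")
    return int(round(n ** expo))


@dataclass(frozen=True)
class ModelCondition:
    """One cell of the simulation grid.

    n taxa, q sampled quartets, consistency fraction c in (0, 1], number
    of replicates and the base seed the per-replicate streams derive from.
    """

    n: int
    q: int
    c: float
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if not (0 < self.c <= 1):
            raise ValueError("c must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ExperimentResult:
    """Per-replicate RF rates plus their mean and standard error."""

    condition: ModelCondition
    rf_rates: List[float]
    records: List[Dict[str, float]] = field(default_factory=list)

    @property
    def mean_rf(self) -> float:
        return float(np.mean(self.rf_rates))

    @property
    def std_error(self) -> float:
        if len(self.rf_rates) < 2:
            return 0.0
        sd = float(np.std(self.rf_rates, ddof=1))
        return sd / math.sqrt(len(self.rf_rates))


def _replicate_seeds(base_seed: int, replicates: int) -> List[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(replicates, dtype=np.uint32)]


def run_experiment(condition: ModelCondition,
                   fn: ScoreFunction = DIFFERENCE,
                   base_case_size: int = BASE_CASE_SIZE,
                   keep_trees: bool = False) -> ExperimentResult:
    """Run one model condition end to end.

    Per replicate: generate a model tree, sample q quartets, flip an exact
    (1 - c) fraction, amalgamate with QFM, and score the estimate against
    the model tree; reproducible from (condition, fn) alone.
    """
    rf_rates: List[float] = []
    records: List[Dict[str, float]] = []
    for r, rep_seed in enumerate(
            _replicate_seeds(condition.seed, condition.replicates)):
        rng = np.random.default_rng(rep_seed)
        model = random_binary_tree(condition.n, rng)
        drawn = sample_quartets(model, condition.q, rng)
        noisy = apply_noise(drawn, condition.c, rng)
        estimate = qfm_tree(leaf_labels(model), noisy, fn, rng,
                            base_case_size=base_case_size)
        rf = rf_rate(model, estimate)
        sat, total = count_satisfied(noisy, estimate)
        rf_rates.append(rf)
        rec = {"replicate": r, "seed": rep_seed, "rf": rf,
               "satisfied_weight": sat, "total_weight": total}
        if keep_trees:
            rec["model_tree"] = model
            rec["estimated_tree"] = estimate
            rec["quartets"] = noisy
        records.append(rec)
    return ExperimentResult(condition, rf_rates, records)


def wilcoxon_comparison(rf_a: Sequence[float], rf_b: Sequence[float]):
    """Paired Wilcoxon signed-rank comparison of two methods' RF vectors.

    Thin hook over :func:`scipy.stats.wilcoxon`; returns its result object.
    """
    from scipy.stats import wilcoxon

    return wilcoxon(rf_a, rf_b)
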