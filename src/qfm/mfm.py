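"""Modified Fiduccia-Mattheyses (MFM) taxon-set bipartitioning.

The search state is a non-singleton bipartition of the working taxon set,
scored by classifying every quartet as satisfied, violated or deferred.
Each iteration ("pass") moves every taxon exactly once, always the free
taxon of maximum gain whose move keeps both sides of size >= 2, locks it,
and records the running cumulative gain; the pass is then rolled back to
the prefix of moves with maximum cumulative gain.  Passes repeat while the
maximum cumulative gain is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .phylo_core import Bipartition, QuartetSet

__all__ = [
    "ScoreFunction",
    "DIFFERENCE",
    "RATIO",
    "get_score_function",
    "MoveLog",
    "MoveRecord",
    "TaxonState",
    "partition_score",
    "gain",
    "initial_bipartition",
    "select_move",
    "fm_pass",
    "rollback",
    "mfm_bipartition",
]

logger = logging.getLogger(__name__)

#: Stand-in for the infinite RATIO score at v = 0; any v = 0 partition must
#: outrank any finite ratio, and among v = 0 partitions larger s must win.
#: 1e12 dwarfs every attainable finite ratio while s (bounded by the total
#: quartet weight) still perturbs the value exactly in float64.
_RATIO_INF_BASE = 1e12

Seedlike = Union[None, int, Sequence[int], np.random.Generator]


def _as_rng(seed: Seedlike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScoreFunction:
    """Maps aggregated (satisfied, violated, deferred) weights to a score.

    The evaluator must accept numpy arrays elementwise; higher is better.
    """

    identifier: str
    evaluator: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]

    def __call__(self, s, v, d):
        return self.evaluator(s, v, d)


def _diff(s, v, d):
    return s - v


def _ratio(s, v, d):
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(v > 0, s / np.where(v > 0, v, 1.0), _RATIO_INF_BASE + s)
    return out if out.ndim else float(out)


DIFFERENCE = ScoreFunction("difference", _diff)
RATIO = ScoreFunction("ratio", _ratio)


def get_score_function(name: str) -> ScoreFunction:
    key = name.lower()
    if key in ("diff", "difference"):
        return DIFFERENCE
    if key in ("ratio",):
        return RATIO
    raise ValueError(f"unknown score function {name!r} (use 'diff' or 'ratio')")


@dataclass
class TaxonState:
    """Per-pass bookkeeping: a taxon is FREE until moved (or force-locked)."""

    taxon: str
    locked: bool = False
    side: int = 0


@dataclass(frozen=True)
class MoveRecord:
    step: int
    taxon: str
    gain: float
    cumulative_gain: float


class MoveLog:
    """Ordered per-pass record of moves used for rollback.

    ``max_cumulative_gain`` is the maximum running gain over the pass and
    ``argmax_index`` the smallest number of initial moves achieving it
    (ties resolve to the earliest prefix).
    """

    def __init__(self, records: Sequence[MoveRecord] = ()) -> None:
        self.records: List[MoveRecord] = list(records)

    def append(self, taxon: str, gain_value: float) -> None:
        prev = self.records[-1].cumulative_gain if self.records else 0.0
        self.records.append(
            MoveRecord(len(self.records) + 1, taxon, gain_value,
                       prev + gain_value))

    @property
    def max_cumulative_gain(self) -> float:
        if not self.records:
            return 0.0
        return max(r.cumulative_gain for r in self.records)

    @property
    def argmax_index(self) -> int:
        """1-based index of the earliest maximum of the cumulative gain."""
        g_max = self.max_cumulative_gain
        for r in self.records:
            if r.cumulative_gain == g_max:
                return r.step
        return 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# vectorized scoring engine


class _Engine:
    """Array view of a quartet set over a fixed taxon ordering."""

    def __init__(self, quartets: QuartetSet, taxa: Sequence[str]) -> None:
        self.taxa = list(taxa)
        self.index = {t: i for i, t in enumerate(self.taxa)}
        rows = []
        weights = []
        for q, w in quartets.items():
            a, b = q.pair_one
            c, d = q.pair_two
            rows.append((self.index[a], self.index[b],
                         self.index[c], self.index[d]))
            weights.append(w)
        self.P = (np.asarray(rows, dtype=np.intp).reshape(-1, 4)
                  if rows else np.empty((0, 4), dtype=np.intp))
        self.w = np.asarray(weights, dtype=float)

    def side_array(self, partition: Bipartition) -> np.ndarray:
        side = np.zeros(len(self.taxa), dtype=np.int8)
        for t in partition.side_b:
            side[self.index[t]] = 1
        return side

    def partition_from(self, side: np.ndarray) -> Bipartition:
        a = [t for t, s in zip(self.taxa, side) if s == 0]
        b = [t for t, s in zip(self.taxa, side) if s == 1]
        return Bipartition(a, b)

    def _status(self, S: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(satisfied, violated) masks for per-quartet side matrix S (M x 4)."""
        same_ab = S[:, 0] == S[:, 1]
        same_cd = S[:, 2] == S[:, 3]
        sat = same_ab & same_cd & (S[:, 0] != S[:, 2])
        viol = (S.sum(axis=1) == 2) & ~sat
        return sat, viol

    def svd(self, side: np.ndarray) -> Tuple[float, float, float]:
        """Aggregate (satisfied, violated, deferred) weights."""
        if self.P.shape[0] == 0:
            return 0.0, 0.0, 0.0
        sat, viol = self._status(side[self.P])
        s = float(self.w[sat].sum())
        v = float(self.w[viol].sum())
        return s, v, float(self.w.sum() - s - v)

    def deltas(self, side: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Per-taxon (delta_s, delta_v) of a hypothetical single-taxon move."""
        n = len(self.taxa)
        ds = np.zeros(n)
        dv = np.zeros(n)
        if self.P.shape[0] == 0:
            return ds, dv
        S = side[self.P]
        sat, viol = self._status(S)
        base_s = self.w * sat
        base_v = self.w * viol
        for j in range(4):
            Sf = S.copy()
            Sf[:, j] ^= 1
            satf, violf = self._status(Sf)
            np.add.at(ds, self.P[:, j], self.w * satf - base_s)
            np.add.at(dv, self.P[:, j], self.w * violf - base_v)
        return ds, dv


# ---------------------------------------------------------------------------
# public operations


def partition_score(quartets: QuartetSet, partition: Bipartition,
                    fn: ScoreFunction = DIFFERENCE) -> float:
    """Score of a bipartition: fn applied to the aggregated (s, v, d)."""
    extra = quartets.taxa - partition.ground_set
    if extra:
        raise ValueError(f"quartet taxa outside partition: {sorted(extra)}")
    eng = _Engine(quartets, sorted(partition.ground_set))
    s, v, d = eng.svd(eng.side_array(partition))
    return float(fn(s, v, d))


def gain(quartets: QuartetSet, partition: Bipartition, taxon: str,
         fn: ScoreFunction = DIFFERENCE) -> float:
    """Score change from moving one taxon to the other side.

    Evaluated even if the move would create a singleton side; legality is
    the move-selection rule's concern, not the gain's.
    """
    return (partition_score(quartets, partition.move(taxon), fn)
            - partition_score(quartets, partition, fn))


def initial_bipartition(taxa, quartets: QuartetSet,
                        seed: Seedlike = None) -> Bipartition:
    """Seed bipartition built from the quartets in descending weight order.

    Distinct quartets are aggregated, sorted by weight (heaviest first) and
    scanned once: the first quartet's pairs found the two sides; afterwards
    each still-unplaced taxon of a quartet joins its pair-partner's side, or
    the side opposite the other pair.  Taxa never mentioned by any quartet
    are assigned uniformly at random.  The result is never singleton.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa to bipartition")
    rng = _as_rng(seed)
    order = sorted(quartets.items(), key=lambda it: (-it[1], str(it[0])))
    sides: Dict[str, int] = {}

    def place(taxon, side_id):
        if taxon in sides or taxon not in taxon_set:
            return
        sides[taxon] = side_id

    taxon_set = set(taxa)
    for q, _w in order:
        t1, t2 = q.pair_one
        t3, t4 = q.pair_two
        if not any(t in sides for t in (t1, t2, t3, t4)):
            place(t1, 0), place(t2, 0), place(t3, 1), place(t4, 1)
            continue
        if t1 not in sides:
            if t2 in sides:
                place(t1, sides[t2])
            else:
                anchor = sides[t3] if t3 in sides else sides[t4]
                place(t1, 1 - anchor)
        if t2 not in sides:
            place(t2, sides[t1])
        if t3 not in sides:
            if t4 in sides:
                place(t3, sides[t4])
            else:
                anchor = sides[t1] if t1 in sides else sides[t2]
                place(t3, 1 - anchor)
        if t4 not in sides:
            place(t4, sides[t3])
    for t in taxa:
        if t not in sides:
            sides[t] = int(rng.integers(2))
    # repair degenerate fills (all-on-one-side or singleton): the search
    # contract requires both sides of size >= 2
    counts = [sum(1 for s in sides.values() if s == k) for k in (0, 1)]
    while min(counts) < 2:
        big = 0 if counts[0] > counts[1] else 1
        movable = sorted(t for t, s in sides.items() if s == big)
        pick = movable[int(rng.integers(len(movable)))]
        sides[pick] = 1 - big
        counts = [sum(1 for s in sides.values() if s == k) for k in (0, 1)]
    return Bipartition([t for t in taxa if sides[t] == 0],
                       [t for t in taxa if sides[t] == 1])


def _select_index(free: np.ndarray, legal: np.ndarray, gains: np.ndarray,
                  sat_after: np.ndarray,
                  rng: np.random.Generator) -> Optional[int]:
    """Shared selection rule on arrays; None when no legal move exists.

    Scans gain levels downward over free taxa whose move keeps both sides
    of size >= 2; at the first non-empty level the taxon whose post-move
    partition satisfies maximum weight wins, ties broken at random.
    """
    mask = free & legal
    if not mask.any():
        return None
    top = gains[mask].max()
    elig = mask & (gains == top)
    best_sat = sat_after[elig].max()
    winners = np.flatnonzero(elig & (sat_after == best_sat))
    if len(winners) == 1:
        return int(winners[0])
    return int(winners[int(rng.integers(len(winners)))])


def select_move(states: Sequence[TaxonState], gains: Dict[str, float],
                partition: Bipartition, quartets: QuartetSet,
                seed: Seedlike = None,
                fn: ScoreFunction = DIFFERENCE) -> Optional[str]:
    """Pick the next taxon to transfer, or None if every move is illegal.

    Free taxa are scanned from the highest gain level downward; a move is
    legal when it leaves no side with fewer than 2 taxa.  Among the top
    eligible level the taxon whose post-move bipartition satisfies maximum
    quartet weight is chosen (random tie-break).  When None is returned the
    caller locks all remaining free taxa with gain zero.
    """
    rng = _as_rng(seed)
    eng = _Engine(quartets, sorted(partition.ground_set))
    side = eng.side_array(partition)
    s, v, d = eng.svd(side)
    ds, dv = eng.deltas(side)
    n = len(eng.taxa)
    free = np.zeros(n, dtype=bool)
    for st in states:
        if not st.locked:
            free[eng.index[st.taxon]] = True
    sizes = np.array([n - side.sum(), side.sum()])
    legal = sizes[side] >= 3
    garr = np.array([gains[t] for t in eng.taxa])
    idx = _select_index(free, legal, garr, s + ds, rng)
    return None if idx is None else eng.taxa[idx]


def fm_pass(quartets: QuartetSet, start: Bipartition,
            fn: ScoreFunction = DIFFERENCE,
            seed: Seedlike = None) -> Tuple[MoveLog, Bipartition]:
    """One full iteration: move-and-lock every taxon once.

    Every taxon begins free; repeatedly the best legal move is applied and
    the realized gain appended to the log.  When no legal move remains, all
    still-free taxa are locked with recorded gain zero, so the log always
    has one entry per taxon.
    """
    if start.is_singleton:
        raise ValueError("fm_pass requires a non-singleton start partition")
    rng = _as_rng(seed)
    eng = _Engine(quartets, sorted(start.ground_set))
    side = eng.side_array(start)
    n = len(eng.taxa)
    free = np.ones(n, dtype=bool)
    log = MoveLog()
    while free.any():
        s, v, d = eng.svd(side)
        ds, dv = eng.deltas(side)
        base = float(fn(s, v, d))
        after = np.asarray(fn(s + ds, v + dv, d - ds - dv), dtype=float)
        gains = after - base
        sizes = np.array([n - side.sum(), side.sum()])
        legal = sizes[side] >= 3
        idx = _select_index(free, legal, gains, s + ds, rng)
        if idx is None:
            for i in sorted(np.flatnonzero(free)):
                log.append(eng.taxa[i], 0.0)
            break
        side[idx] ^= 1
        free[idx] = False
        log.append(eng.taxa[idx], float(gains[idx]))
    return log, eng.partition_from(side)


def rollback(start: Bipartition, log: MoveLog) -> Bipartition:
    """Replay only the move prefix achieving the maximum cumulative gain.

    If the maximum cumulative gain is not positive the start partition is
    returned unchanged (the pass brought no improvement).
    """
    if log.max_cumulative_gain <= 0:
        return start
    part = start
    k = log.argmax_index
    for rec in log.records[:k]:
        part = part.move(rec.taxon)
    return part


def mfm_bipartition(taxa, quartets: QuartetSet,
                    fn: ScoreFunction = DIFFERENCE,
                    seed: Seedlike = None) -> Bipartition:
    """Full MFM search: seeded start, then improving passes until stuck.

    Terminates because each accepted pass strictly increases the partition
    score and there are finitely many bipartitions.  The result is never
    singleton and scores at least as high as the initial bipartition.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa to bipartition")
    rng = _as_rng(seed)
    part = initial_bipartition(taxa, quartets, rng)
    n_pass = 0
    while True:
        n_pass += 1
        log, _end = fm_pass(quartets, part, fn, rng)
        g_max = log.max_cumulative_gain
        logger.debug("MFM pass %d: G_max=%.6g over %d taxa",
                     n_pass, g_max, len(taxa))
        if g_max <= 0:
            break
        part = rollback(part, log)
    return part
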