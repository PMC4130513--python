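# Methods

## Problem and model

The package addresses Maximum Quartet Consistency (MQC): given a weighted
multiset *Q* of quartets over a taxon set *X* (|X| = n), find an unrooted
tree on *X* maximizing the total weight of quartets consistent with it. A
quartet *ab|cd* is consistent with a tree when some edge (path) separates
{a,b} from {c,d}; for any 4 leaves of a binary tree exactly one of the three
topologies is consistent. MQC is NP-hard, so the package implements a
divide-and-conquer heuristic (QFM) whose core is a Fiduccia–Mattheyses-style
bipartition search (MFM).

Weights are interpreted as multiplicities for unweighted input; any
non-negative real weights are accepted by the scoring and search machinery
(e.g. gene-tree support fractions), though the noise model requires integer
multiplicities.

## The MFM bipartition search

State: a bipartition (X₁, X₂) of the working taxon set with both sides of
size ≥ 2 ("singleton" states are excluded everywhere to avoid degenerate
splits and infinite loops). Each quartet is satisfied, violated or deferred
against the state; deferred covers both 3–1 and 4–0 splits — the 4–0 case is
deliberately scored as deferred because the divide step passes such quartets
onward unchanged, so they must contribute to neither *s* nor *v*.

Score functions: `difference` (*s − v*, the default — empirically the most
reliable of the simple choices) and `ratio` (*s/v*). For `ratio` with v = 0
the score is represented as 1e12 + s: any violation-free state outranks any
finite ratio reachable at these problem sizes, and larger *s* wins among
violation-free states, while gains remain finite floats. Custom evaluators
mapping (s, v, d) to a score can be passed anywhere a `ScoreFunction` is
accepted; they must accept numpy arrays elementwise.

Seeding: distinct quartets are aggregated, sorted by descending weight (ties
by canonical quartet string, for determinism), and scanned once. The first
quartet's pairs found the two sides; afterwards each unplaced taxon of a
quartet joins its pair-partner's side if that partner is placed, otherwise
the side opposite the other pair (consulting the earlier-listed taxon of
that pair first — the tie order is fixed arbitrarily but deterministically).
Taxa mentioned by no quartet are assigned uniformly at random. If the fill
leaves a side with fewer than two taxa, seeded random taxa are moved from
the large side until both sides have ≥ 2 — the search contract requires a
non-singleton start.

Passes: all taxa start free. Repeatedly, per-taxon gains (score after moving
that taxon minus current score) are recomputed exactly — vectorized as
per-taxon (Δs, Δv) accumulations over all quartets, which is semantically a
full reclassification, not an approximation — and the mover is chosen by
scanning gain levels downward among free taxa whose move keeps both sides of
size ≥ 2; within the top eligible level the taxon whose post-move state
satisfies maximum weight wins, residual ties broken uniformly at random from
the run's seeded stream. The mover is transferred and locked; (taxon, gain,
cumulative gain) is appended to the move log. When no legal move exists, all
remaining free taxa are locked with recorded gain zero, so the log always
has one entry per taxon. The pass is then rolled back to the earliest prefix
achieving the maximum cumulative gain G_max; if G_max ≤ 0 the start state is
kept. Passes repeat while G_max > 0. Termination is guaranteed: each
accepted pass strictly increases the score and states are finite, so no
state repeats (this argument covers arbitrary score functions, not just the
bounded `difference`).

No gain-bucket data structures are used; gains are recomputed from scratch
each move. This is O(q) vectorized work per move and keeps the semantics
transparent; it comfortably handles the largest benchmark condition shipped
(n = 50, q = 57,164) in seconds per replicate.

## Recursion

`qfm_tree` bipartitions the taxon set, drops satisfied/violated quartets,
adds one fresh dummy taxon (from a reserved `__qfm_dummy_` namespace,
validated against input names at entry) to both halves, renames the stray
taxon of each 3–1 quartet to the dummy, and recurses. A single shared dummy
per split suffices since it marks the same future edge in both halves. The
dummy is an ordinary taxon for scoring and moving; it is special only at
conquer time, when both subtrees are rerooted at its attachment node, the
dummy leaves deleted, and the attachment nodes joined by a new internal
edge (suppressing any degree-2 node this creates).

BASE_CASE_SIZE = 3: recursion returns a depth-one star when the subproblem
has ≤ 3 taxa or no quartets. Three is the smallest size at which every
topology is a star, so this threshold loses no information; it is exposed as
a parameter for sensitivity analysis. A size-4 subproblem with an empty
quartet set also returns a star — the 4-subset is simply unresolvable, and
RF scoring counts the missing edge as a false negative, which is intended.
Both sides of a split have ≥ 2 real taxa, so child subproblems (side + 1
dummy) are strictly smaller than the parent and recursion terminates.

## Simulation harness

`random_binary_tree` draws uniformly from the (2n−5)!! unrooted binary
topologies by inserting each successive leaf into a uniformly chosen edge
(each topology arises from exactly one insertion sequence). A Yule option
(attachment restricted to pendant edges) is provided because the original
benchmark delegated tree generation to an external tool with an unstated
prior; uniform is the documented default and all shipped numbers use it.

`sample_quartets` draws q 4-subsets uniformly with replacement and emits the
tree-induced topology of each, so the input is a multiset, matching the MQC
problem statement. Induced topologies are resolved by the four-point rule on
unit-length (topological) path distances: the pairing with the strictly
smallest distance sum is the induced split; a tie means the restriction is
unresolved (only possible with polytomies).

`apply_noise` flips an exact count round((1−c)·q) of quartet instances
(half-up), chosen without replacement, each to one of its two alternative
topologies uniformly. An exact count rather than per-instance Bernoulli
flipping makes the consistency level c a hard property of every dataset.

`run_experiment` derives one 32-bit seed per replicate from the condition's
base seed via numpy's SeedSequence, then runs generate → sample → flip →
amalgamate → RF per replicate and reports the mean and standard error
sd/√r, with per-replicate records (seed, RF, satisfied weight) for audit.

RF rate is (FP + FN)/(2(n−3)), comparing non-trivial bipartition sets; the
normalizer is the standard one for binary n-leaf trees. Estimates may be
non-binary (stars from the base case), in which case FP and FN counts are
asymmetric — intended, since a polytomy simply lacks edges.

## What the generator does and does not emulate

It reproduces the benchmark's control variables exactly (n, q, c,
replicates) but not the original external generator bit-for-bit: that tool's
tree prior and subset-sampling scheme are unpublished. Consequently
zero-error regimes (dense sampling) reproduce exactly, while sparse-regime
mean RF values land near, not on, the published points: at (n=25, q=625,
c=90%) this implementation measures ≈ 0.085 ± 0.018 (published 0.073), and
at the very sparse noise-free condition (n=25, q=125, c=100%) it measures
≈ 0.34 ± 0.02 against a published 0.444 — stably lower (better) across base
seeds and under the Yule prior as well, plausibly because the maximally
resolving base case here returns stars only below 4 taxa. Passing simulated
benchmarks shows fidelity of the method's behaviour under its own noise
model; real datasets add estimation error in the input quartets themselves,
which no consistency parameter fully captures.

## Numerical and design notes

- All randomness flows from one seed (int, sequence or numpy Generator);
  substreams are consumed in a fixed documented order, so every run is
  reproducible bit-for-bit from its config.
- With integer weights all scores and gains are exact in float64; recorded
  gains equal realized score deltas exactly. With fractional weights,
  equality tests in tie-breaking may split near-ties; this affects only
  which of two near-equally-good moves is taken.
- Quartet canonical form sorts within pairs and orders pairs
  lexicographically, making deduplication and hashing deterministic.
- Newick IO treats trees as unrooted: a degree-2 root is suppressed on
  read, and output uses an arbitrary basal trifurcation (Newick requires a
  root node even for unrooted semantics).
- The problem sizes exercised by the test suite and the reproduction script
  (20 replicates at n=25 for both q=625 and q=8208; 20 at n=50, q=57,164)
  complete in about a minute total; the benchmark grid's n ≥ 100 dense rows
  (e.g. q = 398,108) are supported by the same code path but take
  correspondingly longer.

## Known limitations

- MFM is a local search; no approximation guarantee exists, and very sparse
  quartet coverage (q ≈ n^1.5) leaves large parts of the tree effectively
  unconstrained.
- No branch lengths anywhere: topology in, topology out.
- Performance engineering (FM gain buckets, incremental reclassification,
  parallel recursion) is deliberately out of scope; the vectorized exact
  recomputation is fast enough for hundreds of taxa but not tuned beyond
  that.
- Rooted semantics, outgroups, NEXUS/PhyloXML are unsupported.
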