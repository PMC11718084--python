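# Methods

## Molecular graph model

Structures are compared as node-labeled, edge-weighted simple graphs over
heavy atoms: element symbols on nodes, bond weights 1.0 (single), 1.5
(aromatic), 2.0 (double) on edges. Hydrogens, formal charges, isotopes and
stereochemistry are ignored — two structures differing only in these are
treated as identical, matching the notion of equivalence the distance is
meant to capture. Aromaticity comes from RDKit's perception model after
sanitization, so kekulized input is re-perceived and results are
reproducible per toolkit version. The element alphabet is open-ended; any
symbol is accepted, and mapping between different elements is never
allowed. Triple bonds fall outside the canonical weight set; we accept
them with weight 3.0 (the mathematics is weight-agnostic) and provide
`reject_triple` for callers who prefer a hard error. Multi-fragment
SMILES stay one disconnected graph.

All weights and distances are held internally as integers in quarter
units (value × 4). Weights are multiples of 0.5 and every formula in the
package at most halves a sum of weights, so quarter units are closed
under all operations and every metric test in the suite is an exact
integer comparison — no floating-point tolerances anywhere in the
distance logic.

## Lower bounds

**Degree bound** (linear time): sort both node sets by weighted degree,
pair positionally, sum absolute differences, add the degrees of leftover
nodes, halve (each edge was counted at both endpoints).

**Atom-type matching bound** (cubic time): for each element, a
minimum-weight perfect matching between the nodes of that element in the
two graphs, padded to equal sides. A real-vs-real entry is the exact cost
of matching the two one-hop edge neighborhoods — an incident edge may map
onto an incident edge only when the opposite endpoints share an element,
mapped pairs cost the absolute weight difference, unmapped incident edges
cost their weight — solved as a small assignment problem, hence exact. A
real node facing a padding node costs its weighted degree, mirroring the
leftover rule of the degree bound (the padding cost is a design choice;
it is the one that keeps the bound provably valid and is gated by the
oracle-correctness suite). Matching values are summed over elements and
halved. Only one-hop neighborhoods are enumerated; a larger radius would
strengthen the bound but lose the cubic-time guarantee. Tie-breaking
among optimal matchings is irrelevant since only the value is used.

The matching bound dominates the degree bound (a type-restricted matching
is also a degree matching with entry-wise larger costs), and both are
pseudometrics — each is the value of a minimum-weight matching, and two
matchings compose into one whose weight bounds the third side. The
default pipeline uses the matching bound alone; `use_degree_prefilter`
short-circuits with the cheap bound when it already reaches T (results
then report the degree-bound value, so the flag is off by default to keep
the reported-bound invariant simple).

## Exact ILP

Binary variables: y_ik for element-equal node pairs; c for edge pairs
compatible in at least one orientation; n_e for unmapped edges. The
objective Σ c·|b1−b2| + Σ n·b is minimized subject to: the node map is
injective both ways; for every node and every opposite edge, the summed c
of incident edges is at most the y mass placing that node on the edge's
endpoints (these neighborhood constraints enforce endpoint consistency in
whichever orientation the types allow — a single c variable per edge pair
suffices because the weight is orientation-independent); each edge is
mapped exactly once or flagged unmapped; and, when a threshold is given,
the objective is capped at T. Infeasibility under the cap certifies the
true distance exceeds T and is converted by the caller to the clamped
value T.

Coefficients are integer quarter units, avoiding solver feasibility-
tolerance artifacts; the reported objective is rounded to the nearest
integer quarter. Solving uses HiGHS through `scipy.optimize.milp`:
single-threaded and deterministic, so value-level results are independent
of worker count and visit order (optimal mappings may differ among ties).
No time limit is applied by default; with a user limit the solve becomes
anytime — the solver's dual bound, floored to quarter units and clamped
from below by the matching bound, is returned as a valid lower bound, the
result is flagged approximate, and such values are excluded from the
metric guarantees. `verify_solution` independently rechecks every
constraint family and the objective by direct recomputation.

## Myopic distance and the metric

With threshold T > 0 (default 10, configurable per call and per CLI run):
report the matching bound when it reaches T ("bound" provenance, value ≥
T); otherwise run the capped ILP and report min{d_E, T} ("exact" below T,
"clamped" at T — an exact value equal to T is deliberately reported as
clamped, preserving the strict exact-below-T / bound-at-least-T
dichotomy). This double thresholding makes the distance a metric for
every T: bounds are pseudometrics, the exact distance is a metric, and
any mixed triangle goes through T. Dropping the exact-side clamp breaks
the triangle inequality; `search_triangle_violation` finds concrete
counterexamples by seeded random search over families of same-size
all-carbon graphs (rings, unions of small cycles, paths, chord/weight
variants) where structurally different graphs keep similar degree
profiles. The search is budget-bounded and reported inconclusive, not
failed, when nothing is found. As an alternative to double thresholding,
`metric_closure` applies Floyd–Warshall to a complete table, enforcing
the triangle inequality a posteriori; on double-thresholded tables it is
the identity.

## Batch pipeline

Pairwise tables store the lower triangle in long form (self-distances
implicit zero, one shared threshold). Work is sharded by deterministic
pair index; with any worker count the result is record-for-record
identical, and an interrupted run resumes from its checkpoint CSV by
skipping pairs already present. The square-matrix CSV export (symmetric,
zero diagonal) is the hand-off to embedding tools in precomputed-distance
mode; no embedding is computed here. Values at or above T are censored
("at least this dissimilar"); nearest-neighbor and coverage statistics
carry an explicit censored flag, and the k-th-nearest variant of the
coverage profile is available for k ≥ 1.

## Synthetic generator and oracle

The generator grows a random tree (connectivity guaranteed when
requested), adds ring-forming extra edges under a valence-like degree cap
of 4, and assigns weights: mostly single, some double, aromatic only on
whole rings from the cycle basis so fixtures remain chemically plausible
(a free mode lifts this for adversarial tests). Default element
frequencies are carbon-dominated (C 0.72, O 0.13, N 0.10, S 0.03,
Cl 0.02), loosely echoing heavy-atom compositions of small biomolecules.
All randomness flows through one explicit seed. The generator emulates
size, valence and ring structure of small molecules, not real chemistry:
no valence/charge validation, no realistic functional groups. Passing
tests therefore demonstrate algorithmic correctness and the metric
guarantees, which are input-independent, but say nothing about empirical
distance distributions of real compound databases.

The brute-force oracle enumerates injective, type-consistent partial node
mappings with branch-and-bound on the achievable common-edge weight. It
shares no code with the ILP path and refuses pairs whose smaller graph
has more than 7 edges (the cap keeps worst-case enumeration well under a
second per pair), which is ample for anchoring correctness: every
distance formula, bound and ILP answer is checked against it on hundreds
of seeded random pairs.

## Problem sizes

The test suite and acceptance script run at desk scale: 200 oracle-sized
pairs (4–7 edges) for ILP-vs-oracle agreement, 500 additional pairs for
bound dominance, a 60-graph pool (5–28 atoms) sampling 1000 triples for
the metric checks, an 80-triple budget for the counterexample search, and
a 50-structure all-pairs table for determinism, resume and censoring
statistics. At these sizes the whole suite completes in about a minute on
one CPU; the structure of every check is size-independent.
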