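# Methods

## The model

`hetmotif` analyses a heterogeneous association network over three
biomedical entity types — drugs, diseases and genes — built from
literature-derived subject–predicate–object assertions (predications).
Direction and predicate semantics are deliberately discarded: two entities
are linked if any assertion associates them.  The result is an undirected
simple graph whose nodes carry one of three colors and whose edges
partition into six *layers*, one per unordered pair of types
(disease-disease, disease-drug, disease-gene, drug-drug, drug-gene,
gene-gene).

The object of inference is the set of *colored three-node network motifs*:
connected three-node induced subgraphs, classified up to colored
isomorphism, that occur significantly more often in the real network than
in a randomized ensemble with matched typed structure.  A connected
three-node graph is either a two-edge path (class fixed by the center type
and the unordered leaf-type pair; 3 × 6 = 18 classes) or a triangle (class
fixed by the type multiset; 10 classes), 28 classes in total.
Significant motifs are then aggregated into a *core network* — the union of
the induced edges of all their matches — which serves as the backbone for
neighborhood analytics: shared-neighbor analysis of disease pairs,
guilt-by-association candidate prioritization, hub detection and ego
subnetworks.

## Preprocessing chain

1. **Ingest.** Predication TSVs (`subject_id, subject_type, predicate,
   object_id, object_type, pmid`) are parsed with lenient row handling by
   default (malformed rows logged and skipped; a strict mode aborts).
   Entity identity is the exact token after case-folding and whitespace
   trimming; no concept-identifier resolution is attempted.
2. **Deduplication.** `(A,B)` and `(B,A)` collapse into one undirected
   association (canonical order: lexicographic on id tokens) carrying a
   support count and the set of asserting PMIDs.  Self-assertions are
   dropped and counted.  Support is conserved: supports sum to the input
   record count minus the self-drops.
3. **Drug whitelist.** In the three drug-touching layers only associations
   whose *every* drug endpoint is whitelisted survive (emulating the
   restriction to approved drugs).  Drug-drug associations therefore need
   both endpoints listed.
4. **Derived lists.** The gene (disease) list is read off the surviving
   drug-gene (drug-disease) associations; the gene-gene, disease-disease
   and disease-gene layers are restricted to pairs with both endpoints in
   the corresponding lists.
5. **Stoplist.** Associations touching a generic term (e.g. *protein*,
   *gene*) are removed.  Matching is exact-token and case-insensitive —
   substring matching would delete tokens such as *proteinase*.

All filters are monotone (each returns a subset of its input) and every
stage's per-layer counts are reported, giving an auditable account of the
chain.

## Null model and significance

Randomized replicates are produced by **double-edge swaps confined within
each layer**: two edges of one layer exchange partners; in a mixed-type
layer only same-type endpoints are exchanged, and in a same-type layer the
second edge's orientation is flipped uniformly.  Proposals creating
self-loops or duplicate edges are rejected but still counted as attempts.
This move preserves, exactly: simplicity, node types, per-layer edge counts
and every node's per-layer degree — the strictest structure-matched null
that still randomizes wiring.  A weaker null preserving only per-layer edge
counts (`null_mode="layer_shuffle"`) is available for sensitivity analysis,
since the strict null deliberately conditions motif signal on the degree
sequence.

Each layer receives `round(swaps_per_edge × m)` attempted swaps
(default `swaps_per_edge = 100`, far past the mixing time of sparse
graphs).  The swap loop is numba-compiled; the membership structure is a
hash map over canonical integer edge keys.  All randomness derives from
`(seed, replicate_index, layer_index)` seed sequences, so replicates are
bit-reproducible and independent of execution order.

For each pattern with real count N_real and null counts over n replicates:

    z = (N_real − mean(N_rand)) / sd(N_rand)        (population sd)
    p = #{replicates with count ≥ N_real} / n

A pattern is a motif when **N_real ≥ 5 and p ≤ 0.05** (both
configurable).  Two conventions exist for the empirical p: counting strict
exceedances (`>`), or counting ties as exceedances (`≥`).  Only the `≥`
convention yields valid conservative p-values under exchangeability — with
strict counting, a pattern whose count is tied across many replicates gets
p = 0 and low-variance patterns are called significant spuriously.  The
significance caller therefore defaults to `≥` (also the FANMOD convention);
`empirical_p` itself defaults to strict counting to match its stated
definition, and both are switchable.  With ~28 patterns tested at
alpha = 0.05 no multiple-testing correction is applied by default,
matching the classical motif-analysis recipe; the calibration property
below bounds the per-pattern false-call rate.

Patterns with zero null variance have undefined z (reported as such) but
can still be significant through p and the occurrence floor.

## Core network, degree structure, hubs

The core is the union of induced edges of all matches of significant
patterns, with per-edge and per-node provenance.  By construction it is a
subgraph of the input network and every core edge lies in at least one
significant match; dropping a pattern from the significant set can only
shrink it.

Degree distributions per entity type are summarized by histogram, CCDF and
a discrete power-law fit: alpha is estimated by numerical maximum
likelihood under P(k) = k^(−alpha) / ζ(alpha, xmin), with xmin chosen by a
Kolmogorov–Smirnov scan (log-log regression on binned histograms is biased
and not offered).  The popular closed-form approximation
`1 + n / Σ ln(x/(xmin−½))` is noticeably biased at xmin = 1 and is not
used.  Hub reports are top-k by degree with lexicographic tie-break;
"fewer than 10 links" is echoed as the descriptive hub cutoff in reports,
but selection itself is rank-based since no formal rule exists.

Pattern subnetworks use *induced* edges — all associations among the
participating nodes, not just match edges — so their per-layer counts
describe the full local association structure around a motif.  Candidate
prioritization returns the source anchor's typed neighbors not yet linked
to the target, ranked by the number of nodes adjacent to both candidate
and target (shared-neighbor support), then lexicographically; the premise
(at least one shared neighbor) is checked and the rule is recorded in
output metadata.

## Synthetic data

The generator emulates the statistical shape of a literature predication
corpus, not its content: six layers over three types; redundancy (each
unique pair expanded to ~Poisson-distributed record counts with distinct
synthetic PMIDs and both argument orders); heavy-tailed within-layer
degree structure via Chung-Lu wiring with zeta-distributed weights
(exponent 2.5, capped at √(2m) to avoid hub saturation); contaminating
generic-term nodes; and planted motif matches wired onto reserved nodes so
the planted count is a guaranteed lower bound on the realized count (the
manifest records both).  Planted non-drug nodes are anchored to a small
set of whitelisted reserved drugs, because in the emulated corpus every
analysed disease/gene is drug-connected by construction of the derived
lists; without the anchors no planted motif could survive preprocessing.

The default study configuration is a sparse tripartite regime chosen to
resemble a filtered literature network: 300 diseases, 300 genes, 100
drugs; per-layer edge budgets {disease-disease 200, disease-gene 400,
disease-drug 200, drug-gene 150, drug-drug 50, gene-gene 200}; 30 planted
disease-disease-gene triangles.  What the generator does **not** emulate:
real term frequency distributions, UMLS typing noise, extraction errors
correlated with entity popularity, or inter-layer degree correlations.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signal under heavy-tailed sparsity — not
performance on any real corpus.

## Numerical and design choices

- Census counting is closed-form per center node for paths (neighbor-type
  tallies with a per-triangle correction at each corner) and
  edge-anchored for triangles, so a counts-only census costs one triangle
  enumeration; match-keeping mode enumerates explicitly.  Both modes are
  tested against a brute-force C(n,3) oracle.
- Entity-type conflicts (one id typed two ways) abort graph construction:
  node color is load-bearing for motif classification and must not be
  coerced.  Isolated nodes never enter the graph.
- Canonical pattern strings: `tri:t1,t2,t3` (sorted) and
  `path:center=c;leaves=t1,t2` (leaves sorted); pattern order in reports
  is paths before triangles, each sorted by canonical string.
- Power-law fits require at least two distinct tail values; the xmin scan
  keeps at least 10 tail points (relaxed for tiny samples).
- Problem sizes in the test and acceptance workloads (the 700-node study
  fixture, 100–200 null replicates, 20 recovery seeds, n = 5000 degree
  sequences) were chosen as the smallest scales at which the statistical
  properties are stable; all scale linearly upward.

## Known limitations

- Motifs are limited to three nodes; larger motifs would need a general
  colored-canonical-form enumerator.
- The analytic normality of z is not relied on anywhere; only empirical
  p-values gate significance.
- The weaker `layer_shuffle` null does not preserve degree sequences; its
  z-scores confound degree effects with motif signal (that is its purpose
  as a sensitivity probe).
- N-Triples export serializes associations only (no provenance or support).
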