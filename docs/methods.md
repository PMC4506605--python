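# Methods

## Problem and model

The package analyses candidate protein–protein interactions (PPIs) between
two gamete compartments. Each candidate pair carries heterogeneous
evidence: per-channel confidence probabilities from functional-association
sources, a MINT-inspired (MI) confidence score summarizing physical
(experimental) support, a supporting-publication count, a physical flag and
a cross-species conservation count. The analysis assumes interactions are
undirected and unweighted, that the graph is simple (self-interactions are
rejected at parse time), and that topological centrality in the assembled
network is a usable proxy for protein essentiality — the standard
hub/bottleneck essentiality argument for scale-free PPI networks.

## Evidence handling

Records are canonicalized to lexicographically sorted pairs. Records
duplicated across sources are merged conservatively: per-channel maximum
score, maximum MI score, maximum publication and conservation counts,
logical OR of the physical flag. Maximum is a declared convention (source
databases rarely document reconciliation); it is deterministic,
order-independent and biased toward retention, so no threshold decision is
ever made on an artificially diluted score. Combined scores present in
input files are ignored and always recomputed from the channel scores.

## Confidence filters

* Functional route: `S = 1 − ∏ᵢ(1 − Sᵢ)` (noisy-OR under channel
  independence), keep `S > 0.700`. The cut is strict-greater; with the
  default threshold the inclusive reading differs only on pairs whose score
  is exactly 0.700, and the threshold is a config field.
* Physical route: keep pairs that are physical AND have ≥ 3 publications
  AND are conserved in ≥ 1 species AND have MI ≥ 0.431 (inclusive).

No prior-correction or rescaling is applied to the combiner: the formula is
implemented exactly as written above. All four thresholds live in
`FilterConfig` (YAML-serializable, CLI-overridable).

## Network assembly

The compartment *overlap* keeps the shared nodes and the union of both
compartments' edges restricted to shared pairs. Edge-union (rather than
edge-intersection) is deliberate: each compartment's evidence is an
incomplete sample of the same underlying physical interactions, so an edge
reported by either compartment between two shared proteins is evidence for
the shared interface. This is also the only reading under which the overlap
can carry more interactions than the smaller input, which real studies of
this design exhibit. The *membrane subnetwork* is the induced subgraph on
proteins annotated with a signal peptide and/or transmembrane domain;
missing annotations fail loudly rather than defaulting to non-membrane.
The two high-confidence networks are built over the **full** membrane node
set (a protein that loses all edges to filtering is retained at degree 0)
and merged by node/edge union, so the union's node count equals the
membrane network's even when the two filtered edge sets cover fewer
proteins. Filtering after membrane extraction is the default stage order;
`filter_first` applies the filters to the raw compartment evidence instead.

## Topology

* Degree: incident-edge count.
* Betweenness: shortest-path pair dependencies normalized by
  `(n−1)(n−2)/2`, so values lie in [0,1] and are comparable with published
  hub tables; unreachable pairs contribute 0; n < 3 gives all zeros.
* Closeness: reciprocal mean distance to *reachable* nodes
  (component-restricted); isolated nodes report 0. Note a consequence of
  this convention: an edge bridging two components can lower an endpoint's
  closeness, because newly reachable distant nodes raise its mean distance.
* Path statistics: histogram over connected unordered pairs;
  characteristic path length is the count-weighted mean, reported as
  explicitly undefined (None) when no pair is connected, never as 0.
* Power-law fit: `P(k)` = fraction of positive-degree nodes with degree
  `k`, one point per observed degree (no binning), ordinary least squares
  of `log₁₀P(k)` on `log₁₀k`; the slope is the degree exponent and R² the
  coefficient of determination of that regression. Degree-0 nodes and
  zero-count degrees are excluded (log of zero). Fewer than two distinct
  positive degrees is an error. This unbinned least-squares convention is
  simple and reproducible but systematically shallow: on a preferential-
  attachment graph with asymptotic exponent −3 it fits ≈ −1.9 at n = 2000
  (tail noise flattens the line). That bias is inherent to the convention,
  not a defect of the implementation — the regression itself is verified
  against a closed-form recomputation to 1e-9 — and it is why maximum-
  likelihood fitting with tail selection is the better tool when the
  exponent value itself is the scientific claim (out of scope here).

## Target calling

Hub iff `degree ≥ max(degree)/2`; bottleneck iff
`betweenness ≥ max(betweenness)/2`; both inclusive so boundary values
created by rounding in published tables are retained (on the bundled
reference table this is observable only for betweenness: 0.1 vs max 0.2).
Putative targets are the hubs; bottleneck status is an auxiliary flag.
Output ordering is degree descending, betweenness descending, gene symbol
ascending (a declared tie-break). Drug lookup keys on gene symbol against
a two-column association table; the bundled default covers the six
sperm–egg adhesion hubs with known drugs and intentionally has no row for
hubs without known drugs (e.g. CD9). Drug names are kept verbatim as
published (brand/generic not normalized). One known quirk of the source
material: the published drug table lists EGFR at degree 25 where the
centrality table prints 26; the association fixture stores no degrees, so
nothing needs reconciling, but report readers should expect the
discrepancy in the originals.

## Synthetic studies

`StudySpec` defaults emulate the scale of the motivating study: a
2076-protein sperm network, 409-protein egg network, 167 shared proteins,
membrane fraction 0.63, preferential-attachment parameter m = 4. Both
compartments embed a shared scale-free core (Barabási–Albert with a
complete seed clique, so the edge count is exactly `m(n−m) + C(m,2)`).
`n_planted_hubs` shared proteins — always membrane-annotated — are wired to
degree ≈ 0.55–0.70·n_shared within the core, far above anything
preferential attachment produces, and recorded as ground truth; they are
what end-to-end recovery tests measure against. Evidence fields are drawn
per edge label: true edges get Beta(8,2) channel scores (mean 0.8),
Beta(6,3) MI, Poisson(4) publications, Poisson(2.5) conservation; noise
edges (30% of the true count, sampled from non-adjacent pairs) get
Beta(2,8) channels, Beta(2,8) MI, Poisson(0.8) publications. The physical
flag is Bernoulli(0.7) for all edges — noise is rejected by its MI and
publication support, not by the flag. These distributions are modeling
choices (no study publishes them); their only role is to make the two
filter routes separate signal from noise at realistic, non-trivial rates.
A single integer seed drives every draw, and `write_study` emits a JSON
sidecar with the generating spec.

What the generator does **not** emulate: correlated evidence channels,
study-bias in publication counts, false-negative (missing) true edges,
protein families, or any biological identity of nodes. Passing tests
therefore demonstrate that the pipeline's arithmetic and rules behave as
specified and that strongly separated evidence yields near-perfect target
recovery — not that the method's biological conclusions transfer to real
interactomes.

## Test-scale choices

Property tests use random graphs up to 60 nodes against exhaustive BFS
oracles; the end-to-end recovery check runs 20 seeded studies at
150/120/80 proteins with 8 planted hubs (recovery criterion: ≥ 7 of 8 in
≥ 18 of 20 seeds). These sizes give each run hundreds of evidence records
and non-trivial filtering losses while the whole suite stays interactive.

## Known limitations

* The overlap semantics and duplicate-merge rule are declared conventions;
  other tools' "network intersection" may differ.
* The unbinned least-squares exponent is biased shallow (above).
* Closeness/betweenness conventions target undirected, unweighted simple
  graphs only.
* Drug associations are a static bundled snapshot keyed by gene symbol; no
  identifier mapping or live lookup is attempted.
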