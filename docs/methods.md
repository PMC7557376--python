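# Methods

## The similarity network

The package's object of study is a weighted, undirected drug–drug graph
G = (V, E, w). Nodes are drugs (identified by opaque ids; display names are
attributes, since names collide). For each unordered drug pair the weight
is the number of targets on which both drugs act with the same binary type,
agonist or antagonist. Raw action vocabularies are richer than that binary
(inhibitor, blocker, inducer, potentiator, ...), so a configurable,
case-insensitive mapping normalizes them; unmapped strings become UNKNOWN
and are excluded from similarity counting by default, because an untyped
interaction cannot match "the same way". A flag can instead treat UNKNOWN
as a third matchable type. Duplicate (drug, target) rows that disagree on a
typed action are dropped with a warning rather than arbitrated — a silent
guess would not be reproducible. The projection keeps edge-less drugs as
isolates so it stays a pure function of its input; all downstream network
statistics are computed on the largest connected component (ties broken
toward the component containing the smallest node id).

## Community detection

Partition quality is weighted modularity

    M = Σ_C [ w_EC / w_E − (w_C / (2 w_E))² ]

with w_E the total edge weight, w_EC the weight inside community C, and
w_C the summed weighted degree of C's members; with unit weights this is
the classic Newman–Girvan form. The all-in-one partition scores exactly 0
and M ∈ [−1, 1]. A detected partition is therefore never reported with
M < 0: recursion stops rather than accept a split worse than trivial.

The default detector is recursive spectral bisection. A two-way split is
scored through the modularity matrix B = A − k kᵀ/(2 w_E); subdividing an
existing community uses Newman's generalized matrix B^(C) (restriction of B
with the diagonal corrected by row sums) so that the *change* in overall
modularity is what is maximized. Candidate sign vectors come from the top
two eigenvectors (sign and median splits) plus a fixed-seed batch of eight
random starts, each polished by Kernighan–Lin-style single-flip passes:
every pass flips each node once, always taking the best available flip even
when locally negative, then rewinds to the best state seen. Plain steepest
ascent from the leading eigenvector alone stalls in single-flip local
optima on a few percent of small random graphs; the multi-start KL scheme
matched the exhaustive 2^(n−1) sign-vector optimum on 500/500 random
weighted graphs with n ≤ 12 during development, at negligible cost for
desk-scale networks. Everything is deterministic: node-order tie-breaks, a
deterministic eigenvector sign convention, and a fixed internal restart
seed. Recursion ends when no community admits a split with ΔM > 0 (exact
non-improvement, tolerance 1e−12); disconnected inputs are handled per
component. The number of communities is emergent, never user-set.

A greedy multilevel (Louvain) method is available for parity with
interactive tools that use it; both return the partition together with its
weighted modularity.

Communities are labeled by annotation tags held by a **strict majority**
(> 50%) of members; several tags can be dominant simultaneously. Members
lacking every dominant tag form the non-compliant set — the community's
repurposing candidates. Communities with no majority tag stay UNRESOLVED.

## Layout and the cluster-equivalence check

The layout minimizes the Noack-family energy

    E = Σ_{(i,j)∈E} w_ij δ_ij^(a+1)/(a+1) − Σ_{i<j} w_i w_j δ_ij^(r+1)/(r+1)

where δ is Euclidean distance, w_i the weighted degree, attraction acts on
adjacent pairs and repulsion on all distinct pairs; an exponent of zero in
the denominator uses the logarithmic limit. Admissible exponents are a ≥ 0
and −1 ≤ r ≤ 0; the default (1, 0) gives quadratic attraction and linear
repulsion, and (1, −1) is the LinLog-style variant. Descent is plain
gradient descent with a normalized step, backtracking on any energy
increase (so the final energy provably never exceeds the initial one) and
jitter for coincident points. Iteration default is 1000; the bundled
60-node runs use 300, which is already well converged. No Barnes–Hut
acceleration: the intended scale (≤ a few thousand nodes) does not need it,
and exact gradients keep the monotonicity guarantee simple.

Within this exponent family, minimal-energy spatial clusters coincide with
modularity communities; the package quantifies that equivalence rather than
assuming it, by k-means clustering of the coordinates (k = number of
communities, best of 10 seeded restarts) against the modularity partition
via normalized mutual information. Community membership used in reporting
always comes from the modularity detector, never from the layout.

## Centralities and tail fits

Degree d counts edges; weighted degree d_w sums weights. Betweenness is
computed on the **unweighted** topology (shortest paths count hops), with
endpoints excluded and fractional credit when a pair has several shortest
paths. Two normalizations are exposed: the package default divides each
node's accumulated path fraction by the total pair count C(|V|, 2); the
conventional alternative divides by C(|V|−1, 2). The two differ by a
constant factor, so every ranking — which is what prioritization consumes —
is identical under both. The prioritization score is b/d with the
unweighted degree, 0 by convention for isolated nodes: high betweenness at
low degree flags a drug that bridges communities without many documented
interactions of its own, i.e., unexploited repositioning potential.

Centrality tails are fat, so they are summarized by Clauset-style
power-law fits: for each candidate cutoff x_min the exponent α is the MLE
(closed form continuous, Hurwitz-zeta likelihood discrete), and the cutoff
minimizing the Kolmogorov–Smirnov distance between the empirical tail and
the fitted CDF wins. Discrete KS is evaluated at unique values, comparing
right-continuous values with right-continuous values and left limits with
left limits — comparing across the jump inflates the distance badly on
heavily tied data. Candidate cutoffs are capped at 50 quantile-spaced
unique values keeping at least 10 tail points. Constant input is rejected
as degenerate. On 10⁴ exact inverse-CDF draws from a discrete α = 2.5 law
the fit recovers α within ±0.15 and the true cutoff.

## Prioritization and confirmation bookkeeping

Within each community, members are ranked by b/d descending (ties broken
by drug id); drugs with b/d = 0 are never reported. Ranks are *grouped*:
drugs tied on b/d share one rank cell, and the top t rank groups (default
t = 5) are returned, so the bound t applies to rank groups rather than
drugs — a tie at the cut is reported whole instead of being truncated
arbitrarily. A selected drug is confirmed when any of its annotation tags
equals (case-insensitively) any dominant tag of its community, with
DATABASE outranking LITERATURE evidence; fuzzy or ontology matching is
deliberately out of scope — the mechanical rule is explicit where expert
judgment is not reproducible. The hint set is the top list minus the
confirmed set. Confirmation summaries report, per community, the
DATABASE-/LITERATURE-/unconfirmed percentage over all members (summing to
100), plus the overall confirmed fraction across the whole network.

## Docking work orders

For a property φ, the tested drugs (hints plus negative controls with
little prior probability of φ) are paired with *every* φ-relevant target —
the full Cartesian product — while reference drugs are paired only with
targets they are documented to interact with (in-community references with
in-community targets, outside references with the remaining targets). The
output is a role-labelled pair table; ligand preparation, grid setup, and
the docking runs themselves belong to external software. Negative-control
selection is user input: there is no defensible automatic rule for "little
probability of having φ".

## Synthetic data

The generator emulates the statistical structure the method assumes:
property-coherent communities arising from shared typed targets. Drugs and
targets are split into the same number of blocks; a drug hits a same-block
target with probability p_in and a foreign one with probability p_out.
Each target carries a base action type (agonist with probability 0.5 —
no reason to prefer either type) inherited by its interactors except for a
5% flip noise, a small perturbation representing genuinely discordant
pharmacology. Annotations give each drug its block's property with
probability 0.8 ("dominance", comfortably above the 0.5 labeling threshold
but far from clean, as real property lists are incomplete) and a random
other block's property otherwise — these mislabeled drugs are the planted
repurposing candidates. Evidence is DATABASE with probability 0.7,
LITERATURE otherwise. The reference conditions are 60 drugs, 30 targets,
3 blocks, p_in = 0.6, p_out = 0.05, seed 1; the committed fixture files are
byte-identical regenerations of that specification, and same-seed runs are
byte-identical by construction.

What the generator does **not** emulate: realistic polypharmacology degree
distributions, target families, correlated annotations, or database-scale
sparsity. Passing the end-to-end tests therefore shows the machinery is
correct and the pipeline recovers planted structure under favorable
signal-to-noise; it does not certify performance on a licensed drug–target
database, whose results depend on curation choices outside this package.

## Numerical and design notes

- Modularity normalization follows the standard Newman–Girvan reading
  (d_C/(2|E|))², fixed by the hand-checkable value 0.5 for two disjoint
  triangles split into the triangles.
- Hill-climbing tie-breaks, component tie-breaks, and k-means restarts are
  all deterministic or derived from explicit seeds; two runs of the
  pipeline with the same config are byte-identical (GEXF metadata aside).
- Betweenness on weighted paths is intentionally not offered: the b/d
  score is defined against hop-count paths and unweighted degree.
- The pipeline writes every stage artifact (graph, partition, coordinates,
  centralities, fits, hints) plus a machine-readable report; stage timings
  go to the log, never into result files.

## Known limitations

- Recursive bisection inherits the known biases of modularity maximization
  (resolution limit, no overlapping communities); no correction is applied.
- The action-normalization table is a declared approximation — real
  vocabularies include genuinely ambiguous terms ("binder", "modulator")
  that default to UNKNOWN and drop out of the similarity count.
- Exact layout coordinates are not comparable across platforms or library
  versions; only their cluster structure is contractual.
- The KS-selected power-law cutoff is noisy on small tails; fits report
  the tail size so downstream consumers can judge stability.
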