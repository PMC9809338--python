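# Methods

## The problem

A disease regulatory network — here, the kind built by mapping a
differentially-expressed-gene (DEG) list onto a reference human gene
regulatory network — can be attacked from two directions: find the genes
that hold the *structure* together (hubs, dense modules) or the genes that
*control* the dynamics (driver nodes from structural control theory).  The
package computes both families of candidate target sets, arbitrates between
module detectors with a stability (entropy) criterion, fuses module rankings
across eleven topological metrics, and assembles the **optimized hit
network-target set (OHNS)**: the core module united with the top-k
control-centrality driver nodes.  An evaluation battery quantifies what each
set does to the network when removed, how well it recovers a reference
target list, and whether its genes are essential in knockout screens.

## Network model and conventions

The network is a simple directed graph over gene symbols.  Conventions that
the literature leaves open, fixed here once:

- **Distances are undirected.**  Characteristic path length L, giant
  component, and all hub metrics run on the underlying undirected simple
  graph; connectivity, not reachability, is what they measure.  Only
  controllability and the in/out-degree statistics use edge direction.
  Self-loops are kept in the edge set (they matter for matching) but ignored
  in distance and clique computations.
- **Disconnected pairs are excluded from L**: Li is the mean distance from
  node i to the nodes it can reach, L the mean of Li over nodes with at
  least one partner; a network with no connected pair has no L (an explicit
  marker, never a number).
- **Giant component fraction** is largest-component size over node count.
  In nested removal traces the denominator is the *intact* network's size,
  which makes the trace non-increasing by construction; in single-node
  scans it is the residual network's own size (the conventional definition).
- Gene symbols are matched exactly and case-sensitively; a case-folding
  switch exists at load time because silent folding makes node counts
  irreproducible.

## Driver nodes and control centrality

Drivers are identified by maximum-cardinality matching of the network's
bipartite split (one out-copy and one in-copy per gene, a bipartite edge per
regulatory link): genes unmatched as targets must receive independent
control inputs, and the driver count is max(N − |M|, 1) — a perfectly
matched network still needs one input, by convention at the
lexicographically smallest gene.  Because maximum matchings are degenerate,
the matching is canonicalized by augmenting in-copies in descending
lexicographic order, which makes the reported driver set the
lexicographically smallest one and the whole pipeline machine-independent.

Control centrality Cc(v) — the generic dimension of the subspace
controllable from a single input at v — is computed as the rank over a
prime field (default prime 2³¹ − 1, which must exceed n²) of the Krylov
sequence b, Ab, A²b, … with independent uniformly random nonzero edge
weights, restricted to the subgraph reachable from v.  A specialization can
only lower rank, so each draw fails with probability ≤ n²/p and the maximum
over 3 independent draws (configurable) is reported.  The iteration stops
at the first Krylov vector dependent on its predecessors, since Krylov
spans are nested.  Exact consequences used as test oracles: on a directed
path the rank equals the reachable-set size; on a branching out-tree the
Krylov vectors live on disjoint BFS levels, so the rank is the number of
levels (depth + 1) — *not* the reachable-set size.

The published workflow selects a subset of drivers "according to control
centrality" without stating the rule; the package exposes plain top-k
(descending Cc, lexicographic ties) with configurable k (defaults: 201 for
the driver-node set, 50 for the OHNS component).

## Hub metrics

Eleven per-node metrics (the cytoHubba family): degree, MCC, MNC, DMNC,
closeness, eccentricity, radiality, bottleneck, stress, betweenness, EPC.
Choices worth noting:

- **MCC(v) = Σ over maximal cliques C ∋ v of (|C| − 1)!** via Bron–Kerbosch
  with pivoting; on a node whose neighbors are pairwise non-adjacent this
  reduces to the degree; isolated nodes score 0.  A configurable cap on the
  clique count guards pathological inputs.
- **DMNC** uses the original exponent 1.7 (|E|/|V|^1.7 of the largest
  open-neighborhood component); **bottleneck** uses the original n/4
  subtree threshold with lexicographic BFS parent tie-breaking.
- **Closeness is harmonic** (Σ 1/d), so disconnected graphs are
  well-defined; cross-component terms contribute 0.
- **Betweenness and stress** count ordered source–target pairs,
  unnormalized.  Any consistent convention only rescales ranks, and ranks
  are all the fusion step consumes.
- **EPC** is Monte-Carlo: mean component size of the node under independent
  edge percolation, default keep probability 0.5 and 1000 realizations,
  seeded.

Core nodes (CN) are the top-100 genes by MCC (k configurable).

## Module detection and entropy arbitration

Three detectors are compared: weakly connected components; Markov
clustering (inflation 2.0, 16 iterations, clusters read off as attractor
basins; iteration count from the published workflow, inflation the
canonical default since only the iteration count is published); and MCODE
(degree cutoff 2, k-core 2, node score threshold 0.2 — the published
parameters; haircut and fluff off since only those three are listed).
MCODE weights each node by the core level times the density of the densest
k-core of its closed neighborhood, grows complexes from high-weight seeds
over neighbors within 20% of the seed weight, and discards complexes
without a 2-core.  Modules of size < 2 are dropped everywhere: a single
gene is not a module, and the entropy of an edgeless set is undefined.

The **network structure entropy** of a node set is E = −Σ Ii ln Ii on its
induced undirected subgraph, with Ii = ki/Σkj the degree-normalized
importance (the standard choice; the source workflow does not define Ii).
E is maximal (ln n) exactly on degree-regular subgraphs, so lower entropy
means a more homogeneous, more stable module.  The per-method scalar is the
entropy of the union of its modules' members (a mean-of-modules aggregation
is available; the aggregation behind the published per-method numbers is
not recoverable, union is the default).  The detector with minimum entropy
wins; ties prefer MCODE, then MCL, then components.

## Rank-sum-ratio fusion and the OHNS

Each module of the winning partition is summarized by the arithmetic mean
of its members' eleven metric values (the aggregation is unstated in the
sources; the mean is scale-stable across module sizes).  Per metric, modules
are ranked ascending (best value gets rank m, midranks on ties) and the
rank-sum ratio RSR = Σ ranks/(m · 11) scores each module in [1/m, 1]; a
module dominating every column scores exactly 1.  RSR is invariant under
any strictly monotone transformation of a metric column.  The argmax is the
core module (CM); ties go to the larger module, then to the
lexicographically smallest member.  The OHNS is CM ∪ top-50 drivers by
control centrality, with per-gene provenance (CM / DN / both).

## Evaluation battery

- **Single-node scans**: each gene of a set removed alone (network restored
  between removals), recording residual L and giant-component fraction.
- **Incremental removal**: one seeded permutation per set, removing a
  growing prefix (step 5, 10 iterations — the published protocol),
  recording L and GC per step; random-node (RN) traces draw from the whole
  network.  Nested subsets are the default reading of "genes added each
  time"; independent resampling per step is available behind a flag.
- **F-measure** (Eq. precision/recall harmonic mean) against a reference
  target list.
- **Chi-square** on above-baseline degree ratios across sets (baseline
  |E|/|N| by default), run separately for in- and out-degree; expected
  cells below 1 attach a warning rather than failing.
- **Pearson correlations** between node degrees and post-removal L/GC;
  zero-variance inputs yield an explicit undefined marker.
- **Essentiality filter**: genes whose median (configurable: mean) knockout
  score across cell lines is ≤ −1.0, i.e. at least as depleting as the
  median pan-essential gene on the Chronos scale.  The threshold
  operationalizes the scale's published semantics; the sources state no
  explicit cutoff.
- p-values are reported raw; the assessed workflow applies no
  multiple-testing correction here.

## The synthetic study generator

All inputs the pipeline consumes can be generated with planted ground
truth, so the entire artifact is testable offline.  What the generator
emulates — and what it does not:

- **Regulator/target split.**  Half the genes regulate nothing (real
  regulatory networks are mostly targets); regulator out-degrees follow a
  truncated Pareto tail (exponent 2.5) budgeted so the network-wide mean
  out-degree is 7 on 800 genes, the scale regime of a tumor disease
  network.  Edge targets are drawn proportionally to a heavy-tailed
  per-gene attractiveness, so in-degree is skewed, with many once-regulated
  peripheral genes.  Together these reproduce the regime the method was
  demonstrated in: roughly half the induced network unmatched (driver
  fraction near 50%), and hub removal that visibly fragments the giant
  component — with a light-tailed (near-Poisson) in-degree the network is
  effectively immune to 50-node removals and none of the robustness
  contrasts exist.
- **The planted core module** sits on the 50 highest out-degree regulators
  (the core module of a disease network lives among its master regulators,
  which is what makes it central), and its internal wiring is *replaced* by
  a random near-regular graph at density 0.7 (member degree =
  round(0.7 × 49), parity-adjusted) with random edge directions.  A planted
  stable complex has homogeneous member connectivity — precisely the
  property the minimum-entropy criterion and MCODE's local-density
  weighting reward; Bernoulli wiring instead spreads MCODE vertex weights
  so widely that the detector's own 20% score window cuts the module in
  half, which would make the module unrecoverable by construction rather
  than by signal.  Module regulators broadcast uniformly across the genome
  (only background regulators prefer highly-regulated targets), so no
  outside gene is adjacent to more of the module than the members
  themselves.
- **Pure sources**: 40 non-module regulators have all incoming edges
  deleted; they are in-degree-0 and therefore guaranteed drivers.
- **Gene lists and scores**: the DEG list keeps each gene with probability
  0.6 (0.95 inside the module, so the module survives induction); the
  marker list mixes 50% module genes; the knockout score table draws
  Gaussian scores (sd 0.15 over 20 cell lines) around 0 for background
  genes and −1.1 for 13 planted essential genes chosen from the module
  members present in the DEG list.
- **Not emulated**: expression values, differential-expression calling,
  gene-identifier namespaces, co-expression structure, and any biological
  annotation.  Passing tests show the *algorithms* behave as specified
  under a realistic topology; they say nothing about biological validity on
  real data.

One global seed fans out to per-stage streams keyed by a CRC32 hash of the
stage name, so adding a stage never perturbs the randomness earlier stages
see; identical seeds give byte-identical outputs.

## Problem sizes and numerical choices

The default study is 800 genes / ~5600 edges, inducing a disease network of
~500 genes; the test suite also uses a 200-gene miniature for fast
end-to-end checks.  MCL iterates dense column-stochastic matrices with a
1e−8 max-norm convergence window and a 1e−6 attractor threshold.  The
Krylov rank arithmetic keeps all products of two residues within int64 and
reduces per-row sums modulo the prime before accumulation.  Removal traces
at 100 replicates use the giant component only (L is skipped) to keep the
robustness comparison fast.

## Known limitations

- The rule that reduced the published driver set from 396 to 201 genes is
  not recoverable; top-k by control centrality is exposed instead.
- Module-level fusion ranks modules directly; ranking genes first and then
  scoring modules is a plausible alternative reading of the source
  workflow and is not implemented.
- The entropy aggregation behind the published per-method values (union vs
  mean) is a documented guess; both are available.
- Control centrality is randomized (failure probability ≤ n²/prime per
  draw); a structural path-cycle-cover computation would be exact but is
  not implemented.
- Networks are assumed to fit comfortably in memory as dense n × n float
  matrices during MCL (n up to a few thousand).
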