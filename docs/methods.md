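# Methods

## Model and procedure

`statemotif` treats genome organization as an undirected, unweighted
simple graph G(V, E): nodes are chromatin regions, edges are spatial
interactions, and each node carries exactly one chromatin-state label.
The analysis has four stages.

**1. Census.** All connected induced subgraphs on k ∈ {3, 4} nodes are
enumerated exactly once with an ESU-style algorithm: each subgraph is
grown from its least node (in sorted node order), extension candidates
restricted to exclusive neighborhoods, which guarantees uniqueness
without bookkeeping of seen subsets.  Classification uses
*induced-occurrence* semantics: a k-subset contributes one count to the
type of its full induced subgraph only, so a triangle yields one type-I
count and no type-II count.  Canonical forms are the maximum
upper-triangle bit string of the adjacency matrix over all k!
permutations; at k ≤ 4 this exhaustive search is exact and costs at most
24 permutation evaluations, so no canonical-labelling library is
involved.  A per-(topology, state-tuple) cache makes census cost linear
in the number of connected subsets after the first occurrence of each
labeled shape.

**2. Colored canonicalization.** A state-marked subgraph is mapped to
the lexicographically least state sequence achievable by any isomorphism
onto the canonical graph.  Two labeled subgraphs receive the same
`colored_motif_id` (format `<size>:<adjacency bits>:<state1;...>`) iff
they are color-isomorphic.  When several isomorphisms achieve the
minimal state sequence (automorphic ties), the one giving the
lexicographically least node-index sequence is used to order instance
nodes, making occurrence files deterministic.  The number of *possible*
colored motifs of a type with N states is the number of orbits of state
assignments under the motif's automorphism group, by Burnside's lemma
(average of N^cycles over automorphisms); for the triangle and N = 4
this is 20, i.e. the number of 3-multisets from 4 states, since the
triangle's automorphism group is all of S3.

**3. Null models.**
- *Edge swap* (method I): repeated double-edge swaps a–b, x–y → a–x,
  b–y preserve every node's degree and the edge count.  Two distinct
  edges are drawn uniformly without replacement per proposal; edges are
  held in sorted orientation, and the pairing is always first-with-first
  / second-with-second.  Proposals creating a self-loop or duplicate
  edge are rejected and retried; the budget counts *successful* swaps
  (default 5·|E|, rounded), which keeps the null's distance from the
  real network well defined.  A safety cap of 100 attempts per requested
  swap turns pathological inputs (e.g. complete graphs, where no valid
  swap exists) into a clear error instead of a hang.
- *State shuffle* (method II): the topology is untouched and the
  node→state assignment is permuted uniformly at random, preserving the
  state multiset exactly.

Replicate i of the ensemble is seeded with the pair (base_seed, i) fed
to numpy's `default_rng`, never with shared generator state, so the
ensemble is bit-identical for any worker count; parallelism (joblib) only
distributes replicates.

**4. Enrichment.** For every colored motif with real count ≥ 1, the
empirical P-value is |{replicates with count ≥ real count}| / n_random
(a motif absent from a replicate counts 0 there).  Motifs occurring only
in random networks are not reported — they cannot be over-represented in
the real network.  Fold change is log2((f_real + ε)/(mean_random + ε));
reported records must pass P < threshold and f_real ≥ min_freq and are
ranked by descending fold change within each motif type.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `motif_size` | 3 | subgraph size k; 3 or 4 (one size per fit) |
| `method` | `edge_swap` | null model: degree-preserving rewiring vs state permutation |
| `n_random` | 500 | random-network replicates in the ensemble |
| `swaps_per_edge` | 5 | successful swaps per edge for method I |
| `p_threshold` | 0.05 | empirical P-value cutoff (strict `<`) |
| `min_freq` | 1 | minimum real-network count; raise (e.g. 50) to screen rare motifs |
| `pseudocount` | 1 | ε in the fold change; guards motifs absent from the ensemble |
| `seed` | 0 | base seed for the replicate seed sequence |
| `n_workers` | 1 | joblib workers; never changes results, only wall time |

Numerical conventions: log base 2 (the genomics convention) for fold
change; the ensemble SD is the population SD (ddof = 0) and is reported
descriptively only; an exact P of 0 is reported as 0 per the ratio
definition, with the conventional floor 1/(n_random+1) available via
`pvalue_floor=True` but off by default.  **No multiple-testing
correction is applied** — the enrichment filter uses the raw empirical
P-value, so with hundreds of candidate colored motifs the output should
be read as a ranked screen, not a family-wise-controlled discovery set.

Motif-type labels: size 3 follows the chromatin-network convention
(I = triangle, II = path).  Size 4 has no convention recoverable from
prior art, so types are ordered by ascending edge count with ties broken
by the canonical adjacency string — path, star, cycle,
triangle-plus-pendant, diamond, complete = I…VI; this mapping is a
documented choice of this package and other tools may number size-4
types differently.

## Input handling

The parser enforces ≥ 4 comma-separated fields per data row, strips
surrounding whitespace, treats state labels case-sensitively, collapses
duplicate edges (count logged), and drops self-loop rows with a warning:
the network is defined to be simple and undirected.  A node observed
with two different states is an error by default; the opt-in `first`
and `majority` policies exist because silent coercion could corrupt the
census.  Node identifiers are opaque keys for all computation —
`chromosome:start-end` parsing (1-based inclusive display coordinates
assumed) only feeds the optional BED export, which converts to 0-based
half-open intervals.

## Synthetic data

The fixture generator emulates the input format, not Hi-C physics: a
uniform random simple graph with fixed node and edge counts, states
drawn i.i.d. per node (default: active/repressed/poised/weak, uniform).
It does **not** model genomic-distance-dependent contact probability,
TAD block structure, state autocorrelation along the genome, or the
heavy-tailed degree distributions of real loop networks — so green tests
demonstrate algorithmic correctness (exact census, exact null-model
invariants, recovery of planted signal), not biological realism.
Planted-motif fixtures add vertex-disjoint motif copies on *fresh*
nodes, which makes the planted colored count a provable lower bound in
the census and gives recovery tests a clean expectation.

The recovery experiment used in the test suite plants 40 all-`active`
triangles in a 60-node / 90-edge uniform-4-state background and tests
against 100 state-shuffle replicates; the brute-force equivalence checks
run on networks of up to 14 nodes, where all-subsets enumeration plus
all-permutation isomorphism search is exhaustive yet quick.  These sizes
are the package's reference study conditions for its own validation.

## Degenerate inputs and edge cases

Empty enriched sets write header-only CSVs and skip heatmap images (a
warning is logged); a network with < 2 edges cannot be edge-swapped; a
single-node network state-shuffles to itself; isolated nodes survive
randomization with their states intact but, having no edges, never
appear in any motif.  An edge list cannot represent isolated nodes, so a
CSV round-trip preserves the graph restricted to edge-incident nodes.

## Known limitations

- Motif sizes ≥ 5, directed and weighted networks are out of scope.
- Exhaustive enumeration is exact but not sublinear: very dense or very
  large networks multiply the census cost by n_random; use more workers.
- The edge-swap null preserves degrees but not connectivity or
  clustering; the state-shuffle null preserves topology entirely.  A
  joint degree-plus-state null is not offered.
- Empirical P-values are lower-bounded by 1/n_random in resolution;
  ranking among P = 0 motifs falls back to fold change.
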