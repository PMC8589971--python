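# Methods

## Model and assumptions

All computations assume a simple, undirected, unweighted graph. Edge-list
input drops self-loops and collapses duplicate/reversed duplicates at load
time; labels are opaque strings mapped to contiguous indices. Directed,
weighted and temporal graphs are out of scope, as are asymmetric or
weighted gravity variants.

### Stage-tracked k-shell decomposition

Peeling proceeds shell by shell, the next shell value being the minimum
remaining degree (so shells can be skipped, and isolated nodes form a
0-shell removed at stage 1). Within shell k a *stage* is one simultaneous
sweep that removes every remaining node of current degree ≤ k; degrees are
updated between sweeps. This simultaneous-sweep semantics is the only
reading under which the package's worked example reproduces its printed
stage table (the four 3-core nodes of the toy network share a single
stage, and the 2-shell needs two stages), so it is fixed and not
configurable. The improved index k_s*(i) = k_s(i) + p(i)/(max_k q(k)+1)
takes the max over shells that actually occur; since 1 ≤ p(i) ≤ q(k), the
correction is strictly inside (0, 1), giving floor(k_s*) = k_s and
preserving shell order. Values are stored at full float precision;
table-style comparisons in the tests round to the printed 4 (k_s*, DK) or
2 (DKGM) decimals.

### Gravity engine

One engine computes score(i) = Σ_{1≤d(i,j)≤R} mass(i)·mass(j)/d(i,j)² via
radius-limited BFS per node (O(N⟨k⟩^R) on sparse graphs, rather than full
all-pairs shortest paths). Unreachable pairs are silently excluded.
DKGM, GC and LGM are thin instantiations (mass = DK, k_s, degree); GC's
neighborhood is 1 ≤ d ≤ 3, excluding the node itself. Terms are
accumulated in increasing neighbor-index order so results are independent
of BFS discovery order and bit-reproducible. The truncation radius must be
a positive integer; the heuristic R* ≈ ⟨d⟩/2 is rounded half-up and
clamped below at 1 (the rounding rule is a package choice; the heuristic's
scatter around ⟨d⟩/2 on real networks means nearby radii give very similar
accuracy, so rounding direction is not critical).

### SIR influence

Discrete time, synchronous updating: each step, every infected node
attempts to infect each susceptible neighbor independently with
probability β, after which it recovers with probability λ (default 1, one
infectious step; infections happen before that step's recoveries).
Synchronous updating is the package's reading of a per-step dynamics; with
λ = 1 a β = 1 outbreak is exactly a BFS wave. F(i) is the mean of N_r/N
over independent realizations with i the sole seed. Each outbreak draws
from a substream keyed by (master seed, realization, node) via
`numpy.random.SeedSequence(entropy, spawn_key)`, so results are
bit-reproducible and independent of loop order. "K realizations" means K
outbreaks from every node. The mean-field threshold β_c = ⟨k⟩/(⟨k²⟩−⟨k⟩)
raises an error when ⟨k²⟩ ≤ ⟨k⟩ (e.g. a perfect matching), where the
formula has no positive solution.

### Evaluation metrics

Kendall's tau is implemented exactly as the pair-counting form
2(n₊−n₋)/(N(N−1)): tied pairs (in either sequence) count as neither
concordant nor discordant but remain in the denominator (a tau-a-style
normalization). A tau-b variant (scipy) is available behind
`variant="b"` for comparison and is never used by default. Monotonicity is
[1 − Σ N_t(N_t−1)/(N(N−1))]² over tie classes. Both metrics are
tie-sensitive, so floating scores are compared after rounding to 10
significant digits, which keeps tie classes stable across summation
orders while being far below any meaningful score difference.

### Descriptive statistics

⟨d⟩ averages over unordered *reachable* pairs only — the only finite
choice on disconnected graphs, which are accepted throughout; statistics
are computed on the full graph, not the largest component. Clustering C is
the mean local clustering coefficient with degree-0/1 nodes contributing
0; assortativity r is the Pearson degree correlation over edge endpoints
(both orientations), NaN with a warning when undefined (no edges or
regular graphs); H = ⟨k²⟩/⟨k⟩², the standard degree-heterogeneity index
(1 for regular graphs). Closeness on disconnected graphs uses the
component-scaled (Wasserman–Faust) form, which multiplies the
within-component closeness by n_i/(N−1) and so penalizes small
components; betweenness is the unnormalized unordered-pair form (constant
factors are irrelevant for rankings). Degree-0 nodes get closeness 0 and
H-index 0.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| R (hops) | gravity truncation radius | round(⟨d⟩/2), ≥ 1 | the ⟨d⟩/2 heuristic; 2–3 on small-world graphs |
| β | infection probability per contact per step | β_c | near-threshold is where rankings differ most: below, outbreaks die locally; far above, every seed saturates |
| λ | recovery probability per step | 1.0 | one infectious step; makes β_c the ⟨k⟩/(⟨k²⟩−⟨k⟩) form |
| realizations | outbreaks per seed node | 1000 | Monte-Carlo error ∝ 1/√K; 1000 stabilizes the standard ranking |
| rng_seed | master seed | 0 | all randomness flows from it |

## Synthetic data

The generators emulate the regimes that matter for spreading experiments:
`er` (homogeneous), `ba` (heterogeneous, scale-free; seeded from a K_m
clique so the edge count is exactly m(n−m)+C(m,2)), `ws` (clustered
small-world) and `tree` (uniform labeled trees — the sparse, near-acyclic
regime where neighborhood- and path-based centralities degrade). The
benchmark experiment in the test suite uses a 200-node BA graph with
m = 3 and 1000 SIR realizations per seed at β ∈ {β_c/2, β_c, 2β_c}; this
problem size makes the full suite run in well under a minute of
simulation while leaving the Monte-Carlo error small relative to the
effect sizes checked. Synthetic graphs are Markovian constructions: they
reproduce degree heterogeneity, clustering or sparsity individually but
not the correlated community structure, degree assortativity or fat-tailed
distance profiles of real contact networks. Tests passing on them show
the machinery is correct and that the qualitative ordering (gravity
methods ≥ DC/KS in accuracy and resolution) holds in the regimes they
span — not that the quantitative tau values transfer to any particular
real network.

## Numerical choices and degenerate inputs

* Gravity and tau accumulate integers or fixed-order float sums; repeated
  runs are bit-identical.
* Rank output sorts by descending score with ties broken by node label,
  so CLI output is byte-stable; tied scores are printed tied (no jitter).
* Empty graphs decompose to empty maps; an edgeless graph yields NaN
  assortativity/β_c with a warning rather than an error.
* The toy fixture is hard-coded (not generated): it is the package's
  primary regression fixture and its 13 edges are verified against five
  independent hand-checkable tables in the tests.

## Known limitations

* The SIR simulator is single-seed, synchronous, discrete-time; no
  Gillespie dynamics, SIS/SEIR, or multi-seed spreading.
* Gravity scores on dense graphs with large R approach O(N²) BFS cost; the
  engine targets the sparse regime the truncation is designed for.
* Tau on very large score vectors uses an O(N²) blocked pair count —
  exact and adequate up to ~10⁴ nodes, but not the O(N log N) variant.
* Printed tau values on real benchmark corpora depend on the exact tie
  conventions of whichever tau variant a study used; comparisons across
  implementations should fix the variant explicitly.
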