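# Methods

## Flow model

The unit being described is one step of a random walker along links. For
undirected networks the stationary visit rate of node α is its strength
(sum of incident link weights, self-loops counted twice) divided by the
total strength, in closed form; each link carries flow w/(2W) per
direction. For directed networks the walk teleports to a uniformly random
node at rate τ (default 0.15, the convention of the method's antecedents;
exposed as a parameter) to guarantee ergodicity, and dangling nodes
teleport with probability one. The stationary distribution is found by
power iteration from the uniform start with an L1 tolerance of 1e-12 and a
10,000-iteration cap; non-convergence raises an error carrying the
residual.

Teleportation is a regularization, not part of the system being described,
so it is excluded from the code: each link's flow is the source's
stationary rate times (1-τ) times the link's relative out-weight, all link
flows are renormalized to sum to one, and each node's visit rate is
replaced by its total link inflow (arrivals are what a "node visit"
codeword encodes; this is a documented convention — the outflow aggregate
would differ for directed networks). After the correction a node's in- and
outflow need not balance.

## Codelength

Every vertex of a partition tree owns one codebook. Its entries are the
enter rates of child modules, the visit rates of child leaf nodes, and —
below the root — the vertex's own exit rate; the vertex contributes the
entropy of the normalized entries weighted by their sum (the codebook's use
rate). Logs are base 2, 0·log 0 = 0, so zero-flow modules cost nothing.
The total is exactly additive over vertices, and a depth-2 tree reproduces
the two-level map equation to machine precision (a tested invariant).

One convention deserves note: index codebooks at every level (including the
two-level case) are populated with module *enter* rates, while each
module's *exit* codeword lives in the module's own codebook. For
undirected networks enter and exit coincide and the distinction is
invisible; for directed flows this is the decomposition that makes the
two-level equation the exact depth-2 special case of the hierarchical one,
which the package treats as non-negotiable.

## Search

Flow is computed once on the full network; every nested search operates on
exact aggregates of visit rates and boundary flows, since the objective
depends on rates only.

* **Core.** Singleton modules; in random sequential order each node moves
  to the neighboring module giving the largest codelength decrease (ties:
  stay put if staying ties the best, otherwise the lowest-index module; a
  fresh empty module is also a candidate, which lets the search split
  modules in place). When a sweep changes nothing the network is rebuilt
  with modules as nodes and the procedure repeats.
* **Refinements.** (1) Submodule movements: each module is recursively
  re-clustered in isolation and the resulting submodules become freely
  movable units; (2) single-node movements: the core is re-run from the
  current partition with individual nodes movable. The two alternate while
  they improve the result (round cap 20).
* **Multilevel recursion.** For a module at any level the algorithm first
  finds the best flat split of its interior. If splitting shortens the
  description it recurses two ways: into each submodule's interior (finer
  index codebooks) and onto the aggregate network whose nodes are the
  submodules, with node flow equal to their enter rates (coarser index
  codebooks). An extra level is kept only when it shortens the total by
  more than the improvement threshold (default 1e-10 bits, pure
  floating-point guard). Both the flat one-codebook description and the
  recursive alternative are costed exactly, so accepted structure is never
  a heuristic estimate. Depth is bounded at 20 as a safety cap.
* **Restarts.** The whole construction restarts `n_restarts` times
  (default 100; accuracy grows with repetition) from independent RNG
  streams spawned from the seed, and the shortest description wins. The
  winning tree is re-scored by the codelength module, so search bookkeeping
  can never leak into reported numbers. Identical seed and configuration
  give identical trees.

The exhaustive oracle (`exhaustive_two_level_minimum`) enumerates all set
partitions via restricted growth strings and evaluates them vectorized; the
test suite uses it to verify search optimality on every connected graph
with up to 7 nodes.

## Benchmark generator

Three-level networks with planted partitions. Defaults are the standard
test conditions: 10,000 nodes, mean degree 20, maximum degree 100, degree
exponent -2, coarse sizes 400–4,000 and fine sizes 10–100 with size
exponent -1. Sizes are sampled by inverse CDF on the truncated support and
re-sampled until they tile the node count exactly; fine modules tile each
coarse module, so the fine partition refines the coarse one by
construction.

Each node's degree is split binomially into between-coarse (μ1),
within-coarse-between-fine (μ2) and within-fine stubs. Nodes are placed
largest-fit: high within-fine-degree nodes go to fine modules large enough
to host them, mirroring the constraint the default parameters themselves
satisfy ((1-μ1-μ2)·k_max ≤ n_f,max - 1). For scaled-down runs at N = 1,000
(coarse 100–400, fine 10–50) the package uses k_max = 50 to preserve that
same consistency. Stubs that no placement can accommodate cascade to the
next coarser active pool (and are dropped when μ1 = μ2 = 0, keeping the
zero-mixing network an exact disjoint union of fine modules).

Within-fine interiors are built by Havel–Hakimi (after an Erdős–Gállai
graphicality spill) and randomized by degree-preserving double-edge swaps —
small fine modules are near-complete under realistic mixing, where naive
stub matching sheds many duplicate pairs. The μ2 and μ1 pools use
configuration-model stub matching with swap rewiring; irreparable pairs are
dropped. Realized mixing fractions are recorded from the final edge list;
the generator's fidelity contract (tested) is agreement with the targets
within 0.02 on average. What the generator does *not* emulate:
degree-degree correlations, clustering beyond what dense modules force,
weighted or directed links, overlapping membership. Recovery results on it
therefore speak to mixing structure, not to every property of real
networks.

The feasibility region follows from the density chain
p_fine > p_mid > p_out with p_fine = (1-μ1-μ2)/n_f, p_mid = μ2/(n_c-n_f),
p_out = μ1/(N-n_c), evaluated at the extreme module sizes that make each
inequality tightest. Solved for μ1 at given μ2 this yields a rising line
μ2·(N-n_c,max)/(n_c,max-n_f,min) and a falling line
1 - μ2·n_c,min/(n_c,min-n_f,max); the hierarchy is well defined below both.
The wedge is empty at μ2 = 0 (without within-coarse mixing there is no
coarse level to detect, only a two-level structure), widens to the lines'
crossing, and closes again at large μ2.

## Evaluation

NMI uses the Danon arithmetic normalization 2I/(H(X)+H(Y)) with base-2
logs; two identical one-module partitions score 1 by convention. Hierarchy
summaries use per-node (not per-module) averaging for depth and
finest-module size, and compression gain is the percentage reduction
100·(L2 - Lmulti)/L2 relative to the best two-level description, floored at
zero.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything from scratch at
sizes chosen to keep a full run in the minutes range on one core: the
27-node worked example, the 995 connected atlas graphs (≤ 7 nodes) against
the exhaustive oracle, 100 random graph/partition pairs for the reduction
identity, and five seeds of the N = 1,000 scaled benchmark with 5 restarts
each. Search restarts in tests (10–40) are below the package default of
100; all such runs are seeded and therefore exactly reproducible.

## Known limitations

* The search is a stochastic heuristic; global optimality is verified only
  for tiny networks. Hard degenerate landscapes may need many restarts.
* Teleportation is uniform over nodes; smart-teleportation variants and
  injecting empirically measured flow are out of scope.
* Partitions are hard: no overlapping modules.
* The benchmark generator is undirected and unweighted, matching the
  regime it is meant to probe.
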