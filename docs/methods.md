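# Methods

## Model

The simulator implements synchronous bounded-confidence averaging on a
one-dimensional opinion space [0, 1]. Agent *i* with confidence level
*εᵢ* accepts exactly the opinions within distance *εᵢ* of its own
(inclusive boundary, self always accepted) and moves to their weighted
average; all agents update simultaneously. Uniform weights
1/|Nᵢ(t)| are the default and the only scheme exercised by the shipped
experiments; arbitrary strictly positive row-normalised schemes are
accepted through `WeightScheme`.

Heterogeneity is purely *horizontal*: the population is partitioned into
subgroups by confidence level (close-, moderate-, open-minded in the
three-level experiments, ε = 0.01 / 0.2 / 0.45), never by status or
authority. Cross-subgroup influence asymmetry is emergent — a small-ε
agent simply fails the acceptance test for opinions a large-ε agent
accepts — and is never encoded as an input graph.

Assumptions worth keeping in mind: opinions are scalar; updates are
synchronous and noiseless; the dynamics are a pure function of the
initial profile and the confidence assignment (no randomness after
t = 0); every update is a convex combination of current opinions, so the
opinion range can only contract and the profile stays in [0, 1].

## Parameters

| parameter | default | meaning |
|---|---|---|
| `t_max` | 10 000 | step cap; late cluster merges can occur past step 1000, and large heterogeneous runs (n = 1000) stabilise around step 2000–5000 |
| `tol` | 1e-8 | stop when the max per-agent change falls below this (strict) |
| `gap` | 1e-4 | cluster split threshold; orders of magnitude above post-convergence within-cluster spread, far below the smallest ε (0.01) |
| `consensus_tol` | 0.05 | mean cluster count ≤ 1 + tol counts as a consensus grid point |
| replicates | 20 | per sweep point (the full published protocol is 100; the acceptance script uses 100 for the size sweep) |

Subgroup sizes are `round(f_l · n)` (half away from zero) with the
rounding discrepancy absorbed by the largest-fraction subgroup; a
positive-fraction subgroup that would receive zero agents is rejected
rather than silently dropped.

## Seeding

One user seed feeds a `numpy.random.SeedSequence` that is split into two
independent substreams — initial-opinion draw and label permutation — so
changing the subgroup specification never perturbs a shared initial
opinion vector (needed for the fixed-initials fraction sweep). Replicate
*r* of a sweep derives its seed from `(base_seed, point_index, r)` (or
`(base_seed, r)` when initials are shared across grid points), so
replicate sets are extensible without reshuffling earlier replicates.

## Numerics

In one dimension every neighbour set is a contiguous window of the
sorted profile, so the uniform-weight update is computed from a prefix
sum after one sort — O(n log n) per step rather than the naive O(n²)
pairwise scan. The two formulations agree to ~1e-15 on random instances
(the test suite keeps a literal double-loop transcription as the
independent oracle). Prefix-sum subtraction can round a window mean a
few ulp outside the window, so each mean is clipped to its window's
[min, max]; this makes range contraction exact and costs nothing
measurable. All arithmetic is double precision; opinions are never
rounded during a run. Tabular outputs print floats with shortest
round-trip `repr`, so TSV/CSV round-trips are bit-exact.

Convergence is declared at the first step whose maximum per-agent change
is strictly below `tol`; hitting `t_max` flags the result rather than
raising. A profile in which every pair of agents is either identical or
mutually outside both confidence bounds is an exact fixed point.

## Cluster counting

Final profiles are sorted and split at gaps larger than `gap`; each
maximal run is one cluster (equivalently: connected components of the
threshold graph, i.e. single linkage — chaining is transitive).
Consensus is defined as exactly one cluster, however small the
stragglers; this matches counting every distinct surviving opinion
(the fragmented homogeneous regime at ε = 0.01 yields ≈ 39 such
opinions among 200 agents, many of them near-singletons).

## What the generator emulates — and what it does not

The synthetic populations reproduce the published study conditions:
i.i.d. uniform initial opinions on [0, 1] (or a narrow sub-interval such
as [0.5, 0.55]), three-level differentiation with the close-minded
fraction swept over {1, 2, 5, 10, 30}%, a fixed open-minded fraction,
and group sizes 100–1000. Agents are assigned to subgroups by a seeded
permutation *independent of their opinions*; the source experiments
never state this coupling, and results at bifurcation-sensitive
parameters do depend on the particular initial draw. Real opinion
formation — correlated initial opinions, network topology, noise,
opinion leaders — is out of scope, so passing tests certify the model's
behaviour, not real-world forecasting skill.

Two consequences of per-draw sensitivity are documented rather than
hidden:

- At ε = 0.15, n = 200 the homogeneous model is genuinely bimodal
  between polarization (2 clusters) and mild fragmentation (3): over
  500 seeds the split is roughly 47% / 52%. The modal count over a
  20-seed batch is therefore itself nearly a coin flip.
- With initial opinions packed into [0.5, 0.55] and ten close-minded
  agents, full consensus occurs in roughly half of the runs; in the
  others one or two close-minded agents are left stranded just outside
  their 0.01 bound when the main cluster collapses at step 1, surviving
  as singleton clusters.

## Experiment harness choices

- Sweep aggregation uses the replicate **mean** cluster count.
- The critical close-minded fraction is a grid scan (largest grid
  fraction whose mean count stays within the consensus band), not a
  bisection: its resolution is the grid's.
- The scaling law is an ordinary least-squares fit of mean cluster count
  on the swept factor; it is exact on collinear input. Under the
  three-level conditions the count-vs-size curve is convex near small
  *n* (the count is floored at 1 while most close-minded agents are
  still absorbed), so the global OLS slope over sizes 100–1000 sits
  somewhat below the asymptotic growth rate, which approaches the
  close-minded fraction from below as *n* grows.
- Plotting (`viz`) is lazy, Agg-backed and side-effect-free; numerical
  outputs never depend on it.

## Problem sizes

The shipped tests use n ≤ 200 with 20 seeds per condition and a
six-point size grid (100–1000) at 20 replicates; the acceptance script
raises the size sweep to 100 replicates. These sizes put the Monte-Carlo
error of replicate means well below the effect sizes being checked while
keeping a full run in the minutes range on one CPU.

## Known limitations

- Only uniform weights are exercised end-to-end; non-uniform schemes run
  through a slower per-agent path.
- Cluster identity across time steps is not tracked; merge times are
  visible only through trajectories, not summarised.
- The critical-fraction estimator inherits the sweep grid's resolution
  and the replicate mean's sampling noise near the consensus boundary.
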