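# Methods

## Problem setting

`scensus` consolidates `M` hard partitions of the same `n` cells — produced
by external single-cell clustering tools — into a single partition with a
data-driven cluster count. It never re-runs the base tools; it consumes
their label vectors plus the expression matrix the tools were run on.

## Pre-learning: co-membership, quality weights, consensus

Each base partition becomes a binary co-membership matrix `B_p`. Partition
quality is scored label-free with the Calinski–Harabasz (CH) index on the
expression feature space, and scores are normalized to weights
`u_p = CH_p / Σ CH_q` (so `Σ u_p = 1`, `0 < u_p < 1` for `M ≥ 2`). The
weighted consensus `W = Σ_p u_p B_p` has entries in `[0, 1]` and is
binarized at `W_t` with a *strict* inequality (`w_ij = 1` iff the weighted
vote exceeds `W_t`; at the default `W_t = 0.5` this reads "more than half
agree", and a tie at exactly 0.5 maps to 0). The likelihood consumes the
binary `W`; a config flag retains the weighted variant for exploration.

Two CH variants are provided. The default `standard` form is the usual
variance-ratio criterion with the between-cluster scatter weighted by
cluster size and the `(N−K)/(K−1)` degrees-of-freedom factor — this is the
form that ranks partitions sensibly, and ranking is all the weights need.
The `paper` variant (unweighted between-scatter, inverted factor
`(K−1)/(N−K)`) reproduces an alternative printed formula and is kept only
for comparison; it is not recommended.

## Feature space

All expression-side computations (CH scores, the neighbor graph) use
`log1p(CPM)`: counts are scaled per cell to one million and
natural-log-transformed. This is standard variance stabilization for
scRNA-seq; the method itself is agnostic to the choice. An optional PCA
reduction (top components, off by default) is available for wide matrices.
CPM requires every cell to have a positive total count; cells with zero
totals are reported by name as errors, not silently dropped.

## Neighbor graph

An exact Euclidean k-nearest-neighbor relation (default `k = 10`,
self-neighbors excluded) is OR-symmetrized into a binary adjacency `V`;
`D = diag(d)` with `d_i = Σ_j v_ij` and `L = D − V`. Ties between
equidistant neighbors break deterministically by index order (stable
argsort), so duplicate points cannot make runs irreproducible. The graph
penalty is `R₁(H) = ½ Σ_{ijz} (h_iz − h_jz)² v_ij = tr(HᵀLH)`, summed over
all `Q` latent columns.

## Probabilistic model and objective

For each unordered pair `i < j` (the uninformative diagonal is excluded),

    w_ij ~ Bernoulli(1 − e^{−s_ij}),  s_ij = Σ_z h_iz h_jz,

with `H ≥ 0` of size `n × Q`. Column scales `β_z` carry half-normal priors
on the columns of `H` and inverse-Gamma(a, b) hyperpriors — the ARD
mechanism. With additive constants dropped consistently (so values are
comparable across restarts and `α`), the objective is

    F(H, β) = −Σ_{i<j} [ w_ij log(1 − e^{−s_ij}) − (1 − w_ij) s_ij ]
              + Σ_z [ Σ_i h_iz²/(2β_z) + (n/2) log β_z ]
              + Σ_z [ (a+1) log β_z + b/β_z ]
              + (α/2) · tr(HᵀLH).

The graph term carries a factor ½ so that the multiplicative update below
is the *exact* gradient split of the penalty; counting the penalty at full
weight is identical to running the same iteration at doubled `α`, so the
convention only fixes the scale on which `α` is quoted. The `α` grids and
defaults in this package are quoted on the ½-convention scale.

## Optimization

`H` is updated by a damped multiplicative rule,

    h_iz ← ½ h_iz + ½ h_iz · N_iz / D_iz
    N_iz = Σ_{j≠i} w_ij h_jz / (1 − e^{−s_ij}) + α Σ_j v_ij h_jz
    D_iz = Σ_{j≠i} h_jz + h_iz/β_z + α d_i h_iz,

and `β` by its exact coordinate minimizer `β_z = (2b + Σ_i h_iz²)/(n+2a+2)`.
`D − N` equals `∂F/∂h_iz`, so fixed points of the rule are stationary
points of `F`; the test suite verifies this by finite differences rather
than trusting the algebra. The `h_iz/β_z` prior term in `D` is likewise
pinned down by that stationarity check: it is the unique choice consistent
with the half-normal prior whose `β` minimizer is the closed form above.

Numerical guards: `1 − e^{−s}` is computed with `expm1` and floored at
`1e−12` wherever it divides or is logged; update denominators are floored
the same way. Zero entries of `H` stay exactly zero under the
multiplicative rule (they are permanent, which is why initialization draws
from `(0.01, 1)` — strictly positive, away from the absorbing state).

Iteration stops when `‖β_new − β_old‖ < ρ` (default `1e−5`) or after
`max_iter = 100` sweeps. The fit restarts from `n_restarts = 50` random
initializations with seeds `seed, seed+1, …`; the restart with the lowest
objective is returned, bitwise-reproducibly for a fixed seed. A restart
whose objective turns non-finite is dropped with a logged diagnostic; if
all restarts fail, the fit errors out. The per-iteration objective trace is
recorded and exported. The damped rule is a heuristic descent method, not a
provable majorizer: the trace is *monitored* as non-increasing (observed on
≥ 95 % of random instances, asserted at that rate in the tests) rather than
guaranteed.

## Cluster extraction

Each cell takes the argmax of its row of `H*` (ties to the lowest column
index); used columns are relabeled `1..C` in order of first appearance and
`C` is the number of distinct used columns. Rows whose entries all fall at
or below `prune_tol` (default `1e−4`; a column below it everywhere counts
as deleted by ARD) are still assigned but flagged low-confidence. Column
permutations of `H*` change labels only up to relabeling (ARI 1).

## Validation metrics

ARI and NMI are computed from the contingency table, with natural logs
(the base cancels in NMI's `2I/(H₁+H₂)` normalization), the `0·log 0 = 0`
convention, and NMI defined as 1.0 when both partitions are the single
trivial cluster. Both are cross-checked in the tests against brute-force
pair-counting and entropy oracles over complete small-partition families
and against an independent library implementation.

## Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| `Q` (`q_max`) | 25 | upper bound on cluster count; ARD shrinks it |
| `W_t` (`wt`) | 0.5 | consensus vote threshold, strict |
| `a` (`hyper_a`) | 1.0 | inverse-Gamma shape; influence shrinks with `n` |
| `b` (`hyper_b`) | 0.3 | inverse-Gamma scale; swept over {0.1…0.6} |
| `α` (`alpha`) | 100 | graph-penalty weight; 0 = unregularized ablation; swept over {50,150,…,950} |
| `k` (`knn_k`) | 10 | neighbors per cell in the expression graph |
| `ρ` (`rho`) | 1e−5 | β-convergence threshold |
| `max_iter` | 100 | sweep cap per restart |
| `n_restarts` | 50 | random initializations (sweeps default to 5) |
| `prune_tol` | 1e−4 | column-deletion / low-confidence threshold |

`Q` should comfortably exceed the plausible cluster count; `b` and `α` are
the two parameters worth tuning per dataset (the `sweep` command
grid-searches them against reference labels when any are available).

## Synthetic study conditions

The generator plants `C` clusters (default 5) among `n = 200` cells and
`g = 50` genes: each cluster's mean profile is a shared positive baseline
(uniform on [1, 3] per gene) plus a signed Gaussian location shift scaled
by the separation parameter (default 3.0); cells add Gaussian noise
(sd 1.0), are floored at zero, and a fraction (default 0.10, matching
dropout rates seen in droplet pancreas data) of entries is zeroed
independently. Because shifts are signed, some genes land consistently at
zero for some clusters — marker-like on/off structure. This matters: with
only ~50 genes, dropout noise in log-CPM space is large compared to pure
level shifts, and it is the on/off pattern that keeps clusters separable,
mirroring how marker genes drive real scRNA-seq clustering. Base
clusterings are derived from the truth by optional merge/split directives
followed by independent per-cell label noise (default rates 0.05–0.20
across `M = 4` methods).

What the generator does *not* emulate: negative-binomial count noise,
library-size variation, batch effects, or the systematic (non-random)
biases of specific base algorithms. Passing tests on these fixtures
demonstrate that the machinery — weighting, consensus, factorization, ARD
count selection, graph rescue — behaves as designed when its assumptions
hold; they do not certify performance on any particular real dataset.

## Problem sizes used in the checks

The automated checks run at survey scale chosen for seconds-level
turnaround: oracle equivalence on `n = 30`, stationarity on `n = 20` (run
to `ρ = 1e−13`), pipeline recovery on the default `n = 200` scenario with
5 restarts, weighting sanity over 40 seeds at `n = 120`, and the
update-sweep timing contrast between `n = 100` and `n = 200` (expected
ratio ≈ 4, consistent with the `O(n²Q)` sweep cost; measured by
min-over-repeats wall time with a ±50 % band). The full-size defaults
(50 restarts) remain the library defaults.

## Known limitations

- The alternating updates find local optima; restarts mitigate but do not
  eliminate this. Occasional hard draws (two cluster centroids landing
  close) can merge clusters and return `C` one below truth.
- Dense `n × n` matrices throughout: memory is `O(n²)` and an update sweep
  is `O(n²Q)`, comfortable to a few thousand cells, not for atlases.
- CH weighting assumes cluster quality is reflected in centroid geometry
  of the chosen feature space; pathological base partitions with good CH
  (e.g. capturing a batch effect) would be over-weighted.
- The binarized consensus discards vote-margin information; the weighted
  variant is available but less tested.
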