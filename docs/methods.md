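# Methods

## The model

`funcarto` analyses a *multilayer* (multislice) network: one symmetric
weighted adjacency matrix `A_s` per condition (a task state, or a
window of a resting recording) over a fixed set of `N` nodes.  Node
identity is imposed across the `T` slices by **categorical interslice
coupling**: node `j` in slice `s` is linked to node `j` in *every*
other slice `r != s` with a uniform weight `ω`.  There is no temporal
ordering — conditions are categories, not a time axis — which is why
the coupling is all-to-all rather than chain-like.

Community structure of the whole stack is scored by the multislice
modularity

```
Q = (1/2μ) Σ_{ijsr} [ (A_ijs − γ_s V_ijs) δ_sr + δ_ij ω ] δ(g_is, g_jr)
```

with the Newman–Girvan null within each slice, `V_ijs = k_is k_js /
(2 m_s)`, where `k_is` is node `i`'s intraslice strength and `m_s` the
slice's total edge weight.  `γ_s` (the structural resolution) controls
community size within a slice; `ω` controls label persistence across
slices.  `2μ` is the total edge weight including the coupling terms,
`2μ = Σ_s 2m_s + N·T·(T−1)·ω`.  The sum runs over all ordered tuples,
so the constant diagonal null terms `−γ_s V_iis` are included, exactly
as the quality function is written; intraslice self-weights `A_iis`
are forced to zero (a correlation diagonal carries no community
information — the `ω` term is the only self-interaction).

### Optimization

Q is maximized with a generalized Louvain heuristic operating on the
supra-modularity matrix `B` over the `N·T` (node, slice) pairs: diagonal
blocks `A_s − γ_s V_s`, off-diagonal blocks `ω` on their diagonals.
Phase 1 starts from all-singleton communities and greedily moves
supra-nodes (seed-shuffled visitation order, ties broken toward the
lowest community index, moves accepted when ΔQ > 1e-10); phase 2
collapses communities into super-nodes by summing weights — which
carries the coupling contributions along — and recurses.  Breaking away
into a singleton is always a candidate move, which matters because `B`
has negative entries.  Each restart is deterministic given its seed;
per-run seeds derive from a master seed through `SeedSequence((master,
run_index))` and are recorded in every output.  An *ensemble* of
independent restarts (default 100) is the raw material for everything
downstream; no consensus collapse is applied.

### Allegiance, flexibility, coefficients

The ensemble is summarized by the **module allegiance matrix**
`P_ij`: the fraction of (restart, slice) pairs in which nodes `i` and
`j` share a community.  **Flexibility** of a node is the fraction of
consecutive slice transitions (in input slice order, `T−1` of them) at
which its label changes, averaged over restarts.  Against a
node-to-system map (each node in exactly one named system):

* region recruitment `R_i = (1/n_S) Σ_{j∈S} P_ij` and integration
  `I_i = (1/(N−n_S)) Σ_{j∉S} P_ij`;
* system recruitment `R_S = (1/n_S²) Σ_{i,j∈S} P_ij`, pairwise
  integration `I_kl = (1/(n_k n_l)) Σ_{i∈S_k, j∈S_l} P_ij`, and overall
  integration `I_S = (1/(n_S(N−n_S))) Σ_{i∈S, j∉S} P_ij`.

The literal summation ranges include the self term `P_ii = 1`; the
`exclude_self` flag provides the diagonal-free variant, since the
status of the diagonal is a convention rather than a substantive
choice.  These definitions satisfy the exact conservation identity
`n_S R_i + (N−n_S) I_i = Σ_j P_ij`, which the test suite asserts to
1e-12.

### Null model and roles

Significance is calibrated by permuting the node-to-system assignment
uniformly at random — preserving the number of systems and every
system's size — and recomputing `R_S` and `I_S` per replicate (default
1000 replicates; a warning fires below 100).  The 95% band is the
percentile interval [2.5, 97.5].  Each system is then classified on a
3×3 grid: *ephemeral / unstable / stable* by where `R_S` falls relative
to its band, and *loner / connector / integrator* by where `I_S` falls,
giving roles such as "stable loner" or "ephemeral integrator".
Strict inequalities are used, so a coefficient exactly on a bound is
"within" the band.

Pairwise integration edges are flagged stronger/weaker/ns by comparing
each pair's integration *minus the mean over all off-diagonal pairs*
against the null band of the same centered statistic — centering is
needed because the permutation null preserves the grand mean of
allegiance, so uncentered pairwise values would all sit at the same
level.

### Parameter selection

`grid_search` runs an ensemble at every (γ, ω) grid point and records
mean/SD of node flexibility, mean pairwise partition similarity across
restarts and across slices (z-Rand), mean community count, and mean Q.
The operating point maximizes the *standard deviation* of flexibility —
nodes maximally spread between stable and flexible — with ties (within
1% of the maximum) broken toward high similarity across restarts, then
low similarity across slices, then lexicographically smallest (γ, ω) so
the selection is order-independent.  Partition similarity is the
z-score of the Rand coefficient under the hypergeometric pair-counting
null (zero null variance, e.g. singletons vs singletons, is reported as
similarity 0 with a warning).  The shipped defaults for detection are
γ = 1, ω = 0.45.

## Connectivity estimation

Time-series input is a labelled table: one condition label per
timepoint.  Optionally a design matrix (e.g. task regressors) is
regressed out of every node's signal by OLS (intercept always included;
rank-deficient designs fall back to the pseudo-inverse with a warning)
so that shared stimulus-locked activation does not masquerade as
connectivity.  One Pearson correlation matrix per condition is computed
(conditions ordered by first appearance; a zero-variance node yields
zero correlations with a warning instead of NaNs), then Fisher-z
transformed with |r| clipped to 1 − 1e-7 and the diagonal set to 0.
Resting-style recordings are first chopped into consecutive
non-overlapping windows of 11 samples; trailing samples that do not
fill a window are dropped, so 300 timepoints yield exactly 27 windows.

Negative Fisher-z weights: the Newman–Girvan null is ill-defined for
signed strengths, so the default `sign_policy` truncates negative
weights to zero before optimization; `keep` passes them through for
users who want to handle signs themselves.

## Synthetic data

No public dataset accompanies the method, so every stage is exercised
on planted fixtures generated by the `synthetic` module.

**Planted multilayer networks.**  Each node carries a system label; per
slice it keeps that label with probability `1 − flip_prob`, otherwise
it is reassigned uniformly to another system (flips i.i.d. across nodes
and slices — no temporal autocorrelation, matching the categorical
coupling).  Edge weights are Gaussian: `N(mu_in, sigma)` within a slice
community, `N(mu_out, sigma)` otherwise, symmetrized by averaging with
a zero diagonal — mirroring the structure of a noisy correlation
matrix.  Negative draws pass through to the network's sign policy.
Standard fixture: 4 systems × 8 nodes × 8 slices, `mu_in = 0.8`,
`mu_out = 0.2`, `sigma = 0.1` (noise small relative to the contrast),
flips 0.05–0.30 depending on the experiment.

**Role scenarios** warp one designated system's generative rules so the
downstream pipeline should assign it a known role (5 systems × 6 nodes,
20 slices, flip 0.1, `mu_in = 0.8`, `mu_out = 0.1`, `sigma = 0.1`):

* *stable loner*: the block never flips and never merges.
* *stable integrator*: the block never flips and in every slice merges
  with 3 randomly chosen partner systems.  Merging with a single
  partner would place the system's integration exactly at the null
  mean — the permutation null preserves the grand allegiance mean, and
  a one-partner rotation contributes precisely that mean — so a
  detectable integrator must co-occur with most of the network.
* *ephemeral loner*: each node scatters into its own singleton label
  with probability 0.9, and the designated nodes are fully decoupled in
  weight space (all incident edges zero).  Leaving them a background
  weight of `mu_out` would let the low-strength nodes form a pocket
  community under the degree-based null (`k_i k_j / 2m ≪ mu_out` for
  weak nodes), or let an isolated coupling chain adopt an outsider
  community at zero cost — both genuine modularity behaviors that would
  contradict the planted role.
* *stable connector*: the block never flips and merges with exactly one
  random partner per slice, which places its integration at the level
  typical of the network as a whole.

Outsider flips never target the designated system, keeping its
membership fully rule-controlled.  Role fixtures are analyzed at ω =
0.1 rather than the default 0.45: rotating-partner integration is a
high-flexibility regime, and at strong coupling the optimizer correctly
prefers a single persistent merged community (the coupling term
outweighs per-slice evidence), which masks rotation — exactly the
regime distinction the (γ, ω) grid search exists to resolve.  The
fixture uses 20 slices so that essentially every pair of non-designated
nodes has strictly positive allegiance; with very short, crisp stacks,
random node sets can tie the `1/n_S` recruitment floor exactly and make
the lower percentile degenerate.

**Block time series.**  Per-condition multivariate normal draws with a
compound-symmetric covariance: 1 on the diagonal, `rho_in` within
systems, `rho_out` between.  With `0 ≤ rho_out ≤ rho_in < 1` this is
positive semi-definite by construction; a numerical eigenvalue check
shrinks `rho_in` toward `rho_out` if needed.

**What the fixtures do not emulate:** hemodynamics, scanner noise,
motion artifacts, spatial autocorrelation, or temporal autocorrelation
within a condition.  Passing tests therefore demonstrate that the
statistical machinery behaves as specified on networks with known
structure — not that any particular empirical dataset would yield
particular roles.

## Numerical choices

* Slice symmetry is required within 1e-10 at construction; file readers
  tolerate asymmetry up to 1e-8 (symmetrize with a warning) and error
  above it, reporting the maximum asymmetry.
* Louvain move tolerance 1e-10 on ΔQ; Q comparisons in tests use 1e-9.
* Q is invariant under community relabeling; partitions are
  canonicalized by first appearance (node-major) for comparison and
  output.
* An empty slice (`m_s = 0`) yields an all-zero null matrix with a
  warning rather than an error.
* Floats are written with 17 significant digits and parsed with
  pandas' round-trip parser, so all writers/readers are bit-exact.

## Problem sizes

The exhaustive optimizer cross-check enumerates set partitions exactly
(as a subset DP over the supra-modularity matrix), which is feasible to
~14 supra-nodes; the shipped check uses 50 random instances with N ≤ 6,
T = 2 and 100 restarts each.  Planted-recovery and null-model
experiments use 32-node, 8-slice stacks with 25–100 restarts and 1000
permutation replicates; role recovery uses 30-node, 20-slice stacks
with 15 restarts, 10 master seeds per role.  These sizes were chosen so
the full validation battery runs on a laptop in a few minutes while
every statistical margin (binomial CIs, percentile bands) remains
comfortably resolved.

## Known limitations

* The Newman–Girvan null is undefined for signed networks; truncation
  is a pragmatic default, not a signed-modularity extension.
* Louvain is a heuristic: exactness holds on the enumerable instances
  we can check; at scale only the ensemble-best Q and its stability
  across restarts are available as quality evidence.
* Ordinal (chain) interslice coupling, consensus clustering, and
  deriving the system map from data are out of scope.
* The permutation null preserves system count and sizes but not any
  spatial or topological structure of systems.
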