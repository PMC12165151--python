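# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions implemented in `elscape`, and states what the tests do and
do not demonstrate.

## Pairwise maximum-entropy model and fitting

Activity patterns are vectors V = (σ_1, …, σ_N), σ_i ∈ {−1, +1}, N = 9 in
pipeline use.  The model is the maximum-entropy distribution constrained to
the empirical first and second moments, i.e. the Ising form

    E(V) = − Σ_i h_i σ_i − ½ Σ_{i,j} J_ij σ_i σ_j,
    P(V) = e^{−E(V)} / Σ_ℓ e^{−E(V_ℓ)},

with J symmetric and zero-diagonal.  The state index k encodes the pattern
bitwise (bit i, LSB first, is 1 iff σ_i = +1), and all 2^N states are
enumerated exactly; normalization subtracts the maximum of −E before
exponentiation so arbitrarily strong parameters remain finite.

*Fitting.*  Gradient ascent on the log-likelihood: the update direction is
the moment gap (⟨σ_i⟩ − ⟨σ_i⟩_m, ⟨σ_iσ_j⟩ − ⟨σ_iσ_j⟩_m), with model moments
recomputed by full enumeration at every step — there is no sampling noise
inside the fit, so convergence is deterministic.  Defaults: learning rate
0.2 on both h and J, stopping tolerance 1e−5 on the maximum absolute moment
gap, at most 10^5 iterations, h = J = 0 initialization (the unconstrained
maximum-entropy model).  Non-convergence raises an error carrying the final
gap rather than returning a half-fitted model.  Near-boundary data converge
slowly: moments at exactly ±1 correspond to infinite maximum-likelihood
parameters, so when any moment sits on the boundary all first and
off-diagonal second moments are shrunk by T/(T+1) (logged and warned).  The
independent (1st-order) model is closed form, h_i = atanh⟨σ_i⟩, J = 0.

*Fit accuracy.*  r_D = (D_1 − D_2)/D_1, where D_k is the KL divergence (in
nats) of the empirical pattern distribution from model k, summed over
observed patterns only (0·log 0 = 0).  Because the pairwise model nests the
independent one and both are fitted to convergence on the same moments,
D_2 ≤ D_1 and r_D ∈ [0, 1]; D_1 = 0 (data already exactly independent) is
reported as undefined rather than as a number.

## Landscape construction

Two patterns are adjacent iff they differ at exactly one node (the N-cube).
A local minimum has energy strictly below all N neighbors.  Exact energy
ties between distinct states are broken by state index everywhere, which
makes every construction reproducible under floating-point ties.  A
perfectly flat landscape (h = J = 0 exactly) has no strict minimum; it
cannot arise from a converged fit to non-degenerate data and the dynamics
API accepts `basins=None` for that degenerate case.

*Basins.*  Every state descends to its steepest lower neighbor (lowest
energy; lowest index among ties) until a minimum is reached.  States whose
steepest descending step is tied between neighbors that themselves lead to
different minima are flagged as saddles; they are still assigned
deterministically (via the lowest-index tied neighbor) and counted in basin
sizes by default, with a switch to drop them.

*Disconnectivity tree.*  Conceptually the threshold-lowering procedure:
lower E_threshold through the sorted energy values, remove states above the
threshold, and record the level at which groups of minima disconnect.  The
implementation inserts states in increasing (energy, index) order into a
union-find over the hypercube; when two components containing minima first
touch, the inserting state's energy is the merge level — equal to the
minimax path barrier between the minima, which the tests verify directly
against exhaustive threshold/BFS search.  Basin depth of a minimum is the
merge level with the nearest strictly deeper minimum (the root level for the
global minimum) minus its own energy.

## Random-walk dynamics

Metropolis–Hastings on the hypercube: uniform proposal over the N
neighbors, acceptance min(1, e^{E(V_i)−E(V_j)}), temperature absorbed in the
fitted parameters.  Defaults are 10^5 steps from a uniformly random initial
pattern with the first 100 steps discarded; one chain per subject.  Visited
states are mapped to attractor labels through the basin map.  Dwelling time
of an attractor is the mean length of its consecutive runs (total occupancy
is also computed and can feed the index instead); transition frequency is
the switch count per unordered attractor pair, self-transitions excluded.
Stationarity of the chain against the exact Boltzmann law is checked with
batch-means standard errors, which absorb the walk's autocorrelation.

## Polarization indices and statistics

The Gini coefficient uses the mean-absolute-difference form
G = Σ_ij |x_i − x_j| / (2n²μ), computed through the sorted-rank identity
after normalizing by the maximum (G is scale-free, and this keeps the ratio
finite for extreme inputs).  G ∈ [0, (n−1)/n]; a length-1 or all-zero
vector has no inequality to measure and is reported as 0 with an undefined
flag.  Per subject, G is computed for the dwelling-time vector and for the
transition-count vector over all pairs of attractors visited by the walk
(zero-count pairs included, so rare-but-possible transitions count as
inequality).  Group comparisons use two-sample t-tests (pooled variance by
default, Welch switchable), Bonferroni correction over the family of tests
actually performed in a run, and η² = t²/(t² + df).  Behavior correlations
are plain Pearson r.  For multi-layer (hidden-state-like) inputs each layer
is analyzed independently, layer 1 is excluded (its states merely encode the
input), and the two indices are averaged across layers with defined values.

## Preprocessing routes

*Nine-channel route.*  σ_i(t) = +1 iff the signal of node i strictly
exceeds the across-node average signal at time t (the "whole-recording
average" threshold, which balances active and inactive states).  The
alternative reading — each node against its own temporal mean — is exposed
as `threshold_mode="per_node_temporal_mean"`.  The per-timepoint rule is
the default because the whole-recording average most naturally refers to a
common instantaneous reference; the two differ by one flag.  By
construction the per-timepoint rule cannot represent sign-uniform patterns
(the threshold equals the common value and the strictly-greater convention
yields all −1); that is inherent to the thresholding, not an implementation
artifact.

*High-dimensional route.*  Rows outside the iteration window
[10^4, 6×10^4) are dropped (prompt-dominated start, frozen tail); each
node's time course is z-normalized (numerically constant columns become
all-zero and are logged); k-means with k = 9 partitions the columns by
their normalized time courses (10 seeded restarts, best within-cluster sum
of squares); each cluster-mean time course (over the same normalized
columns) is binarized against its own temporal average, strictly-greater
convention.  On noiseless duplicated channels this chain is exactly
lossless up to cluster relabeling, which the tests assert.

Ties at any threshold resolve as −1 (strictly-greater ⇒ +1); this is a
convention, chosen for determinism.

## Synthetic study conditions

The generator defines the conditions under which every end-to-end claim is
evaluated:

- latent dynamics are sampled i.i.d. from the exact model distribution
  (T = 10^5 time points by default), removing autocorrelation as a
  confounder in recovery experiments; a Glauber single-site chain with the
  same stationary law is provided when temporal correlation matters;
- `uniform_shallow` landscapes: three equally weak ferromagnetic blocks
  (intra-block coupling ≈ 0.30–0.40 with ±5% per-edge jitter, inter-block
  couplings U[−0.05, 0.05], fields U[−0.02, 0.02]) — many minima of similar
  depth (max/min basin-depth ratio < 2);
- `polarized` landscapes: one strong block (≈ 0.75–0.95) among two weak
  ones — coexisting deep and shallow minima (depth ratio ≥ 2).  The depth
  ratio 2 is the declared boundary between the regimes; draws are repeated
  deterministically until the exhaustive landscape check passes;
- emission: each latent channel drives `nodes_per_cluster` observed columns
  through a per-column affine map (gain U[0.5, 1.5], offset U[−1, 1] — so
  normalization has real work to do) plus Gaussian noise of sd 0.1 by
  default.

What the generator does *not* emulate: hemodynamic response functions,
scanner autocorrelation and drift, lesion-induced missing data, or anything
transformer-specific beyond dimensionality and layering.  Passing tests
therefore demonstrate correctness of the analysis chain and its qualitative
regime sensitivity on clean Ising-world data, not performance on real
recordings, whose noise structure neither input source characterizes.

## Problem sizes and determinism

Cohort experiments use 20 subjects per regime, N = 9, T = 10^5 latent
samples, 10^5-step walks; stationarity checks use N = 3 with 10^6-step
walks; landscape oracles run exhaustively at N ≤ 6.  These sizes make every
statistic stable while keeping the full suite and the acceptance script
fast on a single CPU.  All randomness flows through explicit integer seeds
(NumPy `default_rng` / `SeedSequence`); result files are written with fixed
float formatting, so a rerun with the same manifest, config and seed is
byte-identical — which the tests assert.

## Known limitations

- Exact enumeration restricts N to ≤ 16 (N = 9 in practice); there is no
  pseudo-likelihood or MCMC fitting path for larger N, and no L1/L2
  regularization of couplings.
- Near-boundary moments make the plain gradient ascent slow: strongly
  saturated data can need far more than the default iteration budget.
- The dwelling-time Gini discriminates the two synthetic regimes only
  weakly (block-switching dominates run lengths); the transition-frequency
  Gini carries the regime separation, and the group comparison reports
  both.
- Basin "connectedness" and saddle handling follow the declared descent
  rule; other ELA implementations differ in how they treat saddles and
  plateaus.
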