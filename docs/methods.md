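# Methods

## Problem and model

The package divides an undirected, unweighted functional network into
communities by maximizing Newman modularity

    Q = Σ_i (e_ii − a_i²),

where e_ij is the fraction of edges joining communities i and j (split
half-half across the off-diagonal) and a_i = Σ_j e_ij.  Q ∈ [−1, 1); Q of
the single whole-graph community is 0 on every graph, and Q > 0.3 is the
conventional criterion for "this network has community structure".
Networks come either from the user (edge list / adjacency matrix) or from
the signal chain below.

## Signal-to-network chain

1. **Band-pass filter.** Zero-phase forward–backward Butterworth, 4th
   order (scipy `butter(2, band)` + `sosfiltfilt`).  Default band 4–7 Hz
   (θ), the band most associated with emotion-related phase coupling; the
   band is configurable.  The filter type is our choice — only the band is
   prescribed by the study design we follow.
2. **Middle window.** Trials are unstable at onset and offset, so only
   the middle third is analyzed: samples `[floor(n/3), floor(2n/3))`,
   0-based half-open.  A 60 s trial at 512 Hz keeps samples
   [10240, 20480), i.e. the 20 s–40 s span.
3. **Phase.** Analytic-signal (Hilbert) phase per channel.  The phase
   extraction method is our design choice; any narrow-band phase estimate
   would do.  One second is trimmed at each end of the window before PLV
   to suppress filter and Hilbert edge transients (`trim_s`, default 1.0).
4. **PLV.** Computed for all pairs at once as |Z Zᴴ|/N with Z = exp(iφ);
   the matrix is symmetrized and clipped to [0, 1] against rounding.
   PLV is invariant to a common phase offset; for independent phases its
   expected value scales as 1/√N (≈0.01 at N = 10⁴).
5. **Binarization by edge count.** Instead of a fixed numeric PLV cutoff
   (which can yield near-empty or near-complete graphs and is not
   comparable across subjects), the m strongest off-diagonal pairs become
   edges.  Ties are broken by stable sort on (−value, i, j), i < j, so the
   result is deterministic.  An empty or complete result triggers a
   warning.
6. **Adaptive scan.** For each m in the configured range (default 30–40
   for 32-channel networks) the detector is re-run R times (R ≥ 2;
   pipeline default 3) on the binarized network; each m is scored by the
   mean pairwise NMI of the R partitions (stability) and their mean Q.
   The chosen m maximizes stability, ties broken by higher mean Q, then
   smaller m.  Whether PLV should be computed on sub-windows rather than
   the full window is an open design point; we use the full window.

## The detector (MFMICD)

Chromosomes are community-label strings of length n (direct encoding;
decoding groups equal labels and renumbers communities by smallest
member).  Defaults, following the reference configuration for 32-node
brain networks: population 100, 50 global generations, 20 tabu rounds,
tabu tenure 10.

* **Initialization (ID passing).** Labels start as node ids; every node
  then adopts the id of one uniformly random neighbor (isolated nodes keep
  their own).  Labels therefore never cross connected components, and the
  initial population already respects local structure.
* **Fitness calibration.** Selection weights must be non-negative, so raw
  Q is shifted: Fit = Q − min(Q) over the current population.  If all
  members tie, selection falls back to uniform.
* **Dynamic rates.** The convergence rate φ = f_avg/(f_max − f_min)
  (sentinel +∞ when converged) drives the mutation probability through the
  power law pm = 1/(φ + 1), with pc = 1 − pm (crossover and mutation are
  complementary).  Early in a run φ is small, so mutation is high and
  preserves diversity; late it decays toward the lower bound.  Clamps:
  pm ∈ [0.01, 0.5], pc ∈ [0.5, 0.99], chosen to exclude pathological
  extremes (pm = 1 would randomize every locus; pm = 0 would freeze the
  search).
* **Selection.** Roulette wheel: P(i) = Fit_i / Σ_j Fit_j, sampling with
  replacement.
* **Crossover ("strongest first").** Selected parents are sorted by
  fitness (ties by index) and paired 1st–2nd, 3rd–4th, …; each pair, with
  probability pc, swaps a circular two-cut segment of the label string
  (cuts c₁, c₂; the segment walks forward from c₁ and may wrap past the
  end).  Pairing strong with strong concentrates recombination on good
  material while the (μ+λ) replacement keeps the rest competitive.
* **Mutation.** Each locus, with probability pm, takes the current label
  of a uniformly random graph neighbor (read from the pre-mutation
  string).  This keeps every label inside the node's closed neighborhood,
  so mutation explores only structurally plausible moves.
* **Immune operator.** The vaccine is the label assignment of the
  top-decile-degree nodes (at least one node) in the current best member —
  high-degree nodes anchor communities, so their labels carry the most
  transferable information.  It is injected into a random 20% of the
  non-best members; each vaccinated member is kept only if its Q did not
  decrease, else it reverts (immune selection).  The best member is never
  modified.  This vaccination scheme is a standard immunogenetic pattern;
  the operator's internal mechanism was genuinely open and this is our
  instantiation of it.
* **Replacement.** (μ+λ): parents and offspring pooled, top `pop_size` by
  raw Q survive.  Elitism is structural — the best Q never decreases.
* **Tabu refinement.** The global best is refined for `max_gen_tabu`
  rounds.  Neighborhood: every single-node move to a community containing
  at least one graph neighbor of the node, plus a split into a fresh
  singleton.  Objective F = Q − λ·(#communities whose induced subgraph is
  disconnected), λ = 0.1 by default; the penalty discourages label sets
  that "teleport" a node into a community it does not touch (possible
  after crossover).  Whether λ should be scheduled rather than fixed is
  open; we keep it fixed.  Reverting a node to a label it just abandoned
  is tabu for `tabu_tenure` rounds unless it beats the best F seen
  (aspiration).  The best admissible move is taken each round even when it
  worsens F, which is what lets the search leave local optima.  The best-F
  labeling encountered is returned; for a feasible (penalty-free) start
  this can never have lower Q than the start.
* **Randomness.** One `numpy.random.Generator` seeded from
  `GAParams.seed` is threaded through all stochastic steps in a fixed
  order (init → per generation: selection, crossover draws, mutation
  draws, immune targets), so runs are bit-reproducible.  Independent
  restarts (`runs_per_setting`, default 1; use ~100 for benchmark-style
  averaging) derive per-run seeds from the base seed and report the mean
  pairwise NMI across restarts as a stability score.

## Evaluation

* **NMI** uses the entropy-normalized (Danon) form 2·I/(H₁+H₂) with
  natural logarithms and 0·log 0 = 0.  Degenerate case: if both partitions
  are the single whole-set community both entropies vanish and the value
  is defined as 1 (the partitions are necessarily identical); if only one
  side is a single community the value is 0 by the formula itself.
* **Exhaustive oracle.** For graphs with ≤ 10 nodes, all set partitions
  are enumerated (restricted-growth strings) and scored; ties resolve to
  the lexicographically smallest canonical labeling.  This is the
  independent optimum against which the stochastic detector is validated.

## Synthetic data

The generators stand in for license-gated EEG recordings; their defaults
are the study conditions the package targets.

* **Planted-partition graphs.** Within-block pairs are edges with
  probability p_in, cross-block with p_out (benchmark default: 4 blocks of
  8 nodes, p_in = 0.9, p_out = 0.05).  A full LFR generator (power-law
  degrees and community sizes) is deliberately not included; planted
  partitions cover what the validation needs.
* **Coupled-phase signals.** Default: 32 channels (10–20 names), 512 Hz,
  60 s, four groups of eight channels, coupling 0.95, noise SD 0.1.  Each
  group owns a latent narrow-band phase process (drifting in-band
  frequency + slow random phase walk).  Per sample, a channel reads the
  latent phase with probability equal to the coupling and an independent
  in-band phase process otherwise, then gets a small phase jitter
  (SD 0.05 rad) and additive Gaussian amplitude noise.  Same-group PLV is
  1 at coupling 1 with zero noise, statistically indistinguishable from
  cross-group PLV at coupling 0, and monotone in between.  What this does
  *not* emulate: volume conduction, shared reference, artifacts,
  nonstationary band power — so passing recovery tests demonstrates the
  pipeline's correctness on phase-locked group structure, not robustness
  to real EEG confounds.
* **Karate club.** The 34-node, 78-edge Zachary graph with the two-faction
  labeling, embedded as a source-level constant (unweighted; the faction
  split scores Q ≈ 0.358 > 0.3).

## Numerical choices and degenerate inputs

* Modularity tolerance for "optimum attained" comparisons: 1e−9; the
  e-matrix and degree-fraction formulations agree to ~1e−15 and both are
  implemented (the latter as the optimizer's fast path, cross-checked in
  tests against networkx).
* Modularity is undefined (raises) on edgeless graphs; isolated nodes
  contribute a_i = 0.
* A 1-sample epoch is representable (the middle third of a 3-sample
  epoch) but PLV requires ≥ 2 samples.
* All-zero channels are rejected before phase extraction (their phase is
  meaningless).

## Problem sizes used in validation

Oracle-equivalence runs use 25 random connected graphs of 5–8 nodes with
20 detector runs each; recovery checks use the 32-node defaults above
with 10 seeds; the adaptive-scan unit tests use a 10-node two-block PLV
matrix with a clear in/out gap, where the scan's stability-then-Q rule
must select the true intra-pair edge count.  End-to-end signal-chain
validation binarizes at the planted intra-pair count; the adaptive scan
itself is validated separately on the same chain's PLV matrices.

## Known limitations

* Unweighted, undirected, non-overlapping communities only.
* The multi-objective aspect is realized as a stability criterion (NMI
  across repeated runs / threshold scan), not Pareto optimization.
* The immune operator follows a standard vaccination pattern; other
  instantiations are possible.
* Electrode-region statistics assume the 32-channel 10–20 montage; other
  montages require a custom `ElectrodeMap`.
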