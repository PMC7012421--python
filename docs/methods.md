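# Methods

## The model

`flare` fits one Gaussian mixture *jointly* across M cytometry samples.
Sample m is a K-component mixture over its events x ∈ R^D (D markers, on a
transformed scale).  Component k of sample m has mean μ_k^(m) and precision
Λ_k^(m), and the samples are tied together by two prototype layers:

- μ_k^(m) ~ N(η_k, (β₀ I)⁻¹): each sample's k-th mean is a small isotropic
  perturbation of the prototype mean η_k;
- Λ_k^(m) ~ Wishart(mean = Ω_k, dof = σ₀): each sample's k-th precision
  scatters around the prototype precision Ω_k.  This Wishart is
  parameterized by its *mean* (scale Ω_k/σ₀), which is what makes the
  σ₀-factors appear in the Ψ and Φ updates below.

The prototypes carry conjugate hyper-priors η_k ~ N(ξ₀, (ε₀ I)⁻¹) and
Ω_k ~ Inverse-Wishart(Φ₀, ν₀).  Per-sample mixture weights π^(m) carry a
symmetric Dirichlet(α₀) prior; a weight may collapse to zero occupancy in
some samples, which is how the model expresses that a population is present
in only a subset of samples.  Because component index k refers to the same
prototype in every sample, populations are matched across samples by
construction — no post-hoc cluster alignment exists anywhere in the
pipeline.

## Inference

Posterior inference is mean-field variational Bayes with the factorization
q(h) q(π) q(μ) q(Λ) q(η) q(Ω) and closed-form coordinate updates:

- responsibilities: r_nk ∝ exp{E[ln π_k] + ½E[ln|Λ_k|] − ½E[(x−μ_k)ᵀΛ_k(x−μ_k)]},
  normalized in log space with per-row max subtraction (ρ spans hundreds of
  log-units at N ~ 10⁶ in moderate D);
- weights: α_k = α₀ + N_k with N_k = Σ_n r_nk;
- moments: x̄_k = Σ r_nk x_n / N_k, S_k the r-weighted scatter about x̄_k;
- sample precisions: Ψ_k⁻¹ = σ₀ E[Ω_k⁻¹] + N_k (S_k + (x̄_k−ω_k)(x̄_k−ω_k)ᵀ + Γ_k),
  σ_k = σ₀ + N_k;
- sample means: Γ_k = (N_k E[Λ_k] + β₀ I)⁻¹, ω_k = Γ_k (N_k E[Λ_k] x̄_k + β₀ ξ_k);
- prototype means: ξ_k = (ε₀ ξ₀ + β₀ Σ_m ω_k^(m)) / (ε₀ + β₀ M),
  Υ_k = I / (ε₀ + β₀ M);
- prototype shapes: Φ_k = Φ₀ + σ₀ Σ_m σ_k^(m) Ψ_k^(m), ν = ν₀ + M σ₀ (the
  degrees of freedom carry no component dependence, so a single shared ν is
  stored).

Two derivation details matter and are deliberate.  First, the expected
Mahalanobis form in the responsibility update is the exact mean-field
expectation for this model's q factors,
E[(x−μ)ᵀΛ(x−μ)] = σ[(x−ω)ᵀΨ(x−ω) + tr(ΓΨ)]; the D/β₀ form familiar from
the textbook single-sample mixture does not apply here because Γ is not
(β₀ E[Λ])⁻¹ in this hierarchy.  Second, the N_k·Γ_k term in the Ψ update is
the posterior uncertainty of the sample mean; dropping it would make the
update an approximation rather than an exact argmax.  Both choices are what
make every update an exact conditional optimum of the bound, so the ELBO is
provably non-decreasing across sweeps — the property the test suite checks
over 50 seeded runs at 1e-8 relative tolerance, and the convergence monitor
of the fit.

The ELBO is evaluated in closed form after every sweep (expected complete
log-likelihood plus prior cross-terms plus the entropies of all factors).
The inverse-Wishart entropy is written out from −E[ln q] directly; scipy's
`invwishart.entropy` disagrees with a Monte-Carlo estimate of −E[log pdf]
in the installed version, so the tests validate the closed form against
sampling instead of against scipy.

Update order per sweep: responsibilities → weights → moments → sample
precisions → sample means → prototype means → prototype shapes.  Any order
of exact coordinate updates preserves monotonicity; this one simply feeds
each update its freshest dependencies.

### Numerical safeguards

- Every matrix inverse goes through Cholesky with symmetrization
  ((A+Aᵀ)/2) and a one-shot 1e-8·mean-diagonal jitter retry; a failure
  raises an invalid-state error rather than propagating NaNs.
- Empty components (N_k < 1e-8) fall back to x̄_k = ξ_k and S_k = 0, so the
  downstream updates reduce to their prior-only forms instead of dividing
  by ~0.
- Components whose occupancy summed over all samples falls below 1e-8 are
  pruned: their responsibility columns are set to exactly zero and never
  rejoin the softmax.  This is the sparsity mechanism by which a
  deliberately over-provisioned K shrinks to the populations the data
  support, and it guarantees pruned components never reappear.
- Hard-label ties break to the lowest component index.

### Initialization and restarts

Prototype means are seeded by k-means (scikit-learn, one initialization,
seeded) on a pooled subsample of at most 50,000 events; per-sample means
copy the prototypes; K = 1 bypasses k-means and uses the pooled mean
exactly.  Initial precisions use the inverse pooled *total* covariance:
broad, heavily overlapping initial components let redundant components
compete and empty out from the first sweeps.  The tight alternative
(within-cluster covariance) was evaluated and freezes k-means
over-segmentation into split local optima, so it is not used.  Exact
duplicate centers (possible on degenerate data) are separated by a tiny
deterministic jitter.

Coordinate ascent on a mixture posterior has local optima — most visibly,
two components stably sharing one true population.  `fit(...,
n_restarts=n)` runs n seeded initializations and returns the run with the
highest final ELBO; this is the standard guard and is recommended (n ≥ 2–4)
whenever cluster-resolution quality matters.  All randomness flows from the
single seed argument; identical seed and data give bitwise-identical runs.

Convergence is declared when the relative ELBO change drops below `tol`
(default 1e-6; the validation scenarios use 1e-7, which matters when a
redundant component is still slowly draining) or at `max_sweeps` (default
500), in which case the result is returned with `converged=False` rather
than raising.

## Hyperparameters

| name | default | meaning |
| --- | --- | --- |
| K | 100 | maximal components; an upper bound, not a model choice |
| α₀ | 0.01 | Dirichlet concentration; < 1 favours emptying unused components |
| β₀ | 500 | sample-mean precision around the prototype mean (SD ≈ 0.045 on the transformed scale) |
| σ₀ | 6D | Wishart dof tying sample precisions to the prototype |
| Φ₀, ν₀ | I, 6D | diffuse inverse-Wishart hyper-prior on prototype precisions |
| ε₀, ξ₀ | 1, 0 | standard-normal hyper-prior on prototype means |

β₀, σ₀, Φ₀, ν₀ follow the model's intended operating point for data on a
roughly standardized transformed scale (e.g. arcsinh with cofactor 150 for
fluorescence, exposed in the IO layer and the CLI).  α₀ has no canonical
value; 0.01 was fixed once as a standard sub-unity choice.  K defaults to
100 because the intended use starts deliberately over-provisioned and lets
occupancy-based pruning find the effective number of populations; no
information-criterion model selection is performed.

Presence of component k in sample m is called when N_k^(m) ≥ 5 effective
events *and* N_k^(m)/N_m ≥ 1e-5.  These defaults keep a 0.045% population
in a 10⁶-event sample (≈450 events) comfortably present while suppressing
single-event noise.

## The two-step rare-event workflow

Step one is a joint fit plus `summarize`: per-component, per-sample soft
proportions N_k^(m)/N_m, posterior mean signatures ω_k^(m), presence flags,
and a components × markers matrix of prototype-mean percentile ranks
(0–100 per marker across components; a single component ranks 0 by
convention) for heatmap rendering.

Step two, `zoom`, extracts the events inside a region of interest and runs
a fresh fit on them with a smaller default K = 20.  Regions are either
axis-aligned boxes over named markers (open-ended bounds allowed) or
Mahalanobis balls around a fitted prototype, with Φ_k/ν — the posterior
expectation of the average precision — as the metric and default radius 3
(≈97% of a component's mass in low D).  The refit starts from scratch;
transferring step-one posteriors as priors would be a possible extension
but is not implemented.  A full-space region reproduces the direct fit
exactly (same seed, same K), which the tests assert as state equality.

`fold_change_screen` compares per-component proportions between two
conditions of one joint fit (shared component indices are what make this
well-defined).  "More than 1-fold change" is read as ratio > 2 by default;
`min_ratio=1` (any increase) is available because the permissive reading is
also defensible.  Reference proportions of zero are floored at half an
event, 0.5/N_ref (a continuity correction), before forming ratios.

## Partition planning and the parallel contract

For a deployment over W worker slots, each sample's events live on a
dedicated subset of workers (a worker never mixes samples, minimizing
per-worker parameter storage).  The greedy planner gives each sample one
worker and repeatedly gives the next worker to the sample with the highest
per-worker load N_m/W_m (ties to the lowest index).  Partition efficiency
is balance = ⌈N/W⌉ / max_m ⌈N_m/W_m⌉ ∈ (0, 1], 1 exactly at the minimax
optimum; an exhaustive enumeration oracle confirms the greedy plan attains
the minimax load across a seeded grid of small instances.
`PartitionPlan.printed_form_quantities()` preserves, for audit only, an
alternative literal reading of the efficiency formulas that is internally
inconsistent (it can exceed 1) and is not used.

One property worth stating because it is counterintuitive: balance is *not*
monotone in W.  Two equal samples are perfectly balanced at W = 2 but
cannot be at W = 3; the efficiency dips and recovers as W grows.  The test
suite documents this with a frozen counterexample instead of asserting
monotonicity.

`parallel_fit` executes the same sweep arithmetic with the communication
pattern a message-passing deployment would use: event-level terms
(responsibilities) computed block-wise per worker slot; per-sample
reductions (counts, weighted sums, scatters) as partial sums combined in
fixed block order; cross-sample reductions (prototype means and shapes)
combined once per sample.  Per-component work can additionally spread over
threads.  The contract is numerical equivalence with the serial fit — with
one worker per sample the execution path is identical (bitwise); with more,
only floating-point reassociation differs, bounded at 1e-10 per parameter
per sweep in the tests.  No speedup claims are made or measured; the
arithmetic contract is the testable content, and the in-process backend is
an explicit abstraction a message-passing backend could replace.

## The synthetic-data generator

`simulate.generate` draws data from the model's own generative process:
prototype means/covariances, per-sample weights (zeros = absent), component
counts multinomial in the weights, per-sample mean jitter with SD
1/√β₀ ≈ 0.045 by default (matching the model's prior scale), events
Gaussian.  Covariance jitter across samples is off by default — the model
shares shape through a common prior and mean jitter is the dominant
inter-sample variation emulated — but a log-normal scale knob exists for
stress tests.  Rare components are specified as (component, frequency,
present-in-samples) and rewrite the weight columns; a present component
whose expected count falls below one event is rejected as infeasible.

What the generator deliberately does not emulate: fluorescence-scale
artifacts (spillover, compensation residuals, transformation curvature),
non-Gaussian population shapes (skew, heavy tails), doublets, debris, or
acquisition drift.  Passing tests therefore demonstrate correctness of the
inference machinery and the workflow logic under the model's own
assumptions, not robustness to real-data violations of those assumptions.

Two canned scenarios are the standing benchmarks:

- `fig3_scenario`: two 2-D samples, two overlapping large populations
  (means (0,0) and (2.2,0), unit covariance, weights differing between
  samples) plus a tight 1% population at (−1.6, 2.4) with SD 0.3, 4,000
  events per sample.  Fitting each sample alone (K = 12), the rare
  cluster's ~40 events are usually absorbed by the neighbouring large
  population; the joint fit pools its evidence and keeps it.  Detection is
  defined as: a present component with occupancy ≤ 5% of the sample whose
  posterior mean lies within 3 cluster-SD (0.9) of the true rare mean.
- `zoom_scenario`: five 6-D training samples (20,000 events each) with four
  large populations and a 1% parent population (SD 0.5), plus a 10⁶-event
  test sample in which a subpopulation (SD 0.15, offset 2 parent-SD inside
  the parent region) replaces 0.045% of events.  The workflow is: joint fit
  on training (K = 8), anchor a radius-3 region at the prototype nearest
  the parent, zoom-refit the test events inside it (K = 20), and look for a
  component within 0.5 sub-SD of the true subpopulation mean at a frequency
  within ±30% of 0.045%.

## Validation problem sizes

The acceptance battery (tests/test_acceptance.py, scripts/acceptance.py)
runs, per scenario: scalar-transcription checks at 1e-12; 50 monotonicity
runs (M = 3, D = 4, K = 6, 2,000 events/sample, 40 sweeps); the
single-sample reduction at 1e-4; the recovery scenario (M = 5, K_true = 4,
D = 4, 5,000 events/sample, 0.5% rare component in 3/5 samples, fit K = 6,
two restarts, tol 1e-7) over 10 seeds in the tests and 12 in the script;
the two-sample directional benchmark over 12/20 seeds; the zoom scenario
over 5/10 seeds; 200 enumerated partition instances; and a 15-sweep
serial/parallel comparison.  Seed counts per scenario are the package's
validation design; the recovery scenario's 5,000 events/sample put the rare
component at 25 expected events per present sample, the boundary at which
presence recovery is designed to be reliable.

## Known limitations

- Coordinate ascent can converge to split local optima; restarts mitigate
  but do not eliminate this, and the drain of a redundant component can be
  slow (hundreds of sweeps), which is why the validation scenarios use
  tol = 1e-7.
- The Gaussian component family is a deliberate scope choice; heavy-tailed
  or skewed populations will be tiled by several Gaussian components.
- K is not selected automatically; occupancy-based sparsity from an
  over-provisioned start is the mechanism, and the effective component
  count is reported instead.
- The FCS reader targets FCS 3.0/3.1 list mode (float, double, and
  uniform-width integer data, both byte orders, log-amplified integer
  decoding); compensation is assumed done upstream, and FCS 2.0/3.2
  specifics are out of scope.
- The parallel layer proves equivalence, not speed; on one process the
  partitioned fit is bookkeeping, not acceleration.
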