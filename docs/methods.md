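# Methods

## Model and problem statement

A population governed by one *dynamic rule* follows the Ricker map with
additive observation/process noise lumped into a single Gaussian term:

    N_{t+1} = N_t · exp(r · (1 − N_t / K)) + ε_t,   ε_t ~ Normal(0, σ²)

`r` (dimensionless, per step) sets the low-density growth rate and the
qualitative dynamics (monotone approach for small r, damped oscillation,
then periodic and chaotic behaviour as r grows past 2); `K` is the
equilibrium abundance in the data's own units; σ is the residual standard
deviation in the same units. A *dynamic shift* is an abrupt change in
(r, K) at a *break point*, labelled by the last year of the earlier regime
("break after year y"). Given one series of consecutive annual abundances,
the detector infers the number, location, and strength of evidence of such
breaks.

## Segmentation and fitting conventions

* **Transition pairs.** A segment covering years [a, b] is fitted on the
  pairs (N_a→N_{a+1}), …, (N_{b−1}→N_b), so `n_obs = b − a`. Consecutive
  segments share the boundary year but no pair: a break after year y ends
  one segment at y and starts the next at y. Per-segment `n_obs` therefore
  sum to the total number of transitions however the series is partitioned.
* **Minimum segment.** Partition blocks must hold at least four data
  points (`min_segment`, configurable). This is the overfitting guard on
  the search space; see also the AICc feasibility rule below.
* **Fitting.** (r, K) minimise the squared one-step prediction errors via
  `scipy.optimize.least_squares` (trust-region reflective) with an
  analytic Jacobian. K is bounded below by a vanishing fraction of the
  segment's mean abundance to exclude the sign-flip degeneracy; r is
  unbounded. Starting values: r₀ = 1 (mid-range of plausible growth
  rates), K₀ = the segment's mean abundance (a robust guess for series
  fluctuating around carrying capacity). Standard errors come from the
  Jacobian covariance scaled by rss/(n_obs − 2); σ̂ = √(rss/n_obs). A
  segment sitting identically at K makes r unidentifiable — this surfaces
  as infinite standard errors, not an error.

## Information-criterion accounting

Each segment is scored with the Gaussian least-squares form

    IC = n_obs · ln(rss / n_obs) + 2k        (+ AICc correction)
    AICc correction = 2k(k+1) / (n_pts − k − 1),   n_pts = n_obs + 1

with k = 3 estimated quantities (r, K, σ²), and a partition's score is the
sum over its segments. Two deliberate choices deserve explanation:

* **The likelihood term runs over transitions.** Every competing partition
  of the same series then sums the identical n_obs log-variance
  contributions, so comparisons are invariant to the measurement units.
  Counting the shared boundary points instead would add one ln(σ̂²) per
  extra segment — a spurious penalty on large-unit data and, worse, a
  spurious reward on small-unit or near-noiseless data.
* **The small-sample correction runs over the points spanned.** The
  correction must diverge for the smallest admissible segments: a segment
  near-interpolating its three or four transitions drives σ̂² → 0 and its
  log term → −∞, and without a harsh small-n penalty such mini-segments
  swamp the ranking (this is the standard per-segment variance degeneracy
  of changepoint model selection, and the reason AICc rather than AIC is
  the default). With n_pts = n_obs + 1, the correction is finite from four
  transition pairs upward and infinite below.

Consequently, under AICc every segment needs ≥ 4 transition pairs. All
interior and trailing blocks of ≥ 4 points satisfy this automatically (they
inherit the boundary point of the preceding segment); a *leading* block of
exactly 4 points does not, so partitions whose first block holds 4 points
are structurally unscorable under AICc and are dropped with a logged
reason. On a 20-point series this excludes a break directly after point 4 —
1 of 13 admissible single-break placements — which bounds noiseless
single-break accuracy at 12/13 even though such breaks remain perfectly
separable in principle. Under plain AIC no such exclusion applies.

The textbook formulas with caller-chosen n and k are exported as
`aic_least_squares` / `aicc_least_squares`; `segment_ic` applies the
engine's bookkeeping above.

Near-zero residuals are floored at `n_obs · (10⁻⁸ · mean abundance)²`
before taking logarithms so noiseless segments score finitely; on any
realistically noisy series the floor is ~16 orders of magnitude below rss.

## Ranking, weights, and decision rules

Akaike weights are computed over **all** scorable partitions; partitions
with weight < 0.001 are then pruned (equivalence-set members are always
retained) and the retained weights renormalised (`renormalize=False`
reports the pre-pruning weights unchanged). The equivalence set holds
partitions within 2 IC units of the best. Ties in total IC rank fewer
breaks first, then lexicographically, making output deterministic. Break
weight = summed weight of retained partitions containing the year; > 0.8
is read as a supported break, < 0.2 as erroneous, in between as the
strength of evidence. All thresholds are configurable via `DsdConfig` but
default to the method's reference decision rules.

## What the simulator emulates

`simulate_series` iterates the deterministic map and multiplies each
expected value by (1 + η), η ~ Normal(0, τ): noise proportional to
population size, which is how environmental and sampling variation scale
in practice. A draw pushing the population non-positive is redrawn rather
than truncated, to leave the noise mean unbiased (immaterial for τ ≤ 0.15,
where such draws are ~6σ events). Note the asymmetry kept on purpose: the
generator's noise is multiplicative while the fitted model assumes additive
error — both as specified for the benchmark — so the benchmark measures
the detector under mild model misspecification, as real data would.

Breaks multiply the *current* (r, K) by (1 ± δ) with signs drawn uniformly
and independently per break and per parameter, so successive shifts
compound; the realised regimes are recorded in the ground truth. Break
positions are drawn uniformly from the admissible break sets (all blocks
≥ min_segment points) — the same constraint the detector enumerates under.
The transition out of a break year is already governed by the shifted
parameters, matching the detector's segment convention.

Benchmark defaults: N1 = 3000 with K = 2000 (started off equilibrium so
the transient informs the fit), r0 = 2, δr = 25%, δK = 75%, τ = 2%,
20-year series. The 94-scenario grid varies starting r ∈ {0.5, 1, 1.5, 2}
against the δr and δK grids {0, 10, 25, 50, 75}% (40 scenarios), noise
τ ∈ {1, 2, 5, 10, 15}% against both change grids (50), and series length
∈ {15, 20, 25, 30} (4); non-varied parameters sit at the base values, so
the base parameter set recurs in several families exactly as the scenario
count tallies it.

What the generator does **not** emulate: demographic stochasticity, age or
stage structure, observation models separate from process noise, gradual
(press) parameter change, or autocorrelated environments. Passing the
benchmark therefore demonstrates recovery of abrupt shifts in an otherwise
well-specified density-dependent system — not robustness to structural
model error in real data.

## Evaluation metrics

* **Detection accuracy**: the fraction of replicates whose *exact* true
  break set appears among the equivalence-set partitions. Set equality is
  deliberate — supersets containing the truth plus extras do not count,
  and neither do off-by-one placements. A per-break recall diagnostic is
  carried alongside.
* **Break-weight separation**: every break year carrying a weight in the
  reported (retained) break-weight table is partitioned by exact
  ground-truth match; the two pools' means are reported, pooled across
  replicates. An empty pool is reported as absent, not zero.

Replicates are driven by independent `SeedSequence`-spawned streams, so
every number the harness emits is exactly reproducible from one seed.
Replicate counts default to 100 per scenario and break count (the full
study design used 250); `scripts/acceptance.py` runs 100 × {0, 1, 2}
breaks of the base scenario in ~30 s on one CPU.

## Known limitations

* Exhaustive enumeration grows combinatorially with series length; the
  intended regime is the 15–40-point range typical of annual ecological
  monitoring. `max_breaks` caps the partition order for longer series.
* Breaks after the fourth point of a series are invisible under AICc (see
  above); use AIC if candidate shifts at the very start of a series matter.
* Shifts separated by fewer than `min_segment` years violate the search
  constraints and cannot be represented.
* Only the Ricker model ships. The fitting interface is segment-local and
  model-pluggable in structure, but no alternative (logistic,
  Beverton–Holt) is implemented.
* The reported per-segment standard errors are conditional on the selected
  partition; they do not propagate model-selection uncertainty.
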