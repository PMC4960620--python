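# Methods

## Model and assumptions

A cell born at volume `V_b` grows deterministically and exponentially,
`V(t) = V_b e^{αt}`. A timekeeper protein is produced in instantaneous
bursts whose arrivals form an inhomogeneous Poisson process with rate
`r(t) = k_m V(t)`; the volume-proportional rate is what keeps the
protein's concentration homeostatic in a growing cell. Burst sizes
`B_i` are i.i.d. non-negative integers with mean `b` (a burst is the
protein output of one short-lived mRNA; the mRNA stage itself is not
modelled). The protein is stable within a cycle; division fires when
the copy number first reaches the integer threshold `X`, after which
the protein is fully degraded or deactivated (baseline model).
Divisions are symmetric: the daughter inherits half the mother's
division volume. Growth-rate variability between cells, asymmetric
partitioning noise, and any dependence of the C+D period on growth rate
are outside the model.

Key structural facts used throughout:

* Time change. With `R(t) = (k_m V_b/α)(e^{αt} − 1)` the cumulative
  rate, arrivals are unit-rate Poisson in the coordinate `u = R(t)`.
  Because `u = λ·(V(t) − V_b)` with `λ = k_m/α`, inter-burst spacings
  in the *added-volume* coordinate are i.i.d. Exp(λ), independent of
  `V_b`.
* Burst count. `N = min{n : Σ B_i ≥ X}` depends only on the burst law
  and `X`. Division time is the `N`-th arrival time; added volume is a
  sum of `N` spacings, i.e. Gamma(`N`, λ) given `N` — hence the adder
  property and the scale-invariance of mean-rescaled moments are exact
  consequences of the construction, not approximations.

## Parameters

| name | meaning | units | default |
|------|---------|-------|---------|
| `k_m` | burst arrival (transcription) rate, concentration sense | 1/(min·volume) | 0.13 |
| `alpha` | exponential growth rate | 1/min | 0.03 |
| `X` | division threshold | molecules | 65 |
| `b` | mean burst size (geometric law) | molecules | 5 |
| `V_b` | newborn size | size units | 3.0 |

The defaults are the canonical study conditions used by every test and
by `scripts/acceptance.py`; with them `⟨N⟩ = 1 + (X−1)/b = 13.8`,
`⟨ΔV⟩ = ⟨N⟩α/k_m ≈ 3.18` size units, and the stationary newborn size
equals `⟨ΔV⟩` (adder fixed point), which is why `V_b = 3.0` is the
default newborn size. Sizes are abstract "size units": for rod-shaped
cells at fixed width, length is proportional to volume, so experimental
µm lengths map onto them linearly.

Geometric burst support: the default law lives on {1, 2, ...} with mean
`b` (every transcription event yields at least one protein, so `N ≤ X`
and the burst-count series terminates exactly); the {0, 1, ...} variant
is selectable via `support_start=0`. Both have mean `b`, and the
headline predictions are insensitive to the choice.

## Analytic layer — numerical choices

* The burst-count pmf is computed by the tail-difference identity
  `P(N=n) = P(S_{n−1} < X) − P(S_n < X)`, propagating the partial-sum
  distribution by convolution on the sub-threshold states {0..X−1} with
  mass ≥ X absorbed. Only the sub-threshold part of the burst law is
  ever needed, so infinite-support laws are handled exactly. The series
  is truncated adaptively at neglected mass < 1e−10 (configurable); a
  hard cap of 10,000 terms raises an explicit error. An independent
  exhaustive dense-convolution oracle (no truncation or absorption)
  checks this route to 1e−12 in the tests.
* Mixture densities are evaluated in log space (`logsumexp` over the
  burst count), with the `n = 1` term special-cased at `R = 0` so the
  density is finite at the origin.
* Quantiles invert the exact CDF on a 4097-point grid in the
  time-changed coordinate, followed by three Newton corrections on the
  exact CDF/pdf pair; the residual error is far below the resolution of
  any 10,000-sample comparison.
* Division-time moments use the exact time change
  `FPT = (1/α) log(1 + αU/(k_m V_b))` with `U` the Erlang-mixture
  first-passage level, integrated by adaptive quadrature in the
  `u` domain — the time-domain integrand is long-tailed, the `u`-domain
  one is not. Direct quadrature of `t^k f_FPT(t)` is retained as a
  cross-check; the two routes agree to ~1e−6 relative (machine
  precision in practice). Quadrature failure raises, never returns NaN.
* `alpha = 0` is an explicit homogeneous-Poisson branch (Erlang-mixture
  closed forms), not a division by zero; `alpha → 0` continuity is
  tested at `alpha = 1e−9`.
* Added-volume moments come from the Gamma-mixture rising-factorial
  identities; mean-scaled moments are computed in a form from which λ
  cancels algebraically, so their growth-rate invariance is bitwise.
* Initiation model closed form: division-to-division mean added volume
  is `origin_prefactor · ⟨ΔV⟩_per-origin · e^{αT}`. The structural
  result pins down only the `e^{αT}` ratio, so the origin-number
  prefactor is exposed as a parameter defaulting to 1; the simulator
  (below) is the arbiter and reproduces the ratio to ≲0.1%.

## Simulator — exactness

* Baseline: sample the burst-size walk to first passage (recording the
  realized burst count and the overshooting final count), then draw the
  added volume as Gamma(n, λ) — the exact conditional law of the sum of
  `n` Exp(λ) spacings. The division time follows from the logarithmic
  time change; `V_d = V_b e^{α·fpt}` holds to 1e−12 relative in every
  record. The final burst may overshoot `X`; `final_count` keeps the
  overshoot and partial degradation applies κ to it.
* Saturating rate `r(V) = k_m V/(1 + V/V_sat)`: the saturated
  cumulative rate has the closed form
  `(k_m V_sat/α) log((V_sat + V(t))/(V_sat + V(0)))`, so the next
  arrival is sampled by direct inversion. An independent thinning
  sampler (propose from the unsaturated rate, accept with probability
  `1/(1 + V/V_sat)`) is kept for cross-validation; the two agree in
  distribution (KS test in the suite).
* Soft threshold `h(x) = c (x/X)^H`: between bursts the hazard is
  constant, so division-vs-next-burst is an exact race of an Exp(h(x))
  clock in time against the exactly-sampled next arrival. The hazard is
  evaluated in log space so steepness up to `H = 1e7` stays finite; at
  `H → ∞` the soft rule reproduces the sharp-threshold added volume
  (within 2% in mean and 5% in CV² in the suite).
* Volume-dependent bursts `b(V) = b₀ V/V_ref`: the geometric law is
  re-parameterized at the volume at which each burst lands (clamped to
  mean ≥ 1 for the {1,2,...} support).
* Lineages: symmetric halving; under partial degradation the daughter
  inherits Binomial(round(κ·final_count), 1/2) molecules. Each lineage
  runs on its own generator spawned from the master seed, so
  per-lineage streams do not depend on the number of lineages run.
  Bulk i.i.d. single-cycle ensembles (`sample_cycles`) use a single
  generator and vectorized draws instead — they have no per-lineage
  structure to preserve. Identical configuration and seed give
  bitwise-identical tables in both paths.
* Initiation model: event-driven. The protein accumulates towards
  `θX`; at initiation it resets, θ doubles and a division is scheduled
  `T_CD` later; each division halves volume and θ. Bursts remain an
  exact inhomogeneous Poisson process across the division
  discontinuities because the remaining exponential budget is carried
  through each segment in the cumulative-rate coordinate. Per-origin
  increments are recorded via `s = V/θ`, which is continuous across
  divisions (both halve) and halves at initiations — the per-origin
  process is itself an adder over initiation events, which is exactly
  the sense in which the per-origin mean equals the baseline `⟨ΔV⟩`.
  The first 20 divisions are discarded as burn-in. A pending-division
  queue deeper than 64 (T_CD ≫ doubling time) raises an explicit error.

## Mechanism scan (added volume vs newborn size)

Newborn sizes are drawn uniformly on [1, 7] (the minimal assumption for
an interval with no stated law). Baseline, volume-dependent-burst,
saturating-rate and soft-threshold cells start with zero carryover.

Partial degradation needs a mother context to make the scan meaningful:
with symmetric halving the inherited count is independent of newborn
size and the scan would read as an adder. The package models the
scanned newborn as a daughter from an *asymmetric* division — its
mother divided at size `V_lo + V_hi`, and the retained pool
`round(κ·final_count)` (final count from a simulated baseline crossing)
is partitioned binomially with volume-proportional probability
`V_b/(V_lo + V_hi)`. Larger daughters therefore inherit more timekeeper
protein and need less additional volume: the negative association
emerges from volume-proportional protein partitioning, which is the
physically natural rule for a well-mixed cytoplasmic protein. Mechanism
defaults (κ = 0.5, V_ref = 1, V_sat = 5, H = 4, c = 1) are package
choices that realize the four correlation signs robustly; they are not
fits to any particular dataset.

## Analysis choices

* Size bins are half-open [lo, hi) with the last bin closed;
  out-of-range records are counted and reported, never dropped; bins
  under the configured minimum count are flagged and excluded from
  trend tests.
* CV² confidence intervals use the percentile bootstrap (simple,
  stable for ratio statistics at n ≥ 100); a coverage test in the
  suite checks ≥ 92% empirical coverage for the nominal 95% interval
  on Exp(1) samples.
* Distribution collapse uses pairwise two-sample KS at significance
  0.01 (conservative, because several pairs are compared), with each
  sample divided by its own mean when rescaling is on.
* The size–increment association uses Spearman correlation against a
  permutation null (999 permutations, 99% band): verdict "adder" if
  zero association is inside the band, otherwise the sign. The slope
  through 13 bin means is reported alongside for figure parity. The
  growth rate entering user tables is taken as a provided column; the
  package does not estimate per-cell growth rates.
* The initiation model's mean-vs-growth-rate linearity is scored by a
  through-origin least-squares fit with the uncentered R², the standard
  convention for intercept-free regression.

## What the synthetic generator does and does not emulate

The simulator *is* the model: it produces exact draws from the assumed
mechanism. It therefore reproduces the features the mechanism predicts
— adder behaviour, growth-rate collapse after mean-rescaling, rising
division-time noise with newborn size, mother–daughter independence of
the added volume — and omits features real single-cell data have for
other reasons: measurement noise in size estimates, cell-to-cell and
temporal growth-rate variability, asymmetric division noise, extrinsic
parameter fluctuations with lineage memory, and death/filamentation.
Passing tests validate the implementation against the model's own
mathematics, not the model against any organism.

## Problem sizes and runtimes

Default test and acceptance scales: 10,000 cells per KS comparison or
mechanism scan, 200,000 cycles for the moment-matching check (compared
within 3 batch-means standard errors over 20 batches), 10,000 lineages
× 8 generations for mother–daughter independence, 4,000 post-burn-in
cycles for the initiation ratio. These sizes hold every stochastic
check comfortably inside its statistical tolerance while keeping the
full suite under a minute on one core.

## Known limitations

* The burst-count pmf is exact but dense-convolution-based; thresholds
  of order 10⁵ molecules would make it O(X²) per term.
* The soft-threshold and volume-dependent-burst samplers are per-cell
  Python loops (exact but not vectorized); scans much beyond 10⁵ cells
  would benefit from batching.
* `alpha = 0` is supported in the analytic layer only; cycle simulation
  requires growth (`alpha > 0`), since the added-volume coordinate
  degenerates.
* The initiation variant assumes synchronous origin firing, negligible
  partitioning error of the timekeeper between initiations, and a
  growth-rate-independent C+D period.
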