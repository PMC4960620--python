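# celladder

Stochastic first-passage-time model of bacterial cell-size control.

Exponentially growing bacteria such as *E. coli* obey the **adder
principle**: between birth and division a cell adds a fixed mean volume,
independent of how large it was born. `celladder` implements a
mechanistic explanation: a *timekeeper protein* (FtsZ and DnaA are the
usual candidates) is expressed in stochastic bursts at a rate
proportional to the growing cell volume, and division fires when its
copy number first reaches a threshold. The package is for quantitative
cell biologists and modellers who want the exact distributions this
mechanism predicts, an exact stochastic simulator of it, and the
statistical protocols used to test adder behaviour in single-cell data.

## Model

A newborn cell of volume `V_b` grows as `V(t) = V_b e^{αt}`. Bursts of
the timekeeper protein arrive as an inhomogeneous Poisson process with
rate `r(t) = k_m V(t)` (so protein concentration is maintained during
growth); burst sizes `B_i` are i.i.d. with mean `b`, geometric by
default. Division is the first-passage time (FPT) of the copy number
`x(t)` to the threshold `X`, after which the protein is degraded.

With `N = min{n : B_1 + … + B_n ≥ X}` the number of bursts needed, and
`R(t) = (k_m V_b/α)(e^{αt} − 1)` the cumulative arrival rate, the
division time is a mixture over the arrival times of the N-th burst:

    f_FPT(t) = Σ_n P(N = n) · r(t) R(t)^{n−1} e^{−R(t)} / (n−1)!

The added volume `ΔV = V_b (e^{α·FPT} − 1)` is the same process viewed
in the added-volume coordinate, where arrivals are homogeneous with rate
`λ = k_m/α`:

    f_ΔV(v) = Σ_n P(N = n) · Gamma(v; shape n, rate λ)

which contains **no `V_b`** — the adder property — and in which `λ`
enters only as a scale, so `⟨ΔV⟩ = ⟨N⟩ α/k_m` is linear in the growth
rate while CV², skewness and every mean-scaled moment `⟨ΔV^j⟩/⟨ΔV⟩^j`
are growth-rate invariant (distribution collapse after mean-rescaling).

The package also provides:

* a **replication-initiation variant** (threshold `θX` per round with
  `θ` origins of replication, fixed initiation-to-division delay
  `T = C + D`), whose division-to-division mean added volume is the
  per-origin mean times `e^{αT}`;
* the four **deviation-from-adder mechanisms** — partial protein
  degradation at division, volume-dependent burst size, saturating
  transcription rate, soft division threshold — with the predicted
  negative/negative/positive/positive correlation between `ΔV` and
  `V_b`;
* analysis utilities: newborn-size binning, bootstrap CV² confidence
  intervals, KS distribution-collapse diagnostics, and a permutation
  trend test returning an adder/positive/negative verdict.

All simulation is exact (time-change of the inhomogeneous process,
closed-form rate inversion, or competing-exponential races) — there is
no Euler time stepping anywhere.

## Worked example

```python
import numpy as np
from celladder import *

params = ModelParams(k_m=0.13, alpha=0.03, burst=BurstLaw.geometric(5.0), X=65, V_b=2.0)
fpt = fpt_moments(FPTDistribution(params), order=2)
dv = deltaV_moments(AddedVolumeDistribution.from_params(params))
print(f"division time: mean = {fpt.mean:.2f} min, CV2 = {fpt.cv2:.4f}")
print(f"added volume:  mean = {dv.mean:.4f}, CV2 = {dv.cv2:.4f}, skewness = {dv.skewness:.4f}")

df = sample_cycles(params, 10_000, rng=np.random.default_rng(0))
print(f"simulated:     mean dV = {df.delta_V.mean():.4f}, mean FPT = {df.fpt.mean():.2f} min")

trend = adder_trend_test(
    mechanism_correlation_experiment(MechanismSpec.baseline(), params,
                                     n_cells=10_000, rng=np.random.default_rng(1)),
    rng=np.random.default_rng(2))
print(f"adder test:    Spearman rho = {trend.spearman:+.4f} -> verdict: {trend.verdict}")
```

prints

```
division time: mean = 30.97 min, CV2 = 0.0550
added volume:  mean = 3.1846, CV2 = 0.1262, skewness = 0.5469
simulated:     mean dV = 3.1913, mean FPT = 31.00 min
adder test:    Spearman rho = +0.0138 -> verdict: adder
```

A cell born at 2 size units divides after ~31 min on average; the
analytic added-volume mean 3.185 (which a 10,000-cycle exact simulation
reproduces to ~0.2%) is the adder increment, positively skewed; and a
scan of newborn sizes over [1, 7] shows no size–increment association.
The parameter set (`k_m = 0.13 /min`, `α = 0.03 /min`, `X = 65`
molecules, geometric bursts with `b = 5`) is the package's canonical
condition, used as the default everywhere.

## Command line

```
celladder simulate --experiment lineage -n 1000 --generations 10 --seed 1 --out runs/lin
celladder distributions --outdir dists/
celladder analyze --input runs/lin.csv --out runs/report
celladder fixtures --seed 0 --outdir fixtures/
```

Outputs are plain CSV/TSV with the fully resolved configuration and
seed embedded as commented header lines; identical configuration and
seed reproduce files byte for byte.

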