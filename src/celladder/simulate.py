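"""Exact stochastic simulation of cell cycles, lineages and mechanism variants.

The baseline sampler contains no time discretization.  In the
added-volume coordinate ``v = V(t) - V_b`` the burst arrivals of the
inhomogeneous Poisson process become homogeneous with rate
``lambda = k_m / alpha`` (time change through the cumulative rate), so
inter-burst spacings are independent Exp(lambda) added-volume increments
and the division time is recovered with
``fpt = log(1 + delta_V / V_b) / alpha``.

Mechanism variants stay exact:

* ``saturating_rate`` inverts the closed-form saturated cumulative rate
  (a thinning sampler against the unsaturated rate is kept as an
  independent cross-check);
* ``soft_threshold`` races the exactly-sampled next burst against an
  exponential division clock whose rate is the current hazard (the
  hazard is constant between bursts, so the race is exact);
* ``volume_dependent_burst`` re-parameterizes the burst law at the
  volume at which each burst lands.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hazard import SoftThreshold, division_hazard
from .params import (
    BurstLaw,
    ConfigError,
    DomainError,
    InitiationModelParams,
    LineageConfig,
    MechanismSpec,
    ModelParams,
    NumericalError,
)

__all__ = [
    "CellCycleRecord",
    "sample_cycle",
    "sample_cycles",
    "sample_lineage",
    "InitiationResult",
    "sample_initiation_model",
    "mechanism_correlation_experiment",
    "records_to_frame",
    "CYCLE_COLUMNS",
]

CYCLE_COLUMNS = [
    "lineage_id",
    "generation",
    "V_b",
    "V_d",
    "delta_V",
    "fpt",
    "alpha",
    "n_bursts",
    "final_count",
    "carryover_in",
    "mechanism",
]


@dataclass(frozen=True)
class CellCycleRecord:
    """One simulated cell cycle."""

    V_b: float
    V_d: float
    delta_V: float
    fpt: float
    n_bursts: int
    final_count: int
    alpha: float
    generation: int = 0
    lineage_id: int = 0
    carryover_in: int = 0
    mechanism: str = "baseline"


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        df = pd.DataFrame(columns=CYCLE_COLUMNS)
    return df[CYCLE_COLUMNS]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ----------------------------------------------------------------------
# threshold crossing of the burst-size random walk
# ----------------------------------------------------------------------
def _crossing_scalar(burst: BurstLaw, need: int, rng: np.random.Generator):
    """Number of bursts and accumulated count at first passage over `need`."""
    total = 0
    n = 0
    chunk = max(8, int(np.ceil(1.5 * need / max(burst.mean, 1e-12))))
    while True:
        draws = np.asarray(burst.sample(rng, chunk))
        s = np.cumsum(draws) + total
        hit = np.nonzero(s >= need)[0]
        if hit.size:
            i = int(hit[0])
            return n + i + 1, int(s[i])
        total = int(s[-1])
        n += chunk


def _crossing_vec(burst: BurstLaw, need: np.ndarray, rng: np.random.Generator):
    """Vectorized first passage for an array of per-cell thresholds."""
    m = need.shape[0]
    N = np.zeros(m, dtype=np.int64)
    S = np.zeros(m, dtype=np.int64)
    active = np.arange(m)
    base = np.zeros(m, dtype=np.int64)
    chunk = max(8, int(np.ceil(1.5 * float(need.max()) / max(burst.mean, 1e-12))))
    offset = 0
    while active.size:
        draws = np.asarray(burst.sample(rng, (active.size, chunk)))
        cum = np.cumsum(draws, axis=1) + base[active, None]
        crossed = cum >= need[active, None]
        any_hit = crossed.any(axis=1)
        idx = np.argmax(crossed, axis=1)
        hits = active[any_hit]
        N[hits] = offset + idx[any_hit] + 1
        S[hits] = cum[any_hit, idx[any_hit]]
        base[active] = cum[:, -1]
        active = active[~any_hit]
        offset += chunk
    return N, S


# ----------------------------------------------------------------------
# single cycles
# ----------------------------------------------------------------------
def sample_cycle(
    params: ModelParams,
    mechanism: MechanismSpec | None = None,
    carryover: int = 0,
    rng=None,
    generation: int = 0,
    lineage_id: int = 0,
) -> CellCycleRecord:
    """Simulate one cell cycle exactly; see the module docstring for the
    sampling scheme of each mechanism.

    ``carryover`` is the protein count inherited at birth (0 in the
    baseline model); it must lie below the sharp threshold.
    """
    mechanism = mechanism or MechanismSpec.baseline()
    rng = _as_rng(rng)
    if params.alpha <= 0:
        raise DomainError("cycle simulation requires alpha > 0")
    if carryover < 0:
        raise DomainError("carryover must be non-negative")
    X = params.X
    lam = params.rate_lambda

    if mechanism.kind in ("baseline", "partial_degradation"):
        if carryover >= X:
            raise DomainError("carryover must be below the threshold X")
        n, final = _crossing_scalar(params.burst, X - carryover, rng)
        delta_v = float(rng.standard_gamma(n) / lam)
        final += carryover
    elif mechanism.kind == "volume_dependent_burst":
        if carryover >= X:
            raise DomainError("carryover must be below the threshold X")
        if params.burst.kind == "tabulated":
            raise ConfigError("volume_dependent_burst supports geometric or deterministic bursts")
        x = carryover
        delta_v = 0.0
        n = 0
        b0 = params.burst.mean
        while x < X:
            delta_v += rng.exponential(1.0 / lam)
            b_here = b0 * (params.V_b + delta_v) / mechanism.V_ref
            x += _draw_scaled_burst(params.burst, b_here, rng)
            n += 1
        final = x
    elif mechanism.kind == "saturating_rate":
        if carryover >= X:
            raise DomainError("carryover must be below the threshold X")
        x = carryover
        V = params.V_b
        n = 0
        scale = params.alpha / (params.k_m * mechanism.V_sat)
        while x < X:
            # invert the saturated cumulative rate, closed form:
            # R_sat(t) = (k_m V_sat / alpha) log((V_sat + V(t)) / (V_sat + V))
            V = (mechanism.V_sat + V) * np.exp(rng.exponential() * scale) - mechanism.V_sat
            x += int(params.burst.sample(rng))
            n += 1
        delta_v = float(V - params.V_b)
        final = x
    elif mechanism.kind == "soft_threshold":
        spec = SoftThreshold(X=X, H=mechanism.H, c=mechanism.c)
        x = carryover
        V = params.V_b
        n = 0
        alpha = params.alpha
        while True:
            h = division_hazard(spec, x)
            dv_burst = rng.exponential(1.0 / lam)
            dt_burst = np.log1p(dv_burst / V) / alpha
            if h > 0:
                dt_div = 0.0 if np.isinf(h) else rng.exponential(1.0 / h)
                if dt_div < dt_burst:
                    V = V * np.exp(alpha * dt_div)
                    break
            V += dv_burst
            x += int(params.burst.sample(rng))
            n += 1
        delta_v = float(V - params.V_b)
        final = x
    else:  # pragma: no cover - guarded by MechanismSpec validation
        raise ConfigError(f"unknown mechanism {mechanism.kind!r}")

    V_d = params.V_b + delta_v
    fpt = float(np.log1p(delta_v / params.V_b) / params.alpha)
    return CellCycleRecord(
        V_b=params.V_b,
        V_d=V_d,
        delta_V=delta_v,
        fpt=fpt,
        n_bursts=int(n),
        final_count=int(final),
        alpha=params.alpha,
        generation=generation,
        lineage_id=lineage_id,
        carryover_in=int(carryover),
        mechanism=mechanism.kind,
    )


def _draw_scaled_burst(burst: BurstLaw, mean_here: float, rng: np.random.Generator) -> int:
    if burst.kind == "deterministic":
        return max(1, int(round(mean_here)))
    if burst.support_start == 1:
        mean_here = max(mean_here, 1.0)
        return int(rng.geometric(1.0 / mean_here))
    return int(rng.geometric(1.0 / (1.0 + max(mean_here, 0.0)))) - 1


def _sample_saturating_thinning(
    params: ModelParams, mechanism: MechanismSpec, rng: np.random.Generator
) -> CellCycleRecord:
    """Cross-check sampler for the saturating-rate mechanism: propose
    arrivals from the unsaturated rate k_m V (exact, via the added-volume
    coordinate) and accept with probability 1 / (1 + V / V_sat)."""
    rng = _as_rng(rng)
    X = params.X
    lam = params.rate_lambda
    x = 0
    V = params.V_b
    n = 0
    while x < X:
        V += rng.exponential(1.0 / lam)  # proposal from the dominating rate
        if rng.uniform() < 1.0 / (1.0 + V / mechanism.V_sat):
            x += int(params.burst.sample(rng))
            n += 1
    delta_v = float(V - params.V_b)
    return CellCycleRecord(
        V_b=params.V_b,
        V_d=params.V_b + delta_v,
        delta_V=delta_v,
        fpt=float(np.log1p(delta_v / params.V_b) / params.alpha),
        n_bursts=n,
        final_count=int(x),
        alpha=params.alpha,
        mechanism="saturating_rate",
    )


# ----------------------------------------------------------------------
# bulk iid ensembles (baseline dynamics, vectorized)
# ----------------------------------------------------------------------
def sample_cycles(
    params: ModelParams,
    n_cells: int,
    rng=None,
    carryover: int = 0,
    V_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized ensemble of independent baseline cycles.

    ``V_b`` may be an array of per-cell newborn sizes (defaults to the
    one in ``params``).  The added-volume draw never involves the newborn
    size — the adder property is structural, not asserted.
    """
    rng = _as_rng(rng)
    if params.alpha <= 0:
        raise DomainError("cycle simulation requires alpha > 0")
    if carryover >= params.X or carryover < 0:
        raise DomainError("carryover must lie in [0, X)")
    lam = params.rate_lambda
    vb = np.full(n_cells, params.V_b) if V_b is None else np.asarray(V_b, dtype=float)
    if vb.shape[0] != n_cells:
        raise ConfigError("V_b array length must equal n_cells")
    need = np.full(n_cells, params.X - carryover, dtype=np.int64)
    N, S = _crossing_vec(params.burst, need, rng)
    delta_v = rng.standard_gamma(N.astype(float)) / lam
    fpt = np.log1p(delta_v / vb) / params.alpha
    return pd.DataFrame(
        {
            "lineage_id": np.arange(n_cells, dtype=np.int64),
            "generation": np.zeros(n_cells, dtype=np.int64),
            "V_b": vb,
            "V_d": vb + delta_v,
            "delta_V": delta_v,
            "fpt": fpt,
            "alpha": np.full(n_cells, params.alpha),
            "n_bursts": N,
            "final_count": S + carryover,
            "carryover_in": np.full(n_cells, carryover, dtype=np.int64),
            "mechanism": np.full(n_cells, "baseline", dtype=object),
        }
    )


# ----------------------------------------------------------------------
# lineages
# ----------------------------------------------------------------------
def sample_lineage(config: LineageConfig) -> pd.DataFrame:
    """Simulate ``n_lineages`` independent lineages for
    ``n_generations`` each: daughters inherit ``division_ratio * V_d``
    (symmetric halving by default) and, under partial degradation, a
    Binomial(round(kappa * final_count), 1/2) protein carryover.

    Each lineage gets its own generator spawned from the master seed, so
    per-lineage streams do not depend on how many lineages are run.
    """
    mech = config.mechanism
    rows: list[CellCycleRecord] = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_lineages)
    for lid, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        vb = config.params.V_b
        carry = 0
        for gen in range(config.n_generations):
            p = replace(config.params, V_b=vb)
            rec = sample_cycle(
                p, mech, carryover=carry, rng=rng, generation=gen, lineage_id=lid
            )
            rows.append(rec)
            vb = config.division_ratio * rec.V_d
            if mech.kind == "partial_degradation":
                pool = int(round(mech.retention_kappa * rec.final_count))
                carry = int(rng.binomial(pool, 0.5))
                carry = min(carry, config.params.X - 1)
            else:
                carry = 0
    return records_to_frame(rows)


# ----------------------------------------------------------------------
# replication-initiation model
# ----------------------------------------------------------------------
@dataclass
class InitiationResult:
    """Division-to-division cycles plus per-origin initiation increments."""

    cycles: pd.DataFrame
    per_origin_delta: np.ndarray
    params: InitiationModelParams


def sample_initiation_model(
    params: InitiationModelParams,
    n_cycles: int,
    rng=None,
    burn_in: int = 20,
    max_pending: int = 64,
    V0: float | None = None,
) -> InitiationResult:
    """Event-driven simulation of the initiation-triggered model.

    The timekeeper accumulates towards ``theta * X`` (theta = current
    origin count); at initiation it resets, theta doubles, and a division
    is scheduled ``T_CD`` later; each division halves both the volume and
    theta.  Burst arrivals stay an inhomogeneous Poisson process with
    rate ``k_m V(t)`` across division discontinuities: the remaining
    exponential budget is carried over segment by segment (the
    time-change is memoryless in the cumulative-rate coordinate).

    Per-origin initiation increments are recorded through the per-origin
    size ``s = V / theta``, which is continuous across divisions (both
    halve) and halves at each initiation (theta doubles) — so the
    per-origin process is itself an adder over initiation events.
    """
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    rng = _as_rng(rng)
    base = params.base
    if base.alpha <= 0:
        raise DomainError("initiation model requires alpha > 0")
    k_m, alpha, X = base.k_m, base.alpha, base.X
    t = 0.0
    V = V0 if V0 is not None else base.V_b
    theta = params.theta
    x = 0
    pending: deque[float] = deque()
    s_prev: float | None = None
    per_origin: list[float] = []
    cycles: list[dict] = []
    prev_div_t: float | None = None
    vb_current = V
    n_div = 0
    target = n_cycles + burn_in

    while n_div < target:
        budget = rng.exponential()
        # advance to the next burst, processing any divisions on the way
        while True:
            dt_burst = np.log1p(alpha * budget / (k_m * V)) / alpha
            t_div = pending[0] if pending else np.inf
            if t + dt_burst < t_div:
                t += dt_burst
                V *= np.exp(alpha * dt_burst)
                break
            # consume the budget up to the division, then divide
            dtau = t_div - t
            budget -= (k_m * V / alpha) * np.expm1(alpha * dtau)
            t = t_div
            V *= np.exp(alpha * dtau)
            pending.popleft()
            n_div += 1
            if n_div > burn_in and prev_div_t is not None:
                cycles.append(
                    {
                        "V_b": vb_current,
                        "V_d": V,
                        "delta_V": V - vb_current,
                        "fpt": t - prev_div_t,
                        "theta_at_division": theta,
                        "t_division": t,
                    }
                )
            prev_div_t = t
            V *= 0.5
            if theta % 2 != 0:
                raise NumericalError("origin count not divisible at division")
            theta //= 2
            vb_current = V
            if n_div >= target:
                break
        if n_div >= target:
            break
        # burst lands
        x += int(base.burst.sample(rng))
        if x >= theta * X:
            s = V / theta
            if s_prev is not None and n_div >= burn_in:
                per_origin.append(s - s_prev)
            s_prev = 0.5 * s
            x = 0
            theta *= 2
            pending.append(t + params.T_CD)
            if len(pending) > max_pending:
                raise NumericalError(
                    f"more than {max_pending} pending divisions: T_CD too large "
                    "relative to the inter-initiation time"
                )

    df = pd.DataFrame(cycles, columns=[
        "V_b", "V_d", "delta_V", "fpt", "theta_at_division", "t_division",
    ])
    return InitiationResult(
        cycles=df, per_origin_delta=np.asarray(per_origin), params=params
    )


# ----------------------------------------------------------------------
# deviation-mechanism scan (added volume vs newborn size)
# ----------------------------------------------------------------------
def mechanism_correlation_experiment(
    mechanism: MechanismSpec,
    params: ModelParams,
    n_cells: int = 10_000,
    V_b_range: tuple[float, float] = (1.0, 7.0),
    rng=None,
) -> pd.DataFrame:
    """Single-cycle scan over newborn sizes drawn uniformly on
    ``V_b_range``, returning per-cell (V_b, delta_V) pairs.

    For ``partial_degradation`` the scanned newborn is modelled as a
    daughter from an asymmetric division: its mother divided at size
    ``V_lo + V_hi`` and the retained protein pool
    ``round(kappa * final_count)`` is partitioned binomially with
    volume-proportional probability ``V_b / (V_lo + V_hi)``, so larger
    daughters inherit more timekeeper protein.  All other mechanisms use
    zero carryover.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    rng = _as_rng(rng)
    lo, hi = V_b_range
    if not hi > lo > 0:
        raise ConfigError("V_b_range must be an increasing positive interval")
    vb = rng.uniform(lo, hi, size=n_cells)

    if mechanism.kind == "baseline":
        df = sample_cycles(params, n_cells, rng=rng, V_b=vb)
        df["mechanism"] = "baseline"
        return df

    if mechanism.kind == "partial_degradation":
        # mother crossings: only the final count matters (size-free)
        need = np.full(n_cells, params.X, dtype=np.int64)
        _, F = _crossing_vec(params.burst, need, rng)
        pool = np.round(mechanism.retention_kappa * F).astype(np.int64)
        carry = rng.binomial(pool, vb / (lo + hi))
        carry = np.minimum(carry, params.X - 1)
        N, S = _crossing_vec(params.burst, params.X - carry, rng)
        lam = params.rate_lambda
        delta_v = rng.standard_gamma(N.astype(float)) / lam
        return pd.DataFrame(
            {
                "lineage_id": np.arange(n_cells, dtype=np.int64),
                "generation": np.zeros(n_cells, dtype=np.int64),
                "V_b": vb,
                "V_d": vb + delta_v,
                "delta_V": delta_v,
                "fpt": np.log1p(delta_v / vb) / params.alpha,
                "alpha": np.full(n_cells, params.alpha),
                "n_bursts": N,
                "final_count": S + carry,
                "carryover_in": carry,
                "mechanism": np.full(n_cells, "partial_degradation", dtype=object),
            }
        )

    rows = []
    for i in range(n_cells):
        p = replace(params, V_b=float(vb[i]))
        rows.append(sample_cycle(p, mechanism, rng=rng, lineage_id=i))
    return records_to_frame(rows)
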