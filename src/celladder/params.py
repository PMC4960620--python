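"""Parameter containers and validation for the timekeeper-protein model.

The model: a cell born at volume ``V_b`` grows exponentially,
``V(t) = V_b * exp(alpha * t)``.  A timekeeper protein is produced in
bursts arriving as an inhomogeneous Poisson process with rate
``r(t) = k_m * V(t)`` (``k_m`` is the transcription rate in the
concentration sense).  Burst sizes ``B_i`` are i.i.d. non-negative
integers with mean ``b``.  Division fires when the protein copy number
first reaches the threshold ``X``; the protein is then degraded (or
deactivated).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)

import numpy as np

__all__ = [
    "DomainError",
    "ConfigError",
    "NumericalError",
    "BurstLaw",
    "ModelParams",
    "InitiationModelParams",
    "MechanismSpec",
    "LineageConfig",
]


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(ValueError):
    """Inconsistent or invalid model / mechanism configuration."""


class NumericalError(RuntimeError):
    """A numerical routine failed to reach the requested accuracy."""


_BURST_KINDS = ("geometric", "deterministic", "tabulated")


@dataclass(frozen=True)
class BurstLaw:
    """Probability law of the protein burst sizes ``B_i``.

    Parameters
    ----------
    kind
        ``"geometric"``, ``"deterministic"`` or ``"tabulated"``.
    mean_b
        Mean burst size ``b`` (geometric law only).
    value
        Fixed burst size (deterministic law only).
    pmf
        Finite table ``((size, probability), ...)`` with non-negative
        integer support summing to 1 (tabulated law only).
    support_start
        Geometric law only: 1 (default) places the law on {1, 2, ...}
        so every transcription event yields at least one protein;
        0 selects the {0, 1, ...} variant.  Both have mean ``b``.
    """

    kind: str
    mean_b: float | None = None
    value: int | None = None
    pmf: tuple[tuple[int, float], ...] | None = None
    support_start: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _BURST_KINDS:
            raise ConfigError(f"unknown burst law kind {self.kind!r}")
        if self.kind == "geometric":
            if self.mean_b is None or not self.mean_b > 0:
                raise ConfigError("geometric burst law needs mean_b > 0")
            if self.support_start not in (0, 1):
                raise ConfigError("support_start must be 0 or 1")
            if self.support_start == 1 and self.mean_b < 1:
                raise ConfigError("geometric on {1,2,...} needs mean_b >= 1")
        elif self.kind == "deterministic":
            if self.value is None or self.value != int(self.value) or self.value < 0:
                raise ConfigError("deterministic burst law needs a non-negative integer value")
            object.__setattr__(self, "value", int(self.value))
        else:  # tabulated
            if not self.pmf:
                raise ConfigError("tabulated burst law needs a non-empty pmf")
            pmf = tuple((int(k), float(p)) for k, p in self.pmf)
            for k, p in pmf:
                if k < 0:
                    raise ConfigError("tabulated support must be non-negative integers")
                if p < 0:
                    raise ConfigError("tabulated probabilities must be non-negative")
            total = math.fsum(p for _, p in pmf)
            if abs(total - 1.0) > 1e-12:
                raise ConfigError(f"tabulated pmf sums to {total}, not 1 within 1e-12")
            object.__setattr__(self, "pmf", pmf)

    # -- constructors --------------------------------------------------
    @classmethod
    def geometric(cls, mean_b: float, support_start: int = 1) -> "BurstLaw":
        return cls(kind="geometric", mean_b=mean_b, support_start=support_start)

    @classmethod
    def deterministic(cls, value: int) -> "BurstLaw":
        return cls(kind="deterministic", value=value)

    @classmethod
    def tabulated(cls, pmf) -> "BurstLaw":
        return cls(kind="tabulated", pmf=tuple(pmf))

    # -- moments -------------------------------------------------------
    @property
    def mean(self) -> float:
        if self.kind == "geometric":
            return float(self.mean_b)
        if self.kind == "deterministic":
            return float(self.value)
        return float(sum(k * p for k, p in self.pmf))

    @property
    def mass_at_zero(self) -> float:
        if self.kind == "geometric":
            if self.support_start == 1:
                return 0.0
            p = 1.0 / (1.0 + self.mean_b)
            return p
        if self.kind == "deterministic":
            return 1.0 if self.value == 0 else 0.0
        return float(sum(p for k, p in self.pmf if k == 0))

    def pmf_vector(self, kmax: int) -> np.ndarray:
        """P(B = k) for k = 0..kmax; mass above kmax is left implicit."""
        out = np.zeros(kmax + 1)
        if self.kind == "geometric":
            if self.support_start == 1:
                p = 1.0 / self.mean_b
                k = np.arange(1, kmax + 1)
                if kmax >= 1:
                    out[1:] = p * (1.0 - p) ** (k - 1)
            else:
                p = 1.0 / (1.0 + self.mean_b)
                k = np.arange(0, kmax + 1)
                out[:] = p * (1.0 - p) ** k
        elif self.kind == "deterministic":
            if self.value <= kmax:
                out[self.value] = 1.0
        else:
            for k, p in self.pmf:
                if k <= kmax:
                    out[k] += p
        return out

    def sample(self, rng: np.random.Generator, size=None):
        """Draw burst sizes."""
        if self.kind == "geometric":
            if self.support_start == 1:
                return rng.geometric(1.0 / self.mean_b, size=size)
            return rng.geometric(1.0 / (1.0 + self.mean_b), size=size) - 1
        if self.kind == "deterministic":
            if size is None:
                return self.value
            return np.full(size, self.value, dtype=np.int64)
        ks = np.array([k for k, _ in self.pmf], dtype=np.int64)
        ps = np.array([p for _, p in self.pmf])
        ps = ps / ps.sum()
        return rng.choice(ks, size=size, p=ps)


@dataclass(frozen=True)
class ModelParams:
    """Baseline adder model parameters.

    k_m    : burst-arrival (transcription) rate per unit time per unit volume
    alpha  : exponential growth rate per unit time (0 allowed for limit checks)
    burst  : burst-size law with mean b
    X      : division threshold, protein molecules (integer >= 1)
    V_b    : newborn cell volume, size units
    """

    k_m: float
    alpha: float
    burst: BurstLaw
    X: int
    V_b: float

    def __post_init__(self) -> None:
        if not self.k_m > 0:
            raise ConfigError("k_m must be > 0")
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.X != int(self.X) or self.X < 1:
            raise DomainError("threshold X must be an integer >= 1")
        object.__setattr__(self, "X", int(self.X))
        if not self.V_b > 0:
            raise ConfigError("V_b must be > 0")

    @property
    def rate_lambda(self) -> float:
        """Burst arrival rate per unit *added volume*, lambda = k_m / alpha."""
        if self.alpha == 0:
            raise DomainError("rate_lambda undefined for alpha = 0 (no growth)")
        return self.k_m / self.alpha


@dataclass(frozen=True)
class InitiationModelParams:
    """Replication-initiation variant: the timekeeper counts down to the
    next initiation (threshold theta * X with theta origins of replication);
    division follows each initiation after a fixed delay T = C + D.

    ``origin_prefactor`` multiplies the per-origin mean added volume in the
    closed-form division-to-division mean; it defaults to 1 (no extra
    origin-number factor) and is exposed because the structural result only
    pins down the exp(alpha*T) ratio.
    """

    base: ModelParams
    T_CD: float
    theta: int = 1
    origin_prefactor: float = 1.0

    def __post_init__(self) -> None:
        if self.theta != int(self.theta) or self.theta < 1:
            raise ConfigError("theta must be an integer >= 1")
        object.__setattr__(self, "theta", int(self.theta))
        if self.T_CD < 0:
            raise ConfigError("T_CD must be >= 0")
        if not self.origin_prefactor > 0:
            raise ConfigError("origin_prefactor must be > 0")


_MECHANISMS = (
    "baseline",
    "partial_degradation",
    "volume_dependent_burst",
    "saturating_rate",
    "soft_threshold",
)


@dataclass(frozen=True)
class MechanismSpec:
    """Which deviation-from-adder mechanism is active, and its parameters.

    baseline               : sharp threshold, full degradation at division.
    partial_degradation    : a fraction ``retention_kappa`` of the final
                             count survives division and is inherited.
    volume_dependent_burst : burst mean scales with instantaneous volume,
                             b(V) = b0 * V / V_ref.
    saturating_rate        : arrival rate saturates with volume,
                             r(V) = k_m * V / (1 + V / V_sat).
    soft_threshold         : division is a hazard h(x) = c * (x / X)**H
                             per unit time instead of a sharp threshold.
    """

    kind: str = "baseline"
    retention_kappa: float | None = None
    V_ref: float | None = None
    V_sat: float | None = None
    H: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _MECHANISMS:
            raise ConfigError(f"unknown mechanism kind {self.kind!r}")
        required = {
            "baseline": (),
            "partial_degradation": ("retention_kappa",),
            "volume_dependent_burst": ("V_ref",),
            "saturating_rate": ("V_sat",),
            "soft_threshold": ("H", "c"),
        }[self.kind]
        for name in ("retention_kappa", "V_ref", "V_sat", "H", "c"):
            val = getattr(self, name)
            if name in required:
                if val is None:
                    raise ConfigError(f"mechanism {self.kind!r} requires {name}")
            elif val is not None:
                raise ConfigError(f"parameter {name} inconsistent with mechanism {self.kind!r}")
        if self.kind == "partial_degradation" and not 0.0 <= self.retention_kappa <= 1.0:
            raise ConfigError("retention_kappa must lie in [0, 1]")
        if self.kind == "volume_dependent_burst" and not self.V_ref > 0:
            raise ConfigError("V_ref must be > 0")
        if self.kind == "saturating_rate" and not self.V_sat > 0:
            raise ConfigError("V_sat must be > 0")
        if self.kind == "soft_threshold" and (not self.H > 0 or not self.c > 0):
            raise ConfigError("soft threshold needs H > 0 and c > 0")

    # -- constructors --------------------------------------------------
    @classmethod
    def baseline(cls) -> "MechanismSpec":
        return cls(kind="baseline")

    @classmethod
    def partial_degradation(cls, kappa: float = 0.5) -> "MechanismSpec":
        return cls(kind="partial_degradation", retention_kappa=kappa)

    @classmethod
    def volume_dependent_burst(cls, V_ref: float = 1.0) -> "MechanismSpec":
        return cls(kind="volume_dependent_burst", V_ref=V_ref)

    @classmethod
    def saturating_rate(cls, V_sat: float = 5.0) -> "MechanismSpec":
        return cls(kind="saturating_rate", V_sat=V_sat)

    @classmethod
    def soft_threshold(cls, H: float = 4.0, c: float = 1.0) -> "MechanismSpec":
        return cls(kind="soft_threshold", H=H, c=c)


@dataclass(frozen=True)
class LineageConfig:
    """Multi-generation simulation setup: symmetric halving at division,
    one daughter followed per lineage."""

    params: ModelParams
    mechanism: MechanismSpec = field(default_factory=MechanismSpec.baseline)
    n_generations: int = 1
    n_lineages: int = 1
    division_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.n_lineages < 1:
            raise ConfigError("n_lineages must be >= 1")
        if not 0.0 < self.division_ratio < 1.0:
            raise ConfigError("division_ratio must lie in (0, 1)")
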