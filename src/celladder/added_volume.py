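"""Added-volume distribution, moments, scale invariance, initiation mean.

The volume added from birth to division, ``dV = V_b (exp(alpha FPT) - 1)``,
is a compound sum: given ``N = n`` bursts it is Gamma(n, rate = k_m/alpha)
because the burst arrivals, viewed in the added-volume coordinate, form a
homogeneous Poisson process with rate ``lambda = k_m / alpha``.  The
mixture over the burst-count pmf therefore carries no dependence on the
newborn size ``V_b`` at all — the adder property — and ``lambda`` enters
only as a scale, which makes every mean-scaled moment independent of the
growth rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .bursts import BurstCountPMF, burst_count_pmf
from .fpt import _log_mixture_gamma_pdf, _mixture_log_weights
from .params import DomainError, InitiationModelParams, ModelParams

__all__ = [
    "AddedVolumeDistribution",
    "AddedVolumeMoments",
    "deltaV_moments",
    "scaled_moment",
    "initiation_mean_added_volume",
]


@dataclass
class AddedVolumeDistribution:
    """Mixture of Gamma(n, rate_lambda) densities weighted by P(N = n).

    Deliberately carries no newborn-size field: two objects built from
    model parameters differing only in V_b are identical.
    """

    rate_lambda: float
    burst_count: BurstCountPMF

    def __post_init__(self) -> None:
        if not self.rate_lambda > 0:
            raise DomainError("rate_lambda = k_m/alpha must be > 0")

    @classmethod
    def from_params(
        cls,
        params: ModelParams,
        n_max: int | None = None,
        tail_mass_bound: float = 1e-10,
    ) -> "AddedVolumeDistribution":
        pmf = burst_count_pmf(
            params.X, params.burst, n_max=n_max, tail_mass_bound=tail_mass_bound
        )
        return cls(rate_lambda=params.rate_lambda, burst_count=pmf)

    # ------------------------------------------------------------------
    def pdf(self, v):
        """Density of the added volume at v >= 0."""
        v_arr = np.atleast_1d(np.asarray(v, dtype=float))
        if np.any(v_arr < 0):
            raise DomainError("added volume must be non-negative")
        u = self.rate_lambda * v_arr
        n, logw = _mixture_log_weights(self.burst_count)
        out = self.rate_lambda * np.exp(_log_mixture_gamma_pdf(u, n, logw))
        return out if np.ndim(v) else float(out[0])

    def cdf(self, v):
        v_arr = np.atleast_1d(np.asarray(v, dtype=float))
        if np.any(v_arr < 0):
            raise DomainError("added volume must be non-negative")
        u = self.rate_lambda * v_arr
        n = self.burst_count.n_values.astype(float)
        out = special.gammainc(n[None, :], u[:, None]) @ self.burst_count.probs
        return out if np.ndim(v) else float(out[0])

    def ppf(self, q):
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((q_arr < 0) | (q_arr >= 1)):
            raise DomainError("quantile levels must lie in [0, 1)")
        n_hi = float(self.burst_count.n_max)
        u_hi = float(special.gammaincinv(n_hi, 1.0 - 1e-13)) * 1.5 + 20.0
        u_grid = np.linspace(0.0, u_hi, 4097)
        v_grid = u_grid / self.rate_lambda
        c_grid = np.maximum.accumulate(np.atleast_1d(self.cdf(v_grid)))
        v = np.interp(q_arr, c_grid, v_grid)
        for _ in range(3):
            f = np.atleast_1d(self.pdf(v))
            resid = np.atleast_1d(self.cdf(v)) - q_arr
            v = np.clip(v - np.where(f > 0, resid / np.maximum(f, 1e-300), 0.0),
                        0.0, v_grid[-1])
        return v if np.ndim(q) else float(v[0])

    def moment(self, j: int) -> float:
        """Raw moment <dV^j> from the Gamma-mixture identity."""
        return self.burst_count.rising_moment(j) / self.rate_lambda**j

    @property
    def mean(self) -> float:
        return self.moment(1)


@dataclass(frozen=True)
class AddedVolumeMoments:
    mean: float
    variance: float
    cv2: float
    skewness: float
    warnings: tuple[str, ...] = ()


def deltaV_moments(dist: AddedVolumeDistribution) -> AddedVolumeMoments:
    """Mean, CV^2 and skewness of the added volume.

    Uses the compound-sum identities for a sum of N i.i.d. Exp(lambda)
    spacings independent of N: mean = <N>/lambda, variance =
    (<N> + Var N)/lambda^2, with the third central moment assembled from
    the raw Gamma-mixture moments.  CV^2 and skewness are scale-free and
    hence independent of the growth rate.
    """
    m1 = dist.moment(1)
    m2 = dist.moment(2)
    m3 = dist.moment(3)
    var = m2 - m1**2
    mu3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
    warnings: tuple[str, ...] = ()
    if dist.burst_count.tail_mass > 1e-8:
        warnings = (
            f"burst-count truncation tail {dist.burst_count.tail_mass:.3e} exceeds 1e-8",
        )
    return AddedVolumeMoments(
        mean=m1,
        variance=var,
        cv2=var / m1**2,
        skewness=mu3 / var**1.5,
        warnings=warnings,
    )


def scaled_moment(dist: AddedVolumeDistribution, j: int) -> float:
    """<dV^j> / <dV>^j, computed in a form from which the rate lambda
    cancels exactly, so the value is bitwise invariant under changes of
    alpha and k_m at fixed burst law and threshold."""
    if j not in (1, 2, 3, 4):
        raise DomainError("j must be in {1, 2, 3, 4}")
    if j == 1:
        return 1.0
    pmf = dist.burst_count
    return pmf.rising_moment(j) / pmf.moment(1) ** j


def initiation_mean_added_volume(params: InitiationModelParams) -> float:
    """Mean volume added between successive divisions in the
    replication-initiation variant: the per-origin mean added volume
    between initiations times exp(alpha * T), with T = C + D the fixed
    initiation-to-division delay.  An optional origin-number prefactor
    (default 1) is exposed on the parameter object."""
    base = params.base
    if base.alpha == 0:
        raise DomainError("initiation model requires alpha > 0")
    per_origin = AddedVolumeDistribution.from_params(base).mean
    return params.origin_prefactor * per_origin * float(np.exp(base.alpha * params.T_CD))
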