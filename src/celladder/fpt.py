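"""First-passage-time (division-time) distribution and moments.

Burst arrivals form an inhomogeneous Poisson process with rate
``r(t) = k_m V_b exp(alpha t)`` and cumulative rate
``R(t) = (k_m V_b / alpha)(exp(alpha t) - 1)``.  The time ``T_n`` of the
n-th arrival has density ``r(t) R(t)^{n-1} exp(-R(t)) / (n-1)!`` and the
division time is the mixture of the ``T_n`` over the burst-count pmf
``P(N = n)``:

    f_FPT(t) = sum_n P(N = n) r(t) R(t)^{n-1} exp(-R(t)) / (n-1)!

Equivalently, with ``U`` a sum of ``N`` independent unit-mean
exponentials (the time-changed picture), ``FPT = R^{-1}(U) =
(1/alpha) log(1 + alpha U / (k_m V_b))``.  Moments default to the
time-change route, which avoids quadrature of the long-tailed time
integrand; the direct quadrature route is retained as a cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .bursts import BurstCountPMF, burst_count_pmf
from .params import DomainError, ModelParams, NumericalError

__all__ = [
    "cumulative_rate",
    "inverse_cumulative_rate",
    "FPTDistribution",
    "FPTMoments",
    "fpt_moments",
]


def cumulative_rate(params: ModelParams, t):
    """Expected number of bursts in [0, t]: R(t) = (k_m V_b/alpha)(e^{alpha t}-1).

    For alpha = 0 (homogeneous limit) this is k_m V_b t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    if params.alpha == 0:
        out = params.k_m * params.V_b * t
    else:
        out = (params.k_m * params.V_b / params.alpha) * np.expm1(params.alpha * t)
    return out if out.ndim else float(out)


def inverse_cumulative_rate(params: ModelParams, u):
    """Inverse of the cumulative rate: the time by which u bursts are expected."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise DomainError("expected count must be non-negative")
    if params.alpha == 0:
        out = u / (params.k_m * params.V_b)
    else:
        out = np.log1p(params.alpha * u / (params.k_m * params.V_b)) / params.alpha
    return out if out.ndim else float(out)


def _mixture_log_weights(pmf: BurstCountPMF):
    n = pmf.n_values.astype(float)
    with np.errstate(divide="ignore"):
        logw = np.log(pmf.probs)
    return n, logw


def _log_mixture_gamma_pdf(u, n, logw):
    """log of sum_n w_n u^{n-1} e^{-u} / (n-1)!  evaluated at u >= 0."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    with np.errstate(divide="ignore"):
        logu = np.log(u)
    # (n-1) * log(u) with the n = 1 term forced to 0 so that u = 0 is finite
    with np.errstate(invalid="ignore"):
        a = (n[None, :] - 1.0) * logu[:, None]
    a[:, n == 1.0] = 0.0
    terms = logw[None, :] + a - u[:, None] - special.gammaln(n)[None, :]
    return special.logsumexp(terms, axis=1)


@dataclass
class FPTDistribution:
    """Analytic division-time distribution for fixed newborn size.

    The mixture series over the burst count is truncated adaptively so
    that the neglected mass is below ``tail_mass_bound`` (default 1e-10);
    a fixed ``n_max`` may be supplied instead.
    """

    params: ModelParams
    n_max: int | None = None
    tail_mass_bound: float = 1e-10
    burst_pmf: BurstCountPMF = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.burst_pmf = burst_count_pmf(
            self.params.X, self.params.burst, n_max=self.n_max,
            tail_mass_bound=self.tail_mass_bound,
        )

    # ------------------------------------------------------------------
    def pdf(self, t):
        """Probability density of the division time at t >= 0."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise DomainError("time must be non-negative")
        R = np.atleast_1d(cumulative_rate(self.params, t_arr))
        logr = np.log(self.params.k_m * self.params.V_b) + self.params.alpha * t_arr
        n, logw = _mixture_log_weights(self.burst_pmf)
        out = np.exp(logr + _log_mixture_gamma_pdf(R, n, logw))
        return out if np.ndim(t) else float(out[0])

    def cdf(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise DomainError("time must be non-negative")
        R = np.atleast_1d(cumulative_rate(self.params, t_arr))
        n = self.burst_pmf.n_values.astype(float)
        out = special.gammainc(n[None, :], R[:, None]) @ self.burst_pmf.probs
        return out if np.ndim(t) else float(out[0])

    # ------------------------------------------------------------------
    def _u_upper(self, eps: float = 1e-13) -> float:
        n_hi = float(self.burst_pmf.n_max)
        return float(special.gammaincinv(n_hi, 1.0 - eps)) * 1.5 + 20.0

    def support_upper(self) -> float:
        """Time beyond which the neglected probability mass is ~1e-13."""
        return float(inverse_cumulative_rate(self.params, self._u_upper()))

    def ppf(self, q):
        """Inverse CDF by monotone grid inversion plus Newton polishing."""
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((q_arr < 0) | (q_arr >= 1)):
            raise DomainError("quantile levels must lie in [0, 1)")
        u_grid = np.linspace(0.0, self._u_upper(), 4097)
        t_grid = np.atleast_1d(inverse_cumulative_rate(self.params, u_grid))
        c_grid = np.atleast_1d(self.cdf(t_grid))
        c_grid = np.maximum.accumulate(c_grid)
        t = np.interp(q_arr, c_grid, t_grid)
        for _ in range(3):  # Newton correction on the exact cdf
            f = np.atleast_1d(self.pdf(t))
            resid = np.atleast_1d(self.cdf(t)) - q_arr
            step = np.where(f > 0, resid / np.maximum(f, 1e-300), 0.0)
            t = np.clip(t - step, 0.0, t_grid[-1])
        return t if np.ndim(q) else float(t[0])

    def rvs_inverse_cdf(self, size: int, rng: np.random.Generator):
        """Draws by inverse-transform sampling of the analytic cdf."""
        return self.ppf(rng.uniform(size=size))


@dataclass(frozen=True)
class FPTMoments:
    raw: tuple[float, ...]
    mean: float
    variance: float
    cv2: float


def fpt_moments(
    dist: FPTDistribution, order: int = 2, method: str = "time_change"
) -> FPTMoments:
    """Raw moments, mean and CV^2 of the division time.

    ``method="time_change"`` (default) integrates ``g(u)^k`` against the
    Erlang-mixture density of the time-changed first-passage level ``U``,
    with ``g(u) = (1/alpha) log(1 + alpha u / (k_m V_b))``.
    ``method="quadrature"`` integrates ``t^k f_FPT(t)`` directly and is
    kept as an independent cross-check; the two agree to ~1e-6 relative.
    """
    if order not in (1, 2, 3):
        raise DomainError("order must be 1, 2 or 3")
    p = dist.params
    pmf = dist.burst_pmf
    n, logw = _mixture_log_weights(pmf)

    if p.alpha == 0:
        # FPT = U / (k_m V_b); E[U^k] = <N (N+1) ... (N+k-1)>
        scale = p.k_m * p.V_b
        raw = tuple(pmf.rising_moment(k) / scale**k for k in range(1, order + 1))
        return _assemble(raw)

    if method == "time_change":
        u_hi = dist._u_upper()

        def make_integrand(k):
            def f(u):
                g = np.log1p(p.alpha * u / (p.k_m * p.V_b)) / p.alpha
                return g**k * np.exp(_log_mixture_gamma_pdf(u, n, logw))
            return f

        raw = tuple(
            _quad(make_integrand(k), 0.0, u_hi, [pmf.mean]) for k in range(1, order + 1)
        )
    elif method == "quadrature":
        t_hi = dist.support_upper()
        t_mode = float(inverse_cumulative_rate(p, max(pmf.mean, 1.0)))
        raw = tuple(
            _quad(lambda t, k=k: t**k * dist.pdf(t), 0.0, t_hi, [t_mode])
            for k in range(1, order + 1)
        )
    else:
        raise DomainError(f"unknown method {method!r}")
    return _assemble(raw)


def _assemble(raw: tuple[float, ...]) -> FPTMoments:
    mean = raw[0]
    variance = raw[1] - mean**2 if len(raw) > 1 else float("nan")
    cv2 = variance / mean**2 if len(raw) > 1 else float("nan")
    return FPTMoments(raw=raw, mean=mean, variance=variance, cv2=cv2)


def _quad(func, a: float, b: float, points) -> float:
    def scalar(x):
        return float(np.atleast_1d(func(np.asarray([x], dtype=float)))[0])

    val, abserr = integrate.quad(scalar, a, b, limit=300, points=points)
    if not np.isfinite(val) or abserr > 1e-8 * max(abs(val), 1.0):
        raise NumericalError(
            f"moment quadrature failed to converge (value={val}, abserr={abserr})"
        )
    return val
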