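"""Distribution of the number of bursts N needed to reach the threshold.

N is the first-passage index of the burst-size random walk:
``N = min{n : B_1 + ... + B_n >= X}``.  Its pmf is computed through the
tail-difference identity ``P(N = n) = P(S_{n-1} < X) - P(S_n < X)`` with
the partial sums ``S_n`` propagated by convolution on the sub-threshold
states {0, ..., X-1} (mass at or above X is absorbed).  This route is
numerically stable for any burst law, including the infinite-support
geometric, because only the sub-threshold part of the law ever enters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BurstLaw, DomainError, NumericalError

__all__ = ["BurstCountPMF", "burst_count_pmf"]

HARD_CAP = 10_000


@dataclass(frozen=True)
class BurstCountPMF:
    """pmf of the burst count N on {1, ..., n_max} plus the neglected tail."""

    probs: np.ndarray  # probs[i] = P(N = i + 1)
    tail_mass: float

    @property
    def n_max(self) -> int:
        return len(self.probs)

    @property
    def n_values(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    def moment(self, j: int) -> float:
        """Raw moment <N^j>."""
        return float(np.sum(self.probs * self.n_values.astype(float) ** j))

    def rising_moment(self, j: int) -> float:
        """<N (N+1) ... (N+j-1)>, the factorial moments that appear in
        Gamma-mixture moments of the added volume."""
        n = self.n_values.astype(float)
        out = np.ones_like(n)
        for i in range(j):
            out *= n + i
        return float(np.sum(self.probs * out))

    @property
    def mean(self) -> float:
        return self.moment(1)

    @property
    def var(self) -> float:
        return self.moment(2) - self.mean**2

    @property
    def third_central(self) -> float:
        m1, m2, m3 = self.moment(1), self.moment(2), self.moment(3)
        return m3 - 3.0 * m1 * m2 + 2.0 * m1**3

    def sample(self, rng: np.random.Generator, size=None):
        p = self.probs / self.probs.sum()
        return rng.choice(self.n_values, size=size, p=p)


def burst_count_pmf(
    X: int,
    burst: BurstLaw,
    n_max: int | None = None,
    tail_mass_bound: float = 1e-10,
) -> BurstCountPMF:
    """pmf of the minimum number of bursts N for the protein to reach X.

    Parameters
    ----------
    X
        Division threshold (integer >= 1).
    burst
        Burst-size law.
    n_max
        Fixed truncation order; when None (default) the series is extended
        adaptively until the neglected mass falls below ``tail_mass_bound``.
    tail_mass_bound
        Adaptive stopping criterion on the neglected probability mass.

    Raises
    ------
    DomainError
        If X is not a positive integer, or the burst law puts all its mass
        at zero (the threshold would never be reached).
    NumericalError
        If the adaptive series does not converge within 10,000 terms.
    """
    if X != int(X) or X < 1:
        raise DomainError("threshold X must be an integer >= 1")
    X = int(X)
    if burst.mass_at_zero >= 1.0 - 1e-15:
        raise DomainError("burst law has all mass at 0: threshold never reached")

    q = burst.pmf_vector(X - 1)  # P(B = k), k = 0..X-1; mass >= X implicit
    interior = np.zeros(X)
    interior[0] = 1.0  # S_0 = 0 with probability 1
    probs: list[float] = []
    prev_mass = 1.0
    limit = n_max if n_max is not None else HARD_CAP
    n = 0
    while n < limit:
        n += 1
        interior = np.convolve(interior, q)[:X]
        mass = float(interior.sum())
        probs.append(max(prev_mass - mass, 0.0))
        prev_mass = mass
        if n_max is None and mass <= tail_mass_bound:
            break
    else:
        if n_max is None:
            raise NumericalError(
                f"burst-count pmf did not reach tail mass {tail_mass_bound:g} "
                f"within {HARD_CAP} terms"
            )
    return BurstCountPMF(probs=np.asarray(probs), tail_mass=prev_mass)
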