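"""Statistical diagnostics for single-cell cycle tables.

These mirror the standard protocols for size-homeostasis data: binning
by newborn size, CV^2 with percentile-bootstrap confidence intervals,
two-sample Kolmogorov-Smirnov comparisons of (mean-rescaled) added-volume
samples, and a permutation test for the sign of the newborn-size /
added-volume association.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import ConfigError, DomainError

__all__ = [
    "BinnedStat",
    "bin_by_newborn_size",
    "Cv2Result",
    "cv2_bootstrap",
    "CollapseResult",
    "collapse_distance",
    "TrendResult",
    "adder_trend_test",
]

_QUANTITIES = ("fpt", "delta_V", "V_d")


@dataclass
class BinnedStat:
    """Per-bin summary of one quantity against newborn size.

    Bins are half-open [lo, hi) except the last, which is closed; records
    outside every bin are counted in ``out_of_range``, never silently
    dropped.  Bins with fewer than ``min_count`` records are flagged and
    should be excluded from trend tests.
    """

    bin_edges: np.ndarray
    quantity: str
    n_per_bin: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    cv2: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    out_of_range: int
    flagged: np.ndarray
    ci_statistic: str = "cv2"

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "n": self.n_per_bin,
                "mean": self.mean,
                "variance": self.variance,
                "cv2": self.cv2,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "flagged": self.flagged,
            }
        )


def bin_by_newborn_size(
    records: pd.DataFrame,
    edges,
    quantity: str = "delta_V",
    size_column: str = "V_b",
    min_count: int = 1,
    n_boot: int = 0,
    ci_statistic: str = "cv2",
    rng=None,
) -> BinnedStat:
    """Bin records by newborn size and summarize ``quantity`` per bin.

    ``n_boot > 0`` adds percentile-bootstrap 95% confidence intervals for
    the chosen ``ci_statistic`` ("cv2" or "mean"); otherwise the CI
    columns are NaN.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise DomainError("bin edges must be strictly increasing, length >= 2")
    if quantity not in _QUANTITIES:
        raise DomainError(f"quantity must be one of {_QUANTITIES}")
    if ci_statistic not in ("cv2", "mean"):
        raise DomainError("ci_statistic must be 'cv2' or 'mean'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    nb = len(edges) - 1
    n_per_bin = np.zeros(nb, dtype=np.int64)
    mean = np.full(nb, np.nan)
    variance = np.full(nb, np.nan)
    cv2 = np.full(nb, np.nan)
    ci_low = np.full(nb, np.nan)
    ci_high = np.full(nb, np.nan)

    if len(records):
        sizes = records[size_column].to_numpy(dtype=float)
        vals = records[quantity].to_numpy(dtype=float)
        # half-open bins, except the last edge which is included
        idx = np.digitize(sizes, edges, right=False) - 1
        idx[sizes == edges[-1]] = nb - 1
        in_range = (idx >= 0) & (idx < nb)
        out_of_range = int(np.sum(~in_range))
        for i in range(nb):
            v = vals[in_range & (idx == i)]
            n_per_bin[i] = len(v)
            if len(v):
                mean[i] = v.mean()
                variance[i] = v.var(ddof=1) if len(v) > 1 else 0.0
                cv2[i] = variance[i] / mean[i] ** 2 if mean[i] != 0 else np.nan
                if n_boot > 0 and len(v) > 1:
                    res = _bootstrap_stat(v, n_boot, ci_statistic, rng)
                    ci_low[i], ci_high[i] = res
    else:
        out_of_range = 0

    flagged = n_per_bin < min_count
    return BinnedStat(
        bin_edges=edges,
        quantity=quantity,
        n_per_bin=n_per_bin,
        mean=mean,
        variance=variance,
        cv2=cv2,
        ci_low=ci_low,
        ci_high=ci_high,
        out_of_range=out_of_range,
        flagged=flagged,
        ci_statistic=ci_statistic,
    )


def _bootstrap_stat(values, n_boot, statistic, rng):
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    draws = values[idx]
    means = draws.mean(axis=1)
    if statistic == "mean":
        boot = means
    else:
        var = draws.var(axis=1, ddof=1)
        boot = np.divide(var, means**2, out=np.zeros_like(var), where=means != 0)
    return tuple(np.percentile(boot, [2.5, 97.5]))


@dataclass(frozen=True)
class Cv2Result:
    cv2: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int


def cv2_bootstrap(values, n_boot: int = 1000, rng=None) -> Cv2Result:
    """CV^2 = var/mean^2 with a percentile-bootstrap 95% CI."""
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise DomainError("cv2_bootstrap needs at least 10 values")
    if n_boot < 200:
        raise DomainError("n_boot must be >= 200")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mean = values.mean()
    var = values.var(ddof=1)
    cv2 = var / mean**2
    lo, hi = _bootstrap_stat(values, n_boot, "cv2", rng)
    return Cv2Result(cv2=float(cv2), ci_low=float(lo), ci_high=float(hi),
                     n=len(values), n_boot=n_boot)


@dataclass
class CollapseResult:
    """Pairwise two-sample KS comparison of (optionally mean-rescaled)
    samples; ``collapsed`` is True when no pair rejects at the given
    significance level."""

    distance: np.ndarray
    pvalue: np.ndarray
    max_distance: float
    collapsed: bool
    rescaled: bool
    level: float = 0.01


def collapse_distance(samples, rescale: bool = True, level: float = 0.01) -> CollapseResult:
    """Distribution-collapse diagnostic across growth conditions.

    With ``rescale`` on, each sample is divided by its own mean before
    the pairwise KS tests — the scale-invariance prediction is that the
    rescaled distributions coincide.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise DomainError("need at least 2 samples")
    for s in samples:
        if len(s) < 100:
            raise DomainError("each sample must have >= 100 values")
    if rescale:
        samples = [s / s.mean() for s in samples]
    m = len(samples)
    D = np.zeros((m, m))
    P = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            res = stats.ks_2samp(samples[i], samples[j], method="asymp")
            D[i, j] = D[j, i] = res.statistic
            P[i, j] = P[j, i] = res.pvalue
    off = ~np.eye(m, dtype=bool)
    collapsed = bool(np.all(P[off] > level))
    return CollapseResult(
        distance=D, pvalue=P, max_distance=float(D.max()),
        collapsed=collapsed, rescaled=rescale, level=level,
    )


@dataclass(frozen=True)
class TrendResult:
    """Spearman correlation of (V_b, delta_V) with a permutation null.

    ``verdict`` is "adder" when the estimate lies inside the central 99%
    permutation band, otherwise the sign of the estimate.  ``bin_slope``
    is the OLS slope through the 13-bin means, reported for figure parity.
    """

    spearman: float
    band_low: float
    band_high: float
    verdict: str
    n_perm: int
    bin_slope: float


def adder_trend_test(
    records_or_vb,
    delta_v=None,
    n_perm: int = 999,
    rng=None,
    level: float = 0.01,
    n_bins: int = 13,
) -> TrendResult:
    """Classify the newborn-size / added-volume association.

    Accepts either a cycle DataFrame (with V_b and delta_V columns) or
    two arrays.  Requires at least 1,000 pairs and ``n_perm >= 999``.
    """
    if delta_v is None:
        vb = records_or_vb["V_b"].to_numpy(dtype=float)
        dv = records_or_vb["delta_V"].to_numpy(dtype=float)
    else:
        vb = np.asarray(records_or_vb, dtype=float)
        dv = np.asarray(delta_v, dtype=float)
    if len(vb) != len(dv):
        raise ConfigError("V_b and delta_V must have equal length")
    if len(vb) < 1000:
        raise DomainError("trend test needs at least 1,000 pairs")
    if n_perm < 999:
        raise DomainError("n_perm must be >= 999")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    r_vb = stats.rankdata(vb)
    r_dv = stats.rankdata(dv)
    n = len(vb)
    r_vb = (r_vb - r_vb.mean()) / r_vb.std()
    r_dv = (r_dv - r_dv.mean()) / r_dv.std()
    rho = float(np.dot(r_vb, r_dv) / n)

    null = np.empty(n_perm)
    shuffled = r_dv.copy()
    for k in range(n_perm):
        rng.shuffle(shuffled)
        null[k] = np.dot(r_vb, shuffled) / n
    lo, hi = np.percentile(null, [100 * level / 2, 100 * (1 - level / 2)])

    if lo <= rho <= hi:
        verdict = "adder"
    else:
        verdict = "positive" if rho > 0 else "negative"

    # bin-mean slope, for parity with binned-scatter figures
    edges = np.linspace(vb.min(), vb.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(vb, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for i in range(n_bins):
        sel = idx == i
        if sel.sum() > 0:
            centers.append(0.5 * (edges[i] + edges[i + 1]))
            means.append(dv[sel].mean())
    slope = float(np.polyfit(centers, means, 1)[0]) if len(centers) > 1 else float("nan")

    return TrendResult(
        spearman=rho, band_low=float(lo), band_high=float(hi),
        verdict=verdict, n_perm=n_perm, bin_slope=slope,
    )
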