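"""Binning, bootstrap CV^2, distribution collapse and trend verdicts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from celladder import (
    AddedVolumeDistribution,
    DomainError,
    adder_trend_test,
    bin_by_newborn_size,
    collapse_distance,
    cv2_bootstrap,
    deltaV_moments,
    sample_cycles,
)

# the four experimental newborn-size bins used for division-time noise
SIZE_BINS = [1.0, 2.8, 4.5, 6.3, 8.0]


def frame(vb, dv):
    vb = np.asarray(vb, dtype=float)
    dv = np.asarray(dv, dtype=float)
    return pd.DataFrame({"V_b": vb, "delta_V": dv, "fpt": dv, "V_d": vb + dv})


class TestBinning:
    def test_one_record_per_experimental_bin(self):
        df = frame([1.5, 3.0, 5.0, 7.0], [1.0, 1.0, 1.0, 1.0])
        b = bin_by_newborn_size(df, SIZE_BINS)
        assert b.n_per_bin.tolist() == [1, 1, 1, 1]
        assert b.out_of_range == 0

    def test_half_open_bins_last_closed(self):
        df = frame([1.0, 2.8, 8.0, 9.0, 0.5], np.ones(5))
        b = bin_by_newborn_size(df, SIZE_BINS)
        assert b.n_per_bin.tolist() == [1, 1, 0, 1]  # 2.8 opens the 2nd bin; 8.0 closes the last
        assert b.out_of_range == 2

    def test_empty_table(self):
        b = bin_by_newborn_size(frame([], []), SIZE_BINS, min_count=10)
        assert b.n_per_bin.tolist() == [0, 0, 0, 0]
        assert b.flagged.all()
        assert b.out_of_range == 0

    def test_binned_means_match_analytic_added_volume(self, canonical_params, rng):
        from dataclasses import replace

        p = replace(canonical_params, V_b=2.0)
        vb = rng.uniform(2.0, 3.5, size=10_000)
        df = sample_cycles(p, 10_000, rng=rng, V_b=vb)
        edges = np.linspace(2.0, 3.5, 14)  # 13 uniform bins, >100 cells each
        b = bin_by_newborn_size(df, edges, quantity="delta_V", min_count=100)
        assert not b.flagged.any()
        target = deltaV_moments(AddedVolumeDistribution.from_params(p)).mean
        se = np.sqrt(b.variance / b.n_per_bin)
        assert np.all(np.abs(b.mean - target) < 3 * se)

    @given(st.integers(0, 500), st.integers(2, 8))
    def test_record_count_conserved(self, seed, nbins):
        r = np.random.default_rng(seed)
        n = int(r.integers(0, 200))
        sizes = r.uniform(0, 10, n)
        edges = np.sort(r.uniform(0, 10, nbins + 1))
        edges += np.arange(nbins + 1) * 1e-9  # ensure strictly increasing
        b = bin_by_newborn_size(frame(sizes, np.ones(n)), edges)
        assert b.n_per_bin.sum() + b.out_of_range == n

    def test_bad_edges_rejected(self):
        with pytest.raises(DomainError):
            bin_by_newborn_size(frame([1], [1]), [3, 2, 1])


class TestCv2Bootstrap:
    def test_constant_sample_has_zero_noise(self):
        res = cv2_bootstrap([5.0] * 12, n_boot=300, rng=0)
        assert res.cv2 == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_exponential_sample_covers_unit_cv2(self, rng):
        vals = rng.exponential(size=10_000)
        res = cv2_bootstrap(vals, n_boot=1000, rng=rng)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_noise_increases_across_size_bins(self, canonical_params, rng):
        # division-time noise rises with newborn size across the four bins
        from dataclasses import replace

        cv2s = []
        for vb in (1.9, 3.65, 5.4, 7.15):  # experimental bin midpoints
            p = replace(canonical_params, V_b=vb)
            df = sample_cycles(p, 5000, rng=rng)
            cv2s.append(cv2_bootstrap(df["fpt"].to_numpy(), n_boot=300, rng=rng).cv2)
        assert cv2s == sorted(cv2s)

    def test_coverage_of_bootstrap_interval(self):
        # 500 replications on Exp(1) samples: 95% percentile CI for CV^2
        # must cover the true value 1 in at least 92% of cases
        rng = np.random.default_rng(1234)
        hits = 0
        for _ in range(500):
            vals = rng.exponential(size=500)
            res = cv2_bootstrap(vals, n_boot=500, rng=rng)
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits / 500 >= 0.92

    def test_preconditions(self):
        with pytest.raises(DomainError):
            cv2_bootstrap([1.0] * 5)
        with pytest.raises(DomainError):
            cv2_bootstrap([1.0] * 20, n_boot=50)


class TestCollapse:
    def test_identical_samples_have_zero_distance(self, rng):
        s = rng.exponential(size=500)
        res = collapse_distance([s, s.copy()], rescale=False)
        assert res.max_distance == 0.0
        assert res.collapsed

    def test_rescaled_growth_conditions_collapse(self, canonical_params, rng):
        from dataclasses import replace

        samples = []
        for a in (0.01, 0.03, 0.06):
            p = replace(canonical_params, alpha=a)
            samples.append(sample_cycles(p, 5000, rng=rng)["delta_V"].to_numpy())
        assert collapse_distance(samples, rescale=True).collapsed
        assert not collapse_distance(samples, rescale=False).collapsed

    def test_minimum_sizes_enforced(self, rng):
        with pytest.raises(DomainError):
            collapse_distance([rng.normal(size=50), rng.normal(size=200)])
        with pytest.raises(DomainError):
            collapse_distance([rng.normal(size=200)])


class TestTrendVerdicts:
    def test_shuffled_pairs_read_as_adder(self, rng):
        vb = rng.uniform(1, 7, 5000)
        dv = rng.exponential(size=5000)  # independent by construction
        res = adder_trend_test(vb, dv, rng=rng)
        assert res.verdict == "adder"

    def test_monotone_association_detected(self, rng):
        vb = rng.uniform(1, 7, 5000)
        up = adder_trend_test(vb, vb + rng.normal(0, 2, 5000), rng=rng)
        down = adder_trend_test(vb, -vb + rng.normal(0, 2, 5000), rng=rng)
        assert up.verdict == "positive"
        assert down.verdict == "negative"

    def test_accepts_cycle_frame(self, canonical_params, rng):
        vb = rng.uniform(1, 7, 2000)
        df = sample_cycles(canonical_params, 2000, rng=rng, V_b=vb)
        res = adder_trend_test(df, rng=rng)
        assert res.verdict == "adder"
        assert np.isfinite(res.bin_slope)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(DomainError):
            adder_trend_test(np.ones(100), np.ones(100), rng=rng)
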