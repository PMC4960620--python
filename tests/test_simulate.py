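"""Exactness, determinism and mechanism behavior of the simulator."""
import numpy as np
import pytest
from scipy import stats

from celladder import (
    BurstLaw,
    DomainError,
    InitiationModelParams,
    LineageConfig,
    MechanismSpec,
    ModelParams,
    sample_cycle,
    sample_cycles,
    sample_initiation_model,
    sample_lineage,
)
from celladder.simulate import _sample_saturating_thinning


def make_params(k_m=0.13, alpha=0.03, X=65, V_b=2.0, burst=None):
    return ModelParams(k_m=k_m, alpha=alpha, burst=burst or BurstLaw.geometric(5.0),
                       X=X, V_b=V_b)


class TestSingleCycle:
    def test_single_burst_threshold_gives_exponential_added_volume(self, rng):
        p = make_params(X=1, burst=BurstLaw.deterministic(1))
        df = sample_cycles(p, 50_000, rng=rng)
        v = df["delta_V"].to_numpy()
        target = p.alpha / p.k_m  # mean of Exp(rate k_m/alpha)
        assert abs(v.mean() - target) < 3 * v.std(ddof=1) / np.sqrt(len(v))
        assert np.all(df["n_bursts"] == 1)

    def test_carryover_one_below_threshold_needs_single_burst(self, rng):
        p = make_params(X=65)
        for _ in range(50):
            rec = sample_cycle(p, carryover=64, rng=rng)
            assert rec.n_bursts == 1
            assert rec.final_count >= 65

    def test_growth_conservation_every_mechanism(self, rng):
        mechs = [
            MechanismSpec.baseline(),
            MechanismSpec.partial_degradation(0.5),
            MechanismSpec.volume_dependent_burst(1.0),
            MechanismSpec.saturating_rate(5.0),
            MechanismSpec.soft_threshold(4.0),
        ]
        p = make_params()
        for mech in mechs:
            for _ in range(20):
                rec = sample_cycle(p, mech, rng=rng)
                assert rec.V_d == pytest.approx(rec.V_b + rec.delta_V, rel=1e-12)
                assert rec.V_d == pytest.approx(
                    rec.V_b * np.exp(rec.alpha * rec.fpt), rel=1e-12
                )
                if mech.kind != "soft_threshold":
                    assert rec.final_count >= p.X

    def test_smaller_newborn_takes_longer_on_average(self, rng):
        # threshold of 50 molecules, three newborn sizes: mean division
        # time ordered opposite to size
        means = []
        for vb in (1.0, 2.0, 4.0):
            p = make_params(X=50, V_b=vb)
            df = sample_cycles(p, 20_000, rng=rng)
            means.append(df["fpt"].mean())
        assert means[0] > means[1] > means[2]

    def test_carryover_at_threshold_rejected(self, rng):
        p = make_params(X=10)
        with pytest.raises(DomainError):
            sample_cycle(p, carryover=10, rng=rng)

    def test_mechanism_requires_matching_parameters(self):
        from celladder import ConfigError

        with pytest.raises(ConfigError):
            MechanismSpec(kind="saturating_rate")  # missing V_sat
        with pytest.raises(ConfigError):
            MechanismSpec(kind="baseline", V_sat=3.0)  # inconsistent extra


class TestExactness:
    def test_added_volume_is_gamma_for_fixed_burst_count(self, rng):
        # deterministic bursts of 1 with X=13 force N=13 exactly;
        # delta_V must then follow Gamma(13, rate k_m/alpha)
        p = make_params(X=13, burst=BurstLaw.deterministic(1))
        df = sample_cycles(p, 10_000, rng=rng)
        res = stats.kstest(df["delta_V"], "gamma", args=(13, 0, 1 / p.rate_lambda))
        assert res.pvalue > 0.01

    def test_thinning_matches_direct_inversion_for_saturating_rate(self, rng):
        p = make_params()
        mech = MechanismSpec.saturating_rate(5.0)
        direct = np.array([sample_cycle(p, mech, rng=rng).delta_V for _ in range(5000)])
        thinned = np.array(
            [_sample_saturating_thinning(p, mech, rng).delta_V for _ in range(5000)]
        )
        assert stats.ks_2samp(direct, thinned).pvalue > 0.01

    def test_steep_soft_threshold_reproduces_sharp_rule(self, rng):
        p = make_params()
        base = sample_cycles(p, 10_000, rng=rng)["delta_V"].to_numpy()
        mech = MechanismSpec.soft_threshold(H=1e6, c=1.0)
        soft = np.array([sample_cycle(p, mech, rng=rng).delta_V for _ in range(10_000)])
        assert abs(soft.mean() - base.mean()) / base.mean() < 0.02
        cv2 = lambda x: x.var(ddof=1) / x.mean() ** 2  # noqa: E731
        assert abs(cv2(soft) - cv2(base)) / cv2(base) < 0.05


class TestLineage:
    def test_bitwise_determinism(self, canonical_params):
        cfg = LineageConfig(params=canonical_params, n_generations=5, n_lineages=20, seed=42)
        a = sample_lineage(cfg)
        b = sample_lineage(cfg)
        assert a.equals(b)

    def test_single_generation_matches_sample_cycle(self, canonical_params):
        cfg = LineageConfig(params=canonical_params, n_generations=1, n_lineages=1, seed=7)
        df = sample_lineage(cfg)
        child = np.random.SeedSequence(7).spawn(1)[0]
        rec = sample_cycle(canonical_params, rng=np.random.Generator(np.random.PCG64(child)))
        assert df.loc[0, "delta_V"] == rec.delta_V
        assert df.loc[0, "fpt"] == rec.fpt

    def test_stationary_newborn_size_equals_mean_added_volume(self, canonical_params):
        # adder fixed point: with symmetric halving, <V_b> -> <dV>
        from celladder import AddedVolumeDistribution

        cfg = LineageConfig(params=canonical_params, n_generations=40, n_lineages=300, seed=3)
        df = sample_lineage(cfg)
        tail = df[df["generation"] >= 15]
        target = AddedVolumeDistribution.from_params(canonical_params).mean
        assert tail["V_b"].mean() == pytest.approx(target, rel=0.03)

    def test_partial_degradation_inherits_protein(self, canonical_params):
        cfg = LineageConfig(
            params=canonical_params,
            mechanism=MechanismSpec.partial_degradation(0.5),
            n_generations=4,
            n_lineages=50,
            seed=11,
        )
        df = sample_lineage(cfg)
        later = df[df["generation"] > 0]
        assert (later["carryover_in"] > 0).mean() > 0.9
        assert np.all(later["carryover_in"] < canonical_params.X)


class TestInitiationModel:
    def test_zero_delay_reduces_to_baseline_added_volume(self, canonical_params, rng):
        ip = InitiationModelParams(base=canonical_params, T_CD=0.0)
        res = sample_initiation_model(ip, n_cycles=4000, rng=rng)
        base = sample_cycles(canonical_params, 4000, rng=rng)["delta_V"].to_numpy()
        assert stats.ks_2samp(res.cycles["delta_V"], base).pvalue > 0.01
        assert np.all(res.cycles["theta_at_division"] == 2)

    def test_origin_bookkeeping_consistent(self, canonical_params, rng):
        ip = InitiationModelParams(base=canonical_params, T_CD=40.0)
        res = sample_initiation_model(ip, n_cycles=500, rng=rng)
        c = res.cycles
        assert np.all(c["delta_V"] > 0)
        assert np.all(c["fpt"] > 0)
        assert len(res.per_origin_delta) > 0
        assert np.all(res.per_origin_delta > 0)

    def test_runaway_queue_raises(self, canonical_params, rng):
        from celladder import NumericalError

        ip = InitiationModelParams(base=canonical_params, T_CD=5000.0)
        with pytest.raises(NumericalError):
            sample_initiation_model(ip, n_cycles=200, rng=rng, max_pending=8)
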