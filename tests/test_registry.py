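"""Synthetic registry: PPC sampling calibration and the ramping policy."""

import numpy as np
import pytest
from scipy import stats

from swlplan import (
    ALLOWED_RATES,
    PolicyParams,
    PPCVector,
    ValidationError,
    generate_registry,
    sample_ppc,
    simulate_case,
)
from swlplan.registry import ppc_distribution_means


def make_ppc(**kw):
    base = dict(gender=0, age=50.0, stone_location="renal_pelvis",
                stone_size=8.0, mean_arterial_pressure=95.0,
                anticoagulant_use=0, sedation_use=0, multiple_stones=0,
                strapping=0)
    base.update(kw)
    return PPCVector(**base)


#: A policy whose deterministic output is exactly the canonical worked
#: example for any patient: ramp 100-shock steps from 1 to the fixed maximum
#: 8, then hold at 8 until the 3000-shock budget is spent.
TABLE1_POLICY = PolicyParams(
    start_power=1, ramp_block=100, ramp_block_map_coeff=0.0,
    max_power_base=8, max_power_size_coeff=0.0, max_power_map_coeff=0.0,
    rate_rule="constant:120", stop_hazard_base=0.0, stop_hazard_size_coeff=0.0,
    boost_after_holds=None, hold_block=1000, alternate_hold_rates=False,
)


class TestPPCSampling:
    def test_sample_means_match_distribution_means(self):
        rng = np.random.default_rng(123)
        ppcs = sample_ppc(rng, 10_000)
        exact = ppc_distribution_means()
        observed = {
            "gender": np.mean([p.gender for p in ppcs]),
            "age": np.mean([p.age for p in ppcs]),
            "stone_size": np.mean([p.stone_size for p in ppcs]),
            "mean_arterial_pressure":
                np.mean([p.mean_arterial_pressure for p in ppcs]),
            "anticoagulant_use": np.mean([p.anticoagulant_use for p in ppcs]),
            "sedation_use": np.mean([p.sedation_use for p in ppcs]),
            "multiple_stones": np.mean([p.multiple_stones for p in ppcs]),
            "strapping": np.mean([p.strapping for p in ppcs]),
        }
        for key, mu in exact.items():
            # 4 standard errors of a generous scale bound for each field
            scale = {"age": 14.0, "stone_size": 3.0,
                     "mean_arterial_pressure": 10.0}.get(key, 0.5)
            assert abs(observed[key] - mu) < 4 * scale / np.sqrt(10_000), key

    def test_samples_respect_bounds(self):
        rng = np.random.default_rng(5)
        for p in sample_ppc(rng, 2000):
            assert 18.0 <= p.age <= 90.0
            assert 60.0 <= p.mean_arterial_pressure <= 140.0
            assert p.stone_size > 0

    def test_all_locations_appear(self):
        rng = np.random.default_rng(7)
        locs = {p.stone_location for p in sample_ppc(rng, 500)}
        assert len(locs) == 4

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValidationError):
            sample_ppc(np.random.default_rng(0), 0)


class TestPolicyParams:
    def test_rate_rule_ppc_default(self):
        p = PolicyParams()
        assert p.rate_for(make_ppc(anticoagulant_use=1)) == 60
        assert p.rate_for(make_ppc(age=70.0)) == 90
        assert p.rate_for(make_ppc(age=30.0, stone_size=5.0)) == 180
        assert p.rate_for(make_ppc()) == 120
        # anticoagulation dominates the other criteria
        assert p.rate_for(make_ppc(age=30.0, stone_size=5.0,
                                   anticoagulant_use=1)) == 60

    def test_rate_rule_constant(self):
        p = PolicyParams(rate_rule="constant:90")
        assert p.rate_for(make_ppc(anticoagulant_use=1)) == 90
        with pytest.raises(ValidationError):
            PolicyParams(rate_rule="constant:75").rate_for(make_ppc())
        with pytest.raises(ValidationError):
            PolicyParams(rate_rule="nonsense").rate_for(make_ppc())

    def test_max_power_clamped_to_valid_levels(self):
        p = PolicyParams()
        assert p.max_power_for(make_ppc(stone_size=30.0,
                                        mean_arterial_pressure=140.0)) == 9
        assert p.max_power_for(make_ppc(stone_size=0.5,
                                        mean_arterial_pressure=60.0)) >= p.start_power
        assert p.max_power_for(make_ppc()) == 7

    def test_ramp_block_rounded_and_clamped(self):
        p = PolicyParams()
        assert p.ramp_block_for(make_ppc()) == 200
        assert p.ramp_block_for(make_ppc(mean_arterial_pressure=140.0)) == 350
        assert p.ramp_block_for(make_ppc(mean_arterial_pressure=60.0)) == 100
        assert p.ramp_block_for(make_ppc(mean_arterial_pressure=101.0)) == 220

    def test_stop_probability_clamped(self):
        p = PolicyParams()
        assert p.stop_probability(make_ppc(stone_size=100.0)) == 0.0
        assert 0.0 < p.stop_probability(make_ppc()) < 1.0

    def test_roundtrip_dict(self):
        p = PolicyParams(ramp_block=150, noise_level=0.1)
        assert PolicyParams.from_dict(p.to_dict()) == p

    @pytest.mark.parametrize("kw", [
        {"start_power": 0}, {"ramp_block": 0}, {"noise_level": 1.5},
        {"shock_limit": 0},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValidationError):
            PolicyParams(**kw)


class TestSimulateCase:
    def test_table1_policy_reproduces_worked_example(self, table1_plan):
        rng = np.random.default_rng(0)
        plan = simulate_case(make_ppc(), TABLE1_POLICY, rng, case_id="table1")
        assert plan.steps == table1_plan.steps

    def test_deterministic_when_stopping_is_off(self):
        ppc = make_ppc(stone_size=9.0)
        policy = PolicyParams(stop_hazard_base=0.0, stop_hazard_size_coeff=0.0)
        a = simulate_case(ppc, policy, np.random.default_rng(1))
        b = simulate_case(ppc, policy, np.random.default_rng(999))
        assert a.steps == b.steps

    def test_certain_stopping_ends_at_first_max_power_step(self):
        ppc = make_ppc()
        policy = PolicyParams(stop_hazard_base=1.0, stop_hazard_size_coeff=0.0)
        plan = simulate_case(ppc, policy, np.random.default_rng(3))
        max_p = policy.max_power_for(ppc)
        assert plan.steps[-1].power_level == max_p
        assert sum(1 for s in plan.steps if s.power_level == max_p) == 1

    def test_power_monotone_without_noise(self):
        rng = np.random.default_rng(11)
        for ppc in sample_ppc(rng, 50):
            plan = simulate_case(ppc, PolicyParams(), rng)
            powers = [s.power_level for s in plan.steps]
            assert powers == sorted(powers)
            assert plan.steps[0].power_level == 1

    def test_budget_never_exceeded(self):
        rng = np.random.default_rng(13)
        for ppc in sample_ppc(rng, 100):
            plan = simulate_case(ppc, PolicyParams(), rng)
            assert plan.total_shocks <= 3000
            assert all(s.num_shocks <= 1000 for s in plan.steps)

    def test_noise_still_respects_invariants(self):
        rng = np.random.default_rng(17)
        policy = PolicyParams(noise_level=0.3)
        for ppc in sample_ppc(rng, 50):
            plan = simulate_case(ppc, policy, rng)
            assert plan.total_shocks <= 3000
            assert all(s.shock_rate in ALLOWED_RATES for s in plan.steps)
            assert all(1 <= s.power_level <= 9 for s in plan.steps)


class TestGenerateRegistry:
    def test_same_seed_reproduces_registry(self):
        a = generate_registry(30, seed=42)
        b = generate_registry(30, seed=42)
        for (ppc_a, plan_a), (ppc_b, plan_b) in zip(a.cases, b.cases):
            assert ppc_a == ppc_b
            assert plan_a.steps == plan_b.steps

    def test_different_seeds_differ(self):
        a = generate_registry(30, seed=1)
        b = generate_registry(30, seed=2)
        assert any(pa.steps != pb.steps
                   for (_, pa), (_, pb) in zip(a.cases, b.cases))

    def test_case_ids_unique_and_zero_padded(self):
        reg = generate_registry(12, seed=0)
        ids = [plan.case_id for _, plan in reg.cases]
        assert len(set(ids)) == 12
        assert ids[0] == "case00" and ids[11] == "case11"

    def test_all_four_rates_occur_under_defaults(self):
        reg = generate_registry(300, seed=3)
        rates = {s.shock_rate for _, plan in reg.cases for s in plan.steps}
        assert rates == set(ALLOWED_RATES)

    def test_larger_stones_get_longer_plans(self):
        reg = generate_registry(500, seed=8)
        sizes = [ppc.stone_size for ppc, _ in reg.cases]
        lengths = [plan.n_steps for _, plan in reg.cases]
        rho, _ = stats.spearmanr(sizes, lengths)
        assert rho > 0.2

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValidationError):
            generate_registry(0)
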