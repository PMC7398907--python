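"""Dynamic simulation against the hand recurrence and conservation laws."""

import math

import pytest

from atzgem import (
    DynamicConfig,
    compute_uptake_bounds,
    degradation_curve,
    simulate_timecourse,
)
from conftest import make_dynamic_config, mineral_pools


def hand_recurrence_toy1(glc0, nh40, x0=1.0, cap=1.0, dt=1.0, max_cycles=200):
    """Independent reimplementation of the tick loop for TOY-1.

    Uses the closed-form optimum mu = min(b_glc, 2 b_nh4) instead of an LP,
    with b = min(cap, pool/(X dt)).
    """
    glc, nh4, X = glc0, nh40, x0
    series = [(0.0, X, glc)]
    for cycle in range(1, max_cycles + 1):
        b_glc = min(cap, glc / (X * dt))
        b_nh4 = min(cap, nh4 / (X * dt))
        mu = min(b_glc, 2 * b_nh4)
        glc -= mu * X * dt
        nh4 -= 0.5 * mu * X * dt
        X *= 1 + mu * dt
        series.append((cycle * dt, X, glc))
        if mu == 0:
            break
    return series


class TestUptakeBounds:
    def test_cap_binds_when_pool_is_ample(self):
        cfg = DynamicConfig()
        media = compute_uptake_bounds({"EX_glc": 50.0}, 1.0, cfg)
        assert media.uptakes["EX_glc"] == 1.0

    def test_pool_division_binds_when_scarce(self):
        cfg = DynamicConfig()
        media = compute_uptake_bounds({"EX_glc": 0.5}, 1.0, cfg)
        assert media.uptakes["EX_glc"] == 0.5

    def test_exhausted_pool_closes_uptake(self):
        media = compute_uptake_bounds({"EX_glc": 0.0}, 4.0, DynamicConfig())
        assert media.uptakes["EX_glc"] == 0.0

    def test_per_exchange_cap_override(self):
        cfg = DynamicConfig(uptake_caps={"EX_h2o": 100.0})
        media = compute_uptake_bounds({"EX_h2o": math.inf, "EX_glc": math.inf},
                                      1.0, cfg)
        assert media.uptakes == {"EX_h2o": 100.0, "EX_glc": 1.0}

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError):
            compute_uptake_bounds({"EX_glc": 1.0}, 0.0, DynamicConfig())


class TestSimulateTimecourse:
    def test_toy1_matches_hand_recurrence_exactly(self, toy1):
        """Doubling while the cap binds; glc series 50, 49, 47, 43, ..."""
        cfg = DynamicConfig(initial_pools={"EX_glc": 50.0, "EX_nh4": 50.0})
        traj = simulate_timecourse(toy1, cfg)
        expected = hand_recurrence_toy1(50.0, 50.0)
        glc = traj.pool_series("EX_glc")
        assert glc[:5] == pytest.approx([50.0, 49.0, 47.0, 43.0, 35.0])
        for (t, X, g), (tt, XX, gg) in zip(expected, zip(traj.times, traj.biomass, glc)):
            assert t == tt
            assert X == pytest.approx(XX, abs=1e-9)
            assert g == pytest.approx(gg, abs=1e-9)

    def test_final_biomass_equals_yield_times_substrate(self, toy1):
        """One substrate: X_final = X0 + Y S0 with Y = 1 biomass per glc."""
        cfg = DynamicConfig(initial_pools={"EX_glc": 50.0, "EX_nh4": 1000.0})
        traj = simulate_timecourse(toy1, cfg)
        assert traj.final_biomass == pytest.approx(1.0 + 1.0 * 50.0, abs=1e-6)

    def test_geometric_growth_while_cap_binds(self, toy1):
        cfg = DynamicConfig(initial_pools={"EX_glc": 1000.0, "EX_nh4": 1000.0},
                            max_cycles=5)
        traj = simulate_timecourse(toy1, cfg)
        mu_cap = 1.0  # min(cap, 2 cap)
        for i, X in enumerate(traj.biomass):
            assert X == pytest.approx((1 + mu_cap) ** i, rel=1e-12)

    def test_empty_pools_stall_immediately(self, toy1):
        traj = simulate_timecourse(toy1, DynamicConfig(initial_pools={}))
        assert traj.stalled and traj.n_ticks == 1
        assert traj.final_biomass == 1.0

    def test_pools_never_negative_and_consumption_conserved(self, toy1):
        cfg = DynamicConfig(initial_pools={"EX_glc": 13.0, "EX_nh4": 3.0})
        traj = simulate_timecourse(toy1, cfg)
        for pools in traj.pools:
            assert all(p >= 0 for p in pools.values())
        consumed = 13.0 - traj.pool_series("EX_glc")[-1]
        assert consumed <= 13.0 + 1e-9
        # biomass gain accounts exactly for consumed glucose (yield 1)
        assert traj.final_biomass - 1.0 == pytest.approx(consumed, abs=1e-6)

    def test_biomass_never_decreases(self, toy2_pathway, dynamic_caps):
        cfg = make_dynamic_config(dynamic_caps, EX_atz=10.0)
        traj = simulate_timecourse(toy2_pathway, cfg)
        assert all(b >= a - 1e-12 for a, b in zip(traj.biomass, traj.biomass[1:]))

    def test_doubling_substrate_at_least_doubles_biomass_gain(self, toy1):
        def gain(s0):
            cfg = DynamicConfig(initial_pools={"EX_glc": s0, "EX_nh4": 1000.0})
            return simulate_timecourse(toy1, cfg).final_biomass - 1.0
        assert gain(40.0) >= 2 * gain(20.0) - 1e-6

    def test_exponential_update_option(self, toy1):
        cfg = DynamicConfig(initial_pools={"EX_glc": 1000.0, "EX_nh4": 1000.0},
                            max_cycles=3, exponential_update=True)
        traj = simulate_timecourse(toy1, cfg)
        assert traj.biomass[1] == pytest.approx(math.exp(1.0))


class TestDegradationCurve:
    def test_monotone_with_constant_exhausted_tail(self, toy1):
        cfg = DynamicConfig(initial_pools={"EX_glc": 10.0, "EX_nh4": 1000.0},
                            max_cycles=30, stall_tol=1e-9)
        traj = simulate_timecourse(toy1, cfg)
        curve = degradation_curve(traj, "EX_glc")
        amounts = [a for _, a in curve]
        assert all(b <= a + 1e-9 for a, b in zip(amounts, amounts[1:]))
        assert amounts[-1] == pytest.approx(0.0, abs=1e-9)

    def test_unknown_target_raises(self, toy1):
        traj = simulate_timecourse(toy1, DynamicConfig(initial_pools={}))
        with pytest.raises(KeyError, match="EX_mystery"):
            degradation_curve(traj, "EX_mystery")

    def test_glucose_accelerates_atrazine_depletion(self, toy2_pathway,
                                                    dynamic_caps):
        """Biostimulation: a better carbon source grows the degrader
        population faster, so the atrazine pool empties sooner."""
        sole = simulate_timecourse(
            toy2_pathway, make_dynamic_config(dynamic_caps, EX_atz=50.0))
        plus_glc = simulate_timecourse(
            toy2_pathway, make_dynamic_config(dynamic_caps, EX_atz=50.0, EX_glc=50.0))

        def depletion_time(traj):
            for t, amount in degradation_curve(traj, "EX_atz"):
                if amount <= 1e-9:
                    return t
            return math.inf

        assert depletion_time(plus_glc) < depletion_time(sole)

    def test_cyanuric_acid_accumulates_stoichiometrically(self, toy2_pathway,
                                                          dynamic_caps):
        """One mole of cyanuric acid appears per mole of atrazine degraded."""
        traj = simulate_timecourse(
            toy2_pathway, make_dynamic_config(dynamic_caps, EX_atz=50.0))
        consumed = 50.0 - traj.pool_series("EX_atz")[-1]
        accumulated = traj.pool_series("EX_cya")[-1]
        assert accumulated == pytest.approx(consumed, abs=1e-6)

    def test_phosphate_limitation_slows_growth_and_degradation(self, toy2_pathway,
                                                               dynamic_caps):
        rich = simulate_timecourse(
            toy2_pathway,
            make_dynamic_config(dynamic_caps, EX_atz=50.0, EX_glc=50.0))
        poor = simulate_timecourse(
            toy2_pathway,
            make_dynamic_config(dynamic_caps, EX_atz=50.0, EX_glc=50.0,
                                EX_hpo4=2.0))
        assert poor.final_biomass < rich.final_biomass
        assert poor.pool_series("EX_atz")[-1] > rich.pool_series("EX_atz")[-1]
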