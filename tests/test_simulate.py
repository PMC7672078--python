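"""Integration-layer tests: carbon balance along trajectories, incubation
observables, spin-up convergence and warming projections."""

from dataclasses import replace

import numpy as np
import pytest

from soilmend import FixedParams, MicrobialParams, PoolState
from soilmend.simulate import (
    HOURS_PER_YEAR,
    LT_C,
    ST_G,
    Environment,
    SoilInit,
    apply_substrate_pulse,
    integrate,
    make_input_env,
    project_warming,
    run_incubation,
    spin_up,
    steady_state_warming_response,
)


@pytest.fixture(scope="module")
def pulse_state(soil, mp):
    return apply_substrate_pulse(soil.initial_state(mp.r0), "glucose",
                                 soil.total_c)


class TestIntegrate:
    def test_closed_system_conserves_carbon(self, pulse_state, mp, fp):
        """SOC + cumulative CO2 is invariant in a closed incubation."""
        env = Environment(T=22.0)
        t = np.linspace(0.0, 1000.0, 25)
        traj = integrate(pulse_state, mp, fp, env, t)
        total = traj.soc() + traj.pool("CO2cum")
        assert np.all(np.abs(total - total[0]) / total[0] < 1e-6)

    def test_open_system_balance(self, soil, mp, fp):
        """With constant inputs, SOC + CO2 grows by exactly the integral
        of the input rate."""
        env = Environment(T=20.0, IP1=1e-4, IP2=1e-4, ID=5e-5)
        t = np.linspace(0.0, 5000.0, 11)
        traj = integrate(soil.initial_state(mp.r0), mp, fp, env, t)
        total = traj.soc() + traj.pool("CO2cum")
        expected = total[0] + env.total_input * t
        assert np.all(np.abs(total - expected) / expected < 1e-6)

    def test_bitwise_determinism(self, pulse_state, mp, fp):
        env = Environment(T=22.0)
        t = np.linspace(0.0, 500.0, 7)
        a = integrate(pulse_state, mp, fp, env, t)
        b = integrate(pulse_state, mp, fp, env, t)
        assert np.array_equal(a.states, b.states)

    def test_tolerance_refinement(self, pulse_state, mp, fp):
        """Halving the solver tolerance leaves end SOC unchanged to 1e-5
        relative: the default tolerance is converged."""
        env = Environment(T=22.0)
        t = np.array([0.0, 2000.0])
        a = integrate(pulse_state, mp, fp, env, t, rtol=1e-8)
        b = integrate(pulse_state, mp, fp, env, t, rtol=5e-9)
        assert abs(a.soc()[-1] - b.soc()[-1]) / b.soc()[-1] < 1e-5

    def test_bad_grid_rejected(self, pulse_state, mp, fp):
        with pytest.raises(ValueError):
            integrate(pulse_state, mp, fp, Environment(), np.array([0.0]))
        with pytest.raises(ValueError):
            integrate(pulse_state, mp, fp, Environment(),
                      np.array([0.0, 2.0, 1.0]))


class TestIncubation:
    def test_short_schedule_observables(self, soil, mp, fp):
        """The short glucose schedule yields 7 CO2 and 3 MBC collections
        at the prescribed hours."""
        res = run_incubation(soil, mp, fp, "glucose", ST_G)
        assert res.co2_times.tolist() == [2, 4, 8, 24, 48, 72, 144]
        assert res.mbc_times.tolist() == [24, 72, 144]
        assert res.co2_rates.shape == (7,)
        assert np.all(res.co2_rates > 0)

    def test_long_schedule_observables(self, cellulose_soil, mp, fp):
        res = run_incubation(cellulose_soil, mp, fp, "cellulose", LT_C)
        assert len(res.co2_times) == 18
        assert len(res.mbc_times) == 8
        assert res.co2_times[0] == 24.0 and res.co2_times[-1] == 729 * 24.0

    def test_substrate_addition_boosts_respiration(self, soil, mp, fp):
        plain = run_incubation(soil, mp, fp, "none", ST_G)
        fed = run_incubation(soil, mp, fp, "glucose", ST_G)
        assert (fed.trajectory.pool("CO2cum")[-1]
                > plain.trajectory.pool("CO2cum")[-1])

    def test_pulse_routing(self, soil):
        base = soil.initial_state(0.6)
        glu = apply_substrate_pulse(base, "glucose", soil.total_c)
        cel = apply_substrate_pulse(base, "cellulose", soil.total_c)
        pulse = 0.01 * soil.total_c
        assert glu.D - base.D == pytest.approx(pulse)
        assert cel.P2 - base.P2 == pytest.approx(pulse)
        with pytest.raises(ValueError, match="substrate"):
            apply_substrate_pulse(base, "peat", soil.total_c)

    def test_fully_active_inoculum(self, soil):
        state = soil.initial_state(1.0)
        assert state.BD == 0.0
        assert state.BA == pytest.approx(soil.mbc)

    def test_initial_pools(self, soil):
        state = soil.initial_state(0.59)
        assert state.Q == pytest.approx(0.01 * soil.moc)
        assert state.M == pytest.approx(0.99 * soil.moc)
        assert (state.EP1, state.EP2, state.EM) == (1.1e-3, 1.1e-3, 1.4e-3)
        assert state.mbc() == pytest.approx(soil.mbc)


class TestSpinUp:
    def test_residual_below_tolerance(self, soil, mp, fp):
        su = spin_up(soil, mp, fp, T=20.0)
        assert su.residual < 1e-9
        assert min(su.state.as_array()[:10]) >= 0.0

    def test_more_input_more_carbon(self, soil, mp, fp):
        lo = spin_up(soil, mp, fp, annual_input_frac=0.05)
        hi = spin_up(soil, mp, fp, annual_input_frac=0.10)
        assert hi.state.soc() > lo.state.soc()

    def test_steady_state_unique(self, soil, mp, fp):
        """Different initial soils converge to the same steady pools."""
        other = SoilInit(site="X", ecosystem="grassland", poc=2.0, moc=25.0,
                         doc=0.4, mbc=1.2)
        env_soc = soil.total_c     # same input forcing for both
        a = spin_up(soil, mp, fp)
        b = spin_up(replace(other), mp, fp,
                    annual_input_frac=0.05 * env_soc / other.total_c)
        assert np.allclose(a.state.as_array()[:10], b.state.as_array()[:10],
                           rtol=1e-6, atol=1e-8)

    def test_zero_input_rejected(self, soil, mp, fp):
        with pytest.raises(ValueError):
            spin_up(soil, mp, fp, annual_input_frac=0.0)


class TestProjection:
    def test_no_warming_no_change(self, soil, mp, fp):
        su = spin_up(soil, mp, fp)
        pr = project_warming(su, mp, fp, dT=0.0, years=50)
        assert abs(pr.relative_change) < 1e-6

    def test_steady_state_is_fixed_point(self, soil, mp, fp):
        """Projecting at the spin-up temperature leaves SOC flat."""
        su = spin_up(soil, mp, fp)
        t = np.linspace(0.0, 50 * HOURS_PER_YEAR, 26)
        traj = integrate(su.state, mp, fp, su.env, t)
        drift = np.abs(traj.soc() - traj.soc()[0]) / traj.soc()[0]
        assert drift.max() < 1e-4

    def test_cue_controls_projection_sign(self, soil, fp):
        """Warming gains SOC at low carbon use efficiency and loses it at
        high efficiency (the efficiency threshold behaviour)."""
        low = MicrobialParams(Yg=0.30)
        high = MicrobialParams(Yg=0.40)
        pr_low = project_warming(spin_up(soil, low, fp), low, fp, dT=5.0)
        pr_high = project_warming(spin_up(soil, high, fp), high, fp, dT=5.0)
        assert pr_low.relative_change > 0
        assert pr_high.relative_change < 0

    def test_input_env_partition(self, soil):
        env = make_input_env(20.0, soil.total_c)
        total = 0.05 * soil.total_c / HOURS_PER_YEAR
        assert env.total_input == pytest.approx(total)
        assert env.IP1 == pytest.approx(0.4 * total)
        with pytest.raises(ValueError):
            make_input_env(20.0, 30.0, split=(0.5, 0.2, 0.2))
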