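"""Unit and property tests for the pool model core: elementary relations,
flux limits, carbon conservation and temperature scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmend.mend_core import (
    Environment,
    FixedParams,
    MicrobialParams,
    POOL_NAMES,
    PoolState,
    arrhenius_factor,
    compute_fluxes,
    derived_maintenance_rate,
    rhs,
    scale_params,
    yg_at_temperature,
)


class TestMaintenanceRate:
    @pytest.mark.parametrize("Vg, alpha, expected", [
        (0.048, 0.30, 0.0205714),   # short-term glucose mean estimates
        (0.5, 0.0, 0.0),            # no maintenance
        (0.038, 0.27, 0.0140548),   # long-term cellulose mean estimates
    ])
    def test_known_values(self, Vg, alpha, expected):
        assert derived_maintenance_rate(Vg, alpha) == pytest.approx(
            expected, abs=1e-6)

    @pytest.mark.parametrize("alpha", [1.0, 1.5, -0.1])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            derived_maintenance_rate(0.05, alpha)

    @given(Vg=st.floats(1e-4, 1.0), alpha=st.floats(0.0, 0.99))
    def test_alpha_round_trip(self, Vg, alpha):
        """alpha -> Vmt -> alpha is the identity."""
        vmt = derived_maintenance_rate(Vg, alpha)
        assert vmt / (Vg + vmt) == pytest.approx(alpha, abs=1e-12)


class TestArrhenius:
    @pytest.mark.parametrize("Ea, T, expected", [
        (47.0, 20.0, 1.0),       # reference temperature
        (0.0, 35.0, 1.0),        # no activation energy
        (47.0, 25.0, 1.3818),    # warming by 5 degC
    ])
    def test_known_factors(self, Ea, T, expected):
        assert arrhenius_factor(Ea, T, 20.0) == pytest.approx(expected,
                                                              rel=1e-4)

    def test_monotonic_in_temperature(self):
        temps = np.linspace(-5, 40, 10)
        factors = [arrhenius_factor(47.0, t, 20.0) for t in temps]
        assert np.all(np.diff(factors) > 0)

    def test_below_absolute_zero_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_factor(47.0, -300.0, 20.0)


class TestYgTemperature:
    @pytest.mark.parametrize("yg, T, expected", [
        (0.30, 25.0, 0.25),    # default slope, +5 degC
        (0.30, 20.0, 0.30),    # reference
        (0.05, 40.0, 0.001),   # clipped at the numerical floor
    ])
    def test_known_values(self, yg, T, expected):
        assert yg_at_temperature(yg, -0.01, T, 20.0) == pytest.approx(expected)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            yg_at_temperature(1.2, -0.01, 25.0)


def _random_state(rng):
    return PoolState.from_array(rng.uniform(0.0, 5.0, size=11))


class TestFluxes:
    def test_zero_substrate_limit(self, mp, fp):
        """With no DOC: no uptake or reactivation; dormancy at full rate."""
        state = PoolState(P1=1, P2=1, M=5, D=0.0, Q=0.1, BA=0.2, BD=0.1,
                          EP1=1e-3, EP2=1e-3, EM=1e-3)
        env = Environment(T=20.0)
        fx = compute_fluxes(state, mp, fp, env)
        assert fx.uptake == 0.0
        assert fx.reactivation == 0.0
        assert fx.dormancy == pytest.approx(mp.Vmt * state.BA)

    def test_saturated_sorbent(self, mp, fp):
        state = PoolState(D=0.5, Q=fp.Qmax)
        fx = compute_fluxes(state, mp, fp, Environment(T=20.0))
        assert fx.adsorption == 0.0

    def test_uptake_saturation(self, mp, fp):
        """DOC far above KD drives uptake to its Michaelis-Menten limit."""
        state = PoolState(D=1e4 * mp.KD, BA=0.2)
        fx = compute_fluxes(state, mp, fp, Environment(T=20.0))
        limit = (mp.Vg + mp.Vmt) * state.BA / mp.Yg
        assert fx.uptake == pytest.approx(limit, rel=1e-3)

    def test_negative_pool_rejected(self, mp, fp):
        with pytest.raises(ValueError):
            compute_fluxes(PoolState(D=-0.1), mp, fp, Environment())

    def test_outflows_vanish_with_source_pool(self, mp, fp):
        """Every flux out of a pool goes to zero as that pool empties."""
        full = PoolState.from_array(np.full(11, 0.5))
        env = Environment(T=22.0)
        for pool, flux_names in [
            ("P1", ["decomp_P1"]), ("P2", ["decomp_P2"]), ("M", ["decomp_M"]),
            ("D", ["uptake", "adsorption"]), ("Q", ["desorption"]),
            ("BA", ["dormancy", "mortality", "maintenance_active"]),
            ("BD", ["reactivation", "maintenance_dormant"]),
        ]:
            state = PoolState.from_array(full.as_array())
            setattr(state, pool, 0.0)
            fx = compute_fluxes(state, mp, fp, env)
            for name in flux_names:
                assert getattr(fx, name) == 0.0, (pool, name)

    def test_v_rates_increase_with_temperature(self, mp, fp):
        cold = scale_params(mp, fp, 15.0)
        ref = scale_params(mp, fp, 20.0)
        warm = scale_params(mp, fp, 30.0)
        for attr in ("VP1", "VP2", "VM", "Vg", "Vmt"):
            assert getattr(cold, attr) < getattr(ref, attr) < getattr(warm, attr)
        assert ref.VP1 == fp.VP1  # factor is exactly 1 at Tref


class TestConservation:
    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), T=st.floats(5.0, 35.0),
           inputs=st.tuples(st.floats(0, 1e-3), st.floats(0, 1e-3),
                            st.floats(0, 1e-3)))
    def test_derivative_sum_equals_input(self, seed, T, inputs):
        """Sum of pool derivatives plus the CO2 rate equals external input
        exactly: the model creates or destroys no carbon."""
        rng = np.random.default_rng(seed)
        state = _random_state(rng)
        mp = MicrobialParams(
            r0=rng.uniform(0.05, 1.0), Vg=rng.uniform(0.005, 0.15),
            alpha=rng.uniform(0.05, 0.55), KD=rng.uniform(1e-3, 0.4),
            Yg=rng.uniform(0.15, 0.65))
        env = Environment(T=T, IP1=inputs[0], IP2=inputs[1], ID=inputs[2])
        deriv = rhs(state, mp, FixedParams(), env)
        total = sum(getattr(deriv, n) for n in POOL_NAMES)
        scale = max(abs(total), env.total_input, 1.0)
        assert abs(total - env.total_input) / scale < 1e-12

    def test_empty_system_is_inert(self, mp, fp):
        deriv = rhs(PoolState(), mp, fp, Environment())
        assert all(getattr(deriv, n) == 0.0 for n in POOL_NAMES)

    def test_input_only_feeds_target_pool(self, mp, fp):
        deriv = rhs(PoolState(), mp, fp, Environment(ID=1e-3))
        assert deriv.D == pytest.approx(1e-3)
        assert all(getattr(deriv, n) == 0.0
                   for n in POOL_NAMES if n != "D")


class TestFixedParamsConfig:
    def test_packaged_defaults_match_dataclass(self):
        assert FixedParams.from_config() == FixedParams()

    def test_unknown_key_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("decomposition:\n  VXX: 1.0\n")
        with pytest.raises(ValueError, match="VXX"):
            FixedParams.from_config(bad)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            FixedParams(fD=1.4)
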