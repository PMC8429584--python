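import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soccf import rothc
from soccf.environment import MonthlyClimate, SoilProfile
from soccf.exceptions import NoEquilibriumError
from soccf.rothc import (MoistureState, PoolState, RateModifiers, RothCParams,
                         max_tsmd, moisture_modifier, step_month,
                         steady_state, temperature_modifier)

PARAMS = RothCParams()


def _climate(tavg=15.0, precip=120.0):
    return MonthlyClimate(tavg=np.full(12, tavg), precip=np.full(12, precip),
                          day_length=np.full(12, 12.0))


class TestRateModifiers:
    def test_temperature_frozen_limit(self):
        assert temperature_modifier(-18.27) == 0.0
        assert temperature_modifier(-30.0) == 0.0

    @pytest.mark.parametrize("tavg,expected,tol", [
        (9.25, 0.99, 0.01), (25.0, 3.80, 0.01)])
    def test_temperature_logistic_values(self, tavg, expected, tol):
        assert temperature_modifier(tavg) == pytest.approx(expected, abs=tol)

    def test_temperature_monotone(self):
        ts = np.linspace(-18, 45, 100)
        assert np.all(np.diff(temperature_modifier(ts)) >= 0)

    def test_max_tsmd_quadratic(self):
        assert max_tsmd(25.0, 23.0) == pytest.approx(46.25, rel=1e-12)

    def test_wet_soil_full_activity(self):
        b, state = moisture_modifier(precip=150.0, pet=40.0, clay=25.0,
                                     depth=23.0, covered=True,
                                     state=MoistureState(0.0))
        assert b == 1.0 and state.tsmd == 0.0

    def test_dry_soil_floors_at_b_min(self):
        mt = max_tsmd(25.0, 23.0)
        b, state = moisture_modifier(precip=0.0, pet=500.0, clay=25.0,
                                     depth=23.0, covered=True,
                                     state=MoistureState(mt))
        assert b == pytest.approx(PARAMS.b_min)
        assert state.tsmd == pytest.approx(mt)

    def test_bare_soil_cap(self):
        mt = max_tsmd(25.0, 23.0)
        _, state = moisture_modifier(precip=0.0, pet=500.0, clay=25.0,
                                     depth=23.0, covered=False,
                                     state=MoistureState(0.0))
        assert state.tsmd == pytest.approx(mt / 1.8)


class TestStepMonth:
    def test_frozen_month_is_identity(self):
        state = PoolState(dpm=1.0, rpm=2.0, bio=0.5, hum=3.0, iom=1.0)
        new, co2 = step_month(state, RateModifiers(0.0, 1.0, 1.0), 0.0, 0.0,
                              1.44, clay=20.0)
        assert co2 == 0.0
        assert new.total_soc == pytest.approx(state.total_soc, abs=1e-15)

    def test_single_pool_decay_and_partition(self):
        """1 t DPM, unit modifiers, clay 20: survives exp(-10/12), the decayed
        carbon splits CO2 : retained as x : 1 with x ≈ 3.645, retained splits
        46/54 into BIO/HUM."""
        state = PoolState(dpm=1.0)
        new, co2 = step_month(state, RateModifiers(1.0, 1.0, 1.0), 0.0, 0.0,
                              1.44, clay=20.0)
        assert new.dpm == pytest.approx(math.exp(-10.0 / 12.0), rel=1e-12)
        assert co2 == pytest.approx(0.444, abs=1e-3)
        assert new.bio == pytest.approx(0.056, abs=1e-3)
        assert new.hum == pytest.approx(0.066, abs=1e-3)

    def test_input_partitions(self):
        state = PoolState()
        new, _ = step_month(state, RateModifiers(0.0, 1.0, 1.0), 2.44, 1.0,
                            1.44, clay=20.0)
        assert new.dpm == pytest.approx(2.44 * 1.44 / 2.44 + 0.49, rel=1e-12)
        assert new.rpm == pytest.approx(2.44 * 1.0 / 2.44 + 0.49, rel=1e-12)
        assert new.hum == pytest.approx(0.02, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            step_month(PoolState(), RateModifiers(1, 1, 1), -0.1, 0.0, 1.44,
                       clay=20.0)

    @given(dpm=st.floats(0, 50), rpm=st.floats(0, 80), bio=st.floats(0, 10),
           hum=st.floats(0, 150), a=st.floats(0, 5), b=st.floats(0.2, 1),
           covered=st.booleans(), plant=st.floats(0, 3),
           manure=st.floats(0, 2), clay=st.floats(0, 60),
           ratio=st.sampled_from([1.44, 0.25, 0.67]))
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_and_nonnegativity(self, dpm, rpm, bio, hum, a, b,
                                            covered, plant, manure, clay,
                                            ratio):
        """Every monthly step conserves carbon to 1e-9 t C/ha and keeps every
        pool non-negative; the inert pool never changes."""
        state = PoolState(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=2.0)
        c = 0.6 if covered else 1.0
        new, co2 = step_month(state, RateModifiers(a, b, c), plant, manure,
                              ratio, clay)
        assert min(new.dpm, new.rpm, new.bio, new.hum) >= 0
        assert new.iom == state.iom
        balance = new.total_soc - state.total_soc - (plant + manure) + co2
        assert abs(balance) < 1e-9


class TestRunAndSteadyState:
    def test_all_zero_modifiers_preserve_state(self):
        climate = MonthlyClimate(tavg=np.full(12, -30.0),
                                 precip=np.full(12, 100.0),
                                 day_length=np.full(12, 8.0))
        soil = SoilProfile(clay=20.0, soc_init=50.0)
        state = PoolState(dpm=1, rpm=5, bio=1, hum=20, iom=soil.iom)
        pools, co2 = rothc.run(state, climate, (1,) * 12, np.zeros(12),
                               np.zeros(12), 1.44, soil, 1)
        assert np.all(co2 == 0)
        assert pools[-1].sum() == pytest.approx(state.total_soc, abs=1e-12)

    def test_zero_input_trajectory_monotone_to_iom(self):
        """Urban-style decay: total SOC never increases and approaches the
        inert stock."""
        soil = SoilProfile(clay=25.0, soc_init=60.0)
        state = PoolState(dpm=2, rpm=10, bio=2, hum=30, iom=soil.iom)
        pools, _ = rothc.run(state, _climate(), (1,) * 12, np.zeros(12),
                             np.zeros(12), 1.44, soil, 500)
        totals = pools.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-12)
        assert totals[-1] == pytest.approx(soil.iom, abs=0.01)

    def test_steady_state_zero_inputs_is_iom(self):
        ss = steady_state(_climate(), (1,) * 12, np.zeros(12), np.zeros(12),
                          1.44, clay=20.0, iom=3.0)
        assert ss.total_soc == 3.0
        assert ss.active() == pytest.approx(np.zeros(4))

    def test_steady_state_linear_in_inputs(self):
        plant = np.full(12, 0.2)
        ss1 = steady_state(_climate(), (1,) * 12, plant, np.zeros(12), 0.67,
                           clay=20.0, iom=0.0)
        ss2 = steady_state(_climate(), (1,) * 12, 2 * plant, np.zeros(12),
                           0.67, clay=20.0, iom=0.0)
        assert ss2.active() == pytest.approx(2 * ss1.active(), rel=1e-12)

    def test_steady_state_matches_long_simulation(self):
        """The analytic fixed point agrees with a 2000-year brute-force run
        (annual-mean comparison, since the equilibrium is a periodic orbit)."""
        climate = MonthlyClimate(
            tavg=15.0 + 8.0 * np.sin(2 * np.pi * np.arange(12) / 12),
            precip=np.full(12, 150.0), day_length=np.full(12, 12.0))
        soil = SoilProfile(clay=30.0, soc_init=80.0)
        cover = (0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0)
        plant = np.full(12, 0.25)
        ss = steady_state(climate, cover, plant, np.zeros(12), 1.44,
                          soil.clay, soil.iom)
        pools, _ = rothc.run(PoolState(iom=soil.iom), climate, cover, plant,
                             np.zeros(12), 1.44, soil, 2000)
        sim_start_of_year = pools[-12:].sum(axis=1)[-1]  # phase-aligned
        assert sim_start_of_year == pytest.approx(ss.total_soc, rel=1e-6)

    def test_no_equilibrium_when_decay_shut_off(self):
        climate = MonthlyClimate(tavg=np.full(12, -30.0),
                                 precip=np.full(12, 100.0),
                                 day_length=np.full(12, 8.0))
        with pytest.raises(NoEquilibriumError):
            steady_state(climate, (1,) * 12, np.full(12, 0.1), np.zeros(12),
                         1.44, clay=20.0, iom=0.0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RothCParams(k_dpm=-1.0)
        with pytest.raises(ValueError):
            RothCParams(bio_fraction=0.5, hum_fraction=0.6)
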