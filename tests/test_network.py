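"""Reaction-channel propensities and state updates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import toroidyn as td
from toroidyn.network import CHANNEL_NAMES, build_reaction_network
from toroidyn.errors import ConfigurationError, NumericalError


def _channels(params):
    return {c.name: c for c in build_reaction_network(params)}


def _brute_force_pair_count(n):
    """Independent oracle: enumerate unordered reactant pairs."""
    return sum(1 for i in range(n) for j in range(i + 1, n))


class TestPropensities:
    def test_null_rates_give_null_propensities(self, zero_rates, small_state):
        for ch in build_reaction_network(zero_rates):
            assert ch.propensity(small_state, zero_rates) == 0.0

    def test_zero_reactants_give_zero_propensity(self, rng):
        p = td.DEFAULT_RATES
        empty = td.SystemState(time=0, n_inactive=5, n_active_closed=0,
                               n_active_open=0, chains=[],
                               volume_litres=td.volume_for(5, 30.0))
        for name in ("open", "close", "nucleate", "elongate", "join",
                     "relax_scission", "relax_free"):
            assert _channels(p)[name].propensity(empty, p) == 0.0

    @pytest.mark.parametrize("n_open", [2, 3, 7])
    def test_nucleation_counts_reactant_pairs(self, n_open):
        p = td.DEFAULT_RATES
        s = td.SystemState(time=0, n_inactive=0, n_active_closed=0,
                           n_active_open=n_open, chains=[],
                           volume_litres=td.volume_for(100, 30.0))
        c_stoch = p.k_nuc / s.units_per_uM
        expected = c_stoch * _brute_force_pair_count(n_open)
        assert _channels(p)["nucleate"].propensity(s, p) == pytest.approx(expected)
        # chain channels silent without chains
        assert _channels(p)["elongate"].propensity(s, p) == 0.0
        assert _channels(p)["join"].propensity(s, p) == 0.0
        assert _channels(p)["relax_scission"].propensity(s, p) == 0.0

    def test_scission_rate_counts_subunits_and_sites_equiprobable(self, rng):
        p = td.DEFAULT_RATES.replace(k_relax_chain=0.25)
        s = td.SystemState(time=0, n_inactive=0, n_active_closed=0,
                           n_active_open=0, chains=[5],
                           volume_litres=td.volume_for(5, 30.0))
        ch = _channels(p)["relax_scission"]
        assert ch.propensity(s, p) == pytest.approx(5 * 0.25)
        # the five per-subunit outcomes (site index) must be equiprobable:
        # outcome signature = sorted fragment pair
        counts = {}
        n_draws = 20000
        for _ in range(n_draws):
            trial = s.copy()
            td.apply_channel(trial, ch, p, rng)
            key = (trial.n_active_open, tuple(sorted(trial.chains)))
            counts[key] = counts.get(key, 0) + 1
        # sites 1..5 of chain 5 give fragments (0,4),(1,3),(2,2),(3,1),(4,0):
        # signatures: {(0 open, (4,))} x2, {(1 open, (3,))} x2, {(0 open, (2,2))} x1
        assert set(counts) == {(0, (4,)), (1, (3,)), (0, (2, 2))}
        assert counts[(0, (4,))] / n_draws == pytest.approx(2 / 5, abs=0.02)
        assert counts[(1, (3,))] / n_draws == pytest.approx(2 / 5, abs=0.02)
        assert counts[(0, (2, 2))] / n_draws == pytest.approx(1 / 5, abs=0.02)


class TestApply:
    def test_scission_of_dimer_releases_one_open_one_inactive(self, rng):
        p = td.DEFAULT_RATES
        s = td.SystemState(time=0, n_inactive=0, n_active_closed=0,
                           n_active_open=0, chains=[2],
                           volume_litres=td.volume_for(2, 30.0))
        td.apply_channel(s, _channels(p)["relax_scission"], p, rng)
        assert s.chains == []
        assert s.n_inactive == 1 and s.n_active_open == 1
        assert s.total_units == 2

    def test_join_is_additive(self, rng):
        p = td.DEFAULT_RATES
        s = td.SystemState(time=0, n_inactive=3, n_active_closed=4,
                           n_active_open=5, chains=[3, 4],
                           volume_litres=td.volume_for(19, 30.0))
        td.apply_channel(s, _channels(p)["join"], p, rng)
        assert sorted(s.chains) == [7]
        assert (s.n_inactive, s.n_active_closed, s.n_active_open) == (3, 4, 5)

    def test_elongation_audit(self, rng):
        p = td.DEFAULT_RATES
        s = td.SystemState(time=0, n_inactive=0, n_active_closed=0,
                           n_active_open=5, chains=[10],
                           volume_litres=td.volume_for(15, 30.0))
        before = s.total_units
        td.apply_channel(s, _channels(p)["elongate"], p, rng)
        assert s.chains == [11]
        assert s.n_active_open == 4
        assert s.total_units == before

    def test_apply_with_zero_propensity_is_a_logic_error(self, rng):
        p = td.DEFAULT_RATES
        s = td.SystemState(time=0, n_inactive=1, n_active_closed=0,
                           n_active_open=0, chains=[],
                           volume_litres=td.volume_for(1, 30.0))
        with pytest.raises(NumericalError):
            td.apply_channel(s, _channels(p)["elongate"], p, rng)


class TestHeatPulse:
    @pytest.mark.parametrize(
        "n_inactive,eff,expected_moved",
        [(1000, 1.0, 1000), (1000, 0.0, 0), (1000, 0.75, 750), (7, 0.5, 3)],
    )
    def test_floor_rounding_rule(self, n_inactive, eff, expected_moved):
        s = td.SystemState(time=0, n_inactive=n_inactive, n_active_closed=0,
                           n_active_open=0, chains=[],
                           volume_litres=td.volume_for(max(n_inactive, 1), 30.0))
        td.apply_heat_pulse(s, td.DEFAULT_RATES, efficiency=eff)
        assert s.n_active_closed == expected_moved
        assert s.n_inactive == n_inactive - expected_moved

    def test_chains_untouched(self):
        s = td.SystemState(time=0, n_inactive=10, n_active_closed=0,
                           n_active_open=0, chains=[4, 6],
                           volume_litres=td.volume_for(20, 30.0))
        td.apply_heat_pulse(s, td.DEFAULT_RATES, efficiency=1.0)
        assert s.chains == [4, 6]
        assert s.total_units == 20


class TestValidation:
    @pytest.mark.parametrize("field,value", [
        ("k_open", -1.0), ("k_el", -0.5), ("uv_factor", 0.5),
        ("activation_efficiency", 1.2), ("activation_efficiency", -0.1),
    ])
    def test_invalid_params_name_the_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            td.DEFAULT_RATES.replace(**{field: value})

    def test_network_has_exactly_the_expected_channels(self):
        names = [c.name for c in build_reaction_network(td.DEFAULT_RATES)]
        assert names == list(CHANNEL_NAMES)

    def test_default_configuration_constraints(self):
        p = td.DEFAULT_RATES
        assert p.open_close_K == pytest.approx(td.OPEN_CLOSE_EQUILIBRIUM_K)
        assert p.k_el >= 10 * p.k_nuc


@given(
    counts=st.tuples(
        st.integers(0, 50), st.integers(0, 50), st.integers(2, 50),
    ),
    chains=st.lists(st.integers(2, 30), max_size=8),
    moves=st.lists(st.integers(0, 10 ** 6), min_size=30, max_size=30),
)
def test_random_channel_sequences_conserve_units(counts, chains, moves):
    """Any applicable channel sequence conserves total toroid units and
    keeps the cached chain total consistent."""
    p = td.DEFAULT_RATES
    total = sum(counts) + sum(chains)
    s = td.SystemState(
        time=0.0, n_inactive=counts[0], n_active_closed=counts[1],
        n_active_open=counts[2], chains=list(chains),
        volume_litres=td.volume_for(max(total, 1), 30.0),
    )
    channels = build_reaction_network(p)
    rng = np.random.default_rng(99)
    for mv in moves:
        applicable = [c for c in channels if c.propensity(s, p) > 0]
        if not applicable:
            break
        td.apply_channel(s, applicable[mv % len(applicable)], p, rng)
        assert s.total_units == total
        s.validate()
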