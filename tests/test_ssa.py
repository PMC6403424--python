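"""Exact stochastic engine: frozen systems, closed-form death process,
two-state stationarity, reproducibility, ensembles."""

import numpy as np
import pytest

import toroidyn as td
from toroidyn.errors import ConfigurationError


def _two_state_params(k_open=2.0):
    return td.RateParameters(
        k_open=k_open, k_close=k_open / td.OPEN_CLOSE_EQUILIBRIUM_K,
        k_nuc=0, k_el=0, k_join=0, k_relax_free=0, k_relax_chain=0,
    )


def test_frozen_system_stays_put(zero_rates, small_state):
    res = td.simulate(small_state, zero_rates, td.Protocol(), 5.0,
                      [1.0, 5.0], seed=1)
    assert res.event_count == 0
    for s in res.states:
        assert s.n_inactive == small_state.n_inactive
        assert sorted(s.chains) == sorted(small_state.chains)


def test_pure_death_matches_exponential_decay():
    """Relaxation-only: survival is binomial with p = exp(-kt)."""
    k = 0.8
    n0, t, reps = 1000, 1.0, 50
    p = td.RateParameters(k_open=0, k_close=0, k_nuc=0, k_el=0, k_join=0,
                          k_relax_free=k, k_relax_chain=0)
    init = td.SystemState(time=0, n_inactive=0, n_active_closed=n0,
                          n_active_open=0, chains=[],
                          volume_litres=td.volume_for(n0, 30.0))
    ens = td.run_ensemble(reps, 7, init, p, td.Protocol(), t, [t])
    remaining = np.array([r.states[-1].n_active_closed for r in ens.results])
    surv = np.exp(-k * t)
    mean_expect = n0 * surv
    sd_binom = np.sqrt(n0 * surv * (1 - surv))
    assert abs(remaining.mean() - mean_expect) < 3 * sd_binom / np.sqrt(reps)
    # ensemble variance consistent with the binomial law (loose factor)
    assert 0.5 * sd_binom ** 2 < remaining.var(ddof=1) < 2.0 * sd_binom ** 2


def test_two_state_stationary_open_fraction():
    """Open/close only: stationary P(open) = K/(1+K) from the two-state
    closed form, checked against a long trajectory time-average."""
    K = td.OPEN_CLOSE_EQUILIBRIUM_K
    n0 = 20_000
    p = _two_state_params()
    init = td.SystemState(time=0, n_inactive=0, n_active_closed=n0,
                          n_active_open=0, chains=[],
                          volume_litres=td.volume_for(n0, 30.0))
    rec = np.linspace(2.0, 10.0, 81)
    res = td.simulate(init, p, td.Protocol(), 10.0, rec, seed=3)
    fracs = np.array([s.n_active_open / n0 for s in res.states])
    expected = K / (1 + K)
    se = fracs.std(ddof=1) / np.sqrt(len(fracs))
    assert abs(fracs.mean() - expected) < 3 * max(se, 1e-6)


def test_seeded_reproducibility_and_divergence(small_state):
    p = td.DEFAULT_RATES
    rec = np.linspace(0, 2, 9)
    a = td.simulate(small_state, p, td.single_fuel(0.0), 2.0, rec, seed=42)
    b = td.simulate(small_state, p, td.single_fuel(0.0), 2.0, rec, seed=42)
    assert a.event_count == b.event_count
    assert a.to_json() == b.to_json()
    c = td.simulate(small_state, p, td.single_fuel(0.0), 2.0, rec, seed=43)
    assert a.to_json() != c.to_json()


def test_heat_pulse_at_zero_is_visible_in_first_record():
    init = td.SystemState.from_concentration(30.0, 1000)  # all inactive
    res = td.simulate(init, td.DEFAULT_RATES, td.single_fuel(0.0), 1.0,
                      [0.0, 1.0], seed=5)
    assert res.states[0].n_inactive == 0
    assert res.states[0].n_active_closed == 1000


def test_mass_conservation_along_trajectory():
    init = td.SystemState.from_concentration(30.0, 3000)
    res = td.simulate(init, td.DEFAULT_RATES, td.single_fuel(0.0), 10.0,
                      np.linspace(0, 10, 41), seed=8)
    totals = {s.total_units for s in res.states}
    assert totals == {3000}
    for s in res.states:
        s.validate()


class TestEnsemble:
    def test_single_rep_equals_single_trajectory(self, small_state):
        p = td.DEFAULT_RATES
        rec = [0.5, 1.0]
        ens = td.run_ensemble(1, 17, small_state, p, td.Protocol(), 1.0, rec)
        solo = td.simulate(small_state, p, td.Protocol(), 1.0, rec,
                           seed=ens.seeds[0])
        assert ens.results[0].to_json() == solo.to_json()

    def test_frozen_ensemble_has_zero_variance(self, zero_rates, small_state):
        ens = td.run_ensemble(10, 23, small_state, zero_rates, td.Protocol(),
                              2.0, [1.0, 2.0])
        s = ens.summary()
        for col in ("mean_length_all_sd", "active_fraction_sd", "n_chains_sd"):
            assert np.allclose(s[col], 0.0)

    def test_requires_at_least_one_rep(self, zero_rates, small_state):
        with pytest.raises(ConfigurationError):
            td.run_ensemble(0, 1, small_state, zero_rates, td.Protocol(), 1.0, [1.0])

    def test_seed_spawning_is_deterministic(self):
        assert td.spawn_seeds(5, 4) == td.spawn_seeds(5, 4)
        assert td.spawn_seeds(5, 4) != td.spawn_seeds(6, 4)
        assert all(0 <= s < 2 ** 31 for s in td.spawn_seeds(5, 100))


def test_uv_multiplier_applies_to_both_relaxation_rates():
    p = td.DEFAULT_RATES.replace(uv_factor=100.0)
    q = p.with_uv()
    assert q.k_relax_free == pytest.approx(100.0 * p.k_relax_free)
    assert q.k_relax_chain == pytest.approx(100.0 * p.k_relax_chain)
    # factor 1 is a no-op window
    r = p.with_uv(1.0)
    assert r.k_relax_free == p.k_relax_free
    assert r.k_relax_chain == p.k_relax_chain


def test_invalid_t_end_rejected(zero_rates, small_state):
    with pytest.raises(ConfigurationError):
        td.simulate(small_state, zero_rates, td.Protocol(), 0.0, [], seed=1)
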