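"""Mean-field master-equation solver against independent closed forms."""

import numpy as np
import pytest
from scipy.linalg import expm

import toroidyn as td
from toroidyn.errors import ConfigurationError, TruncationError
from toroidyn.meanfield import MeanFieldState, simulate_ode
from toroidyn.model import RECOVERY_BENCHMARK_RATES


def _only(**kw):
    base = dict(k_open=0, k_close=0, k_nuc=0, k_el=0, k_join=0,
                k_relax_free=0, k_relax_chain=0)
    base.update(kw)
    return td.RateParameters(**base)


def test_all_rates_zero_gives_constant_solution():
    mf0 = MeanFieldState(inactive=10.0, active_closed=5.0, active_open=1.0,
                         c=np.array([0.3, 0.2, 0.1]), n_max=4)
    traj = simulate_ode(mf0, _only(), td.Protocol(), 3.0,
                        record_times=[0, 1.5, 3.0])
    assert np.allclose(traj.Y[0], traj.Y[-1])


def test_relaxation_only_matches_analytic_exponential():
    k = 0.31
    mf0 = MeanFieldState.from_concentration(30.0, active_fraction=1.0, n_max=4)
    rec = np.linspace(0, 10, 21)
    traj = simulate_ode(mf0, _only(k_relax_free=k), td.Protocol(), 10.0,
                        record_times=rec)
    assert np.allclose(traj.active_fraction, np.exp(-k * rec), rtol=1e-5)


def test_elongation_ladder_linear_growth_in_excess_monomer():
    """With a large constant open pool, the mean chain length of the
    elongation ladder grows at rate k_el * m (moment closure)."""
    k_el, o0, c0 = 10.0, 20.0, 0.001
    n_max = 400
    c = np.zeros(n_max - 1)
    c[0] = c0
    mf0 = MeanFieldState(inactive=0, active_closed=0, active_open=o0,
                         c=c, n_max=n_max)
    t = 0.25
    traj = simulate_ode(mf0, _only(k_el=k_el), td.Protocol(), t,
                        record_times=[0, t])
    consumed = o0 - traj.active_open[-1]
    assert consumed / o0 < 0.01  # still in excess
    expected = 2.0 + k_el * o0 * t
    assert traj.mean_length("chains_only")[-1] == pytest.approx(expected, rel=0.02)


def test_scission_kernel_matches_site_enumeration_oracle():
    """Scission-only dynamics are linear; compare against a matrix
    exponential built by explicit enumeration of every scission site."""
    r = 0.7
    n_max = 6
    # state vector: [c2..c6, o, i]
    A = np.zeros((7, 7))
    for n in range(2, n_max + 1):
        row = n - 2
        for site in range(1, n + 1):          # relaxed subunit position
            left, right = site - 1, n - site
            A[row, row] -= r                  # chain n consumed
            A[6, row] += r                    # one inactive released
            for frag in (left, right):
                if frag >= 2:
                    A[frag - 2, row] += r
                elif frag == 1:
                    A[5, row] += r            # open monomer
    y0 = np.zeros(7)
    y0[n_max - 2] = 1.0                        # 1 uM of hexamer chains
    t = 0.8
    expected = expm(A * t) @ y0

    c = np.zeros(n_max - 1)
    c[n_max - 2] = 1.0
    mf0 = MeanFieldState(inactive=0, active_closed=0, active_open=0,
                         c=c, n_max=n_max)
    traj = simulate_ode(mf0, _only(k_relax_chain=r), td.Protocol(), t,
                        record_times=[t], abs_tol=1e-12)
    got = np.concatenate((traj.c[-1], [traj.active_open[-1]], [traj.inactive[-1]]))
    assert np.allclose(got, expected, atol=1e-6)


def test_joining_matches_smoluchowski_constant_kernel():
    """Constant-kernel coagulation: total chain number follows
    C(t) = C0 / (1 + (k/2) C0 t)."""
    kj, c0 = 50.0, 0.4
    n_max = 512
    c = np.zeros(n_max - 1)
    c[0] = c0
    mf0 = MeanFieldState(inactive=0, active_closed=0, active_open=0,
                         c=c, n_max=n_max)
    rec = np.linspace(0, 1.0, 6)
    traj = simulate_ode(mf0, _only(k_join=kj), td.Protocol(), 1.0,
                        record_times=rec)
    expected = c0 / (1 + 0.5 * kj * c0 * rec)
    assert np.allclose(traj.chain_number, expected, rtol=1e-4)
    # joining conserves mass exactly
    assert np.allclose(traj.chain_mass, 2 * c0, rtol=1e-8)


def test_two_state_stationary_ratio_is_exactly_K():
    p = td.RateParameters(k_open=2.0, k_close=2.0 / td.OPEN_CLOSE_EQUILIBRIUM_K,
                          k_nuc=0, k_el=0, k_join=0,
                          k_relax_free=0, k_relax_chain=0)
    mf0 = MeanFieldState.from_concentration(30.0, active_fraction=1.0, n_max=4)
    traj = simulate_ode(mf0, p, td.Protocol(), 5.0, record_times=[5.0],
                        rel_tol=1e-10, abs_tol=1e-12)
    ratio = traj.active_open[-1] / traj.active_closed[-1]
    assert ratio == pytest.approx(td.OPEN_CLOSE_EQUILIBRIUM_K, rel=1e-6)


def test_truncation_leak_raises_loudly():
    p = _only(k_el=500.0)
    n_max = 8
    c = np.zeros(n_max - 1)
    c[0] = 1.0
    mf0 = MeanFieldState(inactive=0, active_closed=0, active_open=20.0,
                         c=c, n_max=n_max)
    with pytest.raises(TruncationError, match="n_max"):
        simulate_ode(mf0, p, td.Protocol(), 2.0, record_times=[2.0])


def test_heat_pulse_event_moves_inactive_pool():
    mf0 = MeanFieldState.from_concentration(30.0, 0.0, n_max=4)
    p = _only()
    p = p.replace(activation_efficiency=0.6)
    traj = simulate_ode(mf0, p, td.single_fuel(0.0), 1.0, record_times=[0.0, 1.0])
    assert traj.active_closed[0] == pytest.approx(18.0)
    assert traj.inactive[0] == pytest.approx(12.0)


def test_conservation_on_benchmark_condition():
    mf0 = MeanFieldState.from_concentration(30.0, 0.0, n_max=500)
    traj = simulate_ode(mf0, RECOVERY_BENCHMARK_RATES, td.single_fuel(0.0),
                        12.0, record_times=np.linspace(0, 12, 13),
                        method="LSODA")
    drift = np.ptp(traj.total_units) / 30.0
    assert drift < 1e-6


class TestCrosscheck:
    def test_frozen_system_has_zero_discrepancy(self, zero_rates, small_state):
        rep = td.crosscheck_with_ssa(small_state, zero_rates, td.Protocol(),
                                     2.0, [1.0, 2.0], n_reps=5, seed_base=1,
                                     n_max=40)
        assert rep.attrs["passed"]
        assert np.allclose(rep["z"], 0.0)

    def test_mismatched_engines_fail(self):
        """Negative control: compare SSA at one k_el against the ODE at a
        deliberately different k_el."""
        p_ssa = RECOVERY_BENCHMARK_RATES
        init = td.SystemState.from_concentration(30.0, 5000)
        rec = np.linspace(0.5, 4.0, 8)
        ens = td.run_ensemble(8, 2, init, p_ssa, td.single_fuel(0.0), 4.0, rec)
        summ = ens.summary()
        mf0 = MeanFieldState.from_system_state(init, n_max=500)
        wrong = p_ssa.replace(k_el=p_ssa.k_el * 3)
        traj = simulate_ode(mf0, wrong, td.single_fuel(0.0), 4.0,
                            record_times=rec, method="LSODA")
        z = (summ["mean_length_all_mean"].to_numpy()
             - traj.mean_length("all_assemblies")) \
            / (summ["mean_length_all_sd"].to_numpy() / np.sqrt(8))
        assert np.max(np.abs(z)) > 3.0
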