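"""Calibration model: objective properties, self-consistency, nesting."""

import numpy as np
import pandas as pd
import pytest

import toroidyn as td
from toroidyn.errors import ConfigurationError
from toroidyn.model import (
    RECOVERY_BENCHMARK_RATES,
    HelicalPolymerizationModel,
)

TIMES = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0])

_FAST = dict(n_max=500, ode_method="LSODA", rel_tol=1e-6, abs_tol=1e-10,
             mean_length_mode="chains_only")


def _noiseless_data(params=RECOVERY_BENCHMARK_RATES, times=TIMES):
    probe = HelicalPolymerizationModel(
        pd.DataFrame({"time_days": times, "mean_length_nm": np.ones_like(times)}),
        params_init=params, **_FAST)
    truth = probe.predict(params, times=times)
    return pd.DataFrame({
        "time_days": times,
        "mean_length_nm": truth["mean_length_nm"],
        "cd_signal": truth["cd_signal"],
    })


@pytest.fixture(scope="module")
def benchmark_data():
    return _noiseless_data()


def test_loss_invariant_to_row_order(benchmark_data):
    shuffled = benchmark_data.sample(frac=1.0, random_state=1)
    m1 = HelicalPolymerizationModel(benchmark_data, params_init=RECOVERY_BENCHMARK_RATES,
                                    free=("k_el",), **_FAST)
    m2 = HelicalPolymerizationModel(shuffled, params_init=RECOVERY_BENCHMARK_RATES,
                                    free=("k_el",), **_FAST)
    th = m1._theta_from_params(RECOVERY_BENCHMARK_RATES.replace(k_el=700.0))
    assert np.sum(m1._residuals(th) ** 2) == pytest.approx(
        np.sum(m2._residuals(th) ** 2), rel=1e-12)


def test_all_weights_zero_is_flagged_degenerate(benchmark_data):
    m = HelicalPolymerizationModel(
        benchmark_data, params_init=RECOVERY_BENCHMARK_RATES,
        loss_weights={"mean_length": 0.0, "cd": 0.0}, **_FAST)
    res = m.fit()
    assert res.degenerate
    assert not res.converged
    assert res.loss == 0.0


def test_k_close_cannot_be_freed(benchmark_data):
    with pytest.raises(ConfigurationError, match="k_close"):
        HelicalPolymerizationModel(benchmark_data, free=("k_close",), **_FAST)


def test_fixed_mask_reports_pinned_ratio(benchmark_data):
    m = HelicalPolymerizationModel(benchmark_data, free=("k_el",), **_FAST)
    res = m.fit(max_nfev=1)
    assert "k_close" in res.fixed
    assert "k_open" in res.fixed
    assert res.free == ("k_el",)
    # the ratio constraint holds on the estimates
    assert res.params.open_close_K == pytest.approx(td.OPEN_CLOSE_EQUILIBRIUM_K)


def test_noiseless_self_consistency_recovers_within_5_percent(benchmark_data):
    """Fitting model-generated data from known rates is the calibration
    oracle: the free parameters must come back within 5%."""
    truth = RECOVERY_BENCHMARK_RATES
    start = truth.replace(k_el=truth.k_el * 1.4,
                          k_relax_chain=truth.k_relax_chain * 0.7)
    m = HelicalPolymerizationModel(benchmark_data, params_init=truth,
                                   free=("k_el", "k_relax_chain"), **_FAST)
    res = m.fit(start=start, xtol=1e-8, ftol=1e-10)
    assert res.converged
    for name in res.free:
        est, tr = getattr(res.params, name), getattr(truth, name)
        assert est == pytest.approx(tr, rel=0.05)


def test_forced_noncooperative_fit_is_visibly_worse(benchmark_data):
    """On lag-phase data, forcing k_nuc = k_el (no cooperativity) cannot
    match the curve even with the elongation rate free."""
    truth = RECOVERY_BENCHMARK_RATES
    m_coop = HelicalPolymerizationModel(benchmark_data, params_init=truth,
                                        free=("k_el",), **_FAST)
    loss_coop = m_coop.fit(xtol=1e-8).loss
    noncoop_init = truth.replace(k_nuc=truth.k_el)
    m_flat = HelicalPolymerizationModel(benchmark_data, params_init=noncoop_init,
                                        free=("k_el",), **_FAST)
    loss_flat = m_flat.fit(xtol=1e-8).loss
    assert loss_flat > 10 * max(loss_coop, 1e-8)


def test_conf_int_brackets_estimates(benchmark_data):
    rng = np.random.default_rng(2)
    noisy = benchmark_data.copy()
    noisy["mean_length_nm"] *= 1 + 0.05 * rng.standard_normal(len(noisy))
    m = HelicalPolymerizationModel(noisy, params_init=RECOVERY_BENCHMARK_RATES,
                                   free=("k_el",), **_FAST)
    res = m.fit(xtol=1e-7)
    ci = res.conf_int()
    assert (ci["ci_low"] <= ci["estimate"]).all()
    assert (ci["estimate"] <= ci["ci_high"]).all()


def test_default_calibration_regression_lock():
    """Refitting the shipped default-calibration dataset from a perturbed
    start reproduces the shipped default rates within 1%."""
    from toroidyn.model import default_calibration_dataset

    data = default_calibration_dataset()
    p = td.DEFAULT_RATES
    m = HelicalPolymerizationModel(data, params_init=p,
                                   free=("k_el", "k_relax_chain"),
                                   n_max=3000, rel_tol=1e-5, abs_tol=1e-9)
    start = p.replace(k_el=p.k_el * 1.2, k_relax_chain=p.k_relax_chain * 0.85)
    res = m.fit(start=start, xtol=3e-7, ftol=1e-12)
    assert res.converged
    for name in res.free:
        est, tr = getattr(res.params, name), getattr(p, name)
        assert abs(est - tr) / tr < 0.01
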