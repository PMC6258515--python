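"""The statistic, critical values, pseudo-p, the test decision, and the k-scan."""

import numpy as np
import pytest

from smaup import (
    compute_components,
    critical_value,
    k_scan,
    pseudo_p,
    rook_lattice,
    simulate_sar,
    smaup_statistic,
    smaup_test,
)
from smaup.core import NoSafeAggregationError, NullDistribution, TAU_ROOT


def test_components_limits():
    c = compute_components(1e-12)
    assert c.L == pytest.approx(1 / (1 + np.exp(-2.188)), abs=1e-6)
    assert c.eta == pytest.approx(0.0, abs=1e-9)
    assert c.tau == pytest.approx(5.319, abs=1e-9)
    c = compute_components(1.0)
    assert c.L == pytest.approx(0.00782, abs=5e-6)
    assert c.eta == pytest.approx(0.516)
    assert c.tau == pytest.approx(-0.213)
    for bad in (0.0, -0.2, 1.1):
        with pytest.raises(ValueError):
            compute_components(bad)


def test_statistic_spot_values():
    assert smaup_statistic(0.0, 0.4) == pytest.approx(0.30102, abs=5e-5)
    assert smaup_statistic(0.9, 0.9) == pytest.approx(0.00972, abs=5e-5)
    assert smaup_statistic(-0.9, 0.1) == pytest.approx(0.81501, abs=5e-5)
    with pytest.raises(ValueError):
        smaup_statistic(1.0, 0.5)
    with pytest.raises(ValueError):
        smaup_statistic(0.0, 0.0)


def test_critical_value_lookup_and_interpolation():
    assert critical_value(-0.9, 25, 0.01)[0] == 0.83702
    assert critical_value(0.9, 900, 0.1)[0] == 0.22411
    v, policy = critical_value(0.15, 400, 0.05)
    assert v == pytest.approx(0.08364, abs=1e-5)
    assert "interpolation" in policy
    # conservative mode takes the larger bracketing cell
    v, policy = critical_value(0.15, 400, 0.05, policy="conservative")
    assert v == 0.09766 and "conservative" in policy
    # nearest table N
    v, policy = critical_value(0.0, 110, 0.05)
    assert v == 0.15746 and "N=100" in policy
    # rho beyond the table clamps to the boundary row
    v, policy = critical_value(0.95, 900, 0.05)
    assert v == 0.31424
    with pytest.raises(ValueError):
        critical_value(0.0, 100, alpha=0.2)


def test_pseudo_p():
    null = NullDistribution(4, 0.0, np.array([0.1, 0.2, 0.3, 0.4]))
    assert pseudo_p(0.25, null) == 0.5
    assert pseudo_p(0.9, null) == 0.0
    assert pseudo_p(0.0, null) == 1.0
    with pytest.raises(ValueError):
        pseudo_p(0.5, np.array([]))


def test_test_rejects_uncorrelated_variable_at_moderate_aggregation():
    # N ~ 1000 areas of white noise aggregated to theta ~ 0.4: the
    # distribution cannot survive, and M(0, 0.4) ~ 0.30 far exceeds every
    # alpha = 0.05 critical value at large N
    w = rook_lattice(32, 32)
    y = simulate_sar(w, 0.0, seed=3)
    res = smaup_test(y, w, k=410)
    assert abs(res.rho_hat) < 0.15
    assert res.reject


def test_test_accepts_highly_autocorrelated_variable():
    # rho ~ 0.8, N = 150, k = 90: high positive autocorrelation tolerates
    # aggregation; the test must not reject
    w = rook_lattice(10, 15)
    y = simulate_sar(w, 0.8, seed=6)
    res = smaup_test(y, w, k=90)
    assert res.rho_hat > 0.5
    assert not res.reject


def test_minimal_aggregation_never_rejects():
    # theta = 1 - 1/N: M < L(1) ~ 0.0078, below the smallest tabulated
    # alpha = 0.05 critical value (0.02423)
    for rho in (-0.9, -0.5, 0.0, 0.5, 0.9):
        for n in (25, 100, 900):
            assert smaup_statistic(rho, 1 - 1 / n) < 0.008
    assert smaup_statistic(0.0, 1 - 1 / 900) < 0.02423


def test_test_validates_k(lat55):
    y = simulate_sar(lat55, 0.0, seed=0)
    with pytest.raises(ValueError):
        smaup_test(y, lat55, k=25)


def test_pseudo_p_attached_when_null_supplied(lat1010):
    y = simulate_sar(lat1010, 0.0, seed=2)
    null = NullDistribution(100, 0.0, np.linspace(0.01, 0.5, 100))
    res = smaup_test(y, lat1010, k=20, null=null)
    assert res.pseudo_p == pytest.approx(np.mean(null.m_values > res.M))


# -- k-scan ----------------------------------------------------------------


def brute_force_min_k(y, w, k_grid, alpha=0.05):
    for k in k_grid:
        if not smaup_test(y, w, k, alpha=alpha).reject:
            return k
    return None


def test_k_scan_matches_brute_force(lat1010):
    y = simulate_sar(lat1010, 0.3, seed=9)
    grid = list(range(20, 100, 10))
    res = k_scan(y, lat1010, grid)
    assert res.k_safe == brute_force_min_k(y, lat1010, grid)
    assert set(res.table["k"]) == set(grid)


def test_k_scan_high_rho_low_aggregation(lat1010):
    y = simulate_sar(lat1010, 0.9, seed=1)
    grid = [90, 95, 99]
    res = k_scan(y, lat1010, grid)
    assert res.k_safe == 90  # nothing rejects near k = N


def test_k_scan_two_variables_takes_max(lat1010):
    y1 = simulate_sar(lat1010, 0.9, seed=1)
    y2 = simulate_sar(lat1010, 0.0, seed=2)
    grid = list(range(10, 100, 5))
    single = [k_scan(y, lat1010, grid).k_safe for y in (y1, y2)]
    combined = k_scan([y1, y2], lat1010, grid)
    assert combined.k_safe == max(single)
    assert sorted(combined.per_variable) == ["y0", "y1"]


def test_k_scan_no_safe_k(lat1010):
    y = simulate_sar(lat1010, 0.0, seed=2)
    with pytest.raises(NoSafeAggregationError) as exc:
        k_scan(y, lat1010, [5, 10, 15])
    assert not exc.value.scan_table.empty


def test_k_scan_rejects_unsorted_grid(lat1010):
    y = simulate_sar(lat1010, 0.0, seed=2)
    with pytest.raises(ValueError):
        k_scan(y, lat1010, [30, 10])


def test_tau_sign_change_location():
    assert TAU_ROOT == pytest.approx(0.96151, abs=1e-4)
    assert compute_components(TAU_ROOT - 0.01).tau > 0
    assert compute_components(TAU_ROOT + 0.01).tau < 0
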