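"""SAR generation, Moran's I, ML rho estimation, rank-matching redistribution."""

import numpy as np
import pytest

from smaup import (
    estimate_rho_ml,
    moran_i,
    rank_match,
    retarget_rho,
    rook_lattice,
    simulate_sar,
)
from smaup.sar import ConstantVariableError, StabilityError, _loglik_terms, _concentrated_loglik


def test_rho_zero_returns_noise_exactly(lat1010):
    y = simulate_sar(lat1010, 0.0, seed=5)
    eps = np.random.default_rng(5).standard_normal(100)
    assert np.allclose(y.values, eps, rtol=0, atol=1e-13)


def test_determinism_and_seed_sensitivity(lat1010):
    a = simulate_sar(lat1010, 0.6, seed=7)
    b = simulate_sar(lat1010, 0.6, seed=7)
    c = simulate_sar(lat1010, 0.6, seed=8)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


@pytest.mark.parametrize("rho", [1.0, -1.0, 1.3])
def test_stability_error(lat1010, rho):
    with pytest.raises(StabilityError):
        simulate_sar(lat1010, rho, seed=0)


def test_simulated_mean_is_centered(lat1010):
    draws = simulate_sar(lat1010, 0.5, seed=11, n_draws=1000)
    stacked = np.stack([d.values for d in draws])
    assert np.max(np.abs(stacked.mean(axis=0))) < 0.15


def test_moran_checkerboard_is_minus_one():
    w = rook_lattice(2, 2)
    assert moran_i(np.array([1.0, -1.0, -1.0, 1.0]), w) == pytest.approx(-1.0)


def test_moran_constant_errors(lat55):
    with pytest.raises(ConstantVariableError):
        moran_i(np.ones(25), lat55)


def test_moran_iid_expectation(lat3030):
    # randomization expectation of Moran's I is -1/(n-1)
    rng = np.random.default_rng(3)
    vals = [moran_i(rng.standard_normal(900), lat3030) for _ in range(200)]
    assert np.mean(vals) == pytest.approx(-1 / 899, abs=0.01)


def test_moran_increases_with_rho(lat3030):
    from scipy.stats import spearmanr

    rhos = np.arange(-0.9, 0.91, 0.2)
    med = []
    for rho in rhos:
        draws = simulate_sar(lat3030, rho, seed=100, n_draws=30)
        med.append(np.median([moran_i(d, lat3030) for d in draws]))
    assert spearmanr(rhos, med).statistic > 0.9


def test_sar_high_rho_has_high_moran(lat3030):
    hits = sum(
        moran_i(simulate_sar(lat3030, 0.9, seed=s), lat3030) > 0.4
        for s in range(100)
    )
    assert hits >= 95


def test_ml_recovery(lat3030):
    hats = [
        estimate_rho_ml(simulate_sar(lat3030, 0.9, seed=s), lat3030).rho_hat
        for s in range(100)
    ]
    assert sum(0.8 < h < 0.97 for h in hats) >= 90


def test_ml_near_zero_for_noise(lat3030):
    rng = np.random.default_rng(17)
    hats = [
        estimate_rho_ml(rng.standard_normal(900), lat3030).rho_hat
        for _ in range(100)
    ]
    assert sum(abs(h) < 0.1 for h in hats) >= 90


def test_ml_errors(lat55):
    with pytest.raises(ConstantVariableError):
        estimate_rho_ml(np.full(25, 3.0), lat55)
    with pytest.raises(ValueError):
        estimate_rho_ml(np.arange(24), lat55)  # length mismatch


def test_ml_dominates_likelihood_grid(lat1010):
    y = simulate_sar(lat1010, 0.5, seed=2)
    res = estimate_rho_ml(y, lat1010)
    eigs, yy, ywy, wywy = _loglik_terms(y.values, lat1010)
    grid = np.arange(-0.99, 0.99, 1e-3)
    lls = [_concentrated_loglik(r, eigs, yy, ywy, wywy, 100) for r in grid]
    assert res.log_likelihood >= max(lls) - 1e-9


def test_rank_match_example():
    out = rank_match(np.array([5.0, 1.0, 9.0]), np.array([0.2, 0.9, 0.5]))
    assert np.array_equal(out, [1.0, 9.0, 5.0])


def test_retarget_preserves_multiset_and_hits_target(lat1010):
    y = simulate_sar(lat1010, 0.9, seed=4)
    for rho_t in (-0.5, 0.0, 0.5):
        out = retarget_rho(y, lat1010, rho_t, seed=9)
        assert np.array_equal(np.sort(out.values), np.sort(y.values))
        assert out.mean == pytest.approx(y.mean)
        assert out.variance == pytest.approx(y.variance)
        assert abs(out.provenance["rho_hat"] - rho_t) <= 0.1


def test_retarget_failure_reports_best_gap(lat55):
    y = simulate_sar(lat55, 0.9, seed=1)
    from smaup.sar import RetargetError

    with pytest.raises(RetargetError) as exc:
        retarget_rho(y, lat55, -0.9, tol=0.001, max_attempts=3, seed=0)
    assert exc.value.best_gap > 0.001
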