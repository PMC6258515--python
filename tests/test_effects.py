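"""Effect metrics (RCM/RCV), variance/mean tests, and the experiment grid."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from smaup import (
    effect_experiment,
    ExperimentConfig,
    levene_test,
    relative_change,
    summarize_effects,
    welch_ttest,
)
from smaup.effects import DegenerateRatioError


# -- independent direct-formula oracles ------------------------------------


def levene_oracle(a, b):
    """Classical Levene statistic, two groups, mean-centered, from scratch."""
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    zbar = np.concatenate([za, zb]).mean()
    ntot = len(a) + len(b)
    between = len(a) * (za.mean() - zbar) ** 2 + len(b) * (zb.mean() - zbar) ** 2
    within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    return (ntot - 2) / (2 - 1) * between / within


def welch_oracle(a, b):
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / np.sqrt(va + vb)


def test_relative_change():
    assert relative_change(10, 9) == pytest.approx(0.1)
    assert relative_change(7.3, 7.3) == 0.0
    assert relative_change(2, 3) == pytest.approx(0.5)
    with pytest.raises(DegenerateRatioError):
        relative_change(0.0, 1.0)
    with pytest.raises(ValueError):
        relative_change(1.0, 1.0, kind="median")


def test_summarize_effects():
    s = summarize_effects([0.0, 0.2], [0.1, 0.3])
    assert s.mean_rcv == pytest.approx(0.2)
    assert s.mean_rcm == pytest.approx(0.1)
    rng = np.random.default_rng(0)
    rcm, rcv = rng.random(30), rng.random(30)
    s = summarize_effects(rcm, rcv)
    assert s.mean_rcm == pytest.approx(rcm.sum() / 30, abs=1e-12)
    assert s.mean_rcv == pytest.approx(rcv.sum() / 30, abs=1e-12)
    with pytest.raises(ValueError):
        summarize_effects([], [])


def test_levene_against_direct_formula(rng):
    for _ in range(100):
        a = rng.standard_normal(rng.integers(3, 40))
        b = rng.standard_normal(rng.integers(3, 40)) * rng.uniform(0.5, 3)
        stat, _ = levene_test(a, b)
        assert stat == pytest.approx(levene_oracle(a, b), abs=1e-10)


def test_levene_toy_and_degenerate():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([1.0, 3.0, 5.0, 7.0])
    stat, _ = levene_test(a, b)
    assert stat == pytest.approx(levene_oracle(a, b), abs=1e-12)
    stat, p = levene_test(a, a)
    assert stat == 0.0 and p == 1.0


def test_levene_detects_scale_difference(rng):
    a = rng.standard_normal(30)
    _, p = levene_test(a, 10 * a)
    assert p < 0.05


def test_welch_against_direct_formula(rng):
    for _ in range(100):
        a = rng.standard_normal(rng.integers(3, 40)) + rng.uniform(-1, 1)
        b = rng.standard_normal(rng.integers(3, 40))
        stat, _ = welch_ttest(a, b)
        assert stat == pytest.approx(welch_oracle(a, b), abs=1e-10)


def test_welch_basics(rng):
    a = rng.standard_normal(50)
    _, p = welch_ttest(a, a)
    assert p == pytest.approx(1.0)
    b = rng.standard_normal(50) + 5
    _, p = welch_ttest(a, b)
    assert p < 1e-6
    stat, p = welch_ttest(np.full(3, 2.0), np.full(4, 2.0))
    assert (stat, p) == (0.0, 1.0)


def test_infeasible_k_rejected():
    with pytest.raises(ValueError):
        ExperimentConfig(n_areas=(25,), k_sets={25: (30,)})


# -- scaled experiment grid ------------------------------------------------


@pytest.fixture(scope="module")
def scaled_run():
    cfg = ExperimentConfig(n_areas=(100,), instances=10, seed=12)
    return effect_experiment(cfg)


def test_rcv_decreases_with_rho(scaled_run):
    med = scaled_run.table.groupby("rho")["mean_rcv"].median()
    assert spearmanr(med.index, med.values).statistic <= -0.8


def test_rcv_decreases_with_k(scaled_run):
    med = scaled_run.table.groupby("k")["mean_rcv"].median()
    assert spearmanr(med.index, med.values).statistic <= -0.8


def test_mean_effect_negligible(scaled_run):
    sub = scaled_run.table[scaled_run.table["k"] >= 10]
    assert sub["mean_rcm"].median() < 0.05


def test_levene_rejections_fall_with_rho_and_k(scaled_run):
    by_rho = scaled_run.table.groupby("rho")["levene_rejections"].mean()
    assert spearmanr(by_rho.index, by_rho.values).statistic < 0
    by_k = scaled_run.table.groupby("k")["levene_rejections"].mean()
    assert spearmanr(by_k.index, by_k.values).statistic < 0
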