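"""MAUP-effect metrics and the simulation grid that measures them.

For an original variable with mean ``mu_o`` and (population) variance
``var_o`` and an aggregated variable with ``mu_ag``, ``var_ag``, the effect
of one aggregation is summarized by the relative changes

    RCM = |mu_o - mu_ag| / mu_o        (effect on the mean)
    RCV = |var_o - var_ag| / var_o     (effect on the variance)

averaged over the ``r`` random aggregations of an instance.  The experiment
grid draws SAR instances across autocorrelation levels (by rank-matching
redistribution of a single high-autocorrelation draw, so every level shares
one value multiset), aggregates each into every ``k`` of a per-N set, and
pools two formal checks: a two-sample t-test of mean equality and a Levene
test of variance equality between the N original and k aggregated values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import fdtrc, stdtr

from .regionalize import batch_aggregate, dissolve_mean
from .sar import RetargetError, retarget_rho, simulate_sar
from .weights import rook_lattice

RHO_GRID = (-0.9, -0.7, -0.5, -0.3, 0.0, 0.3, 0.5, 0.7, 0.9)

#: per-N sets of region counts used by the effect experiment
K_SETS = {
    25: (3, 5, 10, 13, 15, 18, 20, 22, 24),
    100: (2, 4, 7, 12, 25, 40, 53, 67, 80, 90, 99),
    225: (3, 5, 10, 15, 30, 60, 90, 120, 150, 180, 200, 220),
    400: (4, 9, 18, 26, 50, 110, 160, 213, 267, 320, 360, 396),
    625: (4, 6, 14, 27, 43, 80, 170, 250, 333, 417, 500, 563, 618),
    900: (4, 9, 20, 40, 60, 120, 240, 360, 480, 600, 720, 810, 890),
}

LATTICE_SHAPES = {25: (5, 5), 100: (10, 10), 225: (15, 15),
                  400: (20, 20), 625: (25, 25), 900: (30, 30)}


class DegenerateRatioError(ZeroDivisionError):
    """Relative change undefined when the original quantity is zero."""


@dataclass(frozen=True)
class EffectSummary:
    """Per-instance MAUP effect over ``r`` aggregations of N areas into k."""

    rcm_per_rep: np.ndarray
    rcv_per_rep: np.ndarray
    n_areas: int = 0
    k: int = 0
    rho_label: float = float("nan")
    instance: int = 0

    @property
    def mean_rcm(self) -> float:
        return float(np.mean(self.rcm_per_rep))

    @property
    def mean_rcv(self) -> float:
        return float(np.mean(self.rcv_per_rep))


@dataclass
class ExperimentConfig:
    """Parameter grid for the MAUP-effect experiment.

    Defaults reproduce the full design: lattices of N in {25, ..., 900},
    nine autocorrelation levels, 50 instances per level, 30 random
    aggregations per (instance, k).  Scaled-down runs shrink ``instances``,
    never ``replicates``.
    """

    n_areas: tuple[int, ...] = (25, 100, 225, 400, 625, 900)
    k_sets: dict = field(default_factory=lambda: dict(K_SETS))
    rho_grid: tuple[float, ...] = RHO_GRID
    instances: int = 50
    replicates: int = 30
    alpha: float = 0.05
    location: float = 10.0
    t_pool_min_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for n, ks in self.k_sets.items():
            if any(k > n for k in ks):
                raise ValueError(f"k set for N={n} contains k > N")


def relative_change(orig: float, agg: float, kind: str = "mean") -> float:
    """Unsigned relative change ``|orig - agg| / orig``.

    ``kind`` is documentation only ("mean" or "variance"); both use the same
    ratio with the original quantity in the denominator.
    """
    if kind not in ("mean", "variance"):
        raise ValueError("kind must be 'mean' or 'variance'")
    if orig == 0:
        raise DegenerateRatioError(
            f"relative change in {kind} undefined: original {kind} is zero"
        )
    return abs(orig - agg) / orig


def summarize_effects(rcm_per_rep, rcv_per_rep, **meta) -> EffectSummary:
    """Average per-replicate effects into an instance summary."""
    rcm = np.asarray(rcm_per_rep, dtype=float)
    rcv = np.asarray(rcv_per_rep, dtype=float)
    if rcm.size == 0 or rcv.size == 0:
        raise ValueError("effect vectors must be non-empty")
    return EffectSummary(rcm_per_rep=rcm, rcv_per_rep=rcv, **meta)


def levene_test(a, b) -> tuple[float, float]:
    """Levene test of variance equality (classical, mean-centered).

    Returns ``(statistic, p_value)`` from the F(1, n_a + n_b - 2) reference
    distribution.  When both samples have zero spread the statistic is
    degenerate; by convention ``(0.0, 1.0)`` is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    if np.ptp(za) == 0 and np.ptp(zb) == 0 and za.mean() == zb.mean():
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center="mean")
    if np.isnan(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (Satterthwaite df), two-sided.

    Unequal variances are the rule under aggregation, hence Welch rather
    than the pooled-variance form.  Two degenerate equal-mean samples give
    ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


# -- fast inner-loop paths -------------------------------------------------
# The Monte-Carlo engines run these tests hundreds of thousands of times;
# the closed-form evaluations below are algebraically identical to
# levene_test / welch_ttest (asserted in the test suite) but skip the
# per-call overhead of the scipy.stats wrappers.


def _abs_dev_stats(x: np.ndarray) -> tuple[float, float, int]:
    """(mean, centered SS, n) of the absolute deviations |x - xbar|."""
    z = np.abs(x - x.mean())
    zm = float(z.mean())
    return zm, float(((z - zm) ** 2).sum()), x.size


def _levene_p_from_stats(a_stats: tuple[float, float, int], b: np.ndarray) -> float:
    zam, ssa, na = a_stats
    zb = np.abs(b - b.mean())
    zbm = float(zb.mean())
    ssb = float(((zb - zbm) ** 2).sum())
    nb = b.size
    ntot = na + nb
    denom = ssa + ssb
    if denom == 0.0:
        return 1.0
    zm = (na * zam + nb * zbm) / ntot
    w = (ntot - 2) * (na * (zam - zm) ** 2 + nb * (zbm - zm) ** 2) / denom
    return float(fdtrc(1.0, float(ntot - 2), w))


def _welch_p_from_stats(
    a_stats: tuple[float, float, int], b: np.ndarray
) -> float:
    ma, va_n, na = a_stats  # va_n = sample variance / n
    mb = float(b.mean())
    vb_n = float(b.var(ddof=1)) / b.size
    denom = va_n + vb_n
    if denom == 0.0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / np.sqrt(denom)
    df = denom**2 / (va_n**2 / (na - 1) + vb_n**2 / (b.size - 1))
    return float(2.0 * stdtr(df, -abs(t)))


def _welch_a_stats(a: np.ndarray) -> tuple[float, float, int]:
    return float(a.mean()), float(a.var(ddof=1)) / a.size, a.size


def _instance_variables(w, rho_grid, instance_seed, retarget_tol=0.1,
                        max_attempts=100):
    """One value multiset, arranged at every autocorrelation level.

    A single SAR(0.9) draw supplies the values; each other level is obtained
    by rank-matching redistribution accepted at ``|rho_hat - rho| <= tol``,
    which guarantees level-to-level effect differences are not artifacts of
    different value vectors.
    """
    ss = (
        instance_seed
        if isinstance(instance_seed, np.random.SeedSequence)
        else np.random.SeedSequence(instance_seed)
    )
    base_ss, retarget_ss = ss.spawn(2)
    base = simulate_sar(w, 0.9, base_ss)
    rng = np.random.default_rng(retarget_ss)
    out = {}
    for rho in rho_grid:
        if rho == 0.9:
            out[rho] = base
        else:
            out[rho] = retarget_rho(
                base, w, rho, tol=retarget_tol, max_attempts=max_attempts,
                seed=rng,
            )
    return out


def effect_experiment(config: ExperimentConfig) -> "EffectExperimentResult":
    """Run the full effect grid and pool the formal mean/variance checks.

    For every (N, rho, instance): one SAR variable (redistributed to the rho
    label), then for every k in the per-N set, ``replicates`` random
    contiguous aggregations with mean dissolve; RCM/RCV per replicate; the
    Welch t-test (original N values vs aggregated k values) and the Levene
    test per replicate.  The pooled t-test rejection proportion is restricted
    to ``k >= t_pool_min_k``; the Levene pool is unrestricted.

    A constant ``location`` shift (default 10) is applied to the simulated
    values before the mean-based quantities are computed: rates and densities
    are positive, and with a strictly mean-zero variable the RCM denominator
    would be numerically meaningless.  Variance-based quantities are
    location-invariant.
    """
    rows = []
    master = np.random.SeedSequence(config.seed)
    pooled_t = {"rejections": 0, "tests": 0}
    pooled_levene = {"rejections": 0, "tests": 0}
    skipped = []

    for n_areas in config.n_areas:
        shape = LATTICE_SHAPES.get(n_areas)
        if shape is None:
            side = int(round(n_areas ** 0.5))
            if side * side != n_areas:
                raise ValueError(f"N={n_areas} is not a square lattice size")
            shape = (side, side)
        w = rook_lattice(*shape)
        k_set = config.k_sets.get(n_areas, ())
        n_ss = np.random.SeedSequence((config.seed, n_areas))
        inst_seeds = n_ss.spawn(config.instances)
        for inst, inst_ss in enumerate(inst_seeds):
            try:
                variables = _instance_variables(w, config.rho_grid, inst_ss)
            except RetargetError as err:
                skipped.append((n_areas, inst, str(err)))
                continue
            agg_master, = inst_ss.spawn(1)
            for rho in config.rho_grid:
                y = variables[rho]
                shifted = y.values + config.location
                mu_o = float(shifted.mean())
                var_o = float(shifted.var())
                for ik, k in enumerate(k_set):
                    if not (1 <= k <= n_areas):
                        skipped.append((n_areas, k, "infeasible k"))
                        continue
                    aggs = batch_aggregate(
                        w, k,
                        np.random.SeedSequence(
                            (config.seed, n_areas, inst, ik,
                             int(round(rho * 10)) + 10)
                        ),
                        r=config.replicates,
                    )
                    lev_stats = _abs_dev_stats(shifted)
                    t_stats = _welch_a_stats(shifted)
                    rcm, rcv = [], []
                    lev_rej = t_rej = 0
                    for agg in aggs:
                        ag = dissolve_mean(shifted, agg)
                        rcm.append(relative_change(mu_o, ag.mean, "mean"))
                        rcv.append(relative_change(var_o, ag.variance, "variance"))
                        lev_rej += _levene_p_from_stats(lev_stats, ag.values) < config.alpha
                        t_rej += _welch_p_from_stats(t_stats, ag.values) < config.alpha
                    summary = summarize_effects(
                        rcm, rcv, n_areas=n_areas, k=k, rho_label=rho,
                        instance=inst,
                    )
                    pooled_levene["rejections"] += lev_rej
                    pooled_levene["tests"] += config.replicates
                    if k >= config.t_pool_min_k:
                        pooled_t["rejections"] += t_rej
                        pooled_t["tests"] += config.replicates
                    rows.append(
                        {
                            "N": n_areas, "rho": rho, "k": k, "instance": inst,
                            "mean_rcm": summary.mean_rcm,
                            "mean_rcv": summary.mean_rcv,
                            "levene_rejections": lev_rej,
                            "t_rejections": t_rej,
                        }
                    )
    table = pd.DataFrame(rows)
    return EffectExperimentResult(
        table=table,
        t_rejection_proportion=(
            pooled_t["rejections"] / pooled_t["tests"] if pooled_t["tests"] else
            float("nan")
        ),
        levene_rejection_proportion=(
            pooled_levene["rejections"] / pooled_levene["tests"]
            if pooled_levene["tests"] else float("nan")
        ),
        n_t_tests=pooled_t["tests"],
        n_levene_tests=pooled_levene["tests"],
        skipped=skipped,
        config=config,
    )


@dataclass(frozen=True)
class EffectExperimentResult:
    """Long-format effect grid plus pooled rejection proportions."""

    table: pd.DataFrame
    t_rejection_proportion: float
    levene_rejection_proportion: float
    n_t_tests: int
    n_levene_tests: int
    skipped: list
    config: ExperimentConfig
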