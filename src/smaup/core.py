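"""The S-maup statistic, its null distribution, and the decision rule.

S-maup measures how sensitive a spatially intensive areal variable is to the
modifiable areal unit problem when ``N`` areas are aggregated into ``k``
contiguous regions.  With the aggregation level ``theta = k/N`` and the
variable's spatial autocorrelation ``rho``, the statistic is the inverted
logistic

    M(rho, theta) = L(theta) / (1 + eta(theta) * exp(tau(theta) * rho))

    L(theta)   = 1 / (1 + exp(b + m*theta))      b = -2.188,  m = 7.031
    eta(theta) = p * theta**a                    p = 0.516,   a = 1.287
    tau(theta) = beta0 + beta1*theta             beta0 = 5.319, beta1 = -5.532

calibrated on large Monte-Carlo experiments of the median relative change in
variance under random contiguous aggregation.  ``M`` lies in (0, 1): values
near 1 mean the variable's distribution is destroyed by the aggregation,
values near 0 mean it is preserved.  Under the null hypothesis of
non-sensitivity, critical values are the (1 - alpha) percentiles of an
empirical null distribution built by rejection sampling (instances kept only
when a Levene test finds no variance change in any of 30 random
aggregations).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .effects import _abs_dev_stats, _levene_p_from_stats
from .regionalize import dissolve_mean, grow_regions
from .sar import AreaVariable, _as_values, estimate_rho_ml, simulate_sar
from .weights import SpatialWeights, rook_lattice

# calibrated constants of the statistic
B = -2.188
M_SLOPE = 7.031
P = 0.516
A = 1.287
BETA0 = 5.319
BETA1 = -5.532

SUPPORTED_ALPHAS = (0.01, 0.05, 0.1)

#: theta at which tau changes sign: -BETA0 / BETA1
TAU_ROOT = -BETA0 / BETA1


@dataclass(frozen=True)
class SmaupComponents:
    """Aggregation-level components of the statistic at ``theta = k/N``."""

    theta: float
    L: float
    eta: float
    tau: float
    b: float = B
    m: float = M_SLOPE
    p: float = P
    a: float = A
    beta0: float = BETA0
    beta1: float = BETA1


@dataclass(frozen=True)
class SmaupResult:
    """Outcome of the S-maup test for one variable and one aggregation level."""

    rho_hat: float
    n_areas: int
    k: int
    theta: float
    M: float
    alpha: float
    critical_value: float
    reject: bool
    pseudo_p: Optional[float] = None
    critical_value_policy: str = "exact"

    def to_dict(self) -> dict:
        return {
            "rho_hat": self.rho_hat,
            "n_areas": self.n_areas,
            "k": self.k,
            "theta": self.theta,
            "M": self.M,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "critical_value_policy": self.critical_value_policy,
            "pseudo_p": self.pseudo_p,
            "reject": bool(self.reject),
        }


@dataclass(frozen=True)
class NullDistribution:
    """Empirical distribution of M under the no-sensitivity null.

    ``m_values[j]`` is the statistic of the j-th retained instance; every
    retained instance passed all ``r`` Levene non-rejections (recorded in
    ``k_drawn`` / ``attempts`` metadata).
    """

    n_areas: int
    rho_label: float
    m_values: np.ndarray
    seed: Optional[int] = None
    k_drawn: np.ndarray = field(default=None, compare=False)
    acceptance_rate: float = float("nan")

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.m_values, q))

    def critical_value(self, alpha: float) -> float:
        return self.percentile(100.0 * (1.0 - alpha))


def compute_components(theta: float) -> SmaupComponents:
    """Evaluate L, eta, tau at an aggregation level ``theta`` in (0, 1]."""
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    return SmaupComponents(
        theta=float(theta),
        L=1.0 / (1.0 + np.exp(B + M_SLOPE * theta)),
        eta=P * theta ** A,
        tau=BETA0 + BETA1 * theta,
    )


def smaup_statistic(rho: float, theta: float) -> float:
    """S-maup statistic ``M(rho, theta)``; always in (0, L(theta)) ⊂ (0, 1)."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    c = compute_components(theta)
    return c.L / (1.0 + c.eta * np.exp(c.tau * rho))


# -- critical values -------------------------------------------------------

_TABLE_RHOS = (-0.9, -0.7, -0.5, -0.3, 0.0, 0.3, 0.5, 0.7, 0.9)
_TABLE_NS = (25, 100, 225, 400, 625, 900)


def _load_packaged_table() -> pd.DataFrame:
    ref = importlib.resources.files("smaup").joinpath("data/critical_values.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


_TABLE_CACHE: dict = {}


def _critical_grid() -> dict:
    """{(rho, alpha, N): value} from the packaged table."""
    if not _TABLE_CACHE:
        df = _load_packaged_table()
        for row in df.itertuples(index=False):
            _TABLE_CACHE[(round(row.rho, 6), round(row.alpha, 6), int(row.N))] = (
                float(row.value)
            )
    return _TABLE_CACHE


def critical_value(
    rho: float,
    n_areas: int,
    alpha: float = 0.05,
    policy: str = "interpolate",
) -> tuple[float, str]:
    """Critical value ``M_{alpha; rho, N}`` from the packaged table.

    On-grid ``(rho, N)`` pairs are exact lookups.  Off-grid ``rho`` is
    linearly interpolated between the bracketing grid rows (clamped at
    ±0.9); off-grid ``N`` snaps to the nearest grid N, ties toward the
    smaller N.  ``policy='conservative'`` takes the larger of the two
    bracketing rho cells instead of interpolating.  Returns
    ``(value, policy_description)``.
    """
    alpha = round(float(alpha), 6)
    if alpha not in [round(a, 6) for a in SUPPORTED_ALPHAS]:
        raise ValueError(
            f"alpha must be one of {SUPPORTED_ALPHAS}, got {alpha}"
        )
    if policy not in ("interpolate", "conservative"):
        raise ValueError("policy must be 'interpolate' or 'conservative'")
    grid = _critical_grid()

    # nearest table N (ties toward smaller N)
    diffs = [abs(n_areas - n) for n in _TABLE_NS]
    n_grid = _TABLE_NS[int(np.argmin(diffs))]
    n_note = "" if n_grid == n_areas else f", nearest N={n_grid}"

    rho = float(rho)
    rho_c = min(max(rho, _TABLE_RHOS[0]), _TABLE_RHOS[-1])
    clamp_note = "" if rho_c == rho else " (rho clamped to ±0.9)"
    exact = grid.get((round(rho_c, 6), alpha, n_grid))
    if exact is not None:
        desc = ("exact" if not n_note and not clamp_note
                else f"row lookup{n_note}{clamp_note}")
        return exact, desc

    hi_idx = int(np.searchsorted(_TABLE_RHOS, rho_c))
    lo, hi = _TABLE_RHOS[hi_idx - 1], _TABLE_RHOS[hi_idx]
    v_lo = grid[(round(lo, 6), alpha, n_grid)]
    v_hi = grid[(round(hi, 6), alpha, n_grid)]
    if policy == "conservative":
        return max(v_lo, v_hi), f"conservative max of rho∈[{lo},{hi}]{n_note}"
    frac = (rho_c - lo) / (hi - lo)
    return (
        v_lo + frac * (v_hi - v_lo),
        f"linear interpolation rho∈[{lo},{hi}]{n_note}{clamp_note}",
    )


def pseudo_p(m: float, null: NullDistribution | Sequence[float]) -> float:
    """Exceedance fraction of the null: ``P(M) = (1/J) * #{ M_j > M }``."""
    values = (
        null.m_values if isinstance(null, NullDistribution) else
        np.asarray(null, dtype=float)
    )
    if values.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.mean(values > m))


# -- null-distribution generation ------------------------------------------


class NullGenerationError(RuntimeError):
    def __init__(self, msg, n_retained, attempts):
        super().__init__(msg)
        self.n_retained = n_retained
        self.attempts = attempts


def generate_null(
    nrows: int,
    ncols: int,
    rho: float,
    n_instances: int = 1000,
    r: int = 30,
    alpha_levene: float = 0.05,
    seed=0,
    use_estimated_rho: bool = False,
    max_attempts_factor: int = 200,
) -> NullDistribution:
    """Empirical null of M by rejection sampling on a rook lattice.

    Each attempt draws a SAR(rho) variable, draws ``k`` uniformly on the
    integers with ``0.1 N < k < N``, and makes ``r`` random contiguous
    aggregations; the instance is retained only if the Levene test of
    variance equality is *not* rejected (at ``alpha_levene``) in all ``r``
    cases — i.e. the aggregation demonstrably preserved the distribution.
    For retained instances ``M = M(rho, k/N)`` (or with the ML estimate
    ``rho_hat`` when ``use_estimated_rho``).  Fresh ``k`` each attempt.
    """
    w = rook_lattice(nrows, ncols)
    n = w.n
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    k_lo = int(np.floor(0.1 * n)) + 1
    k_hi = n - 1
    if k_lo > k_hi:
        raise ValueError(f"no admissible k for N={n}")

    ss = np.random.SeedSequence(seed)
    sar_ss, k_ss, agg_ss = ss.spawn(3)
    sar_rng = np.random.default_rng(sar_ss)
    k_rng = np.random.default_rng(k_ss)
    agg_rng = np.random.default_rng(agg_ss)

    m_values = np.empty(n_instances)
    k_drawn = np.empty(n_instances, dtype=np.int64)
    retained = 0
    attempts = 0
    budget = max_attempts_factor * n_instances
    while retained < n_instances:
        if attempts >= budget:
            raise NullGenerationError(
                f"attempt budget {budget} exhausted with only {retained} of "
                f"{n_instances} instances retained "
                f"(acceptance rate {retained / attempts:.3f})",
                n_retained=retained,
                attempts=attempts,
            )
        attempts += 1
        y = simulate_sar(w, rho, sar_rng)
        k = int(k_rng.integers(k_lo, k_hi + 1))
        lev_stats = _abs_dev_stats(y.values)
        keep = True
        for _ in range(r):
            ag = dissolve_mean(y, grow_regions(w, k, agg_rng))
            if _levene_p_from_stats(lev_stats, ag.values) < alpha_levene:
                keep = False  # variance changed: not a null instance
                break
        if not keep:
            continue
        rho_used = estimate_rho_ml(y, w).rho_hat if use_estimated_rho else rho
        m_values[retained] = smaup_statistic(rho_used, k / n)
        k_drawn[retained] = k
        retained += 1
    return NullDistribution(
        n_areas=n,
        rho_label=rho,
        m_values=m_values,
        seed=seed if isinstance(seed, int) else None,
        k_drawn=k_drawn,
        acceptance_rate=n_instances / attempts,
    )


# -- the test and the k-scan -----------------------------------------------


def smaup_test(
    y,
    w: SpatialWeights,
    k: int,
    alpha: float = 0.05,
    null: Optional[NullDistribution] = None,
    cv_policy: str = "interpolate",
) -> SmaupResult:
    """Run the S-maup test: is ``y`` sensitive to aggregation into k regions?

    Estimates ``rho_hat`` by ML, evaluates ``M(rho_hat, k/N)``, and rejects
    the null of non-sensitivity when M exceeds the tabulated critical value
    ``M_{alpha; rho_hat, N}``.  A pseudo-p is attached when an empirical
    null distribution is supplied.
    """
    yv = _as_values(y)
    n = w.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    rho_hat = estimate_rho_ml(yv, w).rho_hat
    theta = k / n
    m = smaup_statistic(rho_hat, theta)
    cv, policy = critical_value(rho_hat, n, alpha, policy=cv_policy)
    return SmaupResult(
        rho_hat=rho_hat,
        n_areas=n,
        k=k,
        theta=theta,
        M=m,
        alpha=alpha,
        critical_value=cv,
        reject=m > cv,
        pseudo_p=pseudo_p(m, null) if null is not None else None,
        critical_value_policy=policy,
    )


class NoSafeAggregationError(RuntimeError):
    def __init__(self, msg, scan_table):
        super().__init__(msg)
        self.scan_table = scan_table


@dataclass(frozen=True)
class KScanResult:
    """Scan of the test over a k grid, per variable, plus the headline k."""

    k_safe: int
    per_variable: dict
    table: pd.DataFrame


def k_scan(
    ys,
    w: SpatialWeights,
    k_grid: Sequence[int],
    alpha: float = 0.05,
    cv_policy: str = "interpolate",
) -> KScanResult:
    """Smallest safe number of regions for one or more variables.

    For each variable, the minimum k in the (ascending) grid at which the
    test fails to reject; for several variables the headline answer is the
    maximum of the per-variable minima — the aggregation level at which all
    of them keep their distributional characteristics.
    """
    if isinstance(ys, (AreaVariable, np.ndarray)):
        ys = [ys]
    k_grid = list(k_grid)
    if k_grid != sorted(k_grid):
        raise ValueError("k_grid must be sorted ascending")
    if any(k >= w.n for k in k_grid) or any(k < 1 for k in k_grid):
        raise ValueError(f"all k must be in 1..{w.n - 1}")
    rows = []
    per_variable = {}
    for vi, y in enumerate(ys):
        name = f"y{vi}"
        min_safe = None
        for k in k_grid:
            res = smaup_test(y, w, k, alpha=alpha, cv_policy=cv_policy)
            rows.append(
                {
                    "variable": name, "k": k, "rho_hat": res.rho_hat,
                    "M": res.M, "critical_value": res.critical_value,
                    "reject": res.reject,
                }
            )
            if not res.reject and min_safe is None:
                min_safe = k
        per_variable[name] = min_safe
    table = pd.DataFrame(rows)
    if any(v is None for v in per_variable.values()):
        bad = [k for k, v in per_variable.items() if v is None]
        raise NoSafeAggregationError(
            f"test rejects at every k in the grid for variable(s) {bad}", table
        )
    return KScanResult(
        k_safe=max(per_variable.values()),
        per_variable=per_variable,
        table=table,
    )
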