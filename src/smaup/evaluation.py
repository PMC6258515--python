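"""Power, size, and calibration experiments for the S-maup test.

Power: probability of rejecting the null of non-sensitivity when a variable
demonstrably *is* sensitive — an instance enters the experiment only when
the Levene variance-equality test rejects for every one of the 30 random
aggregations at its drawn k.  Size: the complementary rejection-sampling
rule (all 30 non-rejections) measures the type-I error against the
tabulated critical values.  Both default to the generator's rho label for
the statistic and the critical-value row, matching how the reference tables
are indexed; ``use_estimated_rho=True`` switches to the ML estimate.

``fit_components`` re-runs the calibration pipeline that produced the
statistic's six constants from a grid of median relative-variance-change
effects, at whatever scale the input grid provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .core import critical_value, smaup_statistic
from .effects import (  # noqa: F401  (ExperimentConfig re-exported here)
    ExperimentConfig,
    _abs_dev_stats,
    _levene_p_from_stats,
)
from .regionalize import dissolve_mean, grow_regions
from .sar import estimate_rho_ml, simulate_sar
from .weights import rook_lattice


@dataclass(frozen=True)
class RejectionExperimentResult:
    """Outcome of a power or size run at one (N, rho) cell."""

    proportion: float
    n_instances: int
    n_areas: int
    rho: float
    alpha: float
    critical_value: float
    acceptance_rate: float
    seed: int
    kind: str


def _rejection_experiment(
    nrows: int,
    ncols: int,
    rho: float,
    n_instances: int,
    alpha: float,
    seed,
    select_h1: bool,
    r: int = 30,
    alpha_levene: float = 0.05,
    use_estimated_rho: bool = False,
    max_attempts_factor: int = 500,
    cv_override: float | None = None,
) -> RejectionExperimentResult:
    """Shared rejection-sampling engine behind power and size.

    ``select_h1=True`` keeps instances where all ``r`` Levene tests reject
    (variance demonstrably changed: the alternative is true);
    ``select_h1=False`` keeps instances where none rejects (the null is
    true).  The Levene loop short-circuits on the first disqualifying
    outcome.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    w = rook_lattice(nrows, ncols)
    n = w.n
    k_lo = int(np.floor(0.1 * n)) + 1
    k_hi = n - 1

    ss = np.random.SeedSequence(seed)
    sar_ss, k_ss, agg_ss = ss.spawn(3)
    sar_rng = np.random.default_rng(sar_ss)
    k_rng = np.random.default_rng(k_ss)
    agg_rng = np.random.default_rng(agg_ss)

    if cv_override is not None:
        cv = float(cv_override)
    else:
        cv, _ = critical_value(rho, n, alpha)
    rejected = 0
    retained = 0
    attempts = 0
    budget = max_attempts_factor * n_instances
    while retained < n_instances:
        if attempts >= budget:
            raise RuntimeError(
                f"attempt budget {budget} exhausted: retained {retained} of "
                f"{n_instances} (acceptance {retained / max(attempts, 1):.4f})"
            )
        attempts += 1
        y = simulate_sar(w, rho, sar_rng)
        k = int(k_rng.integers(k_lo, k_hi + 1))
        lev_stats = _abs_dev_stats(y.values)
        keep = True
        for _ in range(r):
            ag = dissolve_mean(y, grow_regions(w, k, agg_rng))
            levene_rejects = _levene_p_from_stats(lev_stats, ag.values) < alpha_levene
            if levene_rejects != select_h1:
                keep = False
                break
        if not keep:
            continue
        retained += 1
        rho_used = estimate_rho_ml(y, w).rho_hat if use_estimated_rho else rho
        if use_estimated_rho:
            cv_i, _ = critical_value(rho_used, n, alpha)
        else:
            cv_i = cv
        if smaup_statistic(rho_used, k / n) > cv_i:
            rejected += 1
    return RejectionExperimentResult(
        proportion=rejected / n_instances,
        n_instances=n_instances,
        n_areas=n,
        rho=rho,
        alpha=alpha,
        critical_value=cv,
        acceptance_rate=n_instances / attempts,
        seed=seed if isinstance(seed, int) else -1,
        kind="power" if select_h1 else "size",
    )


def power_experiment(
    nrows: int,
    ncols: int,
    rho: float,
    n_instances: int = 1000,
    alpha: float = 0.05,
    seed=0,
    **kwargs,
) -> RejectionExperimentResult:
    """Estimated power at one (N, rho) cell (H1-selected instances)."""
    return _rejection_experiment(
        nrows, ncols, rho, n_instances, alpha, seed, select_h1=True, **kwargs
    )


def size_experiment(
    nrows: int,
    ncols: int,
    rho: float,
    n_instances: int = 1000,
    alpha: float = 0.05,
    seed=0,
    **kwargs,
) -> RejectionExperimentResult:
    """Estimated size at one (N, rho) cell (H0-selected instances)."""
    return _rejection_experiment(
        nrows, ncols, rho, n_instances, alpha, seed, select_h1=False, **kwargs
    )


# -- calibration of the statistic's constants ------------------------------


@dataclass(frozen=True)
class FittedComponents:
    """Constants recovered by the calibration pipeline, with diagnostics."""

    b: float
    m: float
    p: float
    a: float
    beta0: float
    beta1: float
    r2_logistic: float
    r2_power: float
    r2_linear: float
    per_theta: pd.DataFrame


def _robust_linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Huber-weighted IRLS line fit; returns (intercept, slope, R^2)."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.RLM(np.asarray(y, dtype=float), X, M=sm.robust.norms.HuberT()).fit()
    resid = y - fit.fittedvalues
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return float(fit.params[0]), float(fit.params[1]), r2


def fit_components(effect_medians: pd.DataFrame) -> FittedComponents:
    """Recover (b, m, p, a, beta0, beta1) from median effect curves.

    ``effect_medians`` is a long table with columns ``rho``, ``theta``,
    ``median_rcv`` covering at least 5 theta values and the full rho grid.
    Pipeline: (1) per-theta nonlinear least-squares fit of the inverted
    logistic ``L / (1 + eta * exp(tau * rho))`` (L initialized at the curve
    maximum — the observed maximum itself underestimates the asymptote
    whenever the curve has not plateaued at the most negative rho, so L is
    estimated rather than read off); (2) robust linear fit of the logit
    ``ln((1-L)/L) = b + m*theta``; (3) log-log robust fit
    ``ln eta = ln p + a ln theta``; (4) robust linear fit
    ``tau = beta0 + beta1*theta``.  Exact in the noiseless limit.
    """
    df = pd.DataFrame(effect_medians)
    required = {"rho", "theta", "median_rcv"}
    if not required.issubset(df.columns):
        raise ValueError(f"effect_medians needs columns {sorted(required)}")
    thetas = np.sort(df["theta"].unique())
    if thetas.size < 5:
        raise ValueError("need medians at >= 5 theta values")

    rows = []
    for theta in thetas:
        sub = df[df["theta"] == theta].sort_values("rho")
        rho = sub["rho"].to_numpy(dtype=float)
        med = sub["median_rcv"].to_numpy(dtype=float)
        if rho.size < 4:
            raise ValueError(f"need >= 4 rho points per theta (theta={theta})")
        l0 = float(med.max())
        # eta, tau initial guesses from the calibrated-constant shapes
        p0 = (l0, 0.5 * theta, 5.0 * (1.0 - theta))
        popt, _ = curve_fit(
            lambda r, L, eta, tau: L / (1.0 + eta * np.exp(tau * r)),
            rho,
            med,
            p0=p0,
            bounds=([1e-8, 1e-8, -50.0], [1.0, 50.0, 50.0]),
            maxfev=50000,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        rows.append(
            {"theta": float(theta), "L": popt[0], "eta": popt[1], "tau": popt[2]}
        )
    per_theta = pd.DataFrame(rows)

    th = per_theta["theta"].to_numpy()
    b, m, r2_log = _robust_linfit(
        th, np.log((1.0 - per_theta["L"]) / per_theta["L"])
    )
    ln_p, a, r2_pow = _robust_linfit(np.log(th), np.log(per_theta["eta"]))
    beta0, beta1, r2_lin = _robust_linfit(th, per_theta["tau"].to_numpy())
    return FittedComponents(
        b=b,
        m=m,
        p=float(np.exp(ln_p)),
        a=a,
        beta0=beta0,
        beta1=beta1,
        r2_logistic=r2_log,
        r2_power=r2_pow,
        r2_linear=r2_lin,
        per_theta=per_theta,
    )
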