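"""Analytic and simulation-based power for the study's designs.

Paired-t power uses the noncentral t distribution exactly (df = n-1,
noncentrality d*sqrt(n)); TOST power composes the two one-sided noncentral
t tests.  Alpha conventions follow the registered analysis: the two-sided
t-test's total alpha, and for TOST the per-one-sided-test alpha.  The
ordinal-regression power is estimated by simulation: generate confidence
data from the ordered-probit observer across a grid of IM-coefficient
values, fit the random-intercept model, and count Wald-significant
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .ordinal import fit_cumulative_probit
from .simulate import ObserverParams, simulate_confidence_dataset
from .stats import cohens_d_from_t

__all__ = [
    "power_paired_t",
    "required_n_paired_t",
    "sensitivity_d_paired_t",
    "power_tost_paired",
    "required_n_tost_paired",
    "SimPowerResult",
    "simulate_ordinal_power",
]

_MAX_N = 10_000_000


def _nct_cdf(x: float, df: float, ncp: float) -> float:
    """Noncentral-t CDF, with a quadrature fallback where scipy loses it.

    For extreme noncentrality scipy's ``nct`` returns NaN; there
    P(T <= x) = E_S[Phi(x*S - ncp)] with S = sqrt(chi2_df/df) is computed
    by direct integration over the chi density.
    """
    val = float(sps.nct.cdf(x, df, ncp))
    if np.isfinite(val):
        return val
    from scipy.integrate import quad

    rt_df = np.sqrt(df)

    def integrand(c):  # c ~ chi(df); S = c / sqrt(df)
        return sps.norm.cdf(x * c / rt_df - ncp) * sps.chi.pdf(c, df)

    out, _ = quad(integrand, 0.0, rt_df * 40.0, limit=200)
    return float(min(max(out, 0.0), 1.0))


def power_paired_t(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a paired t-test at ``n`` pairs against standardized effect ``d``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    d = abs(d)
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 2:
        tc = sps.t.ppf(1 - alpha / 2, df)
        return float(1.0 - _nct_cdf(tc, df, ncp) + _nct_cdf(-tc, df, ncp))
    if tails == 1:
        tc = sps.t.ppf(1 - alpha, df)
        return float(1.0 - _nct_cdf(tc, df, ncp))
    raise ValueError("tails must be 1 or 2")


def _smallest_n(predicate, lo: int = 2) -> int:
    """Smallest integer n >= lo with predicate(n) true (predicate monotone)."""
    hi = max(lo, 4)
    while not predicate(hi):
        hi *= 2
        if hi > _MAX_N:
            raise ValueError("required sample size exceeds 10^7; no solution")
    lo_b = lo
    while lo_b < hi:
        mid = (lo_b + hi) // 2
        if predicate(mid):
            hi = mid
        else:
            lo_b = mid + 1
    return lo_b


def required_n_paired_t(
    d: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2
) -> int:
    """Smallest n whose paired-t power reaches ``power``."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if abs(d) <= 0:
        raise ValueError("d = 0: requested power unattainable at any n")
    return _smallest_n(lambda n: power_paired_t(n, d, alpha, tails) >= power)


def sensitivity_d_paired_t(
    n: int, alpha: float = 0.05, power: float = 0.33, tails: int = 2
) -> float:
    """Standardized effect detectable with the requested power at ``n`` pairs."""
    if power <= alpha:
        raise ValueError("power at or below alpha has no positive solution in d")
    return float(
        optimize.brentq(
            lambda d: power_paired_t(n, d, alpha, tails) - power, 1e-12, 20.0,
            xtol=1e-12,
        )
    )


def power_tost_paired(
    n: int,
    lower: float,
    upper: float,
    alpha: float = 0.05,
    true_diff: float = 0.0,
    sd_diff: float | None = None,
) -> float:
    """Power of the paired TOST equivalence test.

    With ``sd_diff`` given, bounds and ``true_diff`` are raw; without it
    they are standardized (units of the SD of paired differences).  The
    power is P(both one-sided noncentral-t tests reject); a true difference
    outside the bounds simply yields power below alpha.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    sd = 1.0 if sd_diff is None else sd_diff
    df = n - 1
    se = sd / np.sqrt(n)
    ta = sps.t.ppf(1 - alpha, df)
    ncp_lower = (true_diff - lower) / se
    ncp_upper = (true_diff - upper) / se
    p = _nct_cdf(-ta, df, ncp_upper) - _nct_cdf(ta, df, ncp_lower)
    return float(max(p, 0.0))


def required_n_tost_paired(
    lower: float,
    upper: float,
    alpha: float = 0.05,
    power: float = 0.80,
    true_diff: float = 0.0,
    sd_diff: float | None = None,
) -> int:
    """Smallest n whose TOST power reaches ``power`` at the given true difference."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not lower < true_diff < upper:
        raise ValueError("true difference outside the bounds: power cannot reach alpha")
    return _smallest_n(
        lambda n: power_tost_paired(n, lower, upper, alpha, true_diff, sd_diff)
        >= power,
        lo=3,
    )


@dataclass
class SimPowerResult:
    """Simulation-based power curve for the IM coefficient of model 1."""

    beta_grid: np.ndarray
    power_per_beta: np.ndarray
    n_excluded: np.ndarray
    reps: int
    n_subjects: int
    n_trials: int
    alpha: float
    cohens_d_mean: np.ndarray = field(default=None)
    cohens_d_sd: np.ndarray = field(default=None)

    def to_dict(self) -> dict:
        return {
            "beta_grid": self.beta_grid.tolist(),
            "power_per_beta": self.power_per_beta.tolist(),
            "n_excluded": self.n_excluded.tolist(),
            "reps": self.reps,
            "n_subjects": self.n_subjects,
            "n_trials": self.n_trials,
            "alpha": self.alpha,
            "cohens_d_mean": self.cohens_d_mean.tolist(),
            "cohens_d_sd": self.cohens_d_sd.tolist(),
        }


def simulate_ordinal_power(
    beta_grid,
    fixed_params: ObserverParams | None = None,
    n_subjects: int = 101,
    n_trials: int = 400,
    reps: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    n_quad: int = 15,
) -> SimPowerResult:
    """Wald power for the IM coefficient of the random-intercept model.

    For each value in ``beta_grid`` the IM coefficient of the generative
    ordered-probit observer is set to that value (other coefficients stay
    at ``fixed_params``), ``reps`` cohorts are simulated and refitted with
    model 1, and the proportion of replicates with a Wald-significant IM
    coefficient is recorded, along with the d = |z|/sqrt(n) effect sizes.
    Non-converged replicates are dropped and counted.
    """
    if rng is None:
        rng = np.random.default_rng()
    base = fixed_params or ObserverParams(meta_noise_im=0.0, meta_noise_wm=0.0)
    beta_grid = np.asarray(beta_grid, dtype=float)
    power = np.zeros(len(beta_grid))
    excluded = np.zeros(len(beta_grid), dtype=int)
    d_mean = np.zeros(len(beta_grid))
    d_sd = np.zeros(len(beta_grid))
    from dataclasses import replace

    for i, b in enumerate(beta_grid):
        params = replace(base, beta_im=float(b), meta_noise_im=0.0, meta_noise_wm=0.0)
        hits = []
        ds = []
        for _ in range(reps):
            data = simulate_confidence_dataset(
                n_subjects, n_trials, params=params, rng=rng
            )
            try:
                fit = fit_cumulative_probit(data, model="model1", n_quad=n_quad)
            except Exception:
                excluded[i] += 1
                continue
            if not fit.converged:
                excluded[i] += 1
                continue
            z = float(fit.zvalues["IM"])
            hits.append(abs(z) > sps.norm.ppf(1 - alpha / 2))
            ds.append(cohens_d_from_t(z, n_subjects))
        power[i] = np.mean(hits) if hits else np.nan
        d_mean[i] = np.mean(ds) if ds else np.nan
        d_sd[i] = np.std(ds, ddof=1) if len(ds) > 1 else np.nan
    return SimPowerResult(
        beta_grid=beta_grid,
        power_per_beta=power,
        n_excluded=excluded,
        reps=reps,
        n_subjects=n_subjects,
        n_trials=n_trials,
        alpha=alpha,
        cohens_d_mean=d_mean,
        cohens_d_sd=d_sd,
    )
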