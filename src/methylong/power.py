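"""Monte-Carlo power for the two-group candidate-CpG comparison, and
the sample-size multiplier search.

The simulation model is a single CpG's M-value

    M_i = intercept + delta * X_i + sigma * T_i,   T_i ~ t(df),

with X_i = 1 for ART-conceived and 0 for naturally conceived subjects.
``sigma`` multiplies a *standard* Student t draw, so the total noise SD
is sigma * sqrt(df / (df - 2)) (about 0.548 at the defaults sigma=0.49,
df=10).  Each iteration tests H0: delta = 0 with a two-sided Wald test
on the group coefficient of an ordinary least-squares fit — for a
single binary covariate this is exactly the pooled-variance two-sample
z comparison, which is how it is computed here.  The default
significance threshold is the Bonferroni-corrected 0.05 / 25 = 0.002
for the 25-probe candidate family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from methylong.errors import AnalysisError, ConfigurationError

logger = logging.getLogger(__name__)

CANDIDATE_FAMILY_SIZE = 25


def bonferroni_threshold(alpha: float = 0.05,
                         n_tests: int = CANDIDATE_FAMILY_SIZE) -> float:
    """Family-wise per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1 or n_tests < 1:
        raise ConfigurationError("need 0 < alpha < 1 and n_tests >= 1")
    threshold = alpha / n_tests
    logger.info("Bonferroni threshold: %g / %d = %g", alpha, n_tests, threshold)
    return threshold


@dataclass(frozen=True)
class PowerSpec:
    """Parameters of the Monte-Carlo power simulation."""

    n_natural: int
    n_art: int
    intercept: float = 1.2
    delta: float = 0.13
    sigma: float = 0.49
    df: float = 10.0
    alpha: float = 0.05 / CANDIDATE_FAMILY_SIZE
    n_iter: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.df <= 2:
            raise ConfigurationError("df must exceed 2 (finite noise variance)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_natural < 2 or self.n_art < 2:
            raise ConfigurationError("both group sizes must be >= 2")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")

    @property
    def noise_sd(self) -> float:
        """Total noise SD: sigma * sqrt(df / (df - 2))."""
        return self.sigma * math.sqrt(self.df / (self.df - 2.0))


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo output: rejection fraction and its binomial SE."""

    power: float
    mc_se: float
    n_rejections: int
    spec: PowerSpec


def analytic_power(spec: PowerSpec) -> float:
    """Large-sample normal-approximation power (independent oracle for
    the Monte-Carlo estimate)."""
    se = spec.noise_sd * math.sqrt(1.0 / spec.n_natural + 1.0 / spec.n_art)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    mu = abs(spec.delta) / se
    return float(stats.norm.cdf(mu - z_crit) + stats.norm.cdf(-mu - z_crit))


def simulate_power(spec: PowerSpec,
                   rng: Optional[np.random.Generator] = None) -> PowerResult:
    """Estimate power by Monte-Carlo at the spec's significance level.

    Vectorized over iterations; the Wald statistic per iteration is the
    group-mean difference over the pooled-variance standard error,
    referred to the normal distribution (identical to the OLS Wald test
    of the group coefficient).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_natural, spec.n_art
    n = n1 + n2
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    rejections = 0
    # chunk iterations to bound the (n_iter x n) noise array at ~2e7 cells
    chunk = max(1, int(2e7 // n))
    done = 0
    while done < spec.n_iter:
        k = min(chunk, spec.n_iter - done)
        nat = spec.intercept + spec.sigma * rng.standard_t(spec.df, (k, n1))
        art = (spec.intercept + spec.delta
               + spec.sigma * rng.standard_t(spec.df, (k, n2)))
        diff = art.mean(axis=1) - nat.mean(axis=1)
        ss = (((nat - nat.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              + ((art - art.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
        se = np.sqrt(ss / (n - 2) * (1.0 / n1 + 1.0 / n2))
        rejections += int(np.count_nonzero(np.abs(diff / se) > z_crit))
        done += k
    power = rejections / spec.n_iter
    mc_se = math.sqrt(power * (1.0 - power) / spec.n_iter)
    return PowerResult(power=power, mc_se=mc_se, n_rejections=rejections,
                       spec=spec)


def required_multiplier(
    base_n_natural: int,
    base_n_art: int,
    target_power: float,
    spec: Optional[PowerSpec] = None,
    step: float = 0.1,
    cap: float = 100.0,
) -> tuple[float, PowerResult]:
    """Smallest sample-size multiplier k (on a ``step`` grid) at which
    the simulated power reaches ``target_power``.

    Every evaluation reuses the spec's seed (common random numbers), so
    power is monotone in k up to discretization and the grid search by
    exponential bracketing plus bisection is stable.  Group sizes are
    ``ceil(k * base_n)``.
    """
    if spec is None:
        spec = PowerSpec(n_natural=base_n_natural, n_art=base_n_art)
    spec.validate()
    if not spec.alpha < target_power < 1:
        raise ConfigurationError(
            f"target_power must lie in (alpha, 1), got {target_power}")

    def power_at(k: float) -> PowerResult:
        eval_spec = replace(spec,
                            n_natural=math.ceil(k * base_n_natural),
                            n_art=math.ceil(k * base_n_art))
        return simulate_power(eval_spec,
                              rng=np.random.default_rng(spec.seed))

    n_grid = int(round(cap / step))  # grid indices: k = i * step
    lo = int(round(1.0 / step))  # multipliers below 1 are not searched
    res_lo = power_at(lo * step)
    if res_lo.power >= target_power:
        return lo * step, res_lo
    # exponential bracketing upward
    hi = lo
    res_hi = res_lo
    while res_hi.power < target_power:
        if hi >= n_grid:
            raise AnalysisError(
                f"target power {target_power} unreachable below "
                f"multiplier cap {cap}")
        hi = min(n_grid, hi * 2)
        res_hi = power_at(hi * step)
    # bisection on the grid
    while hi - lo > 1:
        mid = (lo + hi) // 2
        res_mid = power_at(mid * step)
        if res_mid.power >= target_power:
            hi, res_hi = mid, res_mid
        else:
            lo = mid
    return hi * step, res_hi


__all__ = [
    "CANDIDATE_FAMILY_SIZE", "PowerResult", "PowerSpec", "analytic_power",
    "bonferroni_threshold", "required_multiplier", "simulate_power",
]
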