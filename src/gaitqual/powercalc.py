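"""Sample size for paired pre/post comparisons of gait characteristics.

For a repeated-measures (test-retest) trial design the number of
participants required to detect a change Delta with two-sided significance
alpha and power 1-beta is

    n = 2 * s2_total * (1 - r * s2_bs / s2_total)
          * (t_{n-1,1-beta} + t_{n-1,1-alpha/2})^2 / Delta^2

where s2_total is the total variance of the characteristic, s2_bs its
between-subject variance, and r the assumed within-subject (pre/post)
correlation. Effects are standardized by the total SD, Delta = d *
sqrt(s2_total) with Cohen's d, which makes the formula scale-free:

    n = 2 * (1 - r * rho) * (t_{n-1,1-beta} + t_{n-1,1-alpha/2})^2 / d^2,

with rho = s2_bs / s2_total. Because n appears on both sides through the
t quantiles, the reported n is the smallest integer >= 2 satisfying
n >= f(n); f is decreasing in n, so this is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_N_CAP = 10_000_000


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of the paired comparison."""

    d: float                  # standardized effect size (Cohen's d)
    r_assumed: float          # assumed pre/post within-subject correlation
    alpha: float = 0.05       # two-sided significance level
    power: float = 0.8        # desired power 1 - beta

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.d <= 0:
            raise ValueError("effect size d must be > 0")
        if not 0 <= self.r_assumed < 1:
            raise ValueError("r_assumed must lie in [0, 1)")


def _required_factor(spec: PowerSpec, rho: float, n: int) -> float:
    tq = stats.t.ppf(spec.power, n - 1) + stats.t.ppf(1 - spec.alpha / 2, n - 1)
    return 2.0 * (1.0 - spec.r_assumed * rho) * tq ** 2 / spec.d ** 2


def normal_approx_n(spec: PowerSpec, rho: float) -> float:
    """Closed-form approximation with normal quantiles (no n on the right)."""
    zq = stats.norm.ppf(spec.power) + stats.norm.ppf(1 - spec.alpha / 2)
    return 2.0 * (1.0 - spec.r_assumed * rho) * zq ** 2 / spec.d ** 2


def required_n(s2_total: float, s2_bs: float, spec: PowerSpec) -> int:
    """Smallest integer n >= 2 with n >= f(n) under the repeated-measures formula.

    The search starts at the normal-quantile approximation and scans
    outward; scaling both variances by a common factor leaves the result
    unchanged (the effect is standardized by the total SD).
    """
    if s2_total <= 0:
        raise ValueError("s2_total must be > 0")
    if not 0 <= s2_bs <= s2_total:
        raise ValueError("s2_bs must lie in [0, s2_total]")
    rho = s2_bs / s2_total
    n = max(2, int(np.floor(normal_approx_n(spec, rho))))
    # move down while the next smaller n still satisfies the inequality
    while n > 2 and (n - 1) >= _required_factor(spec, rho, n - 1):
        n -= 1
    while n < _required_factor(spec, rho, n):
        n += 1
        if n > _N_CAP:
            raise RuntimeError("required n exceeds the search cap")
    return n


DEFAULT_D = (0.3, 0.5, 0.8)
DEFAULT_R = (0.3, 0.6, 0.9)


def sample_size_grid(varcomps, d_list=DEFAULT_D, r_list=DEFAULT_R,
                     alpha: float = 0.05, power: float = 0.8) -> pd.DataFrame:
    """Required n per characteristic over the d x r cross product.

    ``varcomps`` is an iterable of objects carrying ``characteristic``,
    ``s2_total`` and ``s2_bs`` (e.g. :class:`gaitqual.varcomp.VarComp`).
    Columns are a (d, r) MultiIndex; infeasible cells are NaN. The variance
    inputs used per characteristic are stored in ``DataFrame.attrs``.
    """
    rows, meta = {}, {}
    for vc in varcomps:
        cells = {}
        for d in d_list:
            for r in r_list:
                try:
                    cells[(d, r)] = required_n(
                        vc.s2_total, vc.s2_bs,
                        PowerSpec(d=d, r_assumed=r, alpha=alpha, power=power))
                except (ValueError, RuntimeError):
                    cells[(d, r)] = np.nan
        rows[vc.characteristic] = cells
        meta[vc.characteristic] = {"s2_total": vc.s2_total, "s2_bs": vc.s2_bs}
    grid = pd.DataFrame.from_dict(rows, orient="index")
    grid.columns = pd.MultiIndex.from_tuples(grid.columns, names=["d", "r"])
    grid = grid.sort_index(axis=1)
    grid.attrs["variance_inputs"] = meta
    grid.attrs["alpha"] = alpha
    grid.attrs["power"] = power
    return grid
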