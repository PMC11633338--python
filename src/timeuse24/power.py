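"""Sample-size planning for multiple regression via the noncentral F.

The overall test of a linear regression with ``u`` predictors on ``n``
observations compares an F statistic against F(u, v) with
``v = n - u - 1`` denominator degrees of freedom; under the alternative
described by Cohen's effect size f^2 = R^2 / (1 - R^2) the statistic
follows a noncentral F with noncentrality ``lambda = f^2 * n``.  The
required sample size is the smallest ``n`` whose power reaches the
requested level, then inflated for anticipated dropout.

Note on conventions: with ``v = n - u - 1`` the two common noncentrality
parameterisations, ``f^2 * n`` and ``f^2 * (u + v + 1)``, are
algebraically identical; the ``ncp`` flag exists for designs where the
denominator df is reduced by extra (untested) model terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import scipy.stats


@dataclass(frozen=True)
class PowerQuery:
    """One sample-size question for the overall regression F test."""

    f2: float                 # Cohen's effect size
    alpha: float = 0.05
    power: float = 0.80
    n_predictors: int = 8     # numerator df (model terms excluding intercept)
    dropout_rate: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must be in (0, 1)")
        if self.f2 <= 0.0:
            raise ValueError("f2 must be > 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_predictors < 1:
            raise ValueError("n_predictors must be >= 1")


def f2_from_r2(r2: float) -> float:
    """Cohen's f^2 = R^2 / (1 - R^2)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    return r2 / (1.0 - r2)


def regression_power(f2: float, n: int, n_predictors: int,
                     alpha: float = 0.05, ncp: str = "n") -> float:
    """Power of the overall F test at sample size ``n``.

    ``ncp='n'`` uses lambda = f^2 * n; ``ncp='u+v+1'`` uses
    f^2 * (u + v + 1) — identical when v = n - u - 1, as here.
    """
    u = n_predictors
    v = n - u - 1
    if v < 1:
        return 0.0
    lam = f2 * (n if ncp == "n" else (u + v + 1))
    f_crit = scipy.stats.f.isf(alpha, u, v)
    return float(scipy.stats.ncf.sf(f_crit, u, v, lam))


def required_sample_size(query: PowerQuery, ncp: str = "n",
                         n_max: int = 1_000_000) -> tuple[int, int]:
    """Smallest analyzable n reaching the requested power, plus recruits.

    Returns ``(n_analyzed, n_recruited)`` where the recruitment number
    inflates for the anticipated dropout rate.  Power is computed from
    the noncentral-F distribution directly (no approximation), and is
    monotone in n, so a doubling search plus bisection finds the
    minimal n.
    """
    u = query.n_predictors
    lo = u + 2  # smallest n with v >= 1
    if regression_power(query.f2, lo, u, query.alpha, ncp) >= query.power:
        return lo, dropout_inflate(lo, query.dropout_rate)
    hi = lo
    while regression_power(query.f2, hi, u, query.alpha, ncp) < query.power:
        hi *= 2
        if hi > n_max:
            raise ValueError("requested power unattainable below n_max")
    lo_search = hi // 2
    while lo_search + 1 < hi:
        mid = (lo_search + hi) // 2
        if regression_power(query.f2, mid, u, query.alpha, ncp) >= query.power:
            hi = mid
        else:
            lo_search = mid
    return hi, dropout_inflate(hi, query.dropout_rate)


def dropout_inflate(n_analyzed: int, dropout_rate: float) -> int:
    """Recruits needed so that n_analyzed remain after dropout."""
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    return math.ceil(n_analyzed / (1.0 - dropout_rate))


def chi2_limit_ncp(n_predictors: int, alpha: float = 0.05,
                   power: float = 0.80) -> float:
    """Large-n limiting noncentrality of the F test (chi-square solution).

    As n grows, u * F(u, v) tends to a noncentral chi-square with u df,
    so the noncentrality required for a given power converges to the
    lambda solving ``P(chi2_nc(u, lambda) > chi2_crit(u, alpha)) = power``.
    Useful as an independent check: required n ~ lambda / f^2.
    """
    crit = scipy.stats.chi2.isf(alpha, n_predictors)

    def pwr(lam):
        return scipy.stats.ncx2.sf(crit, n_predictors, lam)

    lo, hi = 1e-9, 10.0
    while pwr(hi) < power:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if pwr(mid) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
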