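"""Exact power analysis for tests of a Pearson correlation under bivariate normality.

The a-priori sample-size calculation for a correlational individual-differences
study tests H0: rho = 0 against a one-sided alternative using the exact
sampling distribution of the sample correlation coefficient r.  The null
critical value comes from the classical t transform, ``t = r sqrt(nu/(1-r^2))``
with ``nu = n - 2`` degrees of freedom; power is the probability mass of the
non-null exact density of r beyond that critical value.

The non-null density (Fisher 1915; Hotelling 1953) for a bivariate normal
sample of size n with population correlation rho is

    f(r) = (n-2) Gamma(n-1) (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
           / ( sqrt(2 pi) Gamma(n-1/2) (1-rho*r)^(n-3/2) )
           * 2F1(1/2, 1/2; n-1/2; (1+rho*r)/2)

evaluated here in log space for numerical stability and integrated with
adaptive quadrature.  No SciPy distribution exposes this density, so it is
implemented directly.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "pearson_r_logpdf",
    "pearson_r_pdf",
    "critical_r",
    "exact_corr_power",
    "required_n",
]

_TAILS = ("one", "two")


def _check_args(n: int, rho1: float, alpha: float, tails: str) -> None:
    if n < 4:
        raise ValueError(f"need n >= 4 complete pairs, got n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not -1 < rho1 < 1:
        raise ValueError(f"rho1 must lie in (-1, 1), got {rho1}")
    if tails not in _TAILS:
        raise ValueError(f"tails must be one of {_TAILS}, got {tails!r}")


def pearson_r_logpdf(r, rho: float, n: int):
    """Log of the exact density of the sample correlation r.

    Valid for ``|r| < 1``, ``|rho| < 1`` and ``n >= 4``.
    """
    r = np.asarray(r, dtype=float)
    return (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * np.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-r * r)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2))
    )


def pearson_r_pdf(r, rho: float, n: int):
    """Exact density of the sample correlation coefficient."""
    return np.exp(pearson_r_logpdf(r, rho, n))


def critical_r(n: int, alpha: float = 0.05, tails: str = "one") -> float:
    """Null critical value of |r| via the exact t transform (nu = n - 2)."""
    _check_args(n, 0.0, alpha, tails)
    df = n - 2
    a = alpha if tails == "one" else alpha / 2
    tc = stats.t.ppf(1 - a, df)
    return float(tc / np.hypot(tc, np.sqrt(df)))


def exact_corr_power(n: int, rho1: float, alpha: float = 0.05, tails: str = "one") -> float:
    """Power of the exact correlation test at sample size *n*.

    One-tailed tests are taken in the direction of ``rho1``'s sign.
    """
    _check_args(n, rho1, alpha, tails)
    rc = critical_r(n, alpha, tails)
    rho = abs(rho1)  # symmetric problem; test in the direction of the effect

    def dens(r):
        return float(pearson_r_pdf(r, rho, n))

    upper, _ = integrate.quad(dens, rc, 1.0, limit=200)
    if tails == "one":
        return float(upper)
    lower, _ = integrate.quad(dens, -1.0, -rc, limit=200)
    return float(upper + lower)


def required_n(
    rho1: float,
    power_target: float = 0.90,
    alpha: float = 0.05,
    tails: str = "one",
    n_max: int = 100_000,
) -> int:
    """Smallest n whose exact-test power reaches *power_target*."""
    if not 0 < power_target < 1:
        raise ValueError(f"power_target must lie in (0, 1), got {power_target}")
    _check_args(4, rho1, alpha, tails)
    if rho1 == 0:
        raise ValueError("power target unattainable at rho1 = 0")
    # Bracket by doubling, then binary-search: power is monotone in n.
    lo, hi = 4, 8
    while exact_corr_power(hi, rho1, alpha, tails) < power_target:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(
                f"power target {power_target} unattainable below n_max={n_max}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if exact_corr_power(mid, rho1, alpha, tails) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi


def monte_carlo_power(
    n: int,
    rho1: float,
    alpha: float = 0.05,
    tails: str = "one",
    n_rep: int = 1_000_000,
    seed: int | None = None,
    chunk: int = 100_000,
) -> float:
    """Simulation estimate of the exact test's power (independent oracle).

    Draws ``n_rep`` bivariate-normal samples of size n and counts rejections
    at the same critical value used by :func:`exact_corr_power`.
    """
    _check_args(n, rho1, alpha, tails)
    rc = critical_r(n, alpha, tails)
    rng = np.random.default_rng(seed)
    rho = abs(rho1)
    hits = 0
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        x = rng.standard_normal((m, n))
        y = rho * x + np.sqrt(1 - rho * rho) * rng.standard_normal((m, n))
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean(axis=1, keepdims=True)
        r = (x * y).sum(axis=1) / np.sqrt((x * x).sum(axis=1) * (y * y).sum(axis=1))
        hits += int((r > rc).sum() if tails == "one" else (np.abs(r) > rc).sum())
        done += m
    return hits / n_rep
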