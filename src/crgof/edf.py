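"""Modified EDF goodness-of-fit statistics for type-II censored samples.

The observed order statistics are mapped through the fitted cdf,
u(i) = F(x(i); alpha_hat, beta_hat) (the probability integral transform with
estimated parameters), and compared with the uniform law on the censored
range.  With r observed of n and i = 1..r:

Kolmogorov-Smirnov (sup distance)
    D+ = max_i (i/n - u(i)),  D- = max_i (u(i) - (i-1)/n),
    D  = max(D+, D-),                      each inner max floored at 0.

Cramer-von Mises (integrated squared distance)
    C = sum_i [u(i) - (2i-1)/(2n)]^2 + r/(12 n^2) + (n/3) [u(r) - r/n]^3,
    equal to n * integral_0^{u(r)} (G_n(u) - u)^2 du with
    G_n(u) = #{u(i) <= u}/n.

Anderson-Darling (variance-weighted)
    A = -(1/n) sum_i (2i-1) [ln u(i) - ln(1-u(i))] - 2 sum_i ln(1-u(i))
        - (1/n) [(r-n)^2 ln(1-u(r)) - r^2 ln u(r) + n^2 u(r)],
    equal to n * integral_0^{u(r)} (G_n(u) - u)^2 / (u (1-u)) du.

At r = n with u(n) -> 1 these reduce to the classical complete-sample
statistics.  Because the parameters are estimated, the null distributions
are not the classical tabulated ones; they are simulated in
:mod:`crgof.tables`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import CRParams, cr_cdf
from .mle import CensoredSample

__all__ = [
    "UniformizedSample",
    "GofStatistics",
    "uniformize",
    "ks_statistic",
    "cvm_statistic",
    "ad_statistic",
    "all_statistics",
]

#: clipping guard applied to fitted cdf values before logs
U_EPS = 1e-12


@dataclass(frozen=True)
class UniformizedSample:
    """Probability-integral-transformed order statistics u(1..r) of n items."""

    u: np.ndarray
    n: int

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "u", u)
        if u.size < 1:
            raise ValueError("empty uniformized sample")
        if np.any(np.diff(u) < 0):
            raise ValueError("u must be sorted nondecreasing")
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("u must lie strictly inside (0, 1); clip first")
        if self.n < u.size:
            raise ValueError("n must be >= r")

    @property
    def r(self) -> int:
        return int(self.u.size)


@dataclass(frozen=True)
class GofStatistics:
    """The three modified statistics at a single fit."""

    ks: float
    cvm: float
    ad: float

    def as_dict(self) -> dict[str, float]:
        return {"ks": self.ks, "cvm": self.cvm, "ad": self.ad}


def uniformize(s: CensoredSample, alpha: float, beta: float) -> UniformizedSample:
    """u(i) = F(x(i); alpha, beta), clipped to [U_EPS, 1 - U_EPS]."""
    u = np.clip(cr_cdf(s.observed, CRParams(alpha, beta)), U_EPS, 1.0 - U_EPS)
    return UniformizedSample(u=u, n=s.n)


def ks_statistic(us: UniformizedSample) -> float:
    """Modified Kolmogorov-Smirnov sup distance D on the censored range."""
    i = np.arange(1, us.r + 1)
    d_plus = max(float((i / us.n - us.u).max()), 0.0)
    d_minus = max(float((us.u - (i - 1) / us.n).max()), 0.0)
    return max(d_plus, d_minus)


def cvm_statistic(us: UniformizedSample) -> float:
    """Modified Cramer-von Mises statistic C."""
    n, r, u = us.n, us.r, us.u
    i = np.arange(1, r + 1)
    return float(
        ((u - (2 * i - 1) / (2 * n)) ** 2).sum()
        + r / (12 * n**2)
        + (n / 3.0) * (u[-1] - r / n) ** 3
    )


def ad_statistic(us: UniformizedSample) -> float:
    """Modified Anderson-Darling statistic A."""
    n, r, u = us.n, us.r, us.u
    i = np.arange(1, r + 1)
    log_u = np.log(u)
    log_1mu = np.log1p(-u)
    return float(
        -(1.0 / n) * ((2 * i - 1) * (log_u - log_1mu)).sum()
        - 2.0 * log_1mu.sum()
        - (1.0 / n)
        * ((r - n) ** 2 * log_1mu[-1] - r**2 * log_u[-1] + n**2 * u[-1])
    )


def all_statistics(s: CensoredSample, alpha: float, beta: float) -> GofStatistics:
    """Uniformize at (alpha, beta) and evaluate the three statistics."""
    us = uniformize(s, alpha, beta)
    return GofStatistics(
        ks=ks_statistic(us), cvm=cvm_statistic(us), ad=ad_statistic(us)
    )


def _stats_rows(u: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # vectorized (B, r) evaluation used by the Monte Carlo engines
    b, r = u.shape
    i = np.arange(1, r + 1)[None, :]
    d_plus = np.maximum((i / n - u).max(axis=1), 0.0)
    d_minus = np.maximum((u - (i - 1) / n).max(axis=1), 0.0)
    ks = np.maximum(d_plus, d_minus)
    cvm = (
        ((u - (2 * i - 1) / (2 * n)) ** 2).sum(axis=1)
        + r / (12 * n**2)
        + (n / 3.0) * (u[:, -1] - r / n) ** 3
    )
    log_u = np.log(u)
    log_1mu = np.log1p(-u)
    ad = (
        -(1.0 / n) * ((2 * i - 1) * (log_u - log_1mu)).sum(axis=1)
        - 2.0 * log_1mu.sum(axis=1)
        - (1.0 / n)
        * ((r - n) ** 2 * log_1mu[:, -1] - r**2 * log_u[:, -1] + n**2 * u[:, -1])
    )
    return ks, cvm, ad
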