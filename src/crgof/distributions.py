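"""The Compound Rayleigh distribution and the simulation alternatives.

The Compound Rayleigh (CR) family is a two-parameter lifetime distribution
with cdf

    F(x; alpha, beta) = 1 - (1 + x^2 / beta)^(-alpha),   x >= 0,

a Burr-type family in x^2 with shape ``alpha`` and scale ``beta`` (units of
x^2).  Equivalently, if X ~ CR(alpha, beta) then X^2 follows a Lomax
(Pareto II) law with shape alpha and scale beta, and

    ln(1 + X^2 / beta)  ~  Exponential(rate = alpha),

the identity that makes the shape MLE available in closed form for type-II
censored samples (see :mod:`crgof.mle`).

Everything here is computed through ``log1p``/``expm1`` so that extreme
shapes (alpha in the thousands, which arise as boundary fits of small
samples) stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CRParams",
    "AlternativeSpec",
    "cr_cdf",
    "cr_logsf",
    "cr_pdf",
    "cr_quantile",
    "cr_sample",
    "alt_sample",
    "comparison_cdf",
]


@dataclass(frozen=True)
class CRParams:
    """Shape/scale pair of the Compound Rayleigh family.

    Parameters
    ----------
    alpha
        Shape parameter, > 0.  Governs tail weight: the survival function
        decays like x^(-2 alpha).
    beta
        Scale parameter, > 0, in units of x^2.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be a positive finite real, got {self.beta}")


#: parameter names required per alternative family
_FAMILY_PARAMS = {
    "exponential": ("theta",),
    "gamma": ("shape", "scale"),
    "chi_square": ("df",),
    "rayleigh": ("sigma",),
    "exponentiated_rayleigh": ("lam", "theta"),
    "compound_rayleigh": ("alpha", "beta"),
}


@dataclass(frozen=True)
class AlternativeSpec:
    """A named sampling distribution for power studies and comparative fits.

    Supported families and parameterizations:

    - ``exponential``: density (1/theta) exp(-x/theta)  (theta = mean)
    - ``gamma``: shape/scale, density x^(shape-1) exp(-x/scale) / (scale^shape Gamma(shape))
    - ``chi_square``: ``df`` degrees of freedom (positive integer)
    - ``rayleigh``: F(x) = 1 - exp(-x^2 / (2 sigma^2))
    - ``exponentiated_rayleigh``: F(x) = (1 - exp(-lam x^2))^theta
    - ``compound_rayleigh``: F(x) = 1 - (1 + x^2/beta)^(-alpha)
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of "
                f"{sorted(_FAMILY_PARAMS)}"
            )
        required = _FAMILY_PARAMS[self.family]
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ValueError(f"family {self.family!r} requires parameters {missing}")
        for k in required:
            v = self.params[k]
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {k!r} must be positive, got {v}")
        if self.family == "chi_square":
            df = self.params["df"]
            if int(df) != df:
                raise ValueError(f"chi_square df must be a positive integer, got {df}")

    # convenience constructors for the standard study alternatives
    @staticmethod
    def exponential(theta: float = 1.5) -> "AlternativeSpec":
        return AlternativeSpec("exponential", {"theta": theta})

    @staticmethod
    def gamma(shape: float = 1.5, scale: float = 2.0) -> "AlternativeSpec":
        return AlternativeSpec("gamma", {"shape": shape, "scale": scale})

    @staticmethod
    def chi_square(df: int = 4) -> "AlternativeSpec":
        return AlternativeSpec("chi_square", {"df": df})

    @staticmethod
    def compound_rayleigh(alpha: float, beta: float) -> "AlternativeSpec":
        return AlternativeSpec("compound_rayleigh", {"alpha": alpha, "beta": beta})


def _check_nonnegative(x: np.ndarray) -> None:
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")


def cr_cdf(x, p: CRParams):
    """CR cumulative distribution function, F(x) = 1 - (1 + x^2/beta)^(-alpha)."""
    x = np.asarray(x, dtype=float)
    _check_nonnegative(x)
    out = -np.expm1(-p.alpha * np.log1p(x * x / p.beta))
    return out if out.ndim else float(out)


def cr_logsf(x, p: CRParams):
    """Log survival function, ln(1 - F(x)) = -alpha ln(1 + x^2/beta)."""
    x = np.asarray(x, dtype=float)
    _check_nonnegative(x)
    out = -p.alpha * np.log1p(x * x / p.beta)
    return out if out.ndim else float(out)


def cr_pdf(x, p: CRParams):
    """CR density, f(x) = (2 alpha x / beta) (1 + x^2/beta)^(-(alpha+1))."""
    x = np.asarray(x, dtype=float)
    _check_nonnegative(x)
    with np.errstate(divide="ignore"):
        logpdf = (
            np.log(2.0 * p.alpha / p.beta)
            + np.log(x)
            - (p.alpha + 1.0) * np.log1p(x * x / p.beta)
        )
    out = np.where(x == 0.0, 0.0, np.exp(logpdf))
    return out if out.ndim else float(out)


def cr_quantile(u, p: CRParams):
    """Inverse cdf: Q(u) = sqrt(beta ((1-u)^(-1/alpha) - 1)) for u in [0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    out = np.sqrt(p.beta * np.expm1(-np.log1p(-u) / p.alpha))
    return out if out.ndim else float(out)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def cr_sample(n: int, p: CRParams, seed) -> np.ndarray:
    """Draw n i.i.d. CR variates by inverse transform from a seeded generator.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or an existing
    ``Generator`` (advanced use).  Fixed seeds give bit-reproducible output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return cr_quantile(rng.random(int(n)), p)


def alt_sample(spec: AlternativeSpec, n: int, seed) -> np.ndarray:
    """Draw n variates from an alternative family with a seeded generator."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    n = int(n)
    f, q = spec.family, spec.params
    if f == "exponential":
        return rng.exponential(q["theta"], n)
    if f == "gamma":
        return rng.gamma(q["shape"], q["scale"], n)
    if f == "chi_square":
        return rng.chisquare(q["df"], n)
    if f == "rayleigh":
        return rng.rayleigh(q["sigma"], n)
    if f == "exponentiated_rayleigh":
        # inverse transform of F(x) = (1 - exp(-lam x^2))^theta
        u = rng.random(n)
        return np.sqrt(-np.log1p(-u ** (1.0 / q["theta"])) / q["lam"])
    if f == "compound_rayleigh":
        return cr_sample(n, CRParams(q["alpha"], q["beta"]), rng)
    raise ValueError(f"unknown family {f!r}")  # pragma: no cover


def comparison_cdf(spec: AlternativeSpec, x):
    """Cdf of a family used in comparative fitting reports.

    Implemented for ``rayleigh``, ``exponentiated_rayleigh`` and
    ``compound_rayleigh``; other families are simulation sources only.
    """
    x = np.asarray(x, dtype=float)
    _check_nonnegative(x)
    f, q = spec.family, spec.params
    if f == "rayleigh":
        out = -np.expm1(-x * x / (2.0 * q["sigma"] ** 2))
    elif f == "exponentiated_rayleigh":
        with np.errstate(divide="ignore"):
            out = np.exp(q["theta"] * np.log(-np.expm1(-q["lam"] * x * x)))
        out = np.where(x == 0.0, 0.0, out)
    elif f == "compound_rayleigh":
        return cr_cdf(x, CRParams(q["alpha"], q["beta"]))
    else:
        raise ValueError(f"family {f!r} has no comparison cdf")
    return out if out.ndim else float(out)
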