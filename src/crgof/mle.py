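"""Maximum-likelihood estimation of CR parameters under type-II censoring.

A type-II censored sample records the r smallest order statistics
x(1) <= ... <= x(r) of a life test of n items.  With v_i = ln(1 + x_i^2/beta)
the working log-likelihood is

    L(alpha, beta) = r ln alpha - r ln beta + sum ln x_i
                     - (alpha + 1) sum v_i - (n - r) alpha v_r,

which drops two constants of the exact censored log-density: the
combinatorial term ln[n!/(n-r)!] and r ln 2 (both free of the parameters).
Reported log-likelihoods are therefore comparable only within fixed (n, r).

For fixed beta the shape MLE is closed-form,

    alpha_hat(beta) = r / (sum v_i + (n - r) v_r),

because the v_i are exponential with rate alpha under the model.  The joint
MLE is found by profiling: alpha is concentrated out analytically and a
bounded one-dimensional search over ln beta maximizes the profile

    Lp(beta) = r ln alpha_hat(beta) - r ln beta + sum ln x_i - r - sum v_i.

Small samples frequently have no interior maximum: the profile increases
monotonically in beta toward the Rayleigh limit (alpha, beta -> inf with
alpha/beta fixed), in which case the search stops at the box bound and the
result is flagged ``boundary=True`` / ``converged=False``.  The fitted cdf is
stable in that regime (it converges to the limiting Rayleigh fit), so such
estimates remain usable for goodness-of-fit statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CensoredSample",
    "EstimationResult",
    "v_transform",
    "log_likelihood",
    "score",
    "mle_alpha_given_beta",
    "mle_fixed_beta",
    "mle_joint",
]

#: relative convergence tolerance on the score (per component, scaled by r)
SCORE_RTOL = 1e-8
#: beta search box, as multiples of median(x^2)
_BETA_BOX = (1e-6, 1e6)


@dataclass(frozen=True)
class CensoredSample:
    """Ordered observed lifetimes x(1..r) from a life test of n items.

    ``observed`` is sorted nondecreasing on construction (estimation is
    invariant to input order); ``r = len(observed)``; ``r == n`` means the
    sample is complete.
    """

    observed: np.ndarray
    n: int

    def __post_init__(self) -> None:
        x = np.sort(np.asarray(self.observed, dtype=float))
        object.__setattr__(self, "observed", x)
        if x.size < 1:
            raise ValueError("at least one observation is required")
        if not np.all(np.isfinite(x)) or np.any(x <= 0):
            raise ValueError("observations must be positive finite reals")
        if self.n < x.size:
            raise ValueError(f"n={self.n} smaller than number observed r={x.size}")

    @property
    def r(self) -> int:
        return int(self.observed.size)

    @property
    def is_complete(self) -> bool:
        return self.r == self.n

    @staticmethod
    def complete(values: Sequence[float]) -> "CensoredSample":
        values = np.asarray(values, dtype=float)
        return CensoredSample(values, n=values.size)


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of a CR fit.

    ``converged`` means both score components vanished to the declared
    tolerance (|s_alpha| and |beta * s_beta| below ``SCORE_RTOL * r``);
    ``boundary`` flags a profile maximum at the beta search box.
    ``beta_fixed`` is set when beta was held known rather than estimated.
    """

    alpha_hat: float
    beta_hat: float
    log_lik: float
    converged: bool
    iterations: int
    beta_fixed: Optional[float] = None
    boundary: bool = False


def _values(s) -> np.ndarray:
    return s.observed if isinstance(s, CensoredSample) else np.asarray(s, dtype=float)


def v_transform(s, beta: float) -> np.ndarray:
    """v_i = ln(1 + x_i^2 / beta), elementwise, order preserved.

    Accepts a :class:`CensoredSample` or a plain array of values.
    """
    if not (np.isfinite(beta) and beta > 0):
        raise ValueError(f"beta must be positive, got {beta}")
    x = _values(s)
    if np.any(x < 0):
        raise ValueError("observations must be nonnegative")
    return np.log1p(x * x / beta)


def _check_params(alpha: float, beta: float) -> None:
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not (np.isfinite(beta) and beta > 0):
        raise ValueError(f"beta must be positive, got {beta}")


def log_likelihood(s: CensoredSample, alpha: float, beta: float) -> float:
    """Working censored log-likelihood (constants dropped, see module doc)."""
    _check_params(alpha, beta)
    v = v_transform(s, beta)
    r, n = s.r, s.n
    return float(
        r * np.log(alpha)
        - r * np.log(beta)
        + np.log(s.observed).sum()
        - (alpha + 1.0) * v.sum()
        - (n - r) * alpha * v[-1]
    )


def score(s: CensoredSample, alpha: float, beta: float) -> tuple[float, float]:
    """Gradient (dL/dalpha, dL/dbeta) of the working log-likelihood."""
    _check_params(alpha, beta)
    x2 = s.observed**2
    r, n = s.r, s.n
    v = np.log1p(x2 / beta)
    s_alpha = r / alpha - (v.sum() + (n - r) * v[-1])
    w = x2 / (beta * (beta + x2))
    s_beta = -r / beta + (alpha + 1.0) * w.sum() + (n - r) * alpha * w[-1]
    return float(s_alpha), float(s_beta)


def mle_alpha_given_beta(s: CensoredSample, beta: float) -> float:
    """Closed-form shape MLE for known beta: r / (sum v_i + (n-r) v_r)."""
    v = v_transform(s, beta)
    denom = v.sum() + (s.n - s.r) * v[-1]
    if denom <= 0:
        raise ValueError("degenerate sample: all observations at zero")
    return float(s.r / denom)


def mle_fixed_beta(s: CensoredSample, beta: float) -> EstimationResult:
    """Fit with beta held at a known value (shape-only estimation)."""
    alpha = mle_alpha_given_beta(s, beta)
    return EstimationResult(
        alpha_hat=alpha,
        beta_hat=beta,
        log_lik=log_likelihood(s, alpha, beta),
        converged=True,
        iterations=0,
        beta_fixed=beta,
    )


def _profile_neg(log_beta: float, x2: np.ndarray, n: int, sum_log_x: float) -> float:
    # Lp(beta) = r ln alpha_hat - r ln beta + sum ln x - r - sum v
    r = x2.size
    beta = np.exp(log_beta)
    v = np.log1p(x2 / beta)
    denom = v.sum() + (n - r) * v[-1]
    return -(r * np.log(r / denom) - r * log_beta + sum_log_x - r - v.sum())


def mle_joint(s: CensoredSample, max_iter: int = 200) -> EstimationResult:
    """Joint (alpha, beta) MLE by profile likelihood over ln beta.

    Requires at least two distinct observed values (identifiability guard).
    A bounded golden/parabolic search over ln beta in
    ``[1e-6, 1e6] * median(x^2)`` locates the profile maximum; a short Newton
    polish on the beta score then drives both score components below
    ``SCORE_RTOL * r``.  Ties among observations are permitted.
    """
    if np.unique(s.observed).size < 2:
        raise ValueError("joint estimation requires >= 2 distinct observed values")
    x2 = s.observed**2
    sum_log_x = float(np.log(s.observed).sum())
    med = float(np.median(x2))
    lo, hi = np.log(_BETA_BOX[0] * med), np.log(_BETA_BOX[1] * med)

    res = minimize_scalar(
        _profile_neg,
        bounds=(lo, hi),
        args=(x2, s.n, sum_log_x),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    lb = float(res.x)
    iterations = int(res.nfev)
    tol = SCORE_RTOL * s.r

    def scaled_beta_score(lb_: float) -> float:
        beta = np.exp(lb_)
        alpha = mle_alpha_given_beta(s, beta)
        return beta * score(s, alpha, beta)[1]  # dLp/d(ln beta), by envelope

    # Newton polish on g(ln beta) = 0 within the box
    for _ in range(30):
        g = scaled_beta_score(lb)
        if abs(g) < tol:
            break
        h = 1e-6
        dg = (scaled_beta_score(lb + h) - scaled_beta_score(lb - h)) / (2 * h)
        if not np.isfinite(dg) or dg == 0:
            break
        step = g / dg
        cand = lb - step
        if not (lo < cand < hi) or not np.isfinite(cand):
            break
        if abs(_profile_neg(cand, x2, s.n, sum_log_x)) > abs(
            _profile_neg(lb, x2, s.n, sum_log_x)
        ) * (1 + 1e-6) and _profile_neg(cand, x2, s.n, sum_log_x) > _profile_neg(
            lb, x2, s.n, sum_log_x
        ):
            break  # polish made the profile worse; keep search point
        lb = cand
        iterations += 1

    beta = float(np.exp(lb))
    alpha = mle_alpha_given_beta(s, beta)
    s_a, s_b = score(s, alpha, beta)
    at_bound = lb <= lo + 1e-6 or lb >= hi - 1e-6
    converged = (
        not at_bound and abs(s_a) < tol and abs(beta * s_b) < tol
    )
    return EstimationResult(
        alpha_hat=alpha,
        beta_hat=beta,
        log_lik=log_likelihood(s, alpha, beta),
        converged=bool(converged),
        iterations=iterations,
        boundary=bool(at_bound),
    )
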