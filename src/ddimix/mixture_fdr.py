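"""Three-component mixture model on observed/expected frequencies and local FDR.

Across all drug-drug-ADE combinations, the unobserved relative risk
lambda = true rate / baseline rate is modelled as a three-component
mixture:

    lambda ~ P1 * I(lambda = 0)
           + P2 * Gamma(a2, a2)        (background: mean 1)
           + P3 * Gamma(a3, b3)        (signal: mean a3/b3 > 1)

with N | lambda ~ Poisson(lambda * E).  Marginally each gamma component
yields a negative binomial for N:

    F(k; a, b, E) = Gamma(k+a) E^k b^a / (Gamma(a) k! (E+b)^(k+a)).

Most combinations have N = 0, so inference uses the zero-truncated
conditional likelihood over combinations with N > 0, whose free
parameters are (a2, a3, b3, rho) with rho = P3/P2.  The local
("adjusted") FDR of a combination with N = k > 0 is the posterior
probability of the background component,

    fdr(k, E) = F(k; a2, a2, E) / (F(k; a2, a2, E) + rho F(k; a3, b3, E)),

computed from the PS-adjusted expected frequency E.  The zero-inflated
full likelihood (with the extra mass p1 at lambda = 0) is also provided.

All probability mass computations run in log space via log-gamma
functions; optimisation runs in log-parameters so the constraints
a2 > 0, a3 > b3 > 0, rho > 0 hold by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "MixtureParams",
    "FitResult",
    "negbin_logpmf",
    "negbin_pmf",
    "conditional_loglik",
    "full_loglik",
    "fit_conditional",
    "adjusted_fdr",
    "component_moments",
]

_LOG_UNDERFLOW = -745.0  # below this, exp() underflows to 0 in float64


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the three-component relative-risk mixture.

    ``alpha2`` is both shape and rate of the background gamma (mean 1);
    ``alpha3 > beta3`` give the signal gamma mean > 1; ``rho = P3/P2``.
    ``p1`` (zero-component mass) is optional and only needed by the full,
    zero-inflated likelihood.
    """

    alpha2: float
    alpha3: float
    beta3: float
    rho: float
    p1: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha2 > 0):
            raise ValueError("alpha2 must be positive")
        if not (self.beta3 > 0):
            raise ValueError("beta3 must be positive")
        if not (self.alpha3 > self.beta3):
            raise ValueError("alpha3 must exceed beta3 (signal mean > 1)")
        if not (self.rho > 0):
            raise ValueError("rho = P3/P2 must be positive")
        if self.p1 is not None and not (0.0 <= self.p1 < 1.0):
            raise ValueError("p1 must lie in [0, 1)")


@dataclass(frozen=True)
class FitResult:
    params: MixtureParams
    loglik: float
    converged: bool
    n_used: int
    message: str = ""


def negbin_logpmf(k, alpha: float, beta: float, e) -> np.ndarray:
    """Log pmf of the gamma-Poisson (negative binomial) count distribution.

    ``k`` counts and ``e`` exposures broadcast.  E = 0 degenerates to a
    point mass at k = 0.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    k = np.asarray(k, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("k must be non-negative integers")
    if np.any(e < 0):
        raise ValueError("exposure must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        # alpha*log(beta) - (k+alpha)*log(e+beta) written via log1p(e/beta)
        # so large shape/rate values cancel without catastrophic rounding
        lp = (
            special.gammaln(k + alpha)
            - special.gammaln(alpha)
            - special.gammaln(k + 1)
            + k * np.log(e)
            - k * np.log(e + beta)
            - alpha * np.log1p(e / beta)
        )
    # E = 0: point mass at zero (k * log 0 -> 0 for k = 0, -inf otherwise)
    lp = np.where(e == 0, np.where(k == 0, 0.0, -np.inf), lp)
    return lp if lp.ndim else float(lp)


def negbin_pmf(k, alpha: float, beta: float, e) -> np.ndarray:
    pmf = np.exp(np.maximum(negbin_logpmf(k, alpha, beta, e), _LOG_UNDERFLOW))
    return np.where(pmf <= math.exp(_LOG_UNDERFLOW), 0.0, pmf)


def _log_p_positive(alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log P(N > 0) = log(1 - (beta/(e+beta))^alpha), stable for small e."""
    log_p0 = -alpha * np.log1p(e / beta)
    return np.log(-np.expm1(np.minimum(log_p0, -1e-300)))


def conditional_loglik(params: MixtureParams, n: np.ndarray, e: np.ndarray) -> float:
    """Zero-truncated mixture log-likelihood over combinations with N > 0.

    Per datum: log[(F(k;a2,a2,E) + rho F(k;a3,b3,E)) /
    (P(N>0;a2,a2,E) + rho P(N>0;a3,b3,E))].
    """
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(n <= 0):
        raise ValueError("conditional likelihood requires all N > 0")
    if np.any(e <= 0):
        raise ValueError("conditional likelihood requires all E > 0")
    log_rho = math.log(params.rho)
    lf2 = negbin_logpmf(n, params.alpha2, params.alpha2, e)
    lf3 = negbin_logpmf(n, params.alpha3, params.beta3, e)
    num = np.logaddexp(lf2, log_rho + lf3)
    den = np.logaddexp(
        _log_p_positive(params.alpha2, params.alpha2, e),
        log_rho + _log_p_positive(params.alpha3, params.beta3, e),
    )
    terms = num - den
    total = float(np.sum(terms))
    if not np.isfinite(total):
        bad = int(np.argmax(~np.isfinite(terms)))
        raise FloatingPointError(
            f"non-finite likelihood term at datum {bad}: N={n[bad]}, E={e[bad]}"
        )
    return total


def full_loglik(params: MixtureParams, n: np.ndarray, e: np.ndarray) -> float:
    """Zero-inflated full log-likelihood over all combinations (N = 0 allowed).

    P(N) = p1 I(N=0) + P2 F(N;a2,a2,E) + P3 F(N;a3,b3,E), with
    P2 = (1-p1)/(1+rho) and P3 = rho (1-p1)/(1+rho).
    """
    if params.p1 is None:
        raise ValueError("full likelihood needs the zero-component mass p1")
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    p1 = params.p1
    p2 = (1.0 - p1) / (1.0 + params.rho)
    p3 = params.rho * p2
    lf2 = negbin_logpmf(n, params.alpha2, params.alpha2, e)
    lf3 = negbin_logpmf(n, params.alpha3, params.beta3, e)
    mix = np.logaddexp(math.log(p2) + lf2, math.log(p3) + lf3)
    if p1 > 0:
        zero_term = np.where(n == 0, math.log(p1), -np.inf)
        mix = np.logaddexp(zero_term, mix)
    total = float(np.sum(mix))
    if not np.isfinite(total):
        bad = int(np.argmax(~np.isfinite(mix)))
        raise FloatingPointError(
            f"non-finite likelihood term at datum {bad}: N={n[bad]}, E={e[bad]}"
        )
    return total


def _unpack(x: np.ndarray) -> MixtureParams:
    # x = (log a2, log b3, log(a3 - b3), log rho)
    a2 = math.exp(x[0])
    b3 = math.exp(x[1])
    a3 = b3 + math.exp(x[2])
    return MixtureParams(alpha2=a2, alpha3=a3, beta3=b3, rho=math.exp(x[3]))


def _moment_start(n: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Moment-based starting point from the observed RR distribution."""
    lam = n / e
    near_null = lam[(lam > 0.25) & (lam < 2.0)]
    var_null = float(np.var(near_null)) if near_null.size >= 10 else 0.5
    a2 = min(max(1.0 / max(var_null, 1e-3), 0.2), 50.0)
    big = lam[lam > 2.0]
    rho = max(big.size / max(lam.size - big.size, 1), 1e-3)
    if big.size >= 10:
        m, v = float(np.mean(big)), float(np.var(big))
        b3 = min(max(m / max(v, 1e-3), 1e-3), 10.0)
        a3 = max(m * b3, b3 * 1.5)
    else:
        a3, b3 = 1.0, 0.25
    return np.array([math.log(a2), math.log(b3), math.log(a3 - b3), math.log(rho)])


# fixed fallback starts: (a2, a3, b3, rho) on the raw scale
_FIXED_STARTS = (
    (2.0, 1.0, 0.2, 0.1),
    (1.0, 0.5, 0.05, 0.5),
    (5.0, 2.0, 0.5, 0.05),
    (0.5, 0.3, 0.03, 1.0),
)


def fit_conditional(
    n: np.ndarray,
    e: np.ndarray,
    gtol: float = 1e-6,
) -> FitResult:
    """Constrained MLE of (a2, a3, b3, rho) under the conditional likelihood.

    Multi-start quasi-Newton optimisation in log-parameters; the
    deterministic start list is a moment-based start plus four fixed
    points, and the best converged likelihood wins.
    """
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    keep = n > 0
    n, e = n[keep], e[keep]
    if n.size < 4:
        raise ValueError(f"need at least 4 combinations with N > 0, got {n.size}")
    if np.any(e <= 0):
        raise ValueError("all expected frequencies must be positive")

    def objective(x: np.ndarray) -> float:
        try:
            return -conditional_loglik(_unpack(x), n, e)
        except (OverflowError, FloatingPointError):
            return 1e12

    starts = [_moment_start(n, e)]
    starts += [
        np.array([math.log(a2), math.log(b3), math.log(a3 - b3), math.log(rho)])
        for a2, a3, b3, rho in _FIXED_STARTS
    ]
    # generous box in log space: shapes/rates in [1e-5, 1e5], rho in [1e-8, 1e4];
    # RRs and dispersions outside this range are not scientifically meaningful
    log_bounds = [(-11.5, 11.5), (-11.5, 11.5), (-11.5, 11.5), (-18.4, 9.3)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, np.clip(x0, [b[0] for b in log_bounds], [b[1] for b in log_bounds]),
            method="L-BFGS-B", bounds=log_bounds,
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(best.x)
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_used=int(n.size),
        message=str(best.message),
    )


def adjusted_fdr(k, e, params: MixtureParams) -> np.ndarray:
    """Local FDR: posterior probability of the background (mean-1) component.

    fdr = F(k;a2,a2,E) / (F(k;a2,a2,E) + rho F(k;a3,b3,E)), in (0, 1),
    for observed counts k > 0 at expected frequency E > 0.
    """
    k = np.asarray(k, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(k <= 0):
        raise ValueError("adjusted FDR is defined for N > 0")
    if np.any(e <= 0):
        raise ValueError("adjusted FDR requires E > 0")
    lf2 = negbin_logpmf(k, params.alpha2, params.alpha2, e)
    lf3 = negbin_logpmf(k, params.alpha3, params.beta3, e)
    out = special.expit(lf2 - lf3 - math.log(params.rho))
    return out if out.ndim else float(out)


def component_moments(params: MixtureParams) -> tuple[float, float, float, float]:
    """(mean, SD) of the background and signal gamma components.

    mean = a/b and SD = sqrt(a)/b per component; the background mean is
    1 by construction and its SD is 1/sqrt(a2).
    """
    mean2 = 1.0
    sd2 = 1.0 / math.sqrt(params.alpha2)
    mean3 = params.alpha3 / params.beta3
    sd3 = math.sqrt(params.alpha3) / params.beta3
    return mean2, sd2, mean3, sd3
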