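"""Propensity-score machinery and expected frequencies under the no-DDI baseline.

Confounding in spontaneous-report data comes mostly from comedications:
patients on interacting drug pairs tend to share background therapy that
itself predicts the ADE.  The adjustment pipeline is

1. principal components of the binary report x comedication matrix
   (covariance PCA, no unit-variance scaling);
2. per-drug propensity scores PS = P(drug | PCs) from a logistic model;
3. a per-combination logistic outcome model
   logit P(ADE) = b0 + b1 D1 + b2 D2 + b3 D1 D2 + b4 PS1 + b5 PS2;
4. the expected pair frequency under no interaction (b3 dropped),
   summed over the doubly exposed reports:
   E = sum_i invlogit(b0 + b1 + b2 + b4 PS1_i + b5 PS2_i).

Without PS terms the model collapses to the plain multiplicative-odds
baseline E = invlogit(b0 + b1 + b2) * (g + h).

All logistic fits share one Newton (IRLS) maximum-likelihood routine with
step-halving, a relative log-likelihood tolerance of 1e-8, at most 100
iterations, and an optional small ridge guard for quasi-separated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PCBasis",
    "PSModel",
    "InteractionFit",
    "LogisticFitError",
    "compute_pc_basis",
    "pc_scores",
    "fit_ps",
    "fit_interaction",
    "expected_unadjusted",
    "expected_adjusted",
]


class LogisticFitError(RuntimeError):
    """Logistic MLE failed: rank deficiency, separation, or non-convergence."""


def _invlogit(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def _logistic_newton(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> tuple[np.ndarray, bool, int, float]:
    """Newton/IRLS logistic MLE.  Returns (beta, converged, n_iter, loglik).

    Convergence: relative log-likelihood change < tol.  Steps that do not
    improve the penalized log-likelihood are halved (up to 20 times).
    ``ridge`` adds a small L2 penalty to the Hessian and gradient as a
    quasi-separation guard (off by default).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        raise LogisticFitError("outcome has a single class")
    if np.linalg.matrix_rank(X) < p:
        raise LogisticFitError("design matrix is rank deficient")

    def pen_loglik(beta: np.ndarray, eta: np.ndarray) -> float:
        # log L = sum y*eta - log(1 + e^eta), numerically safe form
        ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
        return ll - 0.5 * ridge * float(beta @ beta)

    beta = np.zeros(p)
    # warm start on the intercept-like column if present
    if np.all(X[:, 0] == 1.0):
        ybar = float(y.mean())
        beta[0] = np.log(ybar / (1.0 - ybar))
    eta = X @ beta
    ll = pen_loglik(beta, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _invlogit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        # step halving
        new_beta, new_eta, new_ll = beta, eta, ll
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            cand_eta = X @ cand
            cand_ll = pen_loglik(cand, cand_eta)
            if cand_ll >= ll or np.isclose(cand_ll, ll):
                new_beta, new_eta, new_ll = cand, cand_eta, cand_ll
                break
            scale *= 0.5
        if new_ll < ll:  # no improving step found
            break
        delta = abs(new_ll - ll)
        beta, eta, ll = new_beta, new_eta, new_ll
        if delta < tol * (abs(ll) + 1.0):
            converged = True
            break
    return beta, converged, it, ll


@dataclass(frozen=True)
class PCBasis:
    """Principal components of a column-centered binary comedication matrix."""

    loadings: np.ndarray          # (n_drugs, K) loading vectors, columns
    explained_variance_ratio: np.ndarray  # all components, non-increasing
    k: int
    variance_threshold: float
    column_means: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PSModel:
    """Logistic exposure model on PC scores, with per-report propensity scores."""

    intercept: float
    coef: np.ndarray
    ps: np.ndarray
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class InteractionFit:
    """MLE of the drug-pair outcome model logit P(ADE) = b0+b1 D1+b2 D2+b3 D1D2 [+b4 PS1+b5 PS2]."""

    beta: np.ndarray              # length 6; beta[4] = beta[5] = 0 when PS omitted
    includes_ps: bool
    converged: bool
    n_iter: int
    loglik: float

    @property
    def b0(self) -> float: return float(self.beta[0])
    @property
    def b3(self) -> float: return float(self.beta[3])


def compute_pc_basis(comed: np.ndarray, variance_threshold: float = 0.70) -> PCBasis:
    """Covariance PCA of the reports x drugs indicator matrix.

    K is the minimal number of leading components whose cumulative
    explained-variance fraction reaches ``variance_threshold``.  Columns
    are centered but not scaled: rare comedications genuinely carry less
    variance, and unit scaling would inflate them.  The sign of each
    loading vector is fixed so its largest-magnitude entry is positive.
    """
    comed = np.asarray(comed, dtype=float)
    if comed.ndim != 2 or comed.size == 0:
        raise ValueError("comedication matrix must be a nonempty 2-D array")
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must lie in (0, 1]")
    mu = comed.mean(axis=0)
    centered = comed - mu
    if not np.any(centered):
        raise ValueError("comedication matrix has zero variance (all-constant columns)")
    # SVD of the centered matrix; eigenvalues of the covariance are s^2/(n-1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    loadings = vt.T
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCBasis(
        loadings=loadings[:, :k],
        explained_variance_ratio=ratio,
        k=k,
        variance_threshold=variance_threshold,
        column_means=mu,
    )


def pc_scores(comed: np.ndarray, basis: PCBasis) -> np.ndarray:
    """Project (center + rotate) a comedication matrix onto a PC basis."""
    comed = np.asarray(comed, dtype=float)
    return (comed - basis.column_means) @ basis.loadings


def fit_ps(drug_exposure: np.ndarray, scores: np.ndarray, ridge: float = 0.0) -> PSModel:
    """Propensity-score model: logistic regression of exposure on PC scores."""
    y = np.asarray(drug_exposure, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != y.shape[0]:
        scores = scores.T
    X = np.column_stack([np.ones_like(y), scores])
    beta, converged, n_iter, _ = _logistic_newton(X, y, ridge=ridge)
    ps = np.asarray(_invlogit(X @ beta), dtype=float)
    return PSModel(intercept=float(beta[0]), coef=beta[1:], ps=ps,
                   converged=converged, n_iter=n_iter)


def fit_interaction(
    d1: np.ndarray,
    d2: np.ndarray,
    y: np.ndarray,
    ps1: np.ndarray | None = None,
    ps2: np.ndarray | None = None,
    ridge: float = 0.0,
) -> InteractionFit:
    """Fit the per-combination outcome model, with or without PS adjustment.

    Raises :class:`LogisticFitError` on degenerate designs (e.g. no
    exposed reports) or a single-class outcome; callers running many
    combinations should catch it, flag the combination and move on.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    y = np.asarray(y, dtype=float)
    if (ps1 is None) != (ps2 is None):
        raise ValueError("provide both PS vectors or neither")
    includes_ps = ps1 is not None
    cols = [np.ones_like(y), d1, d2, d1 * d2]
    if includes_ps:
        cols += [np.asarray(ps1, dtype=float), np.asarray(ps2, dtype=float)]
    X = np.column_stack(cols)
    beta, converged, n_iter, ll = _logistic_newton(X, y, ridge=ridge)
    full = np.zeros(6)
    full[: len(beta)] = beta
    return InteractionFit(beta=full, includes_ps=includes_ps,
                          converged=converged, n_iter=n_iter, loglik=ll)


def expected_unadjusted(fit: InteractionFit, n_exposed_both: int) -> float:
    """Expected pair frequency under no interaction, no confounder adjustment.

    E = invlogit(b0 + b1 + b2) * (g + h): the multiplicative-odds
    baseline rate applied to every doubly exposed report.
    """
    eta = float(fit.beta[0] + fit.beta[1] + fit.beta[2])
    return float(_invlogit(eta)) * n_exposed_both


def expected_adjusted(fit: InteractionFit, ps1_exposed: np.ndarray, ps2_exposed: np.ndarray) -> float:
    """PS-adjusted expected pair frequency under no interaction.

    Sums the no-interaction ADE probability over the g + h doubly exposed
    reports, each at its own propensity scores.  Reduces exactly to
    :func:`expected_unadjusted` when b4 = b5 = 0.
    """
    if not fit.includes_ps:
        return expected_unadjusted(fit, len(np.atleast_1d(ps1_exposed)))
    ps1_exposed = np.asarray(ps1_exposed, dtype=float)
    ps2_exposed = np.asarray(ps2_exposed, dtype=float)
    if ps1_exposed.shape != ps2_exposed.shape:
        raise ValueError("PS vectors of the doubly exposed reports must have equal length")
    eta = fit.beta[0] + fit.beta[1] + fit.beta[2] + fit.beta[4] * ps1_exposed + fit.beta[5] * ps2_exposed
    return float(np.sum(_invlogit(eta)))
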