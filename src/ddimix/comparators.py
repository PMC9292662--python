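"""Comparator disproportionality statistics: Omega shrinkage and PRR.

The Omega shrinkage measure compares the observed report frequency N of a
drug-drug-ADE combination to an expected frequency E derived from an
additive-odds baseline, on a log2 scale with an empirical-Bayes shrinkage
prior:  Omega = log2((N + alpha) / (E + alpha)).  Under the gamma-Poisson
model N ~ Pois(lambda * E), lambda ~ Gamma(alpha, alpha), the posterior of
lambda is Gamma(N + alpha, rate E + alpha); Omega025 is log2 of its 2.5%
quantile, and a positive Omega025 flags a DDI signal.

The proportional reporting ratio (PRR) treats the drug pair as a "new
drug" and compares its ADE reporting rate to the rate among reports
without the pair; 95% CI lower bounds of the pair PRR and of both
single-drug PRRs feed the classic signal rule
PRR025_d1d2 > max(PRR025_d1, PRR025_d2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .data_model import ContingencyTable, UndefinedRateError

__all__ = [
    "OmegaResult",
    "PrrResult",
    "ZeroCellError",
    "omega_expected",
    "omega_stats",
    "omega",
    "prr",
]


class ZeroCellError(ValueError):
    """A count needed by a PRR ratio or SD term is zero; no automatic correction is applied."""


@dataclass(frozen=True)
class OmegaResult:
    """Omega shrinkage statistic for one combination (log2 scale)."""

    e_additive: float
    omega: float
    omega025: float
    alpha: float


@dataclass(frozen=True)
class PrrResult:
    """PRR point estimates and 95% CI lower bounds for drug1, drug2 and the pair."""

    prr_d1: float
    prr_d2: float
    prr_d1d2: float
    prr025_d1: float
    prr025_d2: float
    prr025_d1d2: float

    @property
    def is_signal(self) -> bool:
        return self.prr025_d1d2 > max(self.prr025_d1, self.prr025_d2)


def omega_expected(ct: ContingencyTable) -> float:
    """Expected pair frequency under the additive-odds no-interaction baseline.

    With odds O_xy = r_xy / (1 - r_xy), the single-drug odds are floored at
    the background odds (O10 <- max(O10, O00), O01 <- max(O01, O00)), so a
    drug can never look protective relative to background, and

        E = (1 - 1 / (O10 + O01 - O00 + 1)) * (g + h).

    Raises :class:`UndefinedRateError` when any marginal rate has a zero
    denominator or equals 1 (infinite odds), or when g + h = 0.
    """
    if ct.n_both == 0:
        raise UndefinedRateError("no reports exposed to both drugs (g + h = 0)")
    rates = {"r00": ct.r00, "r10": ct.r10, "r01": ct.r01}
    for name, r in rates.items():
        if math.isnan(r):
            raise UndefinedRateError(f"rate {name} has a zero denominator")
        if r >= 1.0:
            raise UndefinedRateError(f"rate {name} equals 1; odds are infinite")
    o00 = rates["r00"] / (1 - rates["r00"])
    o10 = max(rates["r10"] / (1 - rates["r10"]), o00)
    o01 = max(rates["r01"] / (1 - rates["r01"]), o00)
    combined = o10 + o01 - o00
    return (1.0 - 1.0 / (combined + 1.0)) * ct.n_both


def omega_stats(n: int, e: float, alpha: float = 0.5) -> OmegaResult:
    """Omega and its lower 95% credibility bound from observed/expected frequencies.

    Omega025 uses the exact Gamma(n + alpha, rate e + alpha) quantile, not a
    normal approximation.  alpha > 0 is the shrinkage prior strength.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if e < 0:
        raise ValueError("expected frequency must be non-negative")
    om = math.log2((n + alpha) / (e + alpha))
    q = stats.gamma.ppf(0.025, a=n + alpha, scale=1.0 / (e + alpha))
    om025 = math.log2(q) if q > 0 else -math.inf
    return OmegaResult(e_additive=float(e), omega=om, omega025=om025, alpha=alpha)


def omega(ct: ContingencyTable, alpha: float = 0.5) -> OmegaResult:
    """Convenience composition: additive-baseline E, then the shrinkage statistics."""
    return omega_stats(ct.n_observed, omega_expected(ct), alpha=alpha)


def _prr_one(cases_in: int, total_in: int, cases_out: int, total_out: int) -> tuple[float, float]:
    """PRR = rate in the exposed stratum / rate outside it, with its 95% lower bound."""
    for name, v in (("exposed cases", cases_in), ("exposed total", total_in),
                    ("comparator cases", cases_out), ("comparator total", total_out)):
        if v <= 0:
            raise ZeroCellError(f"{name} is zero; PRR undefined without a continuity correction")
    ratio = (cases_in / total_in) / (cases_out / total_out)
    sd = math.sqrt(1 / cases_in - 1 / total_in + 1 / cases_out - 1 / total_out)
    return ratio, math.exp(math.log(ratio) - 1.96 * sd)


def prr(ct: ContingencyTable, continuity: bool = False) -> PrrResult:
    """PRR triples for drug1, drug2 and the pair, with 95% CI lower bounds.

    ``continuity=True`` adds 0.5 to every cell before computation; by
    default zero cells raise :class:`ZeroCellError` naming the degenerate
    term instead of being silently corrected.
    """
    v = {k: c + 0.5 if continuity else c for k, c in ct.as_dict().items()}
    a, b, c, d, e, f, g, h = (v[k] for k in "abcdefgh")
    try:
        prr_d1, prr025_d1 = _prr_one(c + g, c + d + g + h, a + e, a + b + e + f)
    except ZeroCellError as err:
        raise ZeroCellError(f"drug1 PRR: {err}") from None
    try:
        prr_d2, prr025_d2 = _prr_one(e + g, e + f + g + h, a + c, a + b + c + d)
    except ZeroCellError as err:
        raise ZeroCellError(f"drug2 PRR: {err}") from None
    try:
        prr_d1d2, prr025_d1d2 = _prr_one(g, g + h, a + c + e, a + b + c + d + e + f)
    except ZeroCellError as err:
        raise ZeroCellError(f"pair PRR: {err}") from None
    return PrrResult(prr_d1, prr_d2, prr_d1d2, prr025_d1, prr025_d2, prr025_d1d2)
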