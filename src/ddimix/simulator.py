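"""Synthetic spontaneous-report studies for benchmarking DDI detectors.

Each simulated drug pair is an independent cohort of reports.  Per
report, two propensity scores PS1, PS2 ~ Beta(a, b) (default Beta(1, 6),
mean exposure prevalence 1/7) drive independent Bernoulli drug exposures
D1, D2, and the ADE outcome Y follows the logistic model

    logit P(Y = 1) = b0 + b1 D1 + b2 D2 + b3 D1*D2 + b4 PS1 + b5 PS2.

True DDI signals have b3 > 0, negative controls b3 < 0; b4, b5 inject
confounding through the propensity scores.  Coefficients are drawn
uniformly from per-situation ranges:

Situation (a) — signals mix NPIRR and PIRR patterns, no confounding:
  b0 ~ U[-6,-5]; b1, b2 ~ U[-0.8, 0.8]; b3 ~ U[0.1, 1] (signal) or
  U[-1, -0.1] (negative); b4 = b5 = 0.
Situation (b) — signals are NPIRR only (one drug protective-ish):
  signal b1 ~ U[0.1, 2], b2 ~ U[-2, 0.1]; negatives as in (a); b4 = b5 = 0.
Situation (c) — as (a) plus confounding:
  signal b4, b5 ~ U[-2, 1]; negative b4, b5 ~ U[-1, 1].

Defaults reproduce the full-scale study design (100 000 reports per pair,
10 000 signals + 10 000 negatives); desk-scale runs shrink the pair count.
Per-pair random streams are spawned from ``SeedSequence(seed,
spawn_key=(pair_index,))`` so pair i is bit-identical regardless of how
many pairs the study contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .data_model import ContingencyTable

__all__ = [
    "BETA_RANGES",
    "SimulationConfig",
    "SimulatedPair",
    "SimulatedStudy",
    "draw_pair_params",
    "simulate_pair",
    "iter_pairs",
    "simulate_study",
]

# per-situation uniform ranges for (b1, b2, b3, b4, b5); b0 is always U[-6,-5]
BETA_RANGES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "a": {
        "signal":   {"b1": (-0.8, 0.8), "b2": (-0.8, 0.8), "b3": (0.1, 1.0),
                     "b4": (0.0, 0.0), "b5": (0.0, 0.0)},
        "negative": {"b1": (-0.8, 0.8), "b2": (-0.8, 0.8), "b3": (-1.0, -0.1),
                     "b4": (0.0, 0.0), "b5": (0.0, 0.0)},
    },
    "b": {
        "signal":   {"b1": (0.1, 2.0), "b2": (-2.0, 0.1), "b3": (0.1, 1.0),
                     "b4": (0.0, 0.0), "b5": (0.0, 0.0)},
        "negative": {"b1": (-0.8, 0.8), "b2": (-0.8, 0.8), "b3": (-1.0, -0.1),
                     "b4": (0.0, 0.0), "b5": (0.0, 0.0)},
    },
    "c": {
        "signal":   {"b1": (-0.8, 0.8), "b2": (-0.8, 0.8), "b3": (0.1, 1.0),
                     "b4": (-2.0, 1.0), "b5": (-2.0, 1.0)},
        "negative": {"b1": (-0.8, 0.8), "b2": (-0.8, 0.8), "b3": (-1.0, -0.1),
                     "b4": (-1.0, 1.0), "b5": (-1.0, 1.0)},
    },
}
_B0_RANGE = (-6.0, -5.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings; defaults are the full-scale design."""

    situation: str = "a"
    n_reports: int = 100_000
    n_signals: int = 10_000
    n_negatives: int = 10_000
    ps_shape: tuple[float, float] = (1.0, 6.0)
    ps_correlation: float = 0.0  # Gaussian-copula correlation between PS1 and PS2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.situation not in BETA_RANGES:
            raise ValueError(f"situation must be one of {sorted(BETA_RANGES)}")
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.n_signals < 0 or self.n_negatives < 0:
            raise ValueError("pair counts must be non-negative")
        if not (-1.0 < self.ps_correlation < 1.0):
            raise ValueError("ps_correlation must lie in (-1, 1)")


@dataclass(frozen=True)
class SimulatedPair:
    """One simulated drug-pair cohort with its generating truth."""

    pair_id: str
    label: str  # "signal" or "negative"
    betas: np.ndarray  # (b0..b5)
    table: ContingencyTable
    ps1: np.ndarray | None = field(default=None, repr=False)
    ps2: np.ndarray | None = field(default=None, repr=False)
    d1: np.ndarray | None = field(default=None, repr=False)
    d2: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    def drop_reports(self) -> "SimulatedPair":
        return replace(self, ps1=None, ps2=None, d1=None, d2=None, y=None)


@dataclass(frozen=True)
class SimulatedStudy:
    config: SimulationConfig
    pairs: list[SimulatedPair]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label == "signal" for p in self.pairs], dtype=int)


def draw_pair_params(config: SimulationConfig, label: str, rng: np.random.Generator) -> np.ndarray:
    """Draw (b0..b5) uniformly from the situation/label ranges."""
    if label not in ("signal", "negative"):
        raise ValueError("label must be 'signal' or 'negative'")
    ranges = BETA_RANGES[config.situation][label]
    betas = np.empty(6)
    betas[0] = rng.uniform(*_B0_RANGE)
    for i, name in enumerate(("b1", "b2", "b3", "b4", "b5"), start=1):
        lo, hi = ranges[name]
        betas[i] = lo if lo == hi else rng.uniform(lo, hi)
    return betas


def simulate_pair(
    betas: np.ndarray,
    n_reports: int,
    ps_shape: tuple[float, float],
    rng: np.random.Generator,
    pair_id: str = "pair",
    label: str = "signal",
    ps_correlation: float = 0.0,
) -> SimulatedPair:
    """Simulate one pair cohort: PS ~ Beta, D | PS ~ Bernoulli, Y per the outcome model."""
    if n_reports <= 0:
        raise ValueError("n_reports must be positive")
    a, b = ps_shape
    if ps_correlation == 0.0:
        ps1 = rng.beta(a, b, n_reports)
        ps2 = rng.beta(a, b, n_reports)
    else:
        # Gaussian copula; marginals stay Beta(a, b)
        from scipy import stats

        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, ps_correlation], [ps_correlation, 1.0]], size=n_reports
        )
        u = stats.norm.cdf(z)
        ps1 = stats.beta.ppf(u[:, 0], a, b)
        ps2 = stats.beta.ppf(u[:, 1], a, b)
    d1 = (rng.random(n_reports) < ps1).astype(np.int8)
    d2 = (rng.random(n_reports) < ps2).astype(np.int8)
    b0, b1, b2, b3, b4, b5 = betas
    eta = b0 + b1 * d1 + b2 * d2 + b3 * (d1 & d2) + b4 * ps1 + b5 * ps2
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n_reports) < p).astype(np.int8)
    table = _tabulate_arrays(d1, d2, y)
    return SimulatedPair(pair_id=pair_id, label=label, betas=np.asarray(betas, dtype=float),
                         table=table, ps1=ps1, ps2=ps2, d1=d1, d2=d2, y=y)


def _tabulate_arrays(d1: np.ndarray, d2: np.ndarray, y: np.ndarray) -> ContingencyTable:
    idx = d1.astype(np.int64) + 2 * d2.astype(np.int64) + 4 * y.astype(np.int64)
    cells = np.bincount(idx, minlength=8)
    return ContingencyTable(
        a=int(cells[4]), b=int(cells[0]),
        c=int(cells[5]), d=int(cells[1]),
        e=int(cells[6]), f=int(cells[2]),
        g=int(cells[7]), h=int(cells[3]),
    )


def _pair_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def iter_pairs(config: SimulationConfig) -> Iterator[SimulatedPair]:
    """Stream the study's pairs one at a time (signals first), with report data attached.

    Memory-friendly: callers that only need summaries should drop the
    per-report arrays (``pair.drop_reports()``) as they go.
    """
    total = config.n_signals + config.n_negatives
    for i in range(total):
        label = "signal" if i < config.n_signals else "negative"
        rng = _pair_rng(config, i)
        betas = draw_pair_params(config, label, rng)
        yield simulate_pair(
            betas, config.n_reports, config.ps_shape, rng,
            pair_id=f"pair{i:07d}", label=label,
            ps_correlation=config.ps_correlation,
        )


def simulate_study(config: SimulationConfig, store_reports: bool = False) -> SimulatedStudy:
    """Materialize the whole labeled study.

    ``store_reports=True`` keeps the per-report arrays on every pair; at
    the full-scale design that is ~20 GB, so the default retains only the
    contingency tables and generating parameters.
    """
    pairs = [p if store_reports else p.drop_reports() for p in iter_pairs(config)]
    return SimulatedStudy(config=config, pairs=pairs)
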