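"""Pipeline stages: score combinations, fit the mixture, benchmark methods.

Two entry modes:

* **report-level** (:func:`run_score` on :class:`~ddimix.data_model.ReportRecord`
  collections): enumerates frequent drug pairs, builds comedication-PC
  propensity scores, and produces the full scored table (Omega, PRR,
  unadjusted and PS-adjusted expected frequencies).
* **simulation** (:func:`run_benchmark`): streams a synthetic study,
  scores each pair with the true propensity scores, fits the conditional
  mixture across pairs and reports per-method AUC against the labels.

Stage outputs are plain TSV so any stage can be rerun in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators, evaluation, mixture_fdr, ps_expectation
from .data_model import (
    ContingencyTable,
    PairKey,
    ReportRecord,
    UndefinedRateError,
    classify_pattern,
    enumerate_pairs,
    tabulate,
)
from .simulator import SimulationConfig, SimulatedPair, iter_pairs

logger = logging.getLogger("ddimix")

__all__ = ["RunConfig", "BenchmarkResult", "score_simulated_pair", "run_score",
           "score_contingency", "fit_mixture_on_scores", "attach_fdr", "run_benchmark"]

SCORE_COLUMNS = [
    "drug1", "drug2", "ade", "N", "E_additive", "omega", "omega025",
    "prr_d1", "prr_d2", "prr_d1d2", "prr025_d1", "prr025_d2", "prr025_d1d2",
    "prr_signal", "E_unadjusted", "E_adjusted", "converged", "pattern",
]


@dataclass(frozen=True)
class RunConfig:
    """Shared pipeline settings; defaults follow standard practice for FAERS-style data."""

    alpha: float = 0.5              # Omega shrinkage prior
    variance_threshold: float = 0.70  # PC explained-variance cutoff
    min_pair_freq: int = 50         # strict pair co-occurrence filter
    continuity: bool = False        # PRR +0.5 continuity correction
    ridge: float = 0.0              # logistic quasi-separation guard
    seed: int = 0


@dataclass(frozen=True)
class BenchmarkResult:
    auc: dict[str, float]
    scored: pd.DataFrame = field(repr=False)
    mixture: mixture_fdr.FitResult


def _omega_fields(ct: ContingencyTable, alpha: float) -> dict[str, float]:
    try:
        res = comparators.omega(ct, alpha=alpha)
        return {"E_additive": res.e_additive, "omega": res.omega, "omega025": res.omega025}
    except UndefinedRateError:
        return {"E_additive": math.nan, "omega": math.nan, "omega025": math.nan}


def _prr_fields(ct: ContingencyTable, continuity: bool) -> dict[str, float]:
    try:
        res = comparators.prr(ct, continuity=continuity)
        return {
            "prr_d1": res.prr_d1, "prr_d2": res.prr_d2, "prr_d1d2": res.prr_d1d2,
            "prr025_d1": res.prr025_d1, "prr025_d2": res.prr025_d2,
            "prr025_d1d2": res.prr025_d1d2, "prr_signal": res.is_signal,
        }
    except comparators.ZeroCellError:
        return {k: math.nan for k in (
            "prr_d1", "prr_d2", "prr_d1d2", "prr025_d1", "prr025_d2", "prr025_d1d2",
        )} | {"prr_signal": False}


def score_simulated_pair(pair: SimulatedPair, config: RunConfig = RunConfig()) -> dict:
    """Score one simulated pair with every method, using the true propensity scores.

    The PS-adjusted expected frequency comes from the outcome model fit
    with the generating PS values as covariates (simulation never builds
    comedication lists, so there is nothing to estimate PS from).  Pairs
    with N = 0 skip the outcome fit; the mixture stage assigns them
    FDR 1 by convention.
    """
    ct = pair.table
    row: dict = {"pair_id": pair.pair_id, "label": pair.label, "N": ct.n_observed,
                 "n_both": ct.n_both, "pattern": classify_pattern(ct)}
    row.update(_omega_fields(ct, config.alpha))
    row.update(_prr_fields(ct, config.continuity))
    row["E_unadjusted"] = math.nan
    row["E_adjusted"] = math.nan
    row["converged"] = False
    if ct.n_observed > 0 and pair.y is not None:
        try:
            fit = ps_expectation.fit_interaction(
                pair.d1, pair.d2, pair.y, pair.ps1, pair.ps2, ridge=config.ridge
            )
        except ps_expectation.LogisticFitError as err:
            logger.debug("pair %s: outcome fit skipped (%s)", pair.pair_id, err)
        else:
            both = (pair.d1 == 1) & (pair.d2 == 1)
            row["E_unadjusted"] = ps_expectation.expected_unadjusted(fit, ct.n_both)
            row["E_adjusted"] = ps_expectation.expected_adjusted(
                fit, pair.ps1[both], pair.ps2[both]
            )
            row["converged"] = fit.converged
    return row


def score_contingency(
    tables: dict[PairKey, ContingencyTable], config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Degraded-mode scoring from precomputed tables: Omega and PRR only.

    PS-based columns are emitted as NaN with ``converged = False`` since
    report-level covariates are unavailable.
    """
    rows = []
    for key, ct in sorted(tables.items()):
        row: dict = {"drug1": key.drug1, "drug2": key.drug2, "ade": key.ade,
                     "N": ct.n_observed, "pattern": classify_pattern(ct)}
        row.update(_omega_fields(ct, config.alpha))
        row.update(_prr_fields(ct, config.continuity))
        row.update({"E_unadjusted": math.nan, "E_adjusted": math.nan, "converged": False})
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def run_score(
    reports: list[ReportRecord],
    ades: list[str] | None = None,
    config: RunConfig = RunConfig(),
    with_ps: bool = True,
) -> pd.DataFrame:
    """Full report-level scoring pipeline.

    Enumerates drug pairs co-reported more than ``config.min_pair_freq``
    times, crosses them with the requested ADEs, and scores each
    combination.  With ``with_ps``, per-drug propensity scores are fit on
    principal components of the comedication matrix (the focal drug's own
    column excluded from its basis) and the PS-adjusted expectation is
    computed; combinations whose outcome fit fails are flagged, not fatal.
    """
    pairs = enumerate_pairs(reports, config.min_pair_freq, ades)
    drugs = sorted({d for r in reports for d in r.drugs})
    drug_idx = {d: i for i, d in enumerate(drugs)}
    exposure = np.zeros((len(reports), len(drugs)), dtype=float)
    for i, rep in enumerate(reports):
        for d in rep.drugs:
            exposure[i, drug_idx[d]] = 1.0
    ade_indicator = {
        ade: np.array([ade in r.ades for r in reports], dtype=float)
        for ade in {k.ade for k, _ in pairs}
    }

    ps_cache: dict[str, np.ndarray] = {}

    def drug_ps(drug: str) -> np.ndarray | None:
        if drug not in ps_cache:
            others = np.delete(exposure, drug_idx[drug], axis=1)
            try:
                basis = ps_expectation.compute_pc_basis(others, config.variance_threshold)
                scores = ps_expectation.pc_scores(others, basis)
                model = ps_expectation.fit_ps(
                    exposure[:, drug_idx[drug]], scores, ridge=config.ridge
                )
                ps_cache[drug] = model.ps
            except (ValueError, ps_expectation.LogisticFitError) as err:
                logger.warning("PS model for %s failed: %s", drug, err)
                ps_cache[drug] = None
        return ps_cache[drug]

    rows = []
    for key, _count in pairs:
        ct = tabulate(reports, key)
        row: dict = {"drug1": key.drug1, "drug2": key.drug2, "ade": key.ade,
                     "N": ct.n_observed, "pattern": classify_pattern(ct)}
        row.update(_omega_fields(ct, config.alpha))
        row.update(_prr_fields(ct, config.continuity))
        row.update({"E_unadjusted": math.nan, "E_adjusted": math.nan, "converged": False})
        if with_ps:
            ps1, ps2 = drug_ps(key.drug1), drug_ps(key.drug2)
            d1 = exposure[:, drug_idx[key.drug1]]
            d2 = exposure[:, drug_idx[key.drug2]]
            if ps1 is not None and ps2 is not None:
                try:
                    fit = ps_expectation.fit_interaction(
                        d1, d2, ade_indicator[key.ade], ps1, ps2, ridge=config.ridge
                    )
                except ps_expectation.LogisticFitError as err:
                    logger.info("combination %s skipped: %s", key, err)
                else:
                    both = (d1 == 1) & (d2 == 1)
                    row["E_unadjusted"] = ps_expectation.expected_unadjusted(fit, ct.n_both)
                    row["E_adjusted"] = ps_expectation.expected_adjusted(
                        fit, ps1[both], ps2[both]
                    )
                    row["converged"] = fit.converged
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def fit_mixture_on_scores(
    scored: pd.DataFrame, e_col: str = "E_adjusted"
) -> mixture_fdr.FitResult:
    """Fit the conditional three-component mixture across scored combinations.

    Uses combinations with N > 0 and a positive finite expected
    frequency in ``e_col``; others are excluded (and later receive FDR 1
    or NaN from :func:`attach_fdr`).
    """
    n = scored["N"].to_numpy(dtype=float)
    e = scored[e_col].to_numpy(dtype=float)
    use = (n > 0) & np.isfinite(e) & (e > 0)
    fit = mixture_fdr.fit_conditional(n[use], e[use])
    logger.info(
        "mixture fit on %d combinations: a2=%.3f a3=%.3f b3=%.3f rho=%.3f loglik=%.2f",
        fit.n_used, fit.params.alpha2, fit.params.alpha3, fit.params.beta3,
        fit.params.rho, fit.loglik,
    )
    return fit


def attach_fdr(
    scored: pd.DataFrame, fit: mixture_fdr.FitResult, e_col: str = "E_adjusted"
) -> pd.DataFrame:
    """Add ``adjusted_fdr`` and ``neg_log10_fdr`` columns.

    N = 0 combinations get FDR 1 (no evidence can favour the signal
    component); combinations without a usable expected frequency stay NaN
    and rank worst.
    """
    out = scored.copy()
    n = out["N"].to_numpy(dtype=float)
    e = out[e_col].to_numpy(dtype=float)
    fdr = np.full(len(out), np.nan)
    ok = (n > 0) & np.isfinite(e) & (e > 0)
    if ok.any():
        fdr[ok] = mixture_fdr.adjusted_fdr(n[ok], e[ok], fit.params)
    fdr[n == 0] = 1.0
    out["adjusted_fdr"] = fdr
    with np.errstate(divide="ignore"):
        out["neg_log10_fdr"] = -np.log10(fdr)
    return out


def run_benchmark(
    sim_config: SimulationConfig, config: RunConfig = RunConfig()
) -> BenchmarkResult:
    """Simulate a labeled study, score it, and compare detector AUCs.

    The PS-3CMM detector ranks by -log10 adjusted-FDR (expected
    frequencies from the PS-adjusted outcome model); the Omega detector
    ranks by Omega025.  Returns per-method AUCs, the scored table and the
    mixture fit.
    """
    rows = [score_simulated_pair(pair, config) for pair in iter_pairs(sim_config)]
    scored = pd.DataFrame(rows)
    fit = fit_mixture_on_scores(scored)
    scored = attach_fdr(scored, fit)
    labels = (scored["label"] == "signal").to_numpy(dtype=int)
    auc = {
        "ps3cmm": evaluation.roc_auc(scored["neg_log10_fdr"].to_numpy(), labels),
        "omega": evaluation.roc_auc(scored["omega025"].to_numpy(), labels),
        "prr": evaluation.roc_auc(scored["prr025_d1d2"].to_numpy(), labels),
    }
    logger.info("benchmark situation %s: %s", sim_config.situation,
                {k: round(v, 4) for k, v in auc.items()})
    return BenchmarkResult(auc=auc, scored=scored, mixture=fit)
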