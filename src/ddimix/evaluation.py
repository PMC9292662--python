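"""Ranking, ROC/AUC and method-comparison summaries.

AUC is computed as the midrank Mann-Whitney statistic (ties count 1/2),
which equals the area under the empirical ROC curve with the trapezoidal
convention; discrete report counts produce many exact ties, so the
midrank treatment matters.  Missing scores (combinations a method could
not fit) are ranked jointly worst: a method that cannot score a pair has
not detected it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["roc_auc", "rank_table", "compare_topk", "TopKComparison"]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` against binary ``labels`` (1 = positive).

    NaN scores are treated as jointly worst.  Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    finite = np.isfinite(scores)
    if not finite.all():
        floor = (scores[finite].min() - 1.0) if finite.any() else 0.0
        scores = np.where(finite, scores, floor)
    ranks = rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rank_table(scored: pd.DataFrame, by: str, id_col: str = "pair_id") -> pd.DataFrame:
    """Order combinations by a method's score, strongest signal first.

    Scores are taken as "higher = stronger" (rank adjusted-FDR by its
    -log10 transform, not the raw FDR).  NaN scores sort last; ties break
    deterministically by ``id_col``.  Adds a 1-based ``rank`` column.
    """
    if by not in scored.columns:
        raise KeyError(f"no score column {by!r}")
    df = scored.sort_values(
        [by, id_col], ascending=[False, True], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass(frozen=True)
class TopKComparison:
    """Top-k agreement between two rankings, with risk-pattern composition."""

    k: int
    overlap: int
    pattern_fractions_1: dict[str, float]
    pattern_fractions_2: dict[str, float]


def _pattern_fractions(ids: list, patterns: dict) -> dict[str, float]:
    counts = {"NPIRR": 0, "PIRR": 0, "undefined": 0}
    for i in ids:
        counts[patterns.get(i, "undefined")] += 1
    k = max(len(ids), 1)
    return {name: c / k for name, c in counts.items()}


def compare_topk(
    ranked1: pd.DataFrame,
    ranked2: pd.DataFrame,
    k: int,
    patterns: dict | None = None,
    id_col: str = "pair_id",
) -> TopKComparison:
    """Overlap of two methods' top-k sets and their NPIRR/PIRR make-up.

    ``patterns`` maps pair id -> "NPIRR" / "PIRR" / "undefined" (see
    :func:`ddimix.data_model.classify_pattern`); both tables must rank
    the same universe of combinations.
    """
    u1, u2 = set(ranked1[id_col]), set(ranked2[id_col])
    if u1 != u2:
        raise ValueError("rank tables cover different combination universes")
    if k > len(u1):
        raise ValueError(f"k={k} exceeds the {len(u1)} ranked combinations")
    top1 = list(ranked1[id_col].iloc[:k])
    top2 = list(ranked2[id_col].iloc[:k])
    overlap = len(set(top1) & set(top2))
    patterns = patterns or {}
    return TopKComparison(
        k=k,
        overlap=overlap,
        pattern_fractions_1=_pattern_fractions(top1, patterns),
        pattern_fractions_2=_pattern_fractions(top2, patterns),
    )
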