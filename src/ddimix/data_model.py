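"""Report-level data model for spontaneous-report DDI mining.

A spontaneous reporting system (SRS) dataset is a collection of case
reports, each carrying a set of drug names and a set of adverse drug
event (ADE) terms.  For a candidate drug pair and an ADE, the reports
cross-classify into a 2x2x2 contingency table (exposure to drug 1,
exposure to drug 2, ADE present), whose eight cells a..h and four
reporting rates r00, r10, r01, r11 drive every disproportionality
statistic in this package.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ReportRecord",
    "PairKey",
    "ContingencyTable",
    "UndefinedRateError",
    "tabulate",
    "enumerate_pairs",
    "classify_pattern",
    "read_reports_tsv",
    "write_reports_tsv",
    "read_contingency_tsv",
    "write_contingency_tsv",
]


class UndefinedRateError(ValueError):
    """A reporting rate is undefined (zero denominator) or degenerate (rate of 1)."""


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: an opaque id plus drug and ADE term sets."""

    report_id: str
    drugs: frozenset[str] = field(default_factory=frozenset)
    ades: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "ades", frozenset(self.ades))


@dataclass(frozen=True, order=True)
class PairKey:
    """An unordered drug pair crossed with one ADE term.

    The pair is canonicalized so that ``drug1 < drug2`` lexicographically;
    the contingency table is symmetric in the two drugs, so the canonical
    order is purely a labelling convention.
    """

    drug1: str
    drug2: str
    ade: str

    def __post_init__(self) -> None:
        if self.drug1 == self.drug2:
            raise ValueError(f"a drug pair needs two distinct drugs, got {self.drug1!r} twice")
        if self.drug1 > self.drug2:
            d1, d2 = self.drug2, self.drug1
            object.__setattr__(self, "drug1", d1)
            object.__setattr__(self, "drug2", d2)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2x2 counts for one drug-pair/ADE combination.

    Cell layout (exposure drug1, exposure drug2, ADE yes/no):

    ========  ========  =====  =====
    drug1     drug2     ADE    no ADE
    ========  ========  =====  =====
    no        no        a      b
    yes       no        c      d
    no        yes       e      f
    yes       yes       g      h
    ========  ========  =====  =====

    ``N = g`` is the observed report frequency of the combination; the
    reporting rates are r00 = a/(a+b), r10 = c/(c+d), r01 = e/(e+f),
    r11 = g/(g+h).  Rates with zero denominators are NaN, never 0.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int
    g: int
    h: int

    def __post_init__(self) -> None:
        for name in "abcdefgh":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d + self.e + self.f + self.g + self.h

    @property
    def n_observed(self) -> int:
        """Observed report frequency N of the drug-drug-ADE combination (= g)."""
        return self.g

    @property
    def n_both(self) -> int:
        """Number of reports exposed to both drugs (= g + h)."""
        return self.g + self.h

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def r00(self) -> float:
        return self._rate(self.a, self.a + self.b)

    @property
    def r10(self) -> float:
        return self._rate(self.c, self.c + self.d)

    @property
    def r01(self) -> float:
        return self._rate(self.e, self.e + self.f)

    @property
    def r11(self) -> float:
        return self._rate(self.g, self.g + self.h)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in "abcdefgh"}


def tabulate(reports: Iterable[ReportRecord], key: PairKey) -> ContingencyTable:
    """Cross-classify reports into the 2x2x2 table for one pair/ADE key.

    Every report lands in exactly one of the eight cells according to
    whether it mentions ``key.drug1``, ``key.drug2`` and ``key.ade``;
    the cells therefore sum to the number of reports.  An empty input
    yields the all-zero table.
    """
    cells = [0] * 8
    for rep in reports:
        i = (
            (1 if key.drug1 in rep.drugs else 0)
            | ((1 if key.drug2 in rep.drugs else 0) << 1)
            | ((1 if key.ade in rep.ades else 0) << 2)
        )
        cells[i] += 1
    # cells index: bit0 drug1, bit1 drug2, bit2 ade
    return ContingencyTable(
        a=cells[0b100], b=cells[0b000],
        c=cells[0b101], d=cells[0b001],
        e=cells[0b110], f=cells[0b010],
        g=cells[0b111], h=cells[0b011],
    )


def enumerate_pairs(
    reports: Iterable[ReportRecord],
    min_pair_freq: int = 50,
    ades: Sequence[str] | None = None,
) -> list[tuple[PairKey, int]]:
    """Enumerate unordered drug pairs co-reported more than ``min_pair_freq`` times.

    The co-occurrence count of a pair is the number of reports containing
    both drugs (g + h, summed over ADE status).  Pairs are retained under
    a *strict* inequality (count > min_pair_freq) and crossed with each
    requested ADE; when ``ades`` is None, every ADE term observed in the
    reports is used.  Returns ``(PairKey, pair_count)`` tuples sorted by key.
    """
    if min_pair_freq < 0:
        raise ValueError("min_pair_freq must be >= 0")
    reports = list(reports)
    counts: Counter[tuple[str, str]] = Counter()
    seen_ades: set[str] = set()
    for rep in reports:
        seen_ades.update(rep.ades)
        for pair in itertools.combinations(sorted(rep.drugs), 2):
            counts[pair] += 1
    ade_list = sorted(seen_ades) if ades is None else list(ades)
    out = [
        (PairKey(d1, d2, ade), n)
        for (d1, d2), n in counts.items()
        if n > min_pair_freq
        for ade in ade_list
    ]
    out.sort(key=lambda t: t[0])
    return out


def classify_pattern(ct: ContingencyTable) -> str:
    """Classify a combination's single-drug risk pattern.

    ``"NPIRR"`` (nonpositive individual drug relative ADE risk) when at
    least one constituent drug does not raise the ADE reporting rate over
    background, i.e. r01 - r00 <= 0 or r10 - r00 <= 0; ``"PIRR"`` when
    both marginal excesses are strictly positive.  ``"undefined"`` when
    any of the three marginal rates has a zero denominator.
    """
    r00, r10, r01 = ct.r00, ct.r10, ct.r01
    if math.isnan(r00) or math.isnan(r10) or math.isnan(r01):
        return "undefined"
    if (r01 - r00 <= 0) or (r10 - r00 <= 0):
        return "NPIRR"
    return "PIRR"


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_reports_tsv(path) -> list[ReportRecord]:
    """Read a report table: columns report_id, drugs, ades (pipe-delimited sets)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"report_id", "drugs", "ades"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"report TSV missing columns: {sorted(missing)}")
    reports = []
    for row in df.itertuples(index=False):
        drugs = frozenset(x for x in str(row.drugs).split("|") if x)
        ades = frozenset(x for x in str(row.ades).split("|") if x)
        reports.append(ReportRecord(str(row.report_id), drugs, ades))
    ids = [r.report_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate report_id in report TSV")
    return reports


def write_reports_tsv(reports: Iterable[ReportRecord], path) -> None:
    rows = [
        {
            "report_id": r.report_id,
            "drugs": "|".join(sorted(r.drugs)),
            "ades": "|".join(sorted(r.ades)),
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=["report_id", "drugs", "ades"]).to_csv(path, sep="\t", index=False)


def read_contingency_tsv(path) -> dict[PairKey, ContingencyTable]:
    """Read precomputed tables: columns drug1, drug2, ade, a..h."""
    df = pd.read_csv(path, sep="\t", dtype={"drug1": str, "drug2": str, "ade": str})
    required = ["drug1", "drug2", "ade", *"abcdefgh"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"contingency TSV missing columns: {sorted(missing)}")
    out: dict[PairKey, ContingencyTable] = {}
    for row in df.itertuples(index=False):
        key = PairKey(row.drug1, row.drug2, row.ade)
        out[key] = ContingencyTable(*(int(getattr(row, c)) for c in "abcdefgh"))
    return out


def write_contingency_tsv(tables: dict[PairKey, ContingencyTable], path) -> None:
    rows = [
        {"drug1": k.drug1, "drug2": k.drug2, "ade": k.ade, **ct.as_dict()}
        for k, ct in sorted(tables.items())
    ]
    cols = ["drug1", "drug2", "ade", *"abcdefgh"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
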