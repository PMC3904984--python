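"""Statistical comparisons: Yates chi-square, proportion tests, concordance.

These are the planned single comparisons of the study: contingency of
HGT frequency between gene sets (2×2 chi-square with Yates continuity
correction), a proportion-against-reference test for the HGT rate of
lipoylation genes versus the genome-wide average, and the cross-
tabulation of aerobiosis predictions against curated oxygen phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2

from .errors import DataError, ParameterError
from .pathway import AEROBIC_PHENOTYPES, SystemCall


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency cells must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise DataError("contingency table is empty")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    correction: str = "none"
    tail: str = "two_sided"
    p_one_sided: Optional[float] = None
    p_exact: Optional[float] = None


def chi_square_yates(table: ContingencyTable2x2) -> TestResult:
    """Two-sided 2×2 chi-square with Yates continuity correction.

    χ² = N (max(|ad − bc| − N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    A zero marginal leaves the statistic undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise DataError("chi-square undefined: a marginal total is zero")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    stat = n * num / float(np.prod(margins, dtype=float))
    p = float(chi2.sf(stat, 1))
    return TestResult(
        statistic=stat,
        df=1,
        p_value=p,
        correction="yates",
        tail="two_sided",
        p_one_sided=p / 2.0,
    )


def proportion_vs_reference(k: int, n: int, p0: float) -> TestResult:
    """Observed proportion k/n against a fixed reference proportion p0.

    Chi-square goodness of fit of (k, n−k) against (n p0, n (1−p0)),
    df = 1, two-sided; the exact two-sided binomial p-value is reported
    alongside.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    if not 0 <= k <= n:
        raise ParameterError("k must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ParameterError("p0 must lie in (0, 1)")
    expected = np.array([n * p0, n * (1.0 - p0)])
    observed = np.array([k, n - k], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, 1))
    p_exact = float(binomtest(k, n, p0, alternative="two-sided").pvalue)
    return TestResult(
        statistic=stat, df=1, p_value=p, correction="none",
        tail="two_sided", p_one_sided=p / 2.0, p_exact=p_exact,
    )


@dataclass
class ConcordanceReport:
    """Genotype–phenotype concordance of aerobiosis predictions."""

    table: ContingencyTable2x2
    test: TestResult
    n_indeterminate: int
    n_unknown_phenotype: int
    per_order: pd.DataFrame

    @property
    def concordance(self) -> float:
        t = self.table
        return (t.a + t.d) / (t.a + t.b + t.c + t.d)


def concordance_report(calls: Sequence[SystemCall]) -> ConcordanceReport:
    """Cross-tabulate predictions against curated oxygen phenotypes.

    Rows: prediction (aerobic_capable / anaerobe_consistent); columns:
    phenotype (aerobe-facultative-aerotolerant / obligate anaerobe).
    Indeterminate predictions and unknown phenotypes are excluded from
    the test but counted.  Also returns a per-taxonomic-order
    presence/absence breakdown.
    """
    if not calls:
        raise DataError("no calls supplied")
    n_unknown = 0
    n_indet = 0
    cells = {"aa": 0, "ab": 0, "ba": 0, "bb": 0}
    rows = []
    for call in calls:
        inv = call.inventory
        if inv is None:
            raise DataError(f"{call.species_id}: call lacks inventory")
        rows.append(
            {
                "order": inv.order or "unspecified",
                "species_id": inv.species_id,
                "prediction": call.aerobiosis_prediction,
                "oxygen_phenotype": inv.oxygen_phenotype,
                "has_system": bool(call.systems),
                "complete_e2_route": call.aerobiosis_prediction == "aerobic_capable",
            }
        )
        if inv.oxygen_phenotype == "unknown":
            n_unknown += 1
            continue
        if call.aerobiosis_prediction == "indeterminate":
            n_indet += 1
            continue
        pred_aerobic = call.aerobiosis_prediction == "aerobic_capable"
        pheno_aerobic = inv.oxygen_phenotype in AEROBIC_PHENOTYPES
        key = ("a" if pred_aerobic else "b") + ("a" if pheno_aerobic else "b")
        cells[key] += 1
    if n_unknown == len(calls):
        raise DataError("all phenotypes unknown; concordance undefined")
    table = ContingencyTable2x2(cells["aa"], cells["ab"], cells["ba"], cells["bb"])
    test = chi_square_yates(table)
    frame = pd.DataFrame(rows)
    per_order = (
        frame.groupby("order")
        .agg(
            n_species=("species_id", "count"),
            n_with_system=("has_system", "sum"),
            n_aerobic_capable=("complete_e2_route", "sum"),
        )
        .reset_index()
    )
    return ConcordanceReport(
        table=table,
        test=test,
        n_indeterminate=n_indet,
        n_unknown_phenotype=n_unknown,
        per_order=per_order,
    )
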