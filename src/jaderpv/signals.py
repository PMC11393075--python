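"""Disproportionality statistics: 2x2 tables, odds ratios, ROR signals.

A spontaneous-report database has no denominator of exposed-but-healthy
patients, so signal detection compares the reporting frequency of a
drug-event pair against all other pairs.  The reporting odds ratio
(ROR) is the cross-product ratio a*d/(b*c) of the 2x2 table

    ==============  ============  ============
                    target event  other events
    target drug          a             b
    other reports        c             d
    ==============  ============  ============

with a Wald confidence interval on the log scale,
exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d)).  A signal is declared
when the lower 95% bound exceeds 1.  Tables with a zero cell receive
the Haldane-Anscombe correction (0.5 added to every cell) before the
ratio is formed; the attached p-value is the uncorrected Pearson
chi-square on the raw table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisRecord
from .terminology import VITAMIN_D3_ANALOGS

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "build_table",
    "odds_ratio_ci",
    "detect_signals",
    "signals_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts; a+b+c+d is the analyzed dataset size."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose_drug_event(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class SignalResult:
    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    correction_applied: bool
    table: ContingencyTable

    def __post_init__(self) -> None:
        assert self.ci_low <= self.ror <= self.ci_high
        assert self.significant == (self.ci_low > 1.0)


def build_table(
    records: Sequence[AnalysisRecord],
    drug_selector: Callable[[AnalysisRecord], bool],
    event_selector: Callable[[AnalysisRecord], bool],
    comparator: str = "full_dataset",
    restricted_to: Callable[[AnalysisRecord], bool] | None = None,
) -> ContingencyTable:
    """Count the 2x2 table for one drug-event pair.

    With the ``full_dataset`` comparator, c and d come from every
    non-target report in the analyzed dataset; ``restricted`` draws them
    from the caller-supplied subset only.  Each case contributes once.
    """
    if not records:
        raise ValueError("no records")
    if comparator not in ("full_dataset", "restricted"):
        raise ValueError(f"unknown comparator {comparator!r}")
    a = b = c = d = 0
    for r in records:
        if drug_selector(r):
            if event_selector(r):
                a += 1
            else:
                b += 1
        else:
            if comparator == "restricted" and not (
                restricted_to is not None and restricted_to(r)
            ):
                continue
            if event_selector(r):
                c += 1
            else:
                d += 1
    if c + d == 0:
        raise ValueError("empty comparator stratum")
    return ContingencyTable(a, b, c, d)


def odds_ratio_ci(t: ContingencyTable, confidence: float = 0.95) -> SignalResult:
    """Odds ratio with Wald CI; Haldane-Anscombe 0.5 on zero cells.

    The p-value is the two-sided uncorrected Pearson chi-square on the
    raw (uncorrected) table.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    correction = bool((cells == 0).any())
    if correction:
        cells = cells + 0.5
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(ror) - z * se))
    ci_high = float(np.exp(np.log(ror) + z * se))
    raw = np.array([[t.a, t.b], [t.c, t.d]])
    if (raw.sum(axis=0) == 0).any() or (raw.sum(axis=1) == 0).any():
        p_value = 1.0
    else:
        _, p_value, _, _ = stats.chi2_contingency(raw, correction=False)
    return SignalResult(
        ror=float(ror), ci_low=ci_low, ci_high=ci_high,
        p_value=float(p_value), significant=ci_low > 1.0,
        correction_applied=correction, table=t,
    )


def detect_signals(
    records: Sequence[AnalysisRecord],
    drug_list: Sequence[str] = VITAMIN_D3_ANALOGS,
    confidence: float = 0.95,
    pooled_name: str = "active_vitamin_d3",
) -> dict[str, SignalResult]:
    """ROR signal per target analog plus one pooled over the class.

    Uses the full-dataset comparator: for each drug, every non-target
    report in the analyzed set forms the comparison stratum.
    """
    if not drug_list:
        raise ValueError("drug_list must be non-empty")
    out: dict[str, SignalResult] = {}
    for drug in drug_list:
        tab = build_table(
            records,
            drug_selector=lambda r, drug=drug: r.vd3_drug == drug,
            event_selector=lambda r: r.aki,
        )
        out[drug] = odds_ratio_ci(tab, confidence)
    pooled = build_table(
        records,
        drug_selector=lambda r: r.exposed_vd3,
        event_selector=lambda r: r.aki,
    )
    out[pooled_name] = odds_ratio_ci(pooled, confidence)
    return out


def signals_frame(results: Mapping[str, SignalResult]) -> pd.DataFrame:
    rows = []
    for drug, res in results.items():
        t = res.table
        rows.append({
            "drug": drug, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": res.ror, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value, "significant": res.significant,
            "correction_applied": res.correction_applied,
        })
    return pd.DataFrame(rows)
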