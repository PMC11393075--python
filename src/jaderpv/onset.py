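"""Time-to-onset (TTO) analysis.

Latency from starting the suspected drug to adverse-event onset,
counted inclusively: days = (onset date) - (start date) + 1, so a
same-day start and onset counts as day 1.  Only dates resolvable to at
least year-month precision enter the computation (year-month dates
impute day 1 at both endpoints); computed latencies outside [1, 730]
days are excluded — nonpositive values indicate data errors, and the
analysis caps follow-up at 730 days (2 years).  Summaries are reported
in weeks (days / 7).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reports import (
    DateNotResolvable,
    DrugRole,
    PartialDate,
    ReportCase,
    resolve_partial_date,
)
from .terminology import classify_drug, normalize_name

__all__ = [
    "CAP_DAYS",
    "NotComputable",
    "OnsetObservation",
    "OnsetSummary",
    "onset_days",
    "collect_onsets",
    "summarize_onsets",
    "histogram_frame",
]

CAP_DAYS = 730


class NotComputable(enum.Enum):
    """Reason a latency could not enter the analysis."""

    MISSING_DATE = "missing_date"
    UNRESOLVABLE_DATE = "unresolvable_date"  # year-only resolution
    NONPOSITIVE = "nonpositive"              # onset before start
    OVER_CAP = "over_cap"                    # beyond 730 days


def onset_days(
    start: PartialDate | None,
    onset: PartialDate | None,
    cap_days: int = CAP_DAYS,
) -> int | NotComputable:
    """Inclusive day count from start to onset, or the exclusion reason."""
    if start is None or onset is None:
        return NotComputable.MISSING_DATE
    try:
        s = resolve_partial_date(start)
        o = resolve_partial_date(onset)
    except DateNotResolvable:
        return NotComputable.UNRESOLVABLE_DATE
    days = (o - s).days + 1
    if days < 1:
        return NotComputable.NONPOSITIVE
    if days > cap_days:
        return NotComputable.OVER_CAP
    return days


@dataclass(frozen=True)
class OnsetObservation:
    case_id: str
    drug: str
    days: int

    @property
    def weeks(self) -> float:
        return self.days / 7.0


@dataclass(frozen=True)
class OnsetSummary:
    n: int
    median_weeks: float
    q1_weeks: float
    q3_weeks: float
    histogram: tuple[tuple[float, float, int], ...]  # (start, width, count)


def collect_onsets(
    cases: Iterable[ReportCase],
    drug_dict: Mapping[str, frozenset[str]],
    event_dict: Mapping[str, frozenset[str]],
    event_concept: str = "aki",
    cap_days: int = CAP_DAYS,
) -> tuple[list[OnsetObservation], dict[str, int]]:
    """Latency of the first qualifying event for each exposed case.

    For every case with a suspected-role active vitamin D3 analog and at
    least one event in the concept, pairs the analog's start date with
    the earliest computable event onset.  Returns the retained
    observations and a tally of exclusion reasons.
    """
    names = event_dict[event_concept]
    observations: list[OnsetObservation] = []
    excluded: dict[str, int] = {r.value: 0 for r in NotComputable}
    for case in cases:
        analog_entries = [
            d for d in case.drugs
            if d.role is DrugRole.SUSPECTED
            and "active_vitamin_d3" in classify_drug(d.generic_name, drug_dict)
        ]
        if not analog_entries:
            continue
        events = [e for e in case.events if normalize_name(e.pt_name) in names]
        if not events:
            continue
        start = analog_entries[0].start_date
        best: int | None = None
        reason: NotComputable | None = None
        for ev in events:
            res = onset_days(start, ev.onset_date, cap_days)
            if isinstance(res, int):
                best = res if best is None else min(best, res)
            elif reason is None:
                reason = res
        if best is not None:
            observations.append(OnsetObservation(
                case.case_id,
                normalize_name(analog_entries[0].generic_name),
                best,
            ))
        else:
            excluded[(reason or NotComputable.MISSING_DATE).value] += 1
    return observations, excluded


def summarize_onsets(
    observations: Sequence[OnsetObservation],
    bin_width_weeks: float = 4.0,
    max_weeks: float = 104.0,
) -> OnsetSummary:
    """Median and IQR in weeks (linear-interpolation quantiles) plus a
    fixed-width histogram from 0 to ``max_weeks``."""
    if not observations:
        raise ValueError("no onset observations")
    weeks = np.array([o.weeks for o in observations])
    q1, med, q3 = np.quantile(weeks, [0.25, 0.5, 0.75])  # linear interpolation
    edges = np.arange(0.0, max_weeks + bin_width_weeks, bin_width_weeks)
    counts, _ = np.histogram(np.clip(weeks, 0, max_weeks - 1e-9), bins=edges)
    hist = tuple(
        (float(edges[i]), float(bin_width_weeks), int(counts[i]))
        for i in range(len(counts))
    )
    assert sum(c for _, _, c in hist) == len(observations)
    return OnsetSummary(
        n=len(observations),
        median_weeks=float(med),
        q1_weeks=float(q1),
        q3_weeks=float(q3),
        histogram=hist,
    )


def summaries_by_drug(
    observations: Sequence[OnsetObservation], **kwargs
) -> dict[str, OnsetSummary]:
    out = {"all": summarize_onsets(observations, **kwargs)}
    for drug in sorted({o.drug for o in observations}):
        out[drug] = summarize_onsets(
            [o for o in observations if o.drug == drug], **kwargs
        )
    return out


def histogram_frame(summary: OnsetSummary) -> pd.DataFrame:
    return pd.DataFrame(
        list(summary.histogram),
        columns=["bin_start_weeks", "bin_width_weeks", "count"],
    )
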