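"""Exclusion cascade and derivation of the analysis dataset.

The raw spontaneous-report collection is reduced to the analysis set by
a fixed, ordered cascade of exclusion rules (adults with complete
demographics, at least one suspected drug, no intravenous or duplicate
use of the target vitamin D3 analogs).  Surviving cases are flattened
into one :class:`AnalysisRecord` per case: exposure to an active vitamin
D3 analog, the acute-kidney-injury outcome, and the twelve dichotomous
covariates used by the risk model.

Age and weight dichotomies (>= 70 years, < 50 kg) are taken on the
parsed numeric values; with banded input the band lower bound makes
these behave as band-membership checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .reports import NON_NUMERIC_AGE, DrugRole, ReportCase
from .terminology import case_has_event, classify_drug, normalize_name

__all__ = [
    "EXCLUSION_RULES",
    "ExclusionReport",
    "AnalysisRecord",
    "apply_exclusions",
    "derive_records",
    "tabulate_characteristics",
    "COVARIATES",
]

#: Rule names in application order.  Attributed removal counts depend on
#: this order (a case violating several rules is counted under the first);
#: final membership does not.
EXCLUSION_RULES = (
    "age_lt_20",
    "missing_sex_age_weight",
    "non_numeric_age",
    "no_suspected_drug",
    "intravenous_vitamin_d3",
    "duplicate_vitamin_d3",
)


@dataclass
class ExclusionReport:
    initial_count: int
    removed: list[tuple[str, int]]  # (rule_name, cases_removed) in order
    final_count: int
    removed_case_ids: dict[str, list[str]] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.initial_count - sum(n for _, n in self.removed) == self.final_count

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial", self.initial_count)]
        rows += [(rule, -n) for rule, n in self.removed]
        rows.append(("final", self.final_count))
        return pd.DataFrame(rows, columns=["step", "cases"])


def _suspected_analogs(case: ReportCase,
                       drug_dict: Mapping[str, frozenset[str]]) -> set[str]:
    """Distinct active vitamin D3 analogs among suspected-role drugs."""
    out: set[str] = set()
    for dr in case.drugs:
        if dr.role is DrugRole.SUSPECTED and \
                "active_vitamin_d3" in classify_drug(dr.generic_name, drug_dict):
            out.add(normalize_name(dr.generic_name))
    return out


def _violates(case: ReportCase, rule: str,
              drug_dict: Mapping[str, frozenset[str]]) -> bool:
    dm = case.demographics
    age = dm.age_years
    if rule == "age_lt_20":
        return isinstance(age, int) and age < 20
    if rule == "missing_sex_age_weight":
        return dm.sex == "unknown" or age is None or dm.weight_kg is None
    if rule == "non_numeric_age":
        return age is NON_NUMERIC_AGE
    if rule == "no_suspected_drug":
        return not any(d.role is DrugRole.SUSPECTED for d in case.drugs)
    if rule == "intravenous_vitamin_d3":
        return any(
            "active_vitamin_d3" in classify_drug(d.generic_name, drug_dict)
            and d.route.strip().lower() == "intravenous"
            for d in case.drugs
        )
    if rule == "duplicate_vitamin_d3":
        return len(_suspected_analogs(case, drug_dict)) >= 2
    raise ValueError(f"unknown rule {rule!r}")


def apply_exclusions(
    cases: Iterable[ReportCase],
    drug_dict: Mapping[str, frozenset[str]],
) -> tuple[list[ReportCase], ExclusionReport]:
    """Apply the exclusion cascade in its documented order.

    Returns the retained cases and a report whose per-rule counts always
    reconcile with initial and final totals.
    """
    remaining = list(cases)
    initial = len(remaining)
    removed_counts: list[tuple[str, int]] = []
    removed_ids: dict[str, list[str]] = {}
    for rule in EXCLUSION_RULES:
        hit = [c for c in remaining if _violates(c, rule, drug_dict)]
        remaining = [c for c in remaining if not _violates(c, rule, drug_dict)]
        removed_counts.append((rule, len(hit)))
        removed_ids[rule] = [c.case_id for c in hit]
    report = ExclusionReport(initial, removed_counts, len(remaining), removed_ids)
    assert report.reconciles()
    return remaining, report


#: Covariate columns of the analysis record, in risk-model order.
COVARIATES = (
    "sex_female", "age_ge70", "weight_lt50",
    "ckd", "diabetes", "hypertension", "heart_failure",
    "nsaid", "rasi", "loop_diuretic", "thiazide", "mgo",
)

_COMED_CLASSES = {
    "nsaid": "nsaid",
    "rasi": "rasi",
    "loop_diuretic": "loop_diuretic",
    "thiazide": "thiazide_like_diuretic",
    "mgo": "magnesium_oxide",
}


@dataclass(frozen=True)
class AnalysisRecord:
    case_id: str
    exposed_vd3: bool
    vd3_drug: str | None  # analog generic name when exposed
    aki: bool
    sex_female: bool
    age_ge70: bool
    weight_lt50: bool
    ckd: bool
    diabetes: bool
    hypertension: bool
    heart_failure: bool
    nsaid: bool
    rasi: bool
    loop_diuretic: bool
    thiazide: bool
    mgo: bool


def derive_records(
    cases: Iterable[ReportCase],
    drug_dict: Mapping[str, frozenset[str]],
    event_dict: Mapping[str, frozenset[str]],
) -> list[AnalysisRecord]:
    """Flatten filtered cases to analysis records.

    Exposure requires a suspected-role active vitamin D3 analog; the
    outcome is any reported event in the AKI concept; comorbidities come
    from medical history; co-medication flags count drug entries of any
    role other than the target analog itself.
    """
    records = []
    for case in cases:
        analogs = _suspected_analogs(case, drug_dict)
        vd3 = next(iter(analogs)) if analogs else None
        comed = {k: False for k in _COMED_CLASSES}
        for dr in case.drugs:
            classes = classify_drug(dr.generic_name, drug_dict)
            if normalize_name(dr.generic_name) == vd3:
                continue
            for flag, cls in _COMED_CLASSES.items():
                if cls in classes:
                    comed[flag] = True
        dm = case.demographics
        age = dm.age_years
        weight = dm.weight_kg
        records.append(AnalysisRecord(
            case_id=case.case_id,
            exposed_vd3=bool(analogs),
            vd3_drug=vd3,
            aki=case_has_event(case, "aki", event_dict),
            sex_female=dm.sex == "female",
            age_ge70=isinstance(age, int) and age >= 70,
            weight_lt50=weight is not None and weight < 50,
            ckd=case_has_event(case, "ckd", event_dict),
            diabetes=case_has_event(case, "diabetes", event_dict),
            hypertension=case_has_event(case, "hypertension", event_dict),
            heart_failure=case_has_event(case, "heart_failure", event_dict),
            **comed,
        ))
    return records


def records_frame(records: Sequence[AnalysisRecord]) -> pd.DataFrame:
    """Analysis records as a DataFrame (booleans as 0/1 where relevant)."""
    return pd.DataFrame([
        {f.name: getattr(r, f.name) for f in fields(AnalysisRecord)}
        for r in records
    ])


def tabulate_characteristics(records: Sequence[AnalysisRecord]) -> pd.DataFrame:
    """Compare covariate prevalence between AKI and other-event strata.

    Restricted to exposed cases by the caller's contract; each covariate
    gets counts, percentages and a two-sided uncorrected Pearson
    chi-square p-value on its 2x2 table.
    """
    aki = [r for r in records if r.aki]
    other = [r for r in records if not r.aki]
    if not aki or not other:
        raise ValueError("characteristics table undefined: empty stratum")
    rows = []
    for cov in COVARIATES:
        a = sum(getattr(r, cov) for r in aki)
        c = sum(getattr(r, cov) for r in other)
        b, d = len(aki) - a, len(other) - c
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({
            "covariate": cov,
            "aki_n": a, "aki_pct": 100.0 * a / len(aki),
            "other_n": c, "other_pct": 100.0 * c / len(other),
            "chi2": chi2, "p_value": p,
        })
    return pd.DataFrame(rows)
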