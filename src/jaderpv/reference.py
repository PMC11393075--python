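"""Published marginal counts used as a validation fixture.

These are the printed case counts from a nationwide JADER analysis of
acute kidney injury (AKI) among users of active vitamin D3 analogs:
309 AKI cases versus 762 other-adverse-event cases, with per-covariate
counts in each stratum, plus the published per-analog report totals.
They are *inputs* to validation, not outputs of this package: the
univariate odds ratios and chi-square p-values the pipeline computes
from these margins can be checked against the study's printed values.
"""

from __future__ import annotations

from .signals import ContingencyTable

__all__ = [
    "AKI_N",
    "OTHER_N",
    "CHARACTERISTICS_COUNTS",
    "ANALOG_CASE_COUNTS",
    "ANALOG_AKI_COUNTS",
    "covariate_table",
]

#: Case counts in the exposed cohort: AKI stratum and other-AE stratum.
AKI_N = 309
OTHER_N = 762

#: covariate -> (count with covariate among AKI, count among other AEs)
CHARACTERISTICS_COUNTS: dict[str, tuple[int, int]] = {
    "sex_female": (269, 628),
    "age_ge70": (248, 511),
    "weight_lt50": (219, 439),
    "ckd": (59, 121),
    "diabetes": (43, 103),
    "hypertension": (158, 258),
    "heart_failure": (20, 54),
    "nsaid": (69, 105),
    "rasi": (58, 84),
    "loop_diuretic": (32, 79),
    "thiazide": (12, 19),
    "mgo": (75, 99),
}

#: Total reported cases per analog, and AKI cases per analog.
ANALOG_CASE_COUNTS = {"eldecalcitol": 621, "alfacalcidol": 408, "calcitriol": 42}
ANALOG_AKI_COUNTS = {"eldecalcitol": 236, "alfacalcidol": 67, "calcitriol": 6}


def covariate_table(covariate: str) -> ContingencyTable:
    """2x2 table (covariate x AKI stratum) from the published margins.

    a = AKI cases with the covariate, b = AKI cases without,
    c = other-AE cases with, d = other-AE cases without — so the odds
    ratio a*d/(b*c) is the univariate covariate-on-outcome odds ratio.
    """
    a, c = CHARACTERISTICS_COUNTS[covariate]
    return ContingencyTable(a, AKI_N - a, c, OTHER_N - c)
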