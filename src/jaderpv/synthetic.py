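"""Synthetic JADER-dialect data with known ground truth.

Emits four-table spontaneous-report datasets whose generating process
is fully known, so every pipeline stage (loading, exclusion, signal
detection, time-to-onset, risk modelling) can be tested without any
real database download:

* per-case exposure to one of three active vitamin D3 analogs at
  configurable prevalences (defaults at the study scale: 621 / 408 / 42
  exposed cases per 298,891 reports);
* twelve independent dichotomous covariates at configurable
  prevalences (defaults: the study's other-adverse-event column);
* an acute-kidney-injury outcome drawn, for exposed cases, from a
  logistic model with configurable per-covariate odds ratios (defaults:
  the study's multivariate estimates) whose intercept is solved exactly
  so the marginal event rate among exposed cases hits its target;
  non-exposed cases use a flat background reporting rate;
* log-normal onset latencies parameterised by median (in weeks) and
  log-scale sd, attached to start/onset dates in the partial-date
  dialect;
* optional missingness in demographics and dates, and deliberately
  planted exclusion-rule violations whose case ids are recorded.

The same seed always produces byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import datetime as _dt

import numpy as np
import pandas as pd

from .cohort import COVARIATES, derive_records
from .reports import (
    Demographics,
    DrugEntry,
    DrugRole,
    EventEntry,
    HistoryEntry,
    PartialDate,
    ReportCase,
    write_tables,
)
__all__ = ["GeneratorConfig", "GroundTruth", "generate", "generate_files", "truth_check"]

#: Other-adverse-event column prevalences of the study cohort.
DEFAULT_PREVALENCES = {
    "sex_female": 0.824, "age_ge70": 0.671, "weight_lt50": 0.576,
    "ckd": 0.159, "diabetes": 0.135, "hypertension": 0.339,
    "heart_failure": 0.071, "nsaid": 0.138, "rasi": 0.110,
    "loop_diuretic": 0.104, "thiazide": 0.025, "mgo": 0.130,
}

#: Multivariate odds ratios of the study, as generating log-odds.
DEFAULT_LOG_ODDS = {
    "sex_female": math.log(1.14), "age_ge70": math.log(1.47),
    "weight_lt50": math.log(1.55), "ckd": math.log(1.29),
    "diabetes": math.log(0.89), "hypertension": math.log(1.90),
    "heart_failure": math.log(0.72), "nsaid": math.log(1.58),
    "rasi": math.log(1.35), "loop_diuretic": math.log(0.89),
    "thiazide": math.log(1.08), "mgo": math.log(1.96),
}

#: Exposed-case split at the study scale: 621/408/42 per 298,891 reports.
DEFAULT_EXPOSURE = {
    "eldecalcitol": 621 / 298891,
    "alfacalcidol": 408 / 298891,
    "calcitriol": 42 / 298891,
}

_COMED_NAME = {
    "nsaid": "loxoprofen", "rasi": "candesartan",
    "loop_diuretic": "furosemide", "thiazide": "trichlormethiazide",
    "mgo": "magnesium oxide",
}
_COMORBIDITY_PT = {
    "ckd": "chronic kidney disease", "diabetes": "diabetes mellitus",
    "hypertension": "hypertension", "heart_failure": "cardiac failure",
}
_AKI_PT = "acute kidney injury"
_OTHER_PTS = ("nausea", "rash", "pyrexia", "dizziness", "headache", "vomiting")
_FILLER_DRUGS = ("acetaminophen", "amlodipine", "atorvastatin", "omeprazole")

_RULES = (
    "age_lt_20", "missing_sex_age_weight", "non_numeric_age",
    "no_suspected_drug", "intravenous_vitamin_d3", "duplicate_vitamin_d3",
)


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the generator; all defaults follow
    the published cohort where it states a value."""

    n_cases: int = 10000
    seed: int = 20240915
    exposure_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE))
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    outcome_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    #: solved from target_exposed_event_rate when None
    intercept: float | None = None
    #: marginal AKI rate among exposed cases: 309 / 1071
    target_exposed_event_rate: float = 309 / 1071
    #: AKI reporting rate among non-exposed reports (study scale)
    background_event_rate: float = 0.035
    onset_median_weeks: float = 15.4
    onset_log_sd: float = 1.25
    #: resample onset draws beyond the 730-day cap instead of emitting them
    truncate_onset_at_cap: bool = False
    missingness_rates: dict[str, float] = field(default_factory=lambda: {
        "start_date": 0.10, "onset_date": 0.08,
        "start_date_month_only": 0.08, "onset_date_month_only": 0.08,
    })
    violation_counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in _RULES})

    def validate(self) -> None:
        for name, p in {**self.exposure_probs,
                        **self.covariate_prevalences,
                        **self.missingness_rates}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range for {name!r}: {p}")
        if sum(self.exposure_probs.values()) > 1.0:
            raise ValueError("exposure probabilities sum above 1")
        if any(n < 0 for n in self.violation_counts.values()):
            raise ValueError("negative violation count")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        unknown = set(self.violation_counts) - set(_RULES)
        if unknown:
            raise ValueError(f"unknown exclusion rules: {sorted(unknown)}")

    def solved_intercept(self) -> float:
        """Intercept giving the target marginal event rate among exposed.

        The expectation of sigmoid(b0 + sum b_j X_j) over the exact joint
        distribution of the independent binary covariates is computed by
        convolving the per-covariate linear-predictor contributions
        (2^12 atoms), then b0 is found by bisection; the expectation is
        monotone in b0, so the root is unique.
        """
        if self.intercept is not None:
            return self.intercept
        values = np.zeros(1)
        probs = np.ones(1)
        for cov in COVARIATES:
            p = self.covariate_prevalences[cov]
            beta = self.outcome_log_odds[cov]
            values = np.concatenate([values, values + beta])
            probs = np.concatenate([probs * (1 - p), probs * p])

        def mean_rate(b0: float) -> float:
            return float(np.sum(probs / (1.0 + np.exp(-(b0 + values)))))

        lo, hi = -20.0, 20.0
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if mean_rate(mid) < self.target_exposed_event_rate:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0


@dataclass
class LatentRecord:
    case_id: str
    analog: str | None
    covariates: dict[str, bool]
    aki: bool
    onset_days: int | None


@dataclass
class GroundTruth:
    records: dict[str, LatentRecord]
    planted: dict[str, list[str]]          # rule -> case ids
    realized_tables: dict[str, tuple[int, int, int, int]]  # drug -> (a,b,c,d)
    intercept: float

    @property
    def planted_ids(self) -> set[str]:
        return {cid for ids in self.planted.values() for cid in ids}


def _random_full_date(rng: np.random.Generator) -> PartialDate:
    start = _dt.date(2014, 1, 1).toordinal()
    end = _dt.date(2021, 12, 31).toordinal()
    d = _dt.date.fromordinal(int(rng.integers(start, end + 1)))
    return PartialDate(d.year, d.month, d.day)


def _age_token(rng: np.random.Generator, ge70: bool) -> str:
    decade = int(rng.choice([70, 80, 90] if ge70 else [20, 30, 40, 50, 60]))
    if rng.random() < 0.3:  # mix banded and plain-integer ages
        return str(decade + int(rng.integers(0, 10)))
    return f"{decade}s"


def _weight_token(rng: np.random.Generator, lt50: bool) -> str:
    band = int(rng.choice([30, 40] if lt50 else [50, 60, 70]))
    if rng.random() < 0.3:
        return str(band + int(rng.integers(0, 10)))
    return f"{band}s_kg"


def _maybe_degrade(
    rng: np.random.Generator, date: PartialDate,
    miss_rate: float, month_only_rate: float,
) -> PartialDate | None:
    u = rng.random()
    if u < miss_rate:
        return None
    if u < miss_rate + month_only_rate:
        return PartialDate(date.year, date.month)
    return date


def _onset_draw(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    mu = math.log(cfg.onset_median_weeks * 7.0)
    while True:
        days = max(1, int(round(rng.lognormal(mu, cfg.onset_log_sd))))
        if not cfg.truncate_onset_at_cap or days <= 730:
            return days


def generate(cfg: GeneratorConfig) -> tuple[list[ReportCase], GroundTruth]:
    """Generate the case collection and its ground truth.

    Output is a pure function of the config, including the seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    intercept = cfg.solved_intercept()
    analogs = list(cfg.exposure_probs)
    analog_p = np.array([cfg.exposure_probs[a] for a in analogs])
    cases: list[ReportCase] = []
    latent: dict[str, LatentRecord] = {}

    for i in range(cfg.n_cases):
        cid = f"C{i:07d}"
        u = rng.random()
        analog = None
        acc = 0.0
        for name, p in zip(analogs, analog_p):
            acc += p
            if u < acc:
                analog = name
                break
        covs = {c: bool(rng.random() < cfg.covariate_prevalences[c])
                for c in COVARIATES}
        if analog is not None:
            eta = intercept + sum(
                cfg.outcome_log_odds[c] for c in COVARIATES if covs[c])
            p_aki = 1.0 / (1.0 + math.exp(-eta))
        else:
            p_aki = cfg.background_event_rate
        aki = bool(rng.random() < p_aki)

        demo = Demographics(
            cid,
            sex="female" if covs["sex_female"] else "male",
            age_raw=_age_token(rng, covs["age_ge70"]),
            weight_raw=_weight_token(rng, covs["weight_lt50"]),
        )
        drugs: list[DrugEntry] = []
        start_full = _random_full_date(rng)
        miss = cfg.missingness_rates
        start = _maybe_degrade(rng, start_full,
                               miss.get("start_date", 0.0),
                               miss.get("start_date_month_only", 0.0))
        primary = analog if analog is not None else \
            str(rng.choice(_FILLER_DRUGS))
        drugs.append(DrugEntry(cid, primary, DrugRole.SUSPECTED, "oral", start))
        for flag, gname in _COMED_NAME.items():
            if covs[flag]:
                drugs.append(DrugEntry(
                    cid, gname, DrugRole.CONCOMITANT, "oral", start))

        events: list[EventEntry] = []
        onset_days_latent: int | None = None
        if aki:
            onset_days_latent = _onset_draw(rng, cfg)
            onset_full_ord = resolve_ord(start_full) + onset_days_latent - 1
            od = _dt.date.fromordinal(onset_full_ord)
            onset = _maybe_degrade(
                rng, PartialDate(od.year, od.month, od.day),
                miss.get("onset_date", 0.0),
                miss.get("onset_date_month_only", 0.0))
            events.append(EventEntry(cid, _AKI_PT, onset))
        else:
            onset = _maybe_degrade(
                rng, _random_full_date(rng),
                miss.get("onset_date", 0.0),
                miss.get("onset_date_month_only", 0.0))
            events.append(EventEntry(cid, str(rng.choice(_OTHER_PTS)), onset))

        histories = [HistoryEntry(cid, pt)
                     for flag, pt in _COMORBIDITY_PT.items() if covs[flag]]
        cases.append(ReportCase(demo, drugs, events, histories))
        latent[cid] = LatentRecord(cid, analog, covs, aki, onset_days_latent)

    planted = _plant_violations(cfg, rng, cases, latent)

    realized: dict[str, tuple[int, int, int, int]] = {}
    clean = [latent[c.case_id] for c in cases
             if c.case_id not in {x for ids in planted.values() for x in ids}]
    for drug in analogs:
        a = sum(1 for r in clean if r.analog == drug and r.aki)
        b = sum(1 for r in clean if r.analog == drug and not r.aki)
        c_ = sum(1 for r in clean if r.analog != drug and r.aki)
        d = sum(1 for r in clean if r.analog != drug and not r.aki)
        realized[drug] = (a, b, c_, d)
    a = sum(1 for r in clean if r.analog is not None and r.aki)
    b = sum(1 for r in clean if r.analog is not None and not r.aki)
    c_ = sum(1 for r in clean if r.analog is None and r.aki)
    d = sum(1 for r in clean if r.analog is None and not r.aki)
    realized["active_vitamin_d3"] = (a, b, c_, d)

    return cases, GroundTruth(latent, planted, realized, intercept)


def resolve_ord(d: PartialDate) -> int:
    return _dt.date(d.year, d.month or 1, d.day or 1).toordinal()


def _plant_violations(cfg, rng, cases, latent) -> dict[str, list[str]]:
    """Append crafted cases violating exactly one exclusion rule each."""
    planted: dict[str, list[str]] = {r: [] for r in _RULES}
    idx = len(cases)

    def base(cid: str) -> tuple[Demographics, list, list, list]:
        demo = Demographics(cid, "female", "65", "55")
        drugs = [DrugEntry(cid, "eldecalcitol", DrugRole.SUSPECTED, "oral",
                           _random_full_date(rng))]
        events = [EventEntry(cid, str(rng.choice(_OTHER_PTS)))]
        return demo, drugs, events, []

    for rule in _RULES:
        for _ in range(cfg.violation_counts.get(rule, 0)):
            cid = f"V{idx:07d}"
            idx += 1
            demo, drugs, events, hist = base(cid)
            if rule == "age_lt_20":
                demo = Demographics(cid, "female", "15", "55")
            elif rule == "missing_sex_age_weight":
                demo = Demographics(cid, "unknown", "65", "55")
            elif rule == "non_numeric_age":
                demo = Demographics(cid, "female", "elderly", "55")
            elif rule == "no_suspected_drug":
                drugs = [DrugEntry(cid, "eldecalcitol", DrugRole.CONCOMITANT,
                                   "oral", _random_full_date(rng))]
            elif rule == "intravenous_vitamin_d3":
                drugs = [DrugEntry(cid, "calcitriol", DrugRole.SUSPECTED,
                                   "intravenous", _random_full_date(rng))]
            elif rule == "duplicate_vitamin_d3":
                drugs = [
                    DrugEntry(cid, "eldecalcitol", DrugRole.SUSPECTED, "oral",
                              _random_full_date(rng)),
                    DrugEntry(cid, "alfacalcidol", DrugRole.SUSPECTED, "oral",
                              _random_full_date(rng)),
                ]
            cases.append(ReportCase(demo, drugs, events, hist))
            planted[rule].append(cid)
            latent[cid] = LatentRecord(cid, None, {}, False, None)
    return planted


def generate_files(cfg: GeneratorConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write the four CSV tables plus a ground-truth sidecar.

    Same config (and seed) always yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases, truth = generate(cfg)
    write_tables(cases,
                 outdir / "demo.csv", outdir / "drug.csv",
                 outdir / "reac.csv", outdir / "hist.csv")
    rows = []
    for r in truth.records.values():
        rows.append({
            "case_id": r.case_id,
            "analog": r.analog or "",
            "aki": int(r.aki),
            "onset_days": "" if r.onset_days is None else r.onset_days,
            **{c: int(r.covariates.get(c, False)) for c in COVARIATES},
        })
    pd.DataFrame(rows).to_csv(outdir / "ground_truth.csv", index=False)
    planted_rows = [{"rule": rule, "case_id": cid}
                    for rule, ids in truth.planted.items() for cid in ids]
    pd.DataFrame(planted_rows, columns=["rule", "case_id"]).to_csv(
        outdir / "planted_violations.csv", index=False)
    return truth


def truth_check(cases, truth: GroundTruth, drug_dict, event_dict) -> list[str]:
    """Re-derive flags from the emitted cases and compare with the latent
    record for every non-planted case.  Returns a list of discrepancy
    messages (empty = pass)."""
    problems: list[str] = []
    skip = truth.planted_ids
    records = derive_records([c for c in cases if c.case_id not in skip],
                             drug_dict, event_dict)
    for rec in records:
        lat = truth.records.get(rec.case_id)
        if lat is None:
            problems.append(f"{rec.case_id}: no latent record")
            continue
        if rec.exposed_vd3 != (lat.analog is not None) or \
                rec.vd3_drug != lat.analog:
            problems.append(f"{rec.case_id}: exposure mismatch")
        if rec.aki != lat.aki:
            problems.append(f"{rec.case_id}: outcome mismatch")
        for cov in COVARIATES:
            if bool(getattr(rec, cov)) != bool(lat.covariates.get(cov, False)):
                problems.append(f"{rec.case_id}: covariate {cov} mismatch")
                break
    return problems
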