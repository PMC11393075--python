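"""Exclusion cascade, record derivation and the characteristics table."""

import pytest

from jaderpv.cohort import (
    COVARIATES,
    AnalysisRecord,
    apply_exclusions,
    derive_records,
    tabulate_characteristics,
)
from jaderpv.reports import (
    Demographics,
    DrugEntry,
    DrugRole,
    EventEntry,
    HistoryEntry,
    ReportCase,
)
from jaderpv.synthetic import GeneratorConfig, generate


def _case(cid, sex="female", age="65", weight="55", drugs=None,
          events=None, histories=None):
    return ReportCase(
        Demographics(cid, sex, age, weight),
        drugs if drugs is not None else
        [DrugEntry(cid, "eldecalcitol", DrugRole.SUSPECTED, "oral")],
        events if events is not None else [EventEntry(cid, "nausea")],
        histories or [],
    )


@pytest.fixture
def ten_case_fixture():
    """One violation per rule plus four clean cases (hand-traced)."""
    return [
        _case("u20", age="15"),
        _case("missing_wt", weight=""),
        _case("qual_age", age="elderly"),
        _case("conc_only", drugs=[
            DrugEntry("conc_only", "eldecalcitol", DrugRole.CONCOMITANT, "oral")]),
        _case("iv_vd3", drugs=[
            DrugEntry("iv_vd3", "calcitriol", DrugRole.SUSPECTED, "intravenous")]),
        _case("dup_vd3", drugs=[
            DrugEntry("dup_vd3", "eldecalcitol", DrugRole.SUSPECTED, "oral"),
            DrugEntry("dup_vd3", "alfacalcidol", DrugRole.SUSPECTED, "oral")]),
        _case("clean1"), _case("clean2"), _case("clean3"), _case("clean4"),
    ]


def test_hand_traced_cascade(ten_case_fixture, drug_dict):
    kept, report = apply_exclusions(ten_case_fixture, drug_dict)
    assert report.initial_count == 10
    assert report.final_count == 4
    assert dict(report.removed) == {
        "age_lt_20": 1, "missing_sex_age_weight": 1, "non_numeric_age": 1,
        "no_suspected_drug": 1, "intravenous_vitamin_d3": 1,
        "duplicate_vitamin_d3": 1,
    }
    assert {c.case_id for c in kept} == {"clean1", "clean2", "clean3", "clean4"}
    assert report.reconciles()


def test_rule_order_recorded(ten_case_fixture, drug_dict):
    _, report = apply_exclusions(ten_case_fixture, drug_dict)
    assert [r for r, _ in report.removed] == [
        "age_lt_20", "missing_sex_age_weight", "non_numeric_age",
        "no_suspected_drug", "intravenous_vitamin_d3", "duplicate_vitamin_d3"]


def test_multiple_violations_removed_once(drug_dict):
    """A case violating two rules is removed (attributed to the first)."""
    double = _case("dbl", age="15", drugs=[
        DrugEntry("dbl", "eldecalcitol", DrugRole.CONCOMITANT, "oral")])
    kept, report = apply_exclusions([double, _case("ok")], drug_dict)
    assert {c.case_id for c in kept} == {"ok"}
    assert dict(report.removed)["age_lt_20"] == 1
    assert dict(report.removed)["no_suspected_drug"] == 0


def test_reconciliation_on_generated_fixtures(drug_dict):
    for seed in (1, 2, 3):
        cfg = GeneratorConfig(
            n_cases=300, seed=seed,
            exposure_probs={"eldecalcitol": 0.3, "alfacalcidol": 0.2,
                            "calcitriol": 0.05},
            violation_counts={"age_lt_20": 3, "missing_sex_age_weight": 2,
                              "non_numeric_age": 1, "no_suspected_drug": 4,
                              "intravenous_vitamin_d3": 2,
                              "duplicate_vitamin_d3": 3})
        cases, _ = generate(cfg)
        _, report = apply_exclusions(cases, drug_dict)
        assert report.reconciles()


class TestDeriveRecords:
    def test_exposed_with_aki(self, drug_dict, event_dict):
        case = _case("e1", events=[EventEntry("e1", "acute kidney injury")])
        rec, = derive_records([case], drug_dict, event_dict)
        assert rec.exposed_vd3 and rec.vd3_drug == "eldecalcitol" and rec.aki

    def test_unexposed(self, drug_dict, event_dict):
        case = _case("n1", drugs=[
            DrugEntry("n1", "acetaminophen", DrugRole.SUSPECTED, "oral")])
        rec, = derive_records([case], drug_dict, event_dict)
        assert not rec.exposed_vd3 and rec.vd3_drug is None

    def test_concomitant_mgo_sets_flag(self, drug_dict, event_dict):
        case = _case("m1", drugs=[
            DrugEntry("m1", "eldecalcitol", DrugRole.SUSPECTED, "oral"),
            DrugEntry("m1", "magnesium oxide", DrugRole.CONCOMITANT, "oral")])
        rec, = derive_records([case], drug_dict, event_dict)
        assert rec.mgo

    def test_comedication_counts_any_role(self, drug_dict, event_dict):
        """A suspected-role NSAID still counts as NSAID co-medication."""
        case = _case("s1", drugs=[
            DrugEntry("s1", "eldecalcitol", DrugRole.SUSPECTED, "oral"),
            DrugEntry("s1", "loxoprofen", DrugRole.SUSPECTED, "oral")])
        rec, = derive_records([case], drug_dict, event_dict)
        assert rec.nsaid

    def test_banded_age_and_weight_dichotomies(self, drug_dict, event_dict):
        rec, = derive_records(
            [_case("b1", age="70s", weight="40s_kg")], drug_dict, event_dict)
        assert rec.age_ge70 and rec.weight_lt50
        rec, = derive_records(
            [_case("b2", age="60s", weight="50s_kg")], drug_dict, event_dict)
        assert not rec.age_ge70 and not rec.weight_lt50

    def test_comorbidities_from_history(self, drug_dict, event_dict):
        case = _case("h1", histories=[HistoryEntry("h1", "hypertension"),
                                      HistoryEntry("h1", "cardiac failure")])
        rec, = derive_records([case], drug_dict, event_dict)
        assert rec.hypertension and rec.heart_failure
        assert not rec.ckd and not rec.diabetes


def _records_from_counts(cov, a, b, c, d):
    """AnalysisRecords realizing a 2x2 of one covariate against AKI."""
    flags = {k: False for k in COVARIATES}
    recs = []
    for i, (n, aki, val) in enumerate(
            [(a, True, True), (b, True, False), (c, False, True),
             (d, False, False)]):
        for j in range(n):
            recs.append(AnalysisRecord(
                case_id=f"{i}_{j}", exposed_vd3=True, vd3_drug="eldecalcitol",
                aki=aki, **{**flags, cov: val}))
    return recs


class TestCharacteristicsTable:
    def test_sex_p_value_uncorrected_chi_square(self):
        """269/40 vs 628/134 females gives the borderline P = 0.062 only
        without the Yates continuity correction."""
        recs = _records_from_counts("sex_female", 269, 40, 628, 134)
        table = tabulate_characteristics(recs)
        p = table.set_index("covariate").loc["sex_female", "p_value"]
        assert round(p, 3) == 0.062

    def test_hypertension_chi_square_textbook_formula(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 27.617 on these counts
        recs = _records_from_counts("hypertension", 158, 151, 258, 504)
        table = tabulate_characteristics(recs)
        chi2 = table.set_index("covariate").loc["hypertension", "chi2"]
        a, b, c, d = 158, 151, 258, 504
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert chi2 == pytest.approx(27.617, abs=5e-3)

    def test_identical_proportions_give_zero_statistic(self):
        recs = _records_from_counts("ckd", 30, 70, 60, 140)
        table = tabulate_characteristics(recs)
        row = table.set_index("covariate").loc["ckd"]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_empty_stratum_errors(self):
        recs = _records_from_counts("ckd", 5, 5, 0, 0)[:10]
        with pytest.raises(ValueError, match="stratum"):
            tabulate_characteristics(recs)

    def test_percentages(self):
        recs = _records_from_counts("mgo", 75, 234, 99, 663)
        row = tabulate_characteristics(recs).set_index("covariate").loc["mgo"]
        assert row["aki_pct"] == pytest.approx(100 * 75 / 309)
        assert row["other_pct"] == pytest.approx(100 * 99 / 762)
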