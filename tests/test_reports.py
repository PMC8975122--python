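from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vuscooc import reports
from vuscooc.model import (
    CohortGenotypes,
    PhenotypeRecord,
    PhenotypeTable,
    ReceptorStatus,
    SchemaError,
    ValidationError,
)

from conftest import BUILD, vk
from helpers import fisher_enumeration_oracle


# --- data quality report ----------------------------------------------------

@pytest.fixture()
def quality_inputs(tmp_path):
    table = tmp_path / "t.tsv"
    table.write_text(
        "age\tstatus\tid\n"
        "1\t0\ta\n"
        "2\t1\tb\n"
        "3\t2\tc\n"
        "4\t2\td\n"
        "NA\t0\te\n"
        "5\t0\te\n")
    config = reports.FieldConfig([
        reports.FieldSpec("age", "numeric", min_value=0, max_value=120, column=0),
        reports.FieldSpec("status", "categorical", allowed_values=("0", "1"), column=1),
        reports.FieldSpec("id", "identifier", column=2),
    ])
    return str(table), config


def test_data_quality_report_statistics(quality_inputs):
    path, config = quality_inputs
    report = reports.data_quality_report(path, config)
    age = report["fields"]["age"]
    assert age["n_missing"] == 1 and age["n_valid"] == 5
    assert age["stats"] == {
        "min": 1.0, "max": 5.0, "mean": 3.0, "median": 3.0,
        "mode": 1.0, "mode_tied": True,
    }
    status = report["fields"]["status"]
    assert status["n_unexpected"] == 2
    assert status["unexpected_values"] == {"2": 2}
    # count conservation for every field
    for f in report["fields"].values():
        assert f["n"] == f["n_valid"] + f["n_missing"] + f["n_unexpected"]


def test_data_quality_report_mode_and_missing(tmp_path):
    t = tmp_path / "m.tsv"
    t.write_text("x\n5\nNA\n5\n")
    config = reports.FieldConfig([reports.FieldSpec("x", "numeric")])
    f = reports.data_quality_report(str(t), config)["fields"]["x"]
    assert f["n_missing"] == 1
    assert f["stats"]["mode"] == 5.0 and not f["stats"]["mode_tied"]


def test_data_quality_report_headerless_equals_headered(quality_inputs, tmp_path):
    path, config = quality_inputs
    headered = reports.data_quality_report(path, config)
    with open(path) as fh:
        body = "".join(fh.readlines()[1:])
    headerless = tmp_path / "nohdr.tsv"
    headerless.write_text(body)
    assert reports.data_quality_report(
        str(headerless), config, header=False)["fields"] == headered["fields"]


def test_data_quality_report_unknown_column(quality_inputs):
    path, _ = quality_inputs
    config = reports.FieldConfig([reports.FieldSpec("absent", "numeric")])
    with pytest.raises(SchemaError):
        reports.data_quality_report(path, config)


# --- Fisher exact + odds ratio ---------------------------------------------

def test_fisher_exact_known_values():
    # full enumeration over a in {0,1,2} with margins (2,2)/(2,2):
    # p(0)=p(2)=1/6, p(1)=2/3 -> two-sided p for a=2 is 1/6+1/6 = 1/3
    assert reports.fisher_exact_two_sided(2, 0, 0, 2) == pytest.approx(1 / 3)
    # the balanced table is the most probable: every table is included
    assert reports.fisher_exact_two_sided(1, 1, 1, 1) == pytest.approx(1.0)


def test_fisher_exact_zero_margin_undefined():
    with pytest.raises(ValidationError):
        reports.fisher_exact_two_sided(0, 0, 3, 4)
    with pytest.raises(ValidationError):
        reports.fisher_exact_two_sided(2, 0, 3, 0)
    with pytest.raises(ValidationError):
        reports.fisher_exact_two_sided(-1, 1, 1, 1)


@given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
@settings(max_examples=300, derandomize=True)
def test_fisher_exact_matches_enumeration(a, b, c, d):
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    assert reports.fisher_exact_two_sided(a, b, c, d) == pytest.approx(
        fisher_enumeration_oracle(a, b, c, d), abs=1e-10)


def test_odds_ratio_ci_formula():
    or_, low, high = reports.odds_ratio_ci(10, 10, 10, 10)
    assert or_ == pytest.approx(1.0)
    assert low < 1.0 < high
    # direct evaluation of the Woolf interval at (4,1,1,4)
    or_, low, high = reports.odds_ratio_ci(4, 1, 1, 4)
    assert or_ == pytest.approx(16.0)
    se = np.sqrt(1 / 4 + 1 + 1 + 1 / 4)
    assert low == pytest.approx(np.exp(np.log(16) - 1.96 * se))
    assert high == pytest.approx(np.exp(np.log(16) + 1.96 * se))


def test_odds_ratio_zero_cell_correction():
    or_, low, high = reports.odds_ratio_ci(5, 0, 2, 3)
    assert np.isfinite([or_, low, high]).all()
    expected = (5.5 * 3.5) / (0.5 * 2.5)
    assert or_ == pytest.approx(expected)
    with pytest.raises(ValidationError):
        reports.odds_ratio_ci(0, 0, 0, 0)


@given(st.integers(1, 12), st.integers(1, 12), st.integers(1, 12), st.integers(1, 12))
@settings(max_examples=200, derandomize=True)
def test_odds_ratio_stratum_swap_inverts(a, b, c, d):
    """Swapping the strata maps OR to 1/OR when no correction fires."""
    or1, _, _ = reports.odds_ratio_ci(a, b, c, d)
    or2, _, _ = reports.odds_ratio_ci(c, d, a, b)
    assert or1 == pytest.approx(1 / or2)


# --- pathology report -------------------------------------------------------

def rec(i, control=False, er="NEGATIVE", pr="NEGATIVE", her2="NEGATIVE",
        age_dx=None, age_entry=None):
    return PhenotypeRecord(
        id=f"s{i}", is_control=control,
        er_status=ReceptorStatus[er], pr_status=ReceptorStatus[pr],
        her2_status=ReceptorStatus[her2],
        age_at_diagnosis=age_dx, age_at_entry=age_entry)


def test_tnbc_definition_and_denominator():
    phenos = PhenotypeTable({r.id: r for r in [
        rec(1),                                # (-,-,-): TNBC
        rec(2, her2="POSITIVE"),               # (-,-,+)
        rec(3, er="POSITIVE"),                 # (+,-,-)
        rec(4, her2="UNKNOWN"),                # unknown excluded from denominator
    ]})
    carrier = {f"s{i}": (i == 1) for i in range(1, 5)}
    report = reports.pathology_report(phenos, carrier)
    assert report["tnbc"]["n_tnbc"] == 1
    assert report["tnbc"]["n_receptor_status_known"] == 3
    assert report["tnbc"]["proportion"] == pytest.approx(1 / 3)


def test_pathology_feature_stats_and_or():
    samples = (
        [rec(i, er="POSITIVE", age_dx=45) for i in range(1, 5)]      # carriers ER+
        + [rec(i, age_dx=45) for i in range(5, 6)]                   # carrier ER-
        + [rec(i, er="POSITIVE", age_dx=55) for i in range(6, 7)]    # noncarrier ER+
        + [rec(i, age_dx=55) for i in range(7, 11)]                  # noncarriers ER-
    )
    phenos = PhenotypeTable({r.id: r for r in samples})
    carrier = {r.id: (int(r.id[1:]) <= 5) for r in samples}
    report = reports.pathology_report(phenos, carrier)
    er = report["features"]["ER_positive"]
    assert er["status"] == "OK"
    assert er["carriers"] == {"with_feature": 4, "without_feature": 1,
                              "proportion": pytest.approx(0.8)}
    assert er["odds_ratio"] == pytest.approx(16.0)
    assert 0 < er["fisher_p"] <= 1
    ages = report["ages"]["age_at_diagnosis"]
    assert ages["carriers"]["mean"] == pytest.approx(45)
    assert ages["noncarriers"]["mean"] == pytest.approx(55)
    assert ages["welch_p"] is not None


def test_pathology_empty_stratum_not_evaluable():
    samples = [rec(i, age_dx=50) for i in range(1, 5)]
    phenos = PhenotypeTable({r.id: r for r in samples})
    carrier = {r.id: False for r in samples}  # zero carriers
    report = reports.pathology_report(phenos, carrier)
    assert all(f["status"] == reports.NOT_EVALUABLE
               for f in report["features"].values())


def test_pathology_report_contains_no_sample_ids():
    samples = [rec(i, age_dx=50) for i in range(1, 7)]
    phenos = PhenotypeTable({r.id: r for r in samples})
    carrier = {r.id: (int(r.id[1:]) % 2 == 0) for r in samples}
    blob = json.dumps(reports.pathology_report(phenos, carrier))
    assert not any(r.id in blob for r in samples)


# --- genotype-phenotype intersection ----------------------------------------

def test_genotype_phenotype_join_counts():
    v1, v2 = vk("13", 32320000, "C", "G"), vk("13", 32340000, "G", "C")
    alleles = np.zeros((2, 3, 2), dtype=np.int8)
    alleles[0, 0, 1] = 1  # s0 carries v1
    alleles[1, 0, 1] = 1  # s0 carries v2
    alleles[0, 1, 1] = 1  # s1 carries v1
    cohort = CohortGenotypes(
        ["s0", "s1", "s2"], [v1, v2], alleles, np.zeros((2, 3), dtype=bool),
        {v1: "BRCA2", v2: "BRCA2"}, BUILD)
    phenos = PhenotypeTable({
        "s0": PhenotypeRecord(id="s0", is_control=False, age_at_diagnosis=45),
        "s2": PhenotypeRecord(id="s2", is_control=True),
        "sX": PhenotypeRecord(id="sX", is_control=True),
    })
    report = reports.genotype_phenotype_report(cohort, phenos)
    # join count = sum over matched samples of carried-variant count
    assert report["n_joined_records"] == 2
    assert report["n_unmatched_cohort_samples"] == 1   # s1
    assert report["n_unmatched_phenotype_samples"] == 1  # sX
    assert {r["variant"] for r in report["records"]} == {
        v1.coordinate_string(), v2.coordinate_string()}


def test_genotype_phenotype_empty_cohort():
    cohort = CohortGenotypes(
        [], [], np.zeros((0, 0, 2), dtype=np.int8),
        np.zeros((0, 0), dtype=bool), {}, BUILD)
    report = reports.genotype_phenotype_report(cohort, PhenotypeTable({}))
    assert report["n_joined_records"] == 0
    assert report["records"] == []
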