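"""Hospitalization classification, AHR estimation and rate comparison.

The exact-Poisson (Garwood) intervals and two-sample conditional test are
checked against values frozen from an independent reference
implementation (R's poisson.test).
"""

import numpy as np
import pandas as pd
import pytest

from msclaims import outcomes
from msclaims.outcomes import (ahr_from_counts, classify_hospitalizations,
                               compare_rates, compute_ahr, garwood_ci,
                               percent_reduction, procedure_profile,
                               rate_difference)


def _stays(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "admission_date",
                                     "discharge_date", "procedure_code",
                                     "procedure_quantity"])
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    return df


def _lines(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "line_number", "drug_code",
                                     "start", "end"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


LINES = _lines([
    (1, 1, "GLATIRAMER", "2014-01-01", "2015-01-01"),
    (1, 2, "NATALIZUMAB", "2015-01-01", "2016-01-01"),
])


class TestClassification:
    @pytest.mark.parametrize("admission,discharge,expected", [
        ("2015-03-01", "2015-03-02", False),   # one-day stay: excluded
        ("2015-03-01", "2015-03-01", False),   # same-day infusion: excluded
        ("2015-03-01", "2015-03-03", True),    # two days: hospitalization
        ("2015-03-01", "2015-03-05", True),
    ])
    def test_more_than_one_day_rule(self, admission, discharge, expected):
        hosp, _ = classify_hospitalizations(
            _stays([(1, admission, discharge, "MS_RELAPSE_TREATMENT", 1)]), LINES)
        assert bool(hosp.iloc[0]["qualifying"]) is expected

    def test_attributed_to_line_containing_admission(self):
        hosp, _ = classify_hospitalizations(
            _stays([(1, "2015-06-01", "2015-06-05", "MS_RELAPSE_TREATMENT", 1)]),
            LINES)
        assert hosp.iloc[0]["line_number"] == 2
        assert hosp.iloc[0]["line_drug"] == "NATALIZUMAB"

    def test_stay_outside_lines_unattributed(self):
        hosp, _ = classify_hospitalizations(
            _stays([(1, "2017-06-01", "2017-06-05", "MS_RELAPSE_TREATMENT", 1)]),
            LINES)
        assert np.isnan(hosp.iloc[0]["line_number"])

    def test_negative_stay_rejected(self, caplog):
        with caplog.at_level("WARNING", logger="msclaims.outcomes"):
            hosp, _ = classify_hospitalizations(
                _stays([(1, "2015-06-05", "2015-06-01", "MS_RELAPSE_TREATMENT", 1)]),
                LINES)
        assert hosp.empty
        assert "discharge before admission" in caplog.text


class TestGarwood:
    def test_against_reference_implementation(self):
        # frozen from R: poisson.test(12, 100)
        low, high = garwood_ci(12, 100)
        assert low == pytest.approx(0.0620057511, abs=1e-9)
        assert high == pytest.approx(0.2096158505, abs=1e-9)

    def test_zero_events(self):
        est = ahr_from_counts(0, 10)
        assert est.rate == 0.0 and est.ci_low == 0.0
        # frozen from R: poisson.test(0, 10)
        assert est.ci_high == pytest.approx(0.3688879454, abs=1e-9)

    def test_scale_invariance_narrows_ci(self):
        a = ahr_from_counts(12, 100)
        b = ahr_from_counts(24, 200)
        assert b.rate == a.rate
        assert (b.ci_high - b.ci_low) < (a.ci_high - a.ci_low)

    def test_zero_person_time_is_error(self):
        with pytest.raises(ValueError, match="person"):
            ahr_from_counts(3, 0.0)


class TestCompareRates:
    def test_two_sample_p_against_reference(self):
        # frozen from R: poisson.test(c(12, 5), c(100, 80))
        cmp_ = compare_rates(ahr_from_counts(12, 100), ahr_from_counts(5, 80))
        assert cmp_.method == "exact"
        assert cmp_.p_value == pytest.approx(0.2336184620, abs=1e-9)

    def test_equal_rates_give_p_one(self):
        cmp_ = compare_rates(ahr_from_counts(6, 50), ahr_from_counts(6, 50))
        assert cmp_.difference == 0.0
        assert cmp_.p_value == 1.0

    def test_worked_difference_and_reduction(self):
        assert rate_difference(0.124, 0.038) == pytest.approx(0.086)
        assert percent_reduction(0.120, 0.036) == pytest.approx(70.0)

    def test_zero_reference_rate_flags_reduction(self):
        cmp_ = compare_rates(ahr_from_counts(0, 50), ahr_from_counts(3, 50))
        assert cmp_.percent_reduction is None

    def test_weighted_counts_fall_back_to_wald(self):
        a = ahr_from_counts(11.7, 103.2)
        b = ahr_from_counts(4.2, 79.5)
        cmp_ = compare_rates(a, b)
        assert cmp_.method == "wald"
        z = cmp_.difference / np.sqrt(a.rate / a.person_years + b.rate / b.person_years)
        from scipy import stats
        assert cmp_.p_value == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_exact_on_fractional_events_is_error(self):
        with pytest.raises(ValueError, match="integer"):
            compare_rates(ahr_from_counts(1.5, 10), ahr_from_counts(1, 10),
                          method="exact")


class TestProcedureProfile:
    def test_simple_percentages(self):
        hosp, procs = classify_hospitalizations(
            _stays([(1, "2015-06-01", "2015-06-05", "MS_RELAPSE_TREATMENT", 3),
                    (1, "2015-06-01", "2015-06-05", "CRANIUM_MRI", 1)]), LINES)
        assert len(hosp) == 1  # same stay, procedure rows pooled
        prof = procedure_profile(hosp, procs).set_index("procedure_code")
        assert prof.loc["MS_RELAPSE_TREATMENT", "pct"] == pytest.approx(75.0)
        assert prof.loc["CRANIUM_MRI", "pct"] == pytest.approx(25.0)

    def test_hand_computed_per_patient_stats(self):
        stays = _stays([
            (1, "2014-03-01", "2014-03-04", "MS_RELAPSE_TREATMENT", 4),
            (2, "2014-03-01", "2014-03-04", "MS_RELAPSE_TREATMENT", 10),
            (3, "2014-03-01", "2014-03-04", "CRANIUM_MRI", 2),
        ])
        lines = _lines([(p, 1, "GLATIRAMER", "2014-01-01", "2015-01-01")
                        for p in (1, 2, 3)])
        hosp, procs = classify_hospitalizations(stays, lines)
        prof = procedure_profile(hosp, procs).set_index("procedure_code")
        # relapse per hospitalized patient: [4, 10, 0]
        row = prof.loc["MS_RELAPSE_TREATMENT"]
        assert row["per_patient_mean"] == pytest.approx(14 / 3)
        assert row["per_patient_median"] == 4.0
        assert (row["per_patient_min"], row["per_patient_max"]) == (0.0, 10.0)
        assert row["per_patient_sd"] == pytest.approx(np.std([4, 10, 0], ddof=1))
        assert prof["pct"].sum() == pytest.approx(100.0)

    def test_conservation_against_truth(self, linked_clean):
        """Per-code totals in the pipeline profile equal the generator's
        emission counts (qualifying stays only)."""
        truth = linked_clean["truth"]
        hosp, procs = classify_hospitalizations(linked_clean["inp_tag"],
                                                linked_clean["lines"])
        qual = procs[procs["hosp_id"].isin(hosp.loc[hosp["qualifying"], "hosp_id"])]
        got = qual.groupby("procedure_code")["quantity"].sum()
        want = truth.procedures.groupby("procedure_code")["quantity"].sum()
        pd.testing.assert_series_equal(got.sort_index(), want.sort_index(),
                                       check_names=False)


def test_pipeline_ahr_equals_truth_tally(linked_clean):
    """On zero-corruption data the pipeline AHR equals events and
    person-years tallied directly from the ground truth."""
    truth = linked_clean["truth"]
    hosp, _ = classify_hospitalizations(linked_clean["inp_tag"],
                                        linked_clean["lines"])
    est = compute_ahr(hosp, linked_clean["lines"], line_number=1)
    true_events = int((truth.hospitalizations["line_number"] == 1).sum())
    true_py = truth.lines.loc[truth.lines["line_number"] == 1, "person_years"].sum()
    assert est.events == true_events
    assert est.person_years == pytest.approx(true_py, rel=1e-9)
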