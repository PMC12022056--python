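"""Feature pipeline: cleaning, pruning, carry-forward, binning, splitting."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

from conftest import make_patient, years
from mscourse import (ConfigurationError, SimConfig, bin_lesions,
                      build_feature_matrix, carry_forward_features,
                      categorize_treatment, clean_cohort, cumulate_relapses,
                      generate_cohort, prune_rrms_tail,
                      stratified_patient_split)
from mscourse.features import SCHEMAS, get_schema, split_xy
from mscourse.simulate import MriScan, RelapseEvent, VisitRecord


# -- lesion binning ---------------------------------------------------------

@pytest.mark.parametrize("count,expected", [
    (0, 1), (9, 1), (10, 2), (20, 2), (21, 3), (100, 3), (None, -1),
])
def test_bin_lesions_boundaries(count, expected):
    assert bin_lesions(count) == expected


def test_bin_lesions_rejects_negative():
    with pytest.raises(ValueError, match="non-negative"):
        bin_lesions(-1)


# -- treatment categorization ----------------------------------------------

@pytest.mark.parametrize("drug,cat", [
    ("interferon beta", "first_line"),
    ("Natalizumab", "second_line"),
    ("autologous HSCT", "stem_cell"),
    ("methylprednisolone", "relapse_drug"),
])
def test_categorize_treatment_lookup(drug, cat):
    assert categorize_treatment(drug) == cat


def test_unknown_drug_falls_back_to_other(caplog):
    import logging
    with caplog.at_level(logging.WARNING):
        assert categorize_treatment("drugX") == "other"
    assert "drugX" in caplog.text


# -- cleaning ---------------------------------------------------------------

def test_duplicate_visits_collapse_to_one():
    p = make_patient(courses=("RRMS", "RRMS"), visit_years=[1, 1])
    # same date, edss, course -> exact duplicate
    cleaned, report = clean_cohort([p])
    assert len(cleaned[0].visits) == 1
    assert report.removed_visits == {"duplicate_visit": 1}


def test_missing_edss_visit_dropped_with_reason():
    p = make_patient(courses=("RRMS", "RRMS"), visit_years=[0, 1])
    p.visits[1].edss = None
    cleaned, report = clean_cohort([p])
    assert len(cleaned[0].visits) == 1
    assert report.removed_visits == {"missing_edss": 1}


def test_valid_cohort_passes_through_unchanged():
    p = make_patient(courses=("RRMS", "RRMS", "SPMS"))
    cleaned, report = clean_cohort([p])
    assert report.empty
    assert cleaned[0].visits == p.visits


def test_patient_without_birth_date_removed():
    p = replace(make_patient(courses=("RRMS",)), birth_date=None)
    cleaned, report = clean_cohort([p])
    assert cleaned == []
    assert "P1" in report.removed_patients


# -- RRMS tail pruning ------------------------------------------------------

def test_rrms_tail_pruned_within_two_years_of_last_visit():
    p = make_patient(courses=("RRMS",) * 5, visit_years=[0, 5, 8.5, 9.3, 10])
    pruned, report = prune_rrms_tail([p])
    kept_years = [round((v.visit_date - p.debut_date).days / 365.25, 1)
                  for v in pruned[0].visits]
    assert kept_years == [0.0, 5.0]
    assert report.removed_visits == {"rrms_tail": 3}


def test_transitioning_patient_untouched_by_pruning():
    p = make_patient(courses=("RRMS", "RRMS", "SPMS"), visit_years=[0, 1, 1.5])
    pruned, report = prune_rrms_tail([p])
    assert pruned[0].visits == p.visits


def test_single_visit_rrms_patient_dropped_by_pruning():
    p = make_patient(courses=("RRMS",), visit_years=[0])
    pruned, report = prune_rrms_tail([p])
    assert pruned == []
    assert report.removed_patients == ["P1"]


# -- relapse cumulation -----------------------------------------------------

def _relapse(debut, yr, category, steroid=False, remission=True):
    return RelapseEvent(years(debut, yr), category, steroid, remission)


def test_relapse_counts_filtered_by_visit_date():
    debut = date(2000, 1, 1)
    p = make_patient(courses=("RRMS",) * 4, visit_years=[0, 2, 3.5, 4])
    p.visits[1].relapses = [_relapse(debut, 1, "optic_neuritis")]
    p.visits[3].relapses = [_relapse(debut, 3, "multifocal", steroid=True)]
    at_year2 = cumulate_relapses(p, years(debut, 2))
    assert at_year2["n_optic_neuritis"] == 1
    assert at_year2["n_multifocal"] == 0
    assert at_year2["n_steroid_treated_relapses"] == 0
    at_year4 = cumulate_relapses(p, years(debut, 4))
    assert at_year4["n_multifocal"] == 1
    assert at_year4["n_steroid_treated_relapses"] == 1
    assert at_year4["last_relapse_steroid_treated"] == 1.0


def test_no_relapses_gives_zero_counts_and_missing_flags():
    p = make_patient(courses=("RRMS",))
    out = cumulate_relapses(p, p.visits[0].visit_date)
    assert out["n_relapses_total"] == 0
    assert out["last_relapse_steroid_treated"] == -1
    assert out["last_relapse_remission"] == -1


def test_relapse_on_visit_day_included():
    p = make_patient(courses=("RRMS",))
    p.visits[0].relapses = [RelapseEvent(p.visits[0].visit_date, "other", False, True)]
    out = cumulate_relapses(p, p.visits[0].visit_date)
    assert out["n_relapses_total"] == 1


# -- carry-forward ----------------------------------------------------------

def test_mri_carried_forward_with_age_at_measurement():
    debut = date(2000, 1, 1)
    p = make_patient(courses=("RRMS",) * 3, visit_years=[0, 1, 2],
                     birth=date(1968, 10, 15))
    scan_date = p.visits[0].visit_date
    p.visits[0].mri = MriScan(scan_date, 12, 0, 0)
    rows = carry_forward_features(p)
    assert rows[2]["t2_lesion_bin"] == 2  # 12 lesions -> bin 2
    expected_age = round((scan_date - p.birth_date).days / 365.25, 1)
    assert rows[2]["age_at_mri"] == expected_age == 31.2


def test_first_visit_unmeasured_streams_are_minus_one():
    p = make_patient(courses=("RRMS",))
    row = carry_forward_features(p)[0]
    for f in ("sdmt_score", "age_at_sdmt", "t2_lesion_bin", "age_at_mri",
              "current_treatment_category", "first_line_dmt_flag",
              "age_at_treatment_start", "last_relapse_steroid_treated",
              "age_at_last_relapse"):
        assert row[f] == -1
    assert row["edss"] == 2.0
    assert row["n_visits_to_date"] == 1


def test_same_day_measurement_used_for_that_visit():
    p = make_patient(courses=("RRMS",))
    p.visits[0].mri = MriScan(p.visits[0].visit_date, 25, 0, 0)
    assert carry_forward_features(p)[0]["t2_lesion_bin"] == 3


def test_unsorted_visits_raise():
    p = make_patient(courses=("RRMS", "RRMS"), visit_years=[2, 1])
    with pytest.raises(RuntimeError, match="not sorted"):
        carry_forward_features(p)


# -- schemas and matrix -----------------------------------------------------

def test_schema_sizes_and_containment():
    assert len(SCHEMAS["no_msis"]) == 27
    assert set(SCHEMAS["basic_relapse"].features) < set(SCHEMAS["no_msis"].features)
    assert set(SCHEMAS["no_msis"].features) < set(SCHEMAS["full"].features)
    with pytest.raises(ConfigurationError):
        get_schema("bogus")


def test_matrix_missing_markers_are_only_minus_one(fitted_stack):
    matrix = fitted_stack["matrix"]
    feats = matrix[list(fitted_stack["schema"].features)]
    assert not feats.isna().any().any()
    assert np.isfinite(feats.to_numpy()).all()


def test_cumulative_relapse_counts_non_decreasing(fitted_stack):
    matrix = fitted_stack["matrix"]
    for _, grp in matrix.groupby("patient_id"):
        counts = grp["n_relapses_total"].to_numpy()
        assert (np.diff(counts) >= 0).all()


def test_basic_relapse_matrix_is_column_subset(small_cohort):
    records, _ = small_cohort
    m_small = build_feature_matrix(records, SCHEMAS["basic_relapse"])
    m_big = build_feature_matrix(records, SCHEMAS["no_msis"])
    sub = list(SCHEMAS["basic_relapse"].features)
    pd.testing.assert_frame_equal(m_small[sub], m_big[sub])


# -- splitting --------------------------------------------------------------

def test_split_is_disjoint_and_complete(small_cohort):
    records, _ = small_cohort
    split = stratified_patient_split(records, seed=3)
    all_ids = {r.patient_id for r in records}
    union = set(split.train) | set(split.valid) | set(split.calibration) | set(split.test)
    assert union == all_ids
    assert len(split.train) + len(split.valid) + len(split.calibration) \
        + len(split.test) == len(all_ids)


def test_split_respects_archetype_proportions():
    records, truth = generate_cohort(SimConfig(n_patients=100, seed=21))
    split = stratified_patient_split(records, seed=0)
    arch = dict(zip(truth["patient_id"], truth["archetype"]))
    assert abs(len(split.train) - 65) <= 1
    for a, n_arch in (("rrms_only", 68), ("spms_only", 19), ("transitioning", 13)):
        in_train = sum(1 for pid in split.train if arch[pid] == a)
        assert abs(in_train - 0.65 * n_arch) <= 1


def test_split_deterministic_given_seed(small_cohort):
    records, _ = small_cohort
    s1 = stratified_patient_split(records, seed=5)
    s2 = stratified_patient_split(records, seed=5)
    assert s1 == s2
    s3 = stratified_patient_split(records, seed=6)
    assert s1 != s3


def test_bad_split_fractions_rejected(small_cohort):
    records, _ = small_cohort
    with pytest.raises(ConfigurationError):
        stratified_patient_split(records, fractions=(0.5, 0.2, 0.2, 0.2))
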