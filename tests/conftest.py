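"""Shared fixtures: small synthetic cohorts and a fitted conformal stack."""

from datetime import date, timedelta

import numpy as np
import pytest

from mscourse import (ModelSpec, SimConfig, build_feature_matrix, calibrate,
                      clean_cohort, generate_cohort, predict_pvalues,
                      prune_rrms_tail, split_xy, stratified_patient_split,
                      subset_matrix, train)
from mscourse.features import get_schema
from mscourse.simulate import RRMS, SPMS, PatientRecord, VisitRecord


def years(origin: date, y: float) -> date:
    return origin + timedelta(days=round(y * 365.25))


def make_patient(patient_id="P1", courses=("RRMS",), visit_years=None,
                 edss=2.0, birth=date(1970, 1, 1), debut=date(2000, 1, 1),
                 visits_extra=None):
    """Hand-built minimal patient record for feature-rule fixtures."""
    visit_years = visit_years if visit_years is not None else list(range(len(courses)))
    visits = []
    for i, (c, t) in enumerate(zip(courses, visit_years)):
        extra = (visits_extra or {}).get(i, {})
        visits.append(VisitRecord(visit_date=years(debut, t), edss=edss,
                                  recorded_course=c, **extra))
    return PatientRecord(patient_id=patient_id, sex="F", birth_date=birth,
                         debut_date=debut, debut_relapse_age=30.0, visits=visits)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimConfig(n_patients=150, seed=7))


@pytest.fixture(scope="session")
def fitted_stack():
    """Cohort -> features -> split -> RF -> calibrator -> test p-values."""
    cfg = SimConfig(n_patients=400, seed=11, class_separation=1.5)
    records, truth = generate_cohort(cfg)
    records, _ = clean_cohort(records)
    records, _ = prune_rrms_tail(records)
    schema = get_schema("no_msis")
    matrix = build_feature_matrix(records, schema)
    split = stratified_patient_split(records, seed=11)
    train_m = subset_matrix(matrix, split.train | split.valid)
    cal_m = subset_matrix(matrix, split.calibration)
    test_m = subset_matrix(matrix, split.test)
    Xtr, ytr, _ = split_xy(train_m, schema)
    model = train(ModelSpec(seed=11), Xtr, ytr, schema.fingerprint())
    Xc, yc, _ = split_xy(cal_m, schema)
    calibrator = calibrate(model, Xc, yc)
    Xte, yte, gte = split_xy(test_m, schema)
    pairs = predict_pvalues(calibrator, model, Xte, schema.fingerprint())
    truths = [SPMS if v else RRMS for v in yte]
    return dict(records=records, truth=truth, schema=schema, matrix=matrix,
                split=split, model=model, calibrator=calibrator,
                test_matrix=test_m, Xte=Xte, pairs=pairs, truths=truths,
                patient_ids=gte)
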