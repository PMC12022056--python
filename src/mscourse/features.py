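"""Cleaning, carry-forward feature engineering, and patient-level splitting.

Turns raw longitudinal visit records into fixed-width per-visit feature
vectors.  The rules are deliberately simple and fully deterministic:

* visits missing essentials (EDSS, course label, birth or debut date) are
  dropped and counted in a removal report;
* for RRMS-only patients the visits within two years of their last visit are
  pruned -- their clinical endpoint is still undetermined at those visits;
* each visit carries forward the most recent prior-or-same-day value of every
  measurement stream, together with the patient's age when it was collected;
* relapse events are cumulated per category up to the visit day (inclusive);
* MRI lesion counts are binned (<=9 -> 1, 10..20 -> 2, >20 -> 3);
* anything never observed is encoded as -1.

Feature schemas are declared in one place (``SCHEMAS``) so the exact feature
list can be revised without touching pipeline logic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .simulate import (DAYS_PER_YEAR, RRMS, SPMS, ConfigurationError,
                       PatientRecord, RelapseEvent, VisitRecord,
                       largest_remainder_allocation)

logger = logging.getLogger(__name__)

MISSING = -1.0

TREATMENT_CATEGORIES = ("first_line", "second_line", "relapse_drug", "stem_cell", "other")
_TREATMENT_ORDINAL = {c: i + 1 for i, c in enumerate(TREATMENT_CATEGORIES)}

#: Editable drug -> category lookup used by :func:`categorize_treatment`.
DRUG_CATEGORIES: dict[str, str] = {
    "interferon beta": "first_line",
    "glatiramer acetate": "first_line",
    "teriflunomide": "first_line",
    "dimethyl fumarate": "first_line",
    "natalizumab": "second_line",
    "fingolimod": "second_line",
    "rituximab": "second_line",
    "ocrelizumab": "second_line",
    "alemtuzumab": "second_line",
    "cladribine": "second_line",
    "methylprednisolone": "relapse_drug",
    "prednisolone": "relapse_drug",
    "autologous hsct": "stem_cell",
    "fampridine": "other",
    "baclofen": "other",
}


# ---------------------------------------------------------------------------
# feature schemas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSchema:
    """Named, ordered feature list with per-feature kind.

    kinds: ``continuous`` | ``binary`` | ``ordinal_bin``.
    """

    name: str
    features: tuple[str, ...]
    kinds: dict[str, str] = field(default_factory=dict, compare=False)

    def fingerprint(self) -> str:
        payload = self.name + "|" + ",".join(self.features)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __len__(self) -> int:
        return len(self.features)


_BASIC = (
    "edss", "age_at_visit", "sex", "debut_age", "age_at_debut_relapse",
    "disease_duration", "n_visits_to_date",
)
_RELAPSE = (
    "n_relapses_total", "n_optic_neuritis", "n_monofocal", "n_multifocal",
    "n_steroid_treated_relapses", "last_relapse_steroid_treated",
    "last_relapse_remission", "age_at_last_relapse",
)
_NO_MSIS = _BASIC[:6] + (
    "sdmt_score", "age_at_sdmt",
    "current_treatment_category", "first_line_dmt_flag", "second_line_dmt_flag",
    "stem_cell_flag", "other_drug_flag", "age_at_treatment_start",
) + _RELAPSE + (
    "t2_lesion_bin", "t1_gd_brain_bin", "t1_gd_spinal_bin", "age_at_mri",
    "n_visits_to_date",
)
_FULL = _NO_MSIS + ("msis_physical", "msis_psychological", "age_at_msis")

_KINDS = {
    "sex": "binary",
    "first_line_dmt_flag": "binary", "second_line_dmt_flag": "binary",
    "stem_cell_flag": "binary", "other_drug_flag": "binary",
    "last_relapse_steroid_treated": "binary", "last_relapse_remission": "binary",
    "t2_lesion_bin": "ordinal_bin", "t1_gd_brain_bin": "ordinal_bin",
    "t1_gd_spinal_bin": "ordinal_bin",
    "current_treatment_category": "ordinal_bin",
}

SCHEMAS: dict[str, FeatureSchema] = {
    "basic_relapse": FeatureSchema(
        "basic_relapse", _BASIC + _RELAPSE,
        {f: _KINDS.get(f, "continuous") for f in _BASIC + _RELAPSE}),
    "no_msis": FeatureSchema(
        "no_msis", _NO_MSIS, {f: _KINDS.get(f, "continuous") for f in _NO_MSIS}),
    "full": FeatureSchema(
        "full", _FULL, {f: _KINDS.get(f, "continuous") for f in _FULL}),
}

assert len(SCHEMAS["no_msis"]) == 27
assert set(SCHEMAS["basic_relapse"].features) <= set(SCHEMAS["no_msis"].features)
assert set(SCHEMAS["no_msis"].features) <= set(SCHEMAS["full"].features)


def get_schema(name: str) -> FeatureSchema:
    try:
        return SCHEMAS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown feature schema {name!r}; available: {sorted(SCHEMAS)}") from None


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    removed_visits: dict[str, int] = field(default_factory=dict)
    removed_patients: list[str] = field(default_factory=list)

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.removed_visits[reason] = self.removed_visits.get(reason, 0) + n

    @property
    def empty(self) -> bool:
        return not self.removed_visits and not self.removed_patients


def _visit_key(v: VisitRecord) -> tuple:
    return (v.visit_date, v.edss, v.recorded_course)


def clean_cohort(records: Iterable[PatientRecord]) -> tuple[list[PatientRecord], CleaningReport]:
    """Drop duplicate visits and visits missing essential fields.

    Essentials are EDSS, the recorded course label, and the patient-level
    birth and debut dates (a patient missing either loses all visits).
    Visits are re-sorted chronologically; patients left without visits are
    removed and logged.
    """
    report = CleaningReport()
    cleaned: list[PatientRecord] = []
    for rec in records:
        if rec.birth_date is None:
            report.add("missing_birth_date", len(rec.visits))
            report.removed_patients.append(rec.patient_id)
            continue
        if rec.debut_date is None:
            report.add("missing_debut_date", len(rec.visits))
            report.removed_patients.append(rec.patient_id)
            continue
        seen: set[tuple] = set()
        kept: list[VisitRecord] = []
        for v in sorted(rec.visits, key=lambda v: v.visit_date):
            if v.edss is None:
                report.add("missing_edss")
            elif v.recorded_course is None:
                report.add("missing_course")
            elif _visit_key(v) in seen:
                report.add("duplicate_visit")
            else:
                seen.add(_visit_key(v))
                kept.append(v)
        if not kept:
            report.removed_patients.append(rec.patient_id)
            logger.warning("patient %s removed: no valid visits", rec.patient_id)
            continue
        if kept == rec.visits:
            cleaned.append(rec)
        else:
            cleaned.append(replace(rec, visits=kept))
    return cleaned, report


def prune_rrms_tail(records: Iterable[PatientRecord], window_years: float = 2.0,
                    ) -> tuple[list[PatientRecord], CleaningReport]:
    """Remove the undetermined tail of RRMS-only patients.

    For patients whose every visit is recorded RRMS, visits strictly within
    ``window_years`` of that patient's last visit date are removed -- their
    clinical endpoint is not yet determined (the anchoring last visit itself
    is at distance zero and is therefore removed too).  Patients with any
    SPMS visit are untouched.
    """
    report = CleaningReport()
    out: list[PatientRecord] = []
    window_days = window_years * DAYS_PER_YEAR
    for rec in records:
        if any(v.recorded_course == SPMS for v in rec.visits) or not rec.visits:
            out.append(rec)
            continue
        last = rec.visits[-1].visit_date
        kept = [v for v in rec.visits if (last - v.visit_date).days >= window_days]
        removed = len(rec.visits) - len(kept)
        report.add("rrms_tail", removed)
        if not kept:
            report.removed_patients.append(rec.patient_id)
            logger.info("patient %s removed by tail pruning", rec.patient_id)
        else:
            out.append(replace(rec, visits=kept) if removed else rec)
    return out, report


# ---------------------------------------------------------------------------
# feature derivation
# ---------------------------------------------------------------------------

def bin_lesions(count: Optional[int]) -> float:
    """Lesion-count bin: <=9 -> 1, 10..20 -> 2, >20 -> 3; missing -> -1."""
    if count is None:
        return MISSING
    if count < 0:
        raise ValueError(f"lesion count must be non-negative, got {count}")
    if count <= 9:
        return 1.0
    if count <= 20:
        return 2.0
    return 3.0


def categorize_treatment(drug_name: str, lookup: Optional[dict[str, str]] = None) -> str:
    """Map a drug name to its treatment category; unknown drugs -> 'other' (logged)."""
    table = DRUG_CATEGORIES if lookup is None else lookup
    cat = table.get(drug_name.strip().lower())
    if cat is None:
        logger.warning("unknown drug %r categorized as 'other'", drug_name)
        return "other"
    return cat


def cumulate_relapses(patient: PatientRecord, visit_date: date) -> dict:
    """Per-category relapse counts up to and including ``visit_date``.

    Also returns the binary steroid-treatment and remission flags of the
    most recent relapse, and its date (None when no relapse has occurred;
    counts are then zero and flags -1).
    """
    events: list[RelapseEvent] = []
    for v in patient.visits:
        for ev in v.relapses:
            if ev.event_date <= visit_date:
                events.append(ev)
    events.sort(key=lambda e: e.event_date)
    counts = {
        "n_relapses_total": float(len(events)),
        "n_optic_neuritis": float(sum(e.category == "optic_neuritis" for e in events)),
        "n_monofocal": float(sum(e.category == "monofocal" for e in events)),
        "n_multifocal": float(sum(e.category == "multifocal" for e in events)),
        "n_steroid_treated_relapses": float(sum(e.steroid_treated for e in events)),
    }
    if events:
        last = events[-1]
        counts["last_relapse_steroid_treated"] = float(last.steroid_treated)
        counts["last_relapse_remission"] = float(last.remission)
        counts["last_relapse_date"] = last.event_date
    else:
        counts["last_relapse_steroid_treated"] = MISSING
        counts["last_relapse_remission"] = MISSING
        counts["last_relapse_date"] = None
    return counts


def _age_at(birth: date, when: Optional[date]) -> float:
    if when is None:
        return MISSING
    return round((when - birth).days / DAYS_PER_YEAR, 1)


def carry_forward_features(patient: PatientRecord,
                           schema: Optional[FeatureSchema] = None) -> list[dict]:
    """Per-visit feature dictionaries with last-observation carry-forward.

    Each visit uses the most recent prior-or-same-day value of every
    measurement stream together with the patient's age at that measurement;
    streams never observed are -1.  Requires chronologically sorted visits
    (``clean_cohort``'s contract).
    """
    schema = schema or SCHEMAS["no_msis"]
    dates = [v.visit_date for v in patient.visits]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise RuntimeError(f"{patient.patient_id}: visits not sorted; run clean_cohort first")
    birth = patient.birth_date
    debut = patient.debut_date
    if birth is None or debut is None:
        raise RuntimeError(f"{patient.patient_id}: missing birth/debut date; run clean_cohort")

    # carried stream state
    sdmt_score, sdmt_date = MISSING, None
    mri_bins, mri_date = (MISSING, MISSING, MISSING), None
    msis_phys, msis_psych, msis_date = MISSING, MISSING, None
    current_treat, treat_date = MISSING, None
    ever_flags = {c: 0.0 for c in ("first_line", "second_line", "stem_cell", "other")}
    any_treatment = False

    rows: list[dict] = []
    for i, v in enumerate(patient.visits):
        if v.sdmt_score is not None:
            sdmt_score, sdmt_date = float(v.sdmt_score), v.sdmt_date or v.visit_date
        if v.mri is not None:
            mri_bins = (bin_lesions(v.mri.t2_lesion_count),
                        bin_lesions(v.mri.t1_gd_brain_count),
                        bin_lesions(v.mri.t1_gd_spinal_count))
            mri_date = v.mri.scan_date
        if v.msis_physical is not None:
            msis_phys = float(v.msis_physical)
            msis_psych = float(v.msis_psychological) if v.msis_psychological is not None else MISSING
            msis_date = v.msis_date or v.visit_date
        for tr in sorted(v.treatments, key=lambda t: t.start_date):
            cat = tr.category or categorize_treatment(tr.drug)
            current_treat = float(_TREATMENT_ORDINAL.get(cat, _TREATMENT_ORDINAL["other"]))
            treat_date = tr.start_date
            any_treatment = True
            if cat in ever_flags:
                ever_flags[cat] = 1.0

        rel = cumulate_relapses(patient, v.visit_date)

        row = {
            "edss": float(v.edss),
            "age_at_visit": _age_at(birth, v.visit_date),
            "sex": 1.0 if patient.sex == "F" else 0.0,
            "debut_age": _age_at(birth, debut),
            "age_at_debut_relapse": float(patient.debut_relapse_age),
            "disease_duration": round((v.visit_date - debut).days / DAYS_PER_YEAR, 1),
            "n_visits_to_date": float(i + 1),
            "sdmt_score": sdmt_score,
            "age_at_sdmt": _age_at(birth, sdmt_date),
            "current_treatment_category": current_treat,
            "first_line_dmt_flag": ever_flags["first_line"] if any_treatment else MISSING,
            "second_line_dmt_flag": ever_flags["second_line"] if any_treatment else MISSING,
            "stem_cell_flag": ever_flags["stem_cell"] if any_treatment else MISSING,
            "other_drug_flag": ever_flags["other"] if any_treatment else MISSING,
            "age_at_treatment_start": _age_at(birth, treat_date),
            "t2_lesion_bin": mri_bins[0],
            "t1_gd_brain_bin": mri_bins[1],
            "t1_gd_spinal_bin": mri_bins[2],
            "age_at_mri": _age_at(birth, mri_date),
            "msis_physical": msis_phys,
            "msis_psychological": msis_psych,
            "age_at_msis": _age_at(birth, msis_date),
            "n_relapses_total": rel["n_relapses_total"],
            "n_optic_neuritis": rel["n_optic_neuritis"],
            "n_monofocal": rel["n_monofocal"],
            "n_multifocal": rel["n_multifocal"],
            "n_steroid_treated_relapses": rel["n_steroid_treated_relapses"],
            "last_relapse_steroid_treated": rel["last_relapse_steroid_treated"],
            "last_relapse_remission": rel["last_relapse_remission"],
            "age_at_last_relapse": _age_at(birth, rel["last_relapse_date"]),
        }
        rows.append({f: row[f] for f in schema.features})
    return rows


META_COLUMNS = ("patient_id", "visit_date", "label")


def build_feature_matrix(records: Iterable[PatientRecord],
                         schema: Optional[FeatureSchema] = None) -> pd.DataFrame:
    """Cohort-wide per-visit feature matrix.

    Returns a DataFrame with meta columns (patient_id, visit_date, label)
    followed by the schema's features, one row per visit.
    """
    schema = schema or SCHEMAS["no_msis"]
    frames = []
    for rec in records:
        rows = carry_forward_features(rec, schema)
        for v, row in zip(rec.visits, rows):
            row["patient_id"] = rec.patient_id
            row["visit_date"] = v.visit_date.isoformat()
            row["label"] = v.recorded_course
        frames.extend(rows)
    df = pd.DataFrame(frames, columns=list(META_COLUMNS) + list(schema.features))
    df.attrs["schema"] = schema.name
    df.attrs["schema_fingerprint"] = schema.fingerprint()
    return df


def split_xy(matrix: pd.DataFrame, schema: Optional[FeatureSchema] = None,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, groups) from a feature matrix; y is 0 for RRMS, 1 for SPMS."""
    schema = schema or get_schema(matrix.attrs.get("schema", "no_msis"))
    X = matrix[list(schema.features)].to_numpy(dtype=float)
    y = (matrix["label"] == SPMS).to_numpy(dtype=int)
    groups = matrix["patient_id"].to_numpy()
    return X, y, groups


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

SPLIT_NAMES = ("train", "valid", "calibration", "test")


@dataclass(frozen=True)
class CohortSplit:
    train: frozenset
    valid: frozenset
    calibration: frozenset
    test: frozenset
    fractions: tuple[float, float, float, float]
    seed: int

    def __post_init__(self) -> None:
        sets = [self.train, self.valid, self.calibration, self.test]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("split sets are not pairwise disjoint")

    def membership(self) -> dict[str, str]:
        return {pid: name for name in SPLIT_NAMES for pid in getattr(self, name)}

    def fingerprint(self) -> str:
        payload = "|".join(",".join(sorted(map(str, getattr(self, n)))) for n in SPLIT_NAMES)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_archetype(rec: PatientRecord) -> str:
    courses = [v.recorded_course for v in rec.visits]
    if all(c == RRMS for c in courses):
        return "rrms_only"
    if all(c == SPMS for c in courses):
        return "spms_only"
    return "transitioning"


def stratified_patient_split(records: list[PatientRecord],
                             fractions: tuple[float, float, float, float] = (0.65, 0.05, 0.05, 0.25),
                             seed: int = 0) -> CohortSplit:
    """Archetype-stratified patient-level split into train/valid/calibration/test.

    Within each archetype, patient ids are shuffled and allocated to the four
    sets by largest-remainder rounding of the fractions, so every visit stays
    with its patient and the archetype mix is preserved in each set.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    by_arch: dict[str, list[str]] = {}
    for rec in records:
        arch = rec.archetype or derive_archetype(rec)
        by_arch.setdefault(arch, []).append(rec.patient_id)
    sets: dict[str, set] = {n: set() for n in SPLIT_NAMES}
    for arch in sorted(by_arch):
        ids = sorted(by_arch[arch])
        rng.shuffle(ids)
        counts = largest_remainder_allocation(len(ids), tuple(fractions))
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            sets[name].update(ids[start:start + c])
            start += c
    return CohortSplit(frozenset(sets["train"]), frozenset(sets["valid"]),
                       frozenset(sets["calibration"]), frozenset(sets["test"]),
                       tuple(fractions), seed)


def subset_matrix(matrix: pd.DataFrame, ids: Iterable) -> pd.DataFrame:
    out = matrix[matrix["patient_id"].isin(set(ids))].reset_index(drop=True)
    out.attrs.update(matrix.attrs)
    return out
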