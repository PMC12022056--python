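"""CSV schemas, run configuration, and the end-to-end pipeline.

The visit-level CSV has one row per hospital visit; repeated events inside a
visit (relapses, treatment starts) are semicolon-joined within their cells.
All dates are ISO-8601; ages are always derived from dates, never stored.
Every written artifact carries the configuration hash and seed so outputs
from different runs refuse to be combined silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import conformal, evaluation, explain, features, models, trajectory
from .simulate import (RRMS, SPMS, ConfigurationError, MriScan, PatientRecord,
                       RelapseEvent, SimConfig, TreatmentEvent, VisitRecord,
                       generate_cohort)

logger = logging.getLogger(__name__)

VISIT_COLUMNS = (
    "patient_id", "visit_date", "sex", "birth_date", "debut_date",
    "debut_relapse_age", "edss", "recorded_course",
    "relapse_dates", "relapse_categories", "relapse_steroid_treated",
    "relapse_remission",
    "sdmt_score", "sdmt_date",
    "t2_lesion_count", "t1_gd_brain_count", "t1_gd_spinal_count", "mri_date",
    "treatment_drugs", "treatment_categories", "treatment_start_dates",
    "msis_physical", "msis_psychological", "msis_date",
)

_EDSS_GRID = {round(x * 0.5, 1) for x in range(21)}


# ---------------------------------------------------------------------------
# visit CSV
# ---------------------------------------------------------------------------

def _join(values) -> str:
    return ";".join(str(v) for v in values)


def write_visits_csv(records: list[PatientRecord], path) -> None:
    rows = []
    for rec in records:
        for v in rec.visits:
            rows.append({
                "patient_id": rec.patient_id,
                "visit_date": v.visit_date.isoformat(),
                "sex": rec.sex,
                "birth_date": rec.birth_date.isoformat() if rec.birth_date else "",
                "debut_date": rec.debut_date.isoformat() if rec.debut_date else "",
                "debut_relapse_age": rec.debut_relapse_age,
                "edss": "" if v.edss is None else v.edss,
                "recorded_course": v.recorded_course or "",
                "relapse_dates": _join(e.event_date.isoformat() for e in v.relapses),
                "relapse_categories": _join(e.category for e in v.relapses),
                "relapse_steroid_treated": _join(int(e.steroid_treated) for e in v.relapses),
                "relapse_remission": _join(int(e.remission) for e in v.relapses),
                "sdmt_score": "" if v.sdmt_score is None else round(v.sdmt_score, 1),
                "sdmt_date": v.sdmt_date.isoformat() if v.sdmt_date else "",
                "t2_lesion_count": "" if v.mri is None else v.mri.t2_lesion_count,
                "t1_gd_brain_count": "" if v.mri is None else v.mri.t1_gd_brain_count,
                "t1_gd_spinal_count": "" if v.mri is None else v.mri.t1_gd_spinal_count,
                "mri_date": v.mri.scan_date.isoformat() if v.mri else "",
                "treatment_drugs": _join(t.drug for t in v.treatments),
                "treatment_categories": _join(t.category for t in v.treatments),
                "treatment_start_dates": _join(t.start_date.isoformat() for t in v.treatments),
                "msis_physical": "" if v.msis_physical is None else round(v.msis_physical, 1),
                "msis_psychological": ("" if v.msis_psychological is None
                                       else round(v.msis_psychological, 1)),
                "msis_date": v.msis_date.isoformat() if v.msis_date else "",
            })
    pd.DataFrame(rows, columns=list(VISIT_COLUMNS)).to_csv(path, index=False)


class VisitValidationError(ValueError):
    """Row-level validation problems, carrying line numbers."""


def _parse_date(s: str, line: int, col: str, errors: list[str]) -> Optional[date]:
    if not s:
        return None
    try:
        return date.fromisoformat(s)
    except ValueError:
        errors.append(f"line {line}: unparseable {col} {s!r} (expected ISO-8601)")
        return None


def read_visits_csv(path, max_visits_per_patient: Optional[int] = None,
                    ) -> list[PatientRecord]:
    """Parse and validate a visit-level CSV into patient records.

    Unknown columns warn; unparseable dates or off-grid EDSS values raise a
    :class:`VisitValidationError` listing the offending line numbers.  An
    optional per-patient visit cap mirrors batch-size limits of interactive
    deployments (default: unlimited).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise VisitValidationError(f"{path}: no records (empty file)") from None
    if len(df) == 0:
        raise VisitValidationError(f"{path}: no records")
    unknown = set(df.columns) - set(VISIT_COLUMNS)
    if unknown:
        logger.warning("ignoring unknown columns: %s", sorted(unknown))
    missing = {"patient_id", "visit_date", "edss"} - set(df.columns)
    if missing:
        raise VisitValidationError(f"{path}: required columns missing: {sorted(missing)}")

    errors: list[str] = []
    patients: dict[str, PatientRecord] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        get = lambda c: str(row[c]).strip() if c in df.columns else ""
        vdate = _parse_date(get("visit_date"), line, "visit_date", errors)
        edss_raw = get("edss")
        edss = None
        if edss_raw:
            try:
                edss = float(edss_raw)
            except ValueError:
                errors.append(f"line {line}: non-numeric edss {edss_raw!r}")
            else:
                if round(edss, 1) not in _EDSS_GRID:
                    errors.append(f"line {line}: EDSS {edss} off the 0-10 half-point grid")
        if vdate is None and not errors:
            errors.append(f"line {line}: missing visit_date")
        pid = get("patient_id")
        if pid not in patients:
            patients[pid] = PatientRecord(
                patient_id=pid, sex=get("sex") or "F",
                birth_date=_parse_date(get("birth_date"), line, "birth_date", errors),
                debut_date=_parse_date(get("debut_date"), line, "debut_date", errors),
                debut_relapse_age=float(get("debut_relapse_age") or -1))
        rec = patients[pid]

        relapses = []
        rdates = [d for d in get("relapse_dates").split(";") if d]
        rcats = [c for c in get("relapse_categories").split(";") if c]
        rster = [s for s in get("relapse_steroid_treated").split(";") if s]
        rrem = [s for s in get("relapse_remission").split(";") if s]
        for k, dstr in enumerate(rdates):
            d = _parse_date(dstr, line, "relapse_dates", errors)
            if d is not None:
                relapses.append(RelapseEvent(
                    d, rcats[k] if k < len(rcats) else "other",
                    bool(int(rster[k])) if k < len(rster) else False,
                    bool(int(rrem[k])) if k < len(rrem) else False))
        treatments = []
        tdrugs = [s for s in get("treatment_drugs").split(";") if s]
        tcats = [s for s in get("treatment_categories").split(";") if s]
        tdates = [s for s in get("treatment_start_dates").split(";") if s]
        for k, drug in enumerate(tdrugs):
            d = _parse_date(tdates[k], line, "treatment_start_dates", errors) \
                if k < len(tdates) else vdate
            cat = tcats[k] if k < len(tcats) else features.categorize_treatment(drug)
            treatments.append(TreatmentEvent(d or vdate, drug, cat))

        mri = None
        if get("t2_lesion_count"):
            mri = MriScan(
                _parse_date(get("mri_date"), line, "mri_date", errors) or vdate,
                int(float(get("t2_lesion_count"))),
                int(float(get("t1_gd_brain_count") or 0)),
                int(float(get("t1_gd_spinal_count") or 0)))

        rec.visits.append(VisitRecord(
            visit_date=vdate or date.min, edss=edss,
            recorded_course=get("recorded_course") or None,
            relapses=relapses, mri=mri,
            sdmt_score=float(get("sdmt_score")) if get("sdmt_score") else None,
            sdmt_date=_parse_date(get("sdmt_date"), line, "sdmt_date", errors),
            msis_physical=float(get("msis_physical")) if get("msis_physical") else None,
            msis_psychological=(float(get("msis_psychological"))
                                if get("msis_psychological") else None),
            msis_date=_parse_date(get("msis_date"), line, "msis_date", errors),
            treatments=treatments))

    if errors:
        raise VisitValidationError("visit CSV validation failed:\n" + "\n".join(errors))
    if max_visits_per_patient is not None:
        for pid, rec in patients.items():
            if len(rec.visits) > max_visits_per_patient:
                raise VisitValidationError(
                    f"patient {pid} has {len(rec.visits)} visits, exceeding the "
                    f"cap of {max_visits_per_patient}")
    out = list(patients.values())
    for rec in out:
        rec.visits.sort(key=lambda v: v.visit_date)
        rec.archetype = features.derive_archetype(rec) if all(
            v.recorded_course for v in rec.visits) else None
    return out


# ---------------------------------------------------------------------------
# feature matrix CSV (with schema header line)
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    header = (f"# schema={matrix.attrs.get('schema', 'no_msis')} "
              f"fingerprint={matrix.attrs.get('schema_fingerprint', '')}\n")
    with open(path, "w") as fh:
        fh.write(header)
        matrix.to_csv(fh, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = dict(tok.split("=", 1) for tok in first.lstrip("# ").split())
        df = pd.read_csv(fh)
    df.attrs["schema"] = meta.get("schema", "no_msis")
    df.attrs["schema_fingerprint"] = meta.get("fingerprint", "")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    schema_name: str = "no_msis"
    model: models.ModelSpec = field(default_factory=models.ModelSpec)
    split_fractions: tuple[float, float, float, float] = (0.65, 0.05, 0.05, 0.25)
    split_seed: int = 0
    confidences: tuple[float, ...] = (93.0, 95.0, 99.0)
    eps_grid: tuple[float, ...] = evaluation.DEFAULT_EPS_GRID
    sustain: int = 2
    min_gap_months: float = 3.0
    explain_rows: int = 20

    def __post_init__(self) -> None:
        if any(not (0.0 < c < 100.0) for c in self.confidences):
            raise ConfigurationError("confidences must lie in (0, 100)")
        features.get_schema(self.schema_name)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: RunConfig
    records: list
    truth: pd.DataFrame
    matrix: pd.DataFrame
    split: features.CohortSplit
    model: models.ProbabilisticClassifier
    calibrator: conformal.MondrianCalibrator
    test_matrix: pd.DataFrame
    p_pairs: list
    metrics: dict


def run_pipeline(config: RunConfig, outdir: Optional[Path] = None) -> PipelineResult:
    """simulate -> clean -> featurize -> split -> train -> calibrate -> evaluate -> track.

    Writes all artifacts under ``outdir`` when given; every JSON artifact
    embeds the configuration hash and seed.
    """
    stage = "simulate"
    try:
        records, truth = generate_cohort(config.sim)
        logger.info("simulated %d patients, %d visits", len(records),
                    sum(len(r.visits) for r in records))

        stage = "clean"
        records, clean_report = features.clean_cohort(records)
        records, prune_report = features.prune_rrms_tail(records)

        stage = "featurize"
        schema = features.get_schema(config.schema_name)
        matrix = features.build_feature_matrix(records, schema)

        stage = "split"
        split = features.stratified_patient_split(records, config.split_fractions,
                                                  config.split_seed)
        train_ids = sorted(split.train | split.valid)  # merged for classical models
        train_m = features.subset_matrix(matrix, train_ids)
        cal_m = features.subset_matrix(matrix, split.calibration)
        test_m = features.subset_matrix(matrix, split.test)

        stage = "train"
        Xtr, ytr, _ = features.split_xy(train_m, schema)
        model = models.train(config.model, Xtr, ytr, schema.fingerprint())

        stage = "calibrate"
        Xc, yc, _ = features.split_xy(cal_m, schema)
        calibrator = conformal.calibrate(model, Xc, yc,
                                         calibration_ids=split.calibration,
                                         training_ids=train_ids)

        stage = "predict"
        Xte, yte, gte = features.split_xy(test_m, schema)
        p_pairs = conformal.predict_pvalues(calibrator, model, Xte, schema.fingerprint())
        truths = [SPMS if v else RRMS for v in yte]

        stage = "evaluate"
        cal_curve = evaluation.calibration_curve(p_pairs, truths, config.eps_grid)
        eff_curve = evaluation.efficiency_curve(p_pairs, truths, config.eps_grid)
        eps_star = evaluation.peak_confidence(eff_curve)
        confusions = {c: evaluation.confusion_at(p_pairs, truths, c, gte)
                      for c in config.confidences}
        peak_row = eff_curve.table[np.isclose(eff_curve.table["significance"], eps_star)]
        concentration = evaluation.error_concentration(p_pairs, truths, gte, eps_star)

        stage = "track"
        working_eps = conformal.significance_from_confidence(config.confidences[0])
        trajectories, estimates, alternations = _track_patients(
            test_m, p_pairs, working_eps, config)

        stage = "explain"
        importance = None
        if config.explain_rows > 0 and config.model.kind in explain.TREE_KINDS:
            n_rows = min(config.explain_rows, len(Xte))
            importance = explain.global_importance(model, Xte[:n_rows],
                                                   list(schema.features))

        offsets = [e.offset_visits for e in estimates.values()
                   if e.offset_visits is not None]
        metrics = {
            "config_hash": config.config_hash(),
            "seed": config.sim.seed,
            "n_patients": len(records),
            "n_visits": int(len(matrix)),
            "removed_visits": {**clean_report.removed_visits,
                               **prune_report.removed_visits},
            "peak_significance": eps_star,
            "peak_confidence_percent": round((1 - eps_star) * 100, 6),
            "peak_single_correct_fraction": float(peak_row["single_correct"].iloc[0]),
            "observed_error_at_peak": float(peak_row["observed_error"].iloc[0]),
            "confusion": {str(c): conf.counts.to_dict() for c, conf in confusions.items()},
            "efficiency": {str(c): conf.efficiency for c, conf in confusions.items()},
            "error_concentration": {
                k: v.patients_for_half for k, v in concentration.items()},
            "n_transition_estimates": len(offsets),
            "median_offset_visits": float(np.median(offsets)) if offsets else None,
            "n_alternating_patients": sum(alternations.values()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(config, records, truth, matrix, split, model,
                            calibrator, test_m, p_pairs, metrics)
    if outdir is not None:
        _write_artifacts(result, cal_curve, eff_curve, confusions,
                         trajectories, estimates, importance, Path(outdir))
    return result


def _track_patients(test_m: pd.DataFrame, p_pairs, eps: float, config: RunConfig):
    trajectories: dict[str, trajectory.CourseTrajectory] = {}
    estimates: dict[str, trajectory.TransitionEstimate] = {}
    alternations: dict[str, bool] = {}
    df = test_m.reset_index(drop=True)
    for pid in sorted(df["patient_id"].unique()):
        idx = df.index[df["patient_id"] == pid].tolist()
        dates = [date.fromisoformat(df.loc[i, "visit_date"]) for i in idx]
        times = [(d - dates[0]).days / 365.25 for d in dates]
        if len(set(times)) != len(times):
            times = [t + k * 1e-6 for k, t in enumerate(times)]
        traj = trajectory.build_trajectory(
            pid, times, [p_pairs[i] for i in idx],
            [df.loc[i, "label"] for i in idx], eps)
        trajectories[pid] = traj
        estimates[pid] = trajectory.estimate_transition(traj, config.sustain)
        alternations[pid] = trajectory.detect_alternation(
            traj, config.min_gap_months)[0]
    return trajectories, estimates, alternations


def _write_artifacts(result: PipelineResult, cal_curve, eff_curve, confusions,
                     trajectories, estimates, importance, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = result.config.config_hash()
    write_visits_csv(result.records, outdir / "visits.csv")
    result.truth.to_csv(outdir / "ground_truth.csv", index=False)
    write_feature_matrix(result.matrix, outdir / "features.csv")
    with open(outdir / "split.json", "w") as fh:
        json.dump({"config_hash": cfg_hash,
                   **{n: sorted(map(str, getattr(result.split, n)))
                      for n in features.SPLIT_NAMES}}, fh, indent=1, sort_keys=True)
    cal_curve.to_csv(outdir / "calibration_curve.csv", index=False)
    eff_curve.table.to_csv(outdir / "efficiency_curve.csv", index=False)
    for c, conf in confusions.items():
        conf.counts.to_csv(outdir / f"confusion_{c:g}.csv")
    rows = []
    for pid, traj in trajectories.items():
        est = estimates[pid]
        for i in range(len(traj)):
            rows.append({"patient_id": pid, "time_years": traj.times_years[i],
                         "p_rrms": traj.p_rrms[i], "p_spms": traj.p_spms[i],
                         "set": "|".join(sorted(traj.sets[i].labels)),
                         "recorded": traj.recorded[i]})
    pd.DataFrame(rows).to_csv(outdir / "trajectories.csv", index=False)
    pd.DataFrame([
        {"patient_id": pid, "predicted_index": e.predicted_index,
         "recorded_index": e.recorded_index, "offset_visits": e.offset_visits,
         "offset_years": e.offset_years}
        for pid, e in estimates.items()]).to_csv(outdir / "transitions.csv", index=False)
    if importance is not None:
        importance.to_csv(outdir / "importance.csv", index=False)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=1, sort_keys=True, default=str)
    logger.info("artifacts written to %s", outdir)
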