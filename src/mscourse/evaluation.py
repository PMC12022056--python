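"""Validity and efficiency evaluation of the conformal predictor.

* calibration curve: observed error (true label excluded from the set)
  against the prespecified significance level -- a valid predictor tracks
  the diagonal;
* efficiency curve: fractions of correct-single / incorrect-single /
  multiple / empty predictions across the significance grid;
* peak-confidence selection: the significance maximizing the correct
  single-label fraction (ties toward higher confidence);
* confusion-at-confidence tables, per visit or per patient-final-visit;
* error concentration: how few patients account for half of each error
  direction.

"Error" throughout means the true label is not in the prediction set, so an
empty prediction counts as an error and a multiple-label prediction never
does -- the definition under which the diagonal is the theoretical target
of the calibration plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conformal import CLASSES, PValuePair, set_from_pvalues
from .simulate import RRMS, SPMS

DEFAULT_EPS_GRID = tuple(np.round(np.arange(0.01, 0.51, 0.01), 10))

OUTCOMES = ("single_correct", "single_incorrect", "multiple", "empty")


def _check_inputs(p_pairs: Sequence[PValuePair], truths: Sequence[str]) -> None:
    if len(p_pairs) == 0:
        raise ValueError("no predictions supplied")
    if len(p_pairs) != len(truths):
        raise ValueError("p_pairs and truths differ in length")


def calibration_curve(p_pairs: Sequence[PValuePair], truths: Sequence[str],
                      eps_grid: Sequence[float] = DEFAULT_EPS_GRID) -> pd.DataFrame:
    """Observed error rate per significance level.

    error(eps) = fraction of visits whose prediction set at eps excludes the
    true label, i.e. whose true-class p-value is below eps.
    """
    _check_inputs(p_pairs, truths)
    p_true = np.array([pair.get(t) for pair, t in zip(p_pairs, truths)])
    rows = [{"significance": float(e), "observed_error": float(np.mean(p_true < e))}
            for e in eps_grid]
    return pd.DataFrame(rows)


@dataclass
class EfficiencyCurve:
    table: pd.DataFrame  # significance + four outcome fractions + observed_error

    def fraction(self, outcome: str) -> np.ndarray:
        return self.table[outcome].to_numpy()

    @property
    def significances(self) -> np.ndarray:
        return self.table["significance"].to_numpy()


def efficiency_curve(p_pairs: Sequence[PValuePair], truths: Sequence[str],
                     eps_grid: Sequence[float] = DEFAULT_EPS_GRID) -> EfficiencyCurve:
    """Outcome-fraction breakdown per significance level.

    At each eps the four outcome fractions partition the visits (they sum
    to 1); the observed error (single-incorrect + empty) is stored
    explicitly alongside.
    """
    _check_inputs(p_pairs, truths)
    n = len(p_pairs)
    rows = []
    for e in eps_grid:
        counts = dict.fromkeys(OUTCOMES, 0)
        for pair, t in zip(p_pairs, truths):
            counts[set_from_pvalues(pair, float(e)).outcome(t)] += 1
        row = {"significance": float(e)}
        row.update({k: counts[k] / n for k in OUTCOMES})
        row["observed_error"] = (counts["single_incorrect"] + counts["empty"]) / n
        rows.append(row)
    return EfficiencyCurve(pd.DataFrame(rows))


def peak_confidence(curve: EfficiencyCurve) -> float:
    """Significance with the highest correct single-label fraction.

    Ties break toward the smaller significance (higher confidence).
    """
    tab = curve.table
    if len(tab) == 0:
        raise ValueError("empty efficiency curve")
    order = tab.sort_values("significance")
    top = order[np.isclose(order["single_correct"], tab["single_correct"].max())]
    return float(top["significance"].iloc[0])


@dataclass
class ConfusionAtConfidence:
    confidence_percent: float
    counts: pd.DataFrame       # rows: predicted RRMS/SPMS/empty/multiple; cols: true classes
    percentages: pd.DataFrame  # column-normalized, one decimal
    efficiency: float          # single-label fraction over all units

    def __str__(self) -> str:
        return (f"confidence {self.confidence_percent:g}% "
                f"(efficiency {self.efficiency * 100:.1f}%)\n"
                f"{self.counts.to_string()}")


PRED_ROWS = (RRMS, SPMS, "empty", "multiple")


def confusion_at(p_pairs: Sequence[PValuePair], truths: Sequence[str],
                 confidence_percent: float,
                 patient_ids: Optional[Sequence] = None,
                 per_patient_final: bool = False) -> ConfusionAtConfidence:
    """Counts of predicted outcome by true class at one confidence level.

    With ``per_patient_final`` the table is restricted to each patient's
    final visit (``patient_ids`` required, assumed visit-ordered within
    patient); otherwise every visit counts.  Percentages are per true-class
    column, rounded to one decimal -- rounded columns may not sum to 100.
    """
    _check_inputs(p_pairs, truths)
    eps = round(1.0 - confidence_percent / 100.0, 12)
    idx = np.arange(len(p_pairs))
    if per_patient_final:
        if patient_ids is None:
            raise ValueError("per-patient mode requires patient_ids")
        last = {}
        for i, pid in enumerate(patient_ids):
            last[pid] = i
        idx = np.array(sorted(last.values()))
    counts = pd.DataFrame(0, index=list(PRED_ROWS), columns=list(CLASSES))
    for i in idx:
        s = set_from_pvalues(p_pairs[i], eps)
        if s.is_multiple:
            row = "multiple"
        elif s.is_empty:
            row = "empty"
        else:
            row = s.single_label()
        counts.loc[row, truths[i]] += 1
    col_tot = counts.sum(axis=0).replace(0, 1)
    pct = (counts / col_tot * 100).round(1)
    single = counts.loc[[RRMS, SPMS]].to_numpy().sum()
    total = counts.to_numpy().sum()
    return ConfusionAtConfidence(confidence_percent, counts, pct,
                                 float(single / total) if total else float("nan"))


@dataclass
class ErrorConcentration:
    direction: str                  # e.g. "true_RRMS_predicted_SPMS"
    total_errors: int
    patients_for_half: Optional[int]  # None when the direction has no errors
    cumulative_share: pd.DataFrame    # per patient (sorted desc): errors, cumulative fraction


def error_concentration(p_pairs: Sequence[PValuePair], truths: Sequence[str],
                        patient_ids: Sequence, eps: float) -> dict[str, ErrorConcentration]:
    """How concentrated single-label errors are across patients, per direction.

    Patients are sorted by descending error count; ``patients_for_half`` is
    the minimal number of patients whose cumulative errors reach at least
    half of that direction's total.
    """
    _check_inputs(p_pairs, truths)
    errors = {(RRMS, SPMS): {}, (SPMS, RRMS): {}}
    for pair, t, pid in zip(p_pairs, truths, patient_ids):
        s = set_from_pvalues(pair, eps)
        pred = s.single_label()
        if pred is not None and pred != t:
            errors[(t, pred)][pid] = errors[(t, pred)].get(pid, 0) + 1
    out = {}
    for (t, pred), per_patient in errors.items():
        name = f"true_{t}_predicted_{pred}"
        total = sum(per_patient.values())
        if total == 0:
            out[name] = ErrorConcentration(name, 0, None, pd.DataFrame(
                columns=["patient_id", "errors", "cumulative_fraction"]))
            continue
        items = sorted(per_patient.items(), key=lambda kv: (-kv[1], kv[0]))
        cum = np.cumsum([v for _, v in items]) / total
        k = int(np.searchsorted(cum, 0.5) + 1)
        tab = pd.DataFrame({"patient_id": [p for p, _ in items],
                            "errors": [v for _, v in items],
                            "cumulative_fraction": cum})
        out[name] = ErrorConcentration(name, total, k, tab)
    return out
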