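"""Per-patient disease-course analytics over conformal p-value time series.

A :class:`CourseTrajectory` holds, per visit, the RRMS/SPMS p-values, the
prediction set at the working significance level, and the recorded course
label.  On top of it the module provides:

* the predicted transition visit (first sustained SPMS single-label);
* the recorded transition visit (first recorded SPMS label) and the offset
  between the two, in visits and in years (negative = model earlier);
* an alternation flag -- a sustained SPMS stretch later reverting to RRMS,
  which clinically should not happen and marks unreliable predictions;
* a heuristic misclassification taxonomy (cat1..cat4 / misc) codifying the
  qualitative p-value shapes of frequently misclassified patients:
  elevated-and-rising SPMS p-values from the first visit (cat1), a late
  inflection after a quiet prefix (cat2), rise-then-plateau (cat3), and
  fluctuating single labels (cat4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .conformal import PredictionSet, PValuePair, set_from_pvalues
from .simulate import RRMS, SPMS


@dataclass
class CourseTrajectory:
    patient_id: str
    times_years: np.ndarray          # years from first visit, strictly increasing
    p_rrms: np.ndarray
    p_spms: np.ndarray
    sets: list[PredictionSet]        # at self.significance
    recorded: list[str]
    significance: float

    def __post_init__(self) -> None:
        lengths = {len(self.times_years), len(self.p_rrms), len(self.p_spms),
                   len(self.sets), len(self.recorded)}
        if len(lengths) != 1:
            raise ValueError("trajectory series have unequal lengths")
        if np.any(np.diff(self.times_years) <= 0):
            raise ValueError("visit times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_years)

    def single_labels(self) -> list[Optional[str]]:
        return [s.single_label() for s in self.sets]


def build_trajectory(patient_id: str, times_years: Sequence[float],
                     p_pairs: Sequence[PValuePair], recorded: Sequence[str],
                     eps: float) -> CourseTrajectory:
    """Assemble a trajectory; times are re-anchored to years from the first visit."""
    if len(p_pairs) < 1:
        raise ValueError("a trajectory needs at least one visit")
    t = np.asarray(times_years, dtype=float)
    t = t - t[0]
    return CourseTrajectory(
        patient_id=patient_id, times_years=t,
        p_rrms=np.array([p.p_rrms for p in p_pairs]),
        p_spms=np.array([p.p_spms for p in p_pairs]),
        sets=[set_from_pvalues(p, eps) for p in p_pairs],
        recorded=list(recorded), significance=eps)


# ---------------------------------------------------------------------------
# transition detection
# ---------------------------------------------------------------------------

def predicted_transition(traj: CourseTrajectory, sustain: int = 2) -> Optional[int]:
    """First visit of a sustained SPMS prediction, or None.

    The candidate visit must be a single-label SPMS prediction, the next
    ``sustain - 1`` visits (as far as they exist) must keep SPMS in the set
    (single SPMS or multiple), and no later visit may revert to a
    single-label RRMS prediction.
    """
    labels = traj.single_labels()
    spms_in_set = [SPMS in s.labels for s in traj.sets]
    n = len(traj)
    for i in range(n):
        if labels[i] != SPMS:
            continue
        if any(labels[j] == RRMS for j in range(i + 1, n)):
            continue
        window = range(i, min(i + sustain, n))
        if all(spms_in_set[j] for j in window):
            return i
    return None


def recorded_transition(traj_or_labels) -> Optional[int]:
    """First visit with a recorded SPMS label, or None for RRMS-only patients."""
    labels = (traj_or_labels.recorded if isinstance(traj_or_labels, CourseTrajectory)
              else list(traj_or_labels))
    seen_spms = False
    first = None
    for i, lab in enumerate(labels):
        if lab == SPMS:
            if first is None:
                first = i
            seen_spms = True
        elif seen_spms:
            raise ValueError("recorded labels revert SPMS->RRMS; invalid input")
    return first


@dataclass(frozen=True)
class TransitionEstimate:
    predicted_index: Optional[int]
    recorded_index: Optional[int]
    offset_visits: Optional[int]   # predicted - recorded; negative = model earlier
    offset_years: Optional[float]


def transition_offset(predicted: Optional[int], recorded: Optional[int],
                      times_years: Sequence[float]) -> TransitionEstimate:
    """Offset between predicted and recorded transition visits.

    Offsets are defined only when both indices are present; the sign
    convention is (predicted - recorded), so negative means the model
    flagged SPMS earlier than the clinician.
    """
    if predicted is None or recorded is None:
        return TransitionEstimate(predicted, recorded, None, None)
    t = np.asarray(times_years, dtype=float)
    return TransitionEstimate(predicted, recorded, predicted - recorded,
                              float(t[predicted] - t[recorded]))


def estimate_transition(traj: CourseTrajectory, sustain: int = 2) -> TransitionEstimate:
    return transition_offset(predicted_transition(traj, sustain),
                             recorded_transition(traj), traj.times_years)


# ---------------------------------------------------------------------------
# alternation
# ---------------------------------------------------------------------------

def detect_alternation(traj: CourseTrajectory, min_gap_months: float = 3.0,
                       ) -> tuple[bool, list[int]]:
    """Flag a sustained SPMS stretch that later reverts to RRMS.

    True iff there are >= 2 consecutive single-label SPMS visits whose
    consecutive gaps each exceed ``min_gap_months``, followed at some later
    visit by a single-label RRMS prediction.  Returns (flag, indices of the
    offending SPMS run).
    """
    labels = traj.single_labels()
    gap_years = min_gap_months / 12.0
    n = len(traj)
    i = 0
    while i < n:
        if labels[i] != SPMS:
            i += 1
            continue
        run = [i]
        j = i + 1
        while j < n and labels[j] == SPMS:
            run.append(j)
            j += 1
        if len(run) >= 2:
            gaps_ok = all(traj.times_years[b] - traj.times_years[a] > gap_years
                          for a, b in zip(run, run[1:]))
            reverts = any(labels[k] == RRMS for k in range(j, n))
            if gaps_ok and reverts:
                return True, run
        i = j
    return False, []


def multiple_label_count(traj_pairs: Sequence[PValuePair], eps: float) -> int:
    return sum(set_from_pvalues(p, eps).is_multiple for p in traj_pairs)


# ---------------------------------------------------------------------------
# misclassification taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MisclassCategory:
    label: str                     # cat1 | cat2 | cat3 | cat4 | misc
    inflection_index: Optional[int]
    slope: float                   # Theil-Sen slope of p_spms per visit
    fluctuation_count: int


@dataclass(frozen=True)
class TaxonomyThresholds:
    elevated_p: float = 0.1        # "already elevated" initial SPMS p-value
    low_p: float = 0.1             # "quiet" pre-inflection SPMS p-value
    min_pre_visits: int = 2
    rising_slope: float = 0.01     # per visit
    plateau_slope: float = 0.01    # |late-window slope| below this = plateau
    fluctuation_min: int = 3


def _theil_sen(y: np.ndarray) -> float:
    if len(y) < 2 or np.allclose(y, y[0]):
        return 0.0
    return float(stats.theilslopes(y, np.arange(len(y)))[0])


def _fluctuations(labels: Sequence[Optional[str]]) -> int:
    seq = [l for l in labels if l is not None]
    return sum(a != b for a, b in zip(seq, seq[1:]))


def _change_point(p: np.ndarray, thr: TaxonomyThresholds) -> Optional[int]:
    """Index maximizing mean-after minus mean-before, requiring a quiet prefix."""
    best, best_gain = None, 0.0
    for k in range(thr.min_pre_visits, len(p)):
        pre = p[:k]
        if not np.all(pre < thr.low_p):
            continue
        gain = float(p[k:].mean() - pre.mean())
        if gain > best_gain:
            best, best_gain = k, gain
    return best


def frequently_misclassified(traj: CourseTrajectory, min_errors: int = 5,
                             min_error_fraction: float = 0.5) -> bool:
    """Error-visit threshold: >= 5 erroneous visits or >= 50% of visits erroneous."""
    errs = sum(1 for s, t in zip(traj.sets, traj.recorded) if t not in s.labels)
    return errs >= min_errors or errs / len(traj) >= min_error_fraction


def categorize_misclassified(traj: CourseTrajectory,
                             thresholds: TaxonomyThresholds = TaxonomyThresholds(),
                             ) -> MisclassCategory:
    """Deterministic category label for a frequently misclassified patient.

    Precedence: too-short series -> misc; fluctuating single labels -> cat4;
    quiet prefix + change-point with a rising tail -> cat2; elevated start
    with a positive overall trend -> cat1; rise then plateau -> cat3;
    otherwise misc.
    """
    p = traj.p_spms
    slope = _theil_sen(p)
    fluct = _fluctuations(traj.single_labels())
    if len(traj) < 3:
        return MisclassCategory("misc", None, slope, fluct)
    if fluct >= thresholds.fluctuation_min:
        return MisclassCategory("cat4", None, slope, fluct)
    cp = _change_point(p, thresholds)
    if cp is not None and _theil_sen(p[cp:]) > thresholds.rising_slope:
        return MisclassCategory("cat2", cp, slope, fluct)
    if p[0] >= thresholds.elevated_p and slope > thresholds.rising_slope:
        return MisclassCategory("cat1", None, slope, fluct)
    late = p[max(len(p) - max(3, len(p) // 3), 0):]
    rose = float(p.max() - p[0]) > 2 * thresholds.elevated_p
    if rose and abs(_theil_sen(late)) <= thresholds.plateau_slope:
        return MisclassCategory("cat3", None, slope, fluct)
    return MisclassCategory("misc", None, slope, fluct)
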