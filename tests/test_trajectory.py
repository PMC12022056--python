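"""Disease-course trajectories: transition detection, alternation, taxonomy."""

import itertools

import numpy as np
import pytest

from mscourse import (PValuePair, build_trajectory, categorize_misclassified,
                      detect_alternation, estimate_transition,
                      predicted_transition, recorded_transition,
                      transition_offset)
from mscourse.conformal import set_from_pvalues
from mscourse.simulate import RRMS, SPMS
from mscourse.trajectory import CourseTrajectory, multiple_label_count

EPS = 0.07


def pair_for(label):
    """A p-value pair whose single-label set at EPS is `label` ('R'/'S'/'M' multiple)."""
    return {"R": PValuePair(0.9, 0.01), "S": PValuePair(0.01, 0.9),
            "M": PValuePair(0.5, 0.5), "E": PValuePair(0.01, 0.01)}[label]


def traj_from(pattern, times=None, recorded=None):
    pairs = [pair_for(c) for c in pattern]
    times = times if times is not None else list(range(len(pattern)))
    recorded = recorded or [RRMS] * len(pattern)
    return build_trajectory("P", times, pairs, recorded, EPS)


# -- construction -----------------------------------------------------------

def test_single_visit_trajectory():
    t = traj_from("R")
    assert len(t) == 1 and t.times_years[0] == 0.0


def test_series_lengths_and_order_preserved():
    t = traj_from("RRSSS", times=[0, 1.5, 3, 4, 5.5])
    assert len(t) == 5
    assert t.times_years[0] == 0.0  # re-anchored
    assert [s.single_label() for s in t.sets] == [RRMS, RRMS, SPMS, SPMS, SPMS]


def test_sets_recomputable_from_p_series():
    t = traj_from("RSMES")
    for i, s in enumerate(t.sets):
        again = set_from_pvalues(PValuePair(t.p_rrms[i], t.p_spms[i]), EPS)
        assert again.labels == s.labels


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        CourseTrajectory("P", np.array([0.0, 1.0]), np.array([0.5]),
                         np.array([0.5]), [], [], EPS)


# -- predicted transition ---------------------------------------------------

@pytest.mark.parametrize("pattern,expected", [
    ("RRSSS", 2),
    ("RSRSS", 3),    # early flip invalidated by the later RRMS visit
    ("RRRRR", None),
    ("SSSSS", 0),
    ("RRSMS", 2),    # multiple keeps SPMS in the set, sustain holds
    ("RRRRS", 4),    # truncated sustain window at the end
])
def test_predicted_transition_sustain_rule(pattern, expected):
    assert predicted_transition(traj_from(pattern), sustain=2) == expected


# -- recorded transition ----------------------------------------------------

@pytest.mark.parametrize("labels,expected", [
    ((RRMS, RRMS, SPMS), 2),
    ((SPMS, SPMS), 0),
    ((RRMS, RRMS), None),
])
def test_recorded_transition_index(labels, expected):
    assert recorded_transition(labels) == expected


def test_recorded_label_reversal_rejected():
    with pytest.raises(ValueError, match="revert"):
        recorded_transition((RRMS, SPMS, RRMS))


# -- offsets ----------------------------------------------------------------

@pytest.mark.parametrize("pred,rec,visits,years", [
    (3, 5, -2, -2.0),
    (5, 5, 0, 0.0),
    (6, 5, 1, 1.0),
])
def test_transition_offset_sign_convention(pred, rec, visits, years):
    times = list(range(8))
    est = transition_offset(pred, rec, times)
    assert est.offset_visits == visits
    assert est.offset_years == pytest.approx(years)


def test_offset_absent_when_either_side_missing():
    est = transition_offset(None, 3, [0, 1, 2, 3])
    assert est.offset_visits is None and est.offset_years is None


def test_estimate_transition_combines_both_sides():
    t = traj_from("RRSSS", recorded=[RRMS, RRMS, RRMS, SPMS, SPMS])
    est = estimate_transition(t)
    assert (est.predicted_index, est.recorded_index, est.offset_visits) == (2, 3, -1)


# -- alternation ------------------------------------------------------------

def test_alternation_detected_for_sustained_then_reverting_spms():
    t = traj_from("RSSR", times=[0.0, 0.5, 0.9, 1.4])  # gaps > 3 months
    flag, run = detect_alternation(t)
    assert flag and run == [1, 2]


@pytest.mark.parametrize("pattern", ["RSSS", "RSR"])
def test_alternation_negative_cases(pattern):
    assert not detect_alternation(traj_from(pattern))[0]


def test_alternation_requires_gap_above_three_months():
    t = traj_from("RSSR", times=[0.0, 0.5, 0.6, 1.0])  # 0.1 y < 3 months
    assert not detect_alternation(t)[0]


def test_alternation_impossible_on_monotone_sequences():
    """Exhaustive: every monotone R...RS...S pattern of length <= 8 is unflagged."""
    for n in range(3, 9):
        for k in range(n + 1):
            pattern = "R" * k + "S" * (n - k)
            t = traj_from(pattern, times=[i * 0.5 for i in range(n)])
            assert not detect_alternation(t)[0]


def test_raising_confidence_never_reduces_multiple_labels(fitted_stack):
    """Nestedness corollary: multiple-label visits at 99% >= at 93%, per patient."""
    pairs = fitted_stack["pairs"]
    pids = fitted_stack["patient_ids"]
    for pid in set(pids):
        p = [pr for pr, g in zip(pairs, pids) if g == pid]
        assert multiple_label_count(p, 0.01) >= multiple_label_count(p, 0.07)


# -- misclassification taxonomy ---------------------------------------------

def _traj_with_pspms(p_spms, pattern=None):
    n = len(p_spms)
    pattern = pattern or "S" * n
    pairs = [PValuePair(0.01 if c == "S" else 0.9, p) for c, p in zip(pattern, p_spms)]
    return build_trajectory("P", list(range(n)), pairs, [RRMS] * n, EPS)


def test_cat1_rising_from_elevated_start():
    t = _traj_with_pspms([0.3, 0.5, 0.7, 0.9])
    assert categorize_misclassified(t).label == "cat1"


def test_cat2_inflection_after_quiet_prefix():
    t = _traj_with_pspms([0.02, 0.02, 0.02, 0.4, 0.8])
    cat = categorize_misclassified(t)
    assert cat.label == "cat2"
    assert cat.inflection_index == 3


def test_cat3_rise_then_plateau():
    t = _traj_with_pspms([0.02, 0.2, 0.4, 0.41, 0.4, 0.41, 0.4])
    assert categorize_misclassified(t).label == "cat3"


def test_cat4_fluctuating_single_labels():
    t = _traj_with_pspms([0.5, 0.01, 0.5, 0.01, 0.5], pattern="SRSRS")
    cat = categorize_misclassified(t)
    assert cat.label == "cat4"
    assert cat.fluctuation_count >= 3


def test_too_short_series_is_misc():
    t = _traj_with_pspms([0.5, 0.6])
    assert categorize_misclassified(t).label == "misc"
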