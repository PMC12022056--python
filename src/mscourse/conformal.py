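"""Mondrian inductive conformal prediction for binary disease-course labels.

Inductive conformal prediction attaches a rank-based p-value to every
(visit, candidate label) pair: the nonconformity score of the visit under
that label is ranked against the calibration scores, and

    p = |{j = 1..n+1 : alpha_j >= alpha_{n+1}}| / (n + 1),

where the test point counts as its own (n+1)-th element and ties count as
``>=``.  The Mondrian variant keeps a separate calibration list per true
class, which controls the error rate within each class rather than only on
the population.

The default nonconformity of a probabilistic classifier is
``alpha = 1 - P(label | x)``.  P-values are non-smoothed (deterministic) by
default; a smoothed variant that randomizes over ties -- and is exactly
uniform under exchangeability -- is available behind a flag.

A prediction set at significance ``eps`` contains every label whose p-value
is >= eps; with two classes the set is one of {RRMS}, {SPMS}, {RRMS, SPMS},
or {} (empty).  Confidence is 1 - eps; user surfaces express it in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .models import ProbabilisticClassifier, SchemaMismatchError
from .simulate import RRMS, SPMS

CLASSES = (RRMS, SPMS)


def significance_from_confidence(confidence_percent: float) -> float:
    """Convert a confidence in percent (e.g. 93) to a significance level."""
    if not 0.0 < confidence_percent < 100.0:
        raise ValueError(f"confidence must be in (0, 100), got {confidence_percent}")
    return round(1.0 - confidence_percent / 100.0, 12)


def nonconformity(prob_vector: np.ndarray, label: str) -> float:
    """Default nonconformity: 1 minus the predicted probability of ``label``."""
    prob_vector = np.asarray(prob_vector, dtype=float)
    if not np.isclose(prob_vector.sum(), 1.0, atol=1e-6):
        raise ValueError("probability vector must sum to 1")
    try:
        idx = CLASSES.index(label)
    except ValueError:
        raise ValueError(f"unknown label {label!r}; classes are {CLASSES}") from None
    return float(1.0 - prob_vector[idx])


@dataclass
class MondrianCalibrator:
    """Per-class sorted calibration nonconformity scores.

    ``scores[c]`` is ascending; p-values are computed by ranking a test
    score against the list for the hypothesized class only.
    """

    scores: dict[str, np.ndarray]
    source_fingerprint: Optional[str] = None
    calibration_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for c in CLASSES:
            if c not in self.scores or len(self.scores[c]) < 1:
                raise ValueError(f"calibration requires at least one score for class {c}")
            s = np.sort(np.asarray(self.scores[c], dtype=float))
            self.scores[c] = s

    def n(self, label: str) -> int:
        return len(self.scores[label])

    def min_p(self, label: str) -> float:
        return 1.0 / (self.n(label) + 1)


def calibrate(model: ProbabilisticClassifier, X_cal: np.ndarray, y_cal: np.ndarray,
              calibration_ids: Optional[Iterable] = None,
              training_ids: Optional[Iterable] = None) -> MondrianCalibrator:
    """Build a Mondrian calibrator from true-label nonconformities.

    ``y_cal`` uses 0 for RRMS, 1 for SPMS.  When both id collections are
    given, any overlap between calibration and training patients is rejected
    as leakage.
    """
    if calibration_ids is not None and training_ids is not None:
        overlap = set(calibration_ids) & set(training_ids)
        if overlap:
            raise ValueError(f"calibration patients overlap training patients: "
                             f"{sorted(overlap)[:5]}...")
    y_cal = np.asarray(y_cal, dtype=int)
    proba = model.predict_proba(X_cal)
    scores: dict[str, np.ndarray] = {}
    for ci, c in enumerate(CLASSES):
        mask = y_cal == ci
        if not mask.any():
            raise ValueError(f"class {c} absent from the calibration labels")
        scores[c] = 1.0 - proba[mask, ci]
    return MondrianCalibrator(scores, model.schema_fingerprint,
                              frozenset(calibration_ids or ()))


def p_value(calibrator: MondrianCalibrator, label: str, alpha_test: float,
            smoothed: bool = False, rng: Optional[np.random.Generator] = None) -> float:
    """Conformal p-value of a test nonconformity against one class's calibration list.

    Non-smoothed (default): ``p = (#{alpha_cal >= alpha_test} + 1) / (n + 1)``,
    the test point counting as its own (n+1)-th element and ties counting as
    ``>=``.  Smoothed: ties (including the test point's own) enter with a
    shared uniform weight, which makes p exactly U(0,1) under exchangeability.
    """
    s = calibrator.scores[label]
    n = len(s)
    n_ge = n - int(np.searchsorted(s, alpha_test, side="left"))
    if not smoothed:
        return (n_ge + 1) / (n + 1)
    n_gt = n - int(np.searchsorted(s, alpha_test, side="right"))
    n_ties = n_ge - n_gt  # calibration scores equal to alpha_test
    tau = (rng or np.random.default_rng()).uniform()
    return (n_gt + tau * (n_ties + 1)) / (n + 1)


@dataclass(frozen=True)
class PValuePair:
    p_rrms: float
    p_spms: float

    def get(self, label: str) -> float:
        return self.p_rrms if label == RRMS else self.p_spms


@dataclass(frozen=True)
class PredictionSet:
    labels: frozenset
    significance: float

    @property
    def is_single(self) -> bool:
        return len(self.labels) == 1

    @property
    def is_multiple(self) -> bool:
        return len(self.labels) == 2

    @property
    def is_empty(self) -> bool:
        return len(self.labels) == 0

    def single_label(self) -> Optional[str]:
        return next(iter(self.labels)) if self.is_single else None

    def outcome(self, truth: str) -> str:
        """One of single_correct / single_incorrect / multiple / empty."""
        if self.is_multiple:
            return "multiple"
        if self.is_empty:
            return "empty"
        return "single_correct" if truth in self.labels else "single_incorrect"


def set_from_pvalues(pair: PValuePair, eps: float) -> PredictionSet:
    if not 0.0 < eps < 1.0:
        raise ValueError(f"significance must be in (0, 1), got {eps}")
    labels = frozenset(c for c in CLASSES if pair.get(c) >= eps)
    return PredictionSet(labels, eps)


def predict_pvalues(calibrator: MondrianCalibrator, model: ProbabilisticClassifier,
                    X: np.ndarray, fingerprint: Optional[str] = None,
                    smoothed: bool = False,
                    rng: Optional[np.random.Generator] = None) -> list[PValuePair]:
    """Vectorized per-visit p-value pairs for a feature matrix."""
    if (fingerprint is not None and calibrator.source_fingerprint is not None
            and fingerprint != calibrator.source_fingerprint):
        raise SchemaMismatchError("feature schema does not match the calibrator's")
    proba = model.predict_proba(X, fingerprint)
    out = []
    for row in proba:
        ps = {}
        for ci, c in enumerate(CLASSES):
            ps[c] = p_value(calibrator, c, float(1.0 - row[ci]), smoothed=smoothed, rng=rng)
        out.append(PValuePair(ps[RRMS], ps[SPMS]))
    return out


def predict_set(calibrator: MondrianCalibrator, model: ProbabilisticClassifier,
                x: np.ndarray, eps: float, fingerprint: Optional[str] = None,
                ) -> tuple[PValuePair, PredictionSet]:
    """P-values and the prediction set at significance ``eps`` for one visit."""
    pair = predict_pvalues(calibrator, model, np.atleast_2d(x), fingerprint)[0]
    return pair, set_from_pvalues(pair, eps)
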