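"""Synthetic longitudinal MS cohort generator.

Emulates a registry-like cohort of multiple sclerosis patients observed at
irregular hospital visits, with known ground truth for every patient.  Three
patient archetypes are generated:

* ``rrms_only`` -- relapsing-remitting throughout the observation window;
* ``spms_only`` -- secondary progressive at every recorded visit (the true
  transition predates the first visit);
* ``transitioning`` -- RRMS at the first visit, SPMS at the last, with a
  latent transition date inside the window.

The clinician's recorded course label switches to SPMS only after a
retrospective labelling delay (truncated normal, ~3 years on average), so
the recorded label lags the latent state -- the central confound the
downstream conformal predictor is meant to expose.

All state-dependent dynamics (progressive EDSS drift, relapse-rate drop,
steroid/remission shifts) are scaled by ``class_separation``; at 0 the two
disease states are statistically indistinguishable, which gives an exact
null for calibration tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

RRMS = "RRMS"
SPMS = "SPMS"

ARCHETYPES = ("rrms_only", "spms_only", "transitioning")

RELAPSE_CATEGORIES = ("optic_neuritis", "monofocal", "multifocal", "other")


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardParams:
    """Discrete-time transition hazard: h(t) = baseline + age_coef*(age-30) + duration_coef*t."""

    baseline: float = 0.02
    age_coef: float = 0.002
    duration_coef: float = 0.012


@dataclass(frozen=True)
class EdssDynamics:
    baseline_mean: float = 1.5
    baseline_sd: float = 0.8
    relapse_spike: float = 1.5       # EDSS points at relapse peak
    recovery_fraction: float = 0.75  # fraction of the spike that recovers
    # progressive phase: EDSS gain A*(1 - exp(-(t - tau)/T)) -- fast initial
    # worsening that plateaus, so the EDSS level marks the state change
    # without acting as a clock of the exact time since transition
    progression_amplitude: float = 3.5   # median plateau gain per unit class separation
    amplitude_log_sd: float = 0.6        # per-patient lognormal spread of the gain
    progression_timescale: float = 1.0   # median years to ~2/3 of the plateau
    timescale_log_sd: float = 0.5
    noise_sd: float = 0.25


@dataclass(frozen=True)
class LabelDelay:
    """Clinician SPMS-labelling delay, truncated-at-zero normal, in years."""

    mean_years: float = 3.0
    sd_years: float = 1.0


@dataclass(frozen=True)
class MissingnessRates:
    """Per-stream probability that a due measurement is skipped at a visit."""

    mri: float = 0.55
    sdmt: float = 0.45
    msis: float = 0.55


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 1000
    frac_rrms_only: float = 0.68
    frac_spms_only: float = 0.19
    frac_transitioning: float = 0.13
    mean_visits_per_patient: int = 10
    visit_interval_months: float = 9.0
    visit_interval_jitter_months: float = 3.0
    transition_hazard: HazardParams = field(default_factory=HazardParams)
    edss: EdssDynamics = field(default_factory=EdssDynamics)
    relapse_rate_rrms: float = 0.45  # events / year
    relapse_rate_spms: float = 0.10
    label_delay: LabelDelay = field(default_factory=LabelDelay)
    missingness: MissingnessRates = field(default_factory=MissingnessRates)
    class_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_rrms_only, self.frac_spms_only, self.frac_transitioning)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigurationError(f"archetype fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(f"archetype fractions must sum to 1, got {sum(fracs)!r}")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("relapse_rate_rrms", "relapse_rate_spms", "class_separation",
                     "visit_interval_months", "visit_interval_jitter_months"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.mean_visits_per_patient < 1:
            raise ConfigurationError("mean_visits_per_patient must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class RelapseEvent:
    event_date: date
    category: str
    steroid_treated: bool
    remission: bool


@dataclass
class MriScan:
    scan_date: date
    t2_lesion_count: int
    t1_gd_brain_count: int
    t1_gd_spinal_count: int


@dataclass
class TreatmentEvent:
    start_date: date
    drug: str
    category: str


@dataclass
class VisitRecord:
    visit_date: date
    edss: Optional[float]
    recorded_course: Optional[str]
    relapses: list[RelapseEvent] = field(default_factory=list)
    mri: Optional[MriScan] = None
    sdmt_score: Optional[float] = None
    sdmt_date: Optional[date] = None
    msis_physical: Optional[float] = None
    msis_psychological: Optional[float] = None
    msis_date: Optional[date] = None
    treatments: list[TreatmentEvent] = field(default_factory=list)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str  # 'F' | 'M'
    birth_date: Optional[date]
    debut_date: Optional[date]
    debut_relapse_age: float
    visits: list[VisitRecord] = field(default_factory=list)
    true_transition_date: Optional[date] = None
    archetype: Optional[str] = None

    def validate(self) -> None:
        """Assert the structural invariants of a longitudinal record."""
        dates = [v.visit_date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"{self.patient_id}: visit dates not strictly increasing")
        if self.debut_date is not None and dates and self.debut_date > dates[0]:
            raise ValueError(f"{self.patient_id}: debut after first visit")
        seen_spms = False
        for v in self.visits:
            if v.recorded_course == SPMS:
                seen_spms = True
            elif seen_spms:
                raise ValueError(f"{self.patient_id}: recorded course reverts SPMS->RRMS")
            for ev in v.relapses:
                if ev.event_date > v.visit_date:
                    raise ValueError(f"{self.patient_id}: relapse dated after its visit")
            for stream_date in (v.sdmt_date, v.msis_date,
                                v.mri.scan_date if v.mri else None):
                if stream_date is not None and stream_date > v.visit_date:
                    raise ValueError(f"{self.patient_id}: measurement dated after its visit")
            for tr in v.treatments:
                if tr.start_date > v.visit_date:
                    raise ValueError(f"{self.patient_id}: treatment start after its visit")
        if self.true_transition_date is not None:
            recorded = [v.visit_date for v in self.visits if v.recorded_course == SPMS]
            if recorded and recorded[0] < self.true_transition_date:
                raise ValueError(f"{self.patient_id}: recorded SPMS before true transition")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _years_to_date(origin: date, years: float) -> date:
    return origin + timedelta(days=round(years * DAYS_PER_YEAR))

def _years_between(a: date, b: date) -> float:
    return (b - a).days / DAYS_PER_YEAR


def largest_remainder_allocation(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer counts summing to ``n`` proportional to ``fractions``.

    Floors the exact products, then hands the remaining units to the largest
    fractional parts (ties resolved by position, giving a deterministic
    allocation).
    """
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero by rejection; degenerate sd -> max(mean, 0)."""
    if sd <= 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    return max(mean, 1e-6)


def _round_edss(x: float) -> float:
    return float(np.clip(np.round(x * 2) / 2, 0.0, 10.0))


# drug names drawn per treatment category (see features.DRUG_CATEGORIES)
_FIRST_LINE = ("interferon beta", "glatiramer acetate", "teriflunomide", "dimethyl fumarate")
_SECOND_LINE = ("natalizumab", "fingolimod", "rituximab", "ocrelizumab", "alemtuzumab")
_OTHER = ("fampridine", "baclofen")


# ---------------------------------------------------------------------------
# per-patient simulation
# ---------------------------------------------------------------------------

def simulate_patient(archetype: str, config: SimConfig,
                     rng: np.random.Generator, patient_id: str) -> PatientRecord:
    """Simulate one patient of the given archetype.

    Time is measured in years since disease debut; calendar dates are derived
    from a sampled debut date.  The latent transition time tau (years from
    debut) separates relapsing-remitting dynamics (relapse spikes with
    partial recovery) from progressive dynamics (monotone-in-expectation
    drift, reduced relapse rate).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    sep = config.class_separation
    ed = config.edss

    sex = "F" if rng.random() < 0.71 else "M"
    debut_age = float(np.clip(rng.normal(30.0, 8.0), 15.0, 50.0))
    debut_year = rng.uniform(1985.0, 2012.0)
    debut_date = date(int(debut_year), 1, 1) + timedelta(
        days=round((debut_year % 1.0) * DAYS_PER_YEAR))
    birth_date = _years_to_date(debut_date, -debut_age)

    # -- visit schedule (years from debut) ---------------------------------
    mean_iv = config.visit_interval_months / 12.0
    jitter = max(config.visit_interval_jitter_months / 12.0, 1e-3)
    shape = (mean_iv / jitter) ** 2
    scale = mean_iv / shape

    def draw_interval() -> float:
        return max(rng.gamma(shape, scale), 30.0 / DAYS_PER_YEAR)

    n_visits = max(int(rng.poisson(config.mean_visits_per_patient)), 2)

    delay = _truncated_normal(rng, config.label_delay.mean_years,
                              config.label_delay.sd_years)

    if archetype == "spms_only":
        # true transition between debut and the first recorded visit; entry
        # times span recently transitioned through long-standing SPMS, so
        # disease durations overlap those of transitioning patients
        t_first = rng.uniform(3.0, 14.0)
        tau = rng.uniform(1.0, max(t_first - 0.5, 1.5))
        times = [t_first]
        for _ in range(n_visits - 1):
            times.append(times[-1] + draw_interval())
        recorded_transition = times[0]  # SPMS at every recorded visit
    else:
        t_first = rng.uniform(0.05, 0.5)
        times = [t_first]
        for _ in range(n_visits - 1):
            times.append(times[-1] + draw_interval())
        if archetype == "transitioning":
            # the observation window must accommodate the labelling delay
            min_span = delay + 1.5
            while times[-1] - times[0] < min_span:
                times.append(times[-1] + draw_interval())
            tau = _sample_transition_time(
                rng, config.transition_hazard, debut_age,
                lo=times[0] + 0.1, hi=times[-1] - delay - 0.25)
            recorded_transition = tau + delay
        else:
            tau = None
            recorded_transition = None

    # -- relapse process ----------------------------------------------------
    rate_rr = config.relapse_rate_rrms
    rate_sp = max(rate_rr + sep * (config.relapse_rate_spms - rate_rr), 0.02)
    steroid_p_rr, steroid_p_sp = 0.5, float(np.clip(0.5 - 0.3 * sep, 0.0, 1.0))
    remiss_p_rr, remiss_p_sp = 0.85, float(np.clip(0.85 - 0.35 * sep, 0.0, 1.0))

    relapse_times: list[float] = []
    relapse_events: list[tuple[float, str, bool, bool]] = []
    t_end = times[-1]
    t = 0.0
    rate_max = max(rate_rr, rate_sp)
    while True:
        t += rng.exponential(1.0 / rate_max) if rate_max > 0 else t_end + 1.0
        if t > t_end:
            break
        in_spms = tau is not None and t >= tau
        rate = rate_sp if in_spms else rate_rr
        if rng.random() < rate / rate_max:
            cat = RELAPSE_CATEGORIES[rng.choice(4, p=[0.25, 0.35, 0.25, 0.15])]
            steroid = rng.random() < (steroid_p_sp if in_spms else steroid_p_rr)
            remiss = rng.random() < (remiss_p_sp if in_spms else remiss_p_rr)
            relapse_times.append(t)
            relapse_events.append((t, cat, steroid, remiss))

    # -- EDSS trajectory ----------------------------------------------------
    baseline = float(np.clip(rng.normal(ed.baseline_mean, ed.baseline_sd), 0.0, 4.0))
    # per-patient progression course: rates and plateaus vary widely between
    # patients, so the EDSS level cannot be inverted into an exact
    # time-since-transition
    amplitude = ed.progression_amplitude * sep * float(rng.lognormal(0.0, ed.amplitude_log_sd))
    timescale = ed.progression_timescale * float(rng.lognormal(0.0, ed.timescale_log_sd))

    def edss_continuous(t: float) -> float:
        val = baseline
        for rt in relapse_times:
            if rt <= t:
                dt = t - rt
                residual = ed.relapse_spike * (1.0 - ed.recovery_fraction)
                transient = ed.relapse_spike * ed.recovery_fraction * np.exp(-dt / 0.25)
                val += residual + transient
        if tau is not None and t > tau:
            val += amplitude * (1.0 - np.exp(-(t - tau) / timescale))
        return val

    # -- treatment history --------------------------------------------------
    treatments: list[tuple[float, str, str]] = []  # (time, drug, category)
    if rng.random() < 0.85:
        treatments.append((rng.uniform(0.0, 1.0), rng.choice(_FIRST_LINE), "first_line"))
    escalation_done = False
    for i, rt in enumerate(relapse_times):
        if not escalation_done and i + 1 >= 3 and rng.random() < 0.5:
            treatments.append((rt + rng.uniform(0.1, 0.5), rng.choice(_SECOND_LINE),
                               "second_line"))
            escalation_done = True
        if relapse_events[i][2]:  # steroid-treated relapse
            treatments.append((rt, "methylprednisolone", "relapse_drug"))
    if rng.random() < 0.01:
        treatments.append((rng.uniform(1.0, max(t_end - 1.0, 1.5)),
                           "autologous HSCT", "stem_cell"))
    if rng.random() < 0.10:
        treatments.append((rng.uniform(0.5, max(t_end - 0.5, 1.0)),
                           rng.choice(_OTHER), "other"))
    treatments.sort(key=lambda x: x[0])

    # -- assemble visits ----------------------------------------------------
    miss = config.missingness
    visits: list[VisitRecord] = []
    prev_t = -np.inf
    used_dates: set[date] = set()
    for t in times:
        vdate = _years_to_date(debut_date, t)
        while vdate in used_dates:  # enforce strictly increasing dates
            vdate += timedelta(days=1)
        used_dates.add(vdate)
        age_t = debut_age + t

        edss_val = _round_edss(edss_continuous(t) + rng.normal(0.0, ed.noise_sd))

        new_relapses = [
            RelapseEvent(_cap(_years_to_date(debut_date, rt), vdate), cat, st, rem)
            for rt, cat, st, rem in relapse_events if prev_t < rt <= t
        ]
        new_treatments = [
            TreatmentEvent(_cap(_years_to_date(debut_date, tt), vdate), drug, cat)
            for tt, drug, cat in treatments if prev_t < tt <= t
        ]

        mri = None
        if rng.random() >= miss.mri:
            n_rel = sum(1 for rt in relapse_times if rt <= t)
            t2 = int(rng.poisson(4.0 + 0.5 * t + 0.3 * n_rel))
            gd_b = int(rng.poisson(0.4))
            gd_s = int(rng.poisson(0.15))
            mdate = _cap(_years_to_date(debut_date, max(t - rng.uniform(0.0, 0.2), 0.0)), vdate)
            mri = MriScan(mdate, t2, gd_b, gd_s)

        sdmt = sdmt_date = None
        if rng.random() >= miss.sdmt:
            sdmt = float(np.clip(
                55.0 - 1.1 * edss_continuous(t) - 0.25 * (age_t - 40.0) + rng.normal(0, 4),
                0.0, 110.0))
            sdmt_date = _cap(_years_to_date(debut_date, max(t - rng.uniform(0.0, 0.1), 0.0)), vdate)

        msis_p = msis_ps = msis_date = None
        if rng.random() >= miss.msis:
            msis_p = float(np.clip(10.0 + 8.0 * edss_continuous(t) + rng.normal(0, 6), 0, 100))
            msis_ps = float(np.clip(15.0 + 4.0 * edss_continuous(t) + rng.normal(0, 8), 0, 100))
            msis_date = vdate

        course = RRMS
        if recorded_transition is not None and t >= recorded_transition - 1e-9:
            course = SPMS

        visits.append(VisitRecord(
            visit_date=vdate, edss=edss_val, recorded_course=course,
            relapses=new_relapses, mri=mri, sdmt_score=sdmt, sdmt_date=sdmt_date,
            msis_physical=msis_p, msis_psychological=msis_ps, msis_date=msis_date,
            treatments=new_treatments))
        prev_t = t

    return PatientRecord(
        patient_id=patient_id, sex=sex, birth_date=birth_date, debut_date=debut_date,
        debut_relapse_age=round(debut_age, 1), visits=visits,
        true_transition_date=None if tau is None else _years_to_date(debut_date, tau),
        archetype=archetype)


def _cap(d: date, upper: date) -> date:
    return min(d, upper)


def _sample_transition_time(rng: np.random.Generator, hz: HazardParams,
                            debut_age: float, lo: float, hi: float) -> float:
    """Sample a latent transition time from a discrete-time hazard restricted to (lo, hi).

    The hazard increases with current age and disease duration, so later
    months in the window carry more mass relative to their survival weight.
    """
    if hi <= lo:
        return lo
    grid = np.arange(lo, hi, 1.0 / 12.0)
    if len(grid) == 0:
        grid = np.array([lo])
    h = hz.baseline + hz.age_coef * np.maximum(debut_age + grid - 30.0, 0.0) \
        + hz.duration_coef * grid
    h = np.clip(h / 12.0, 1e-9, 0.999)  # per-month hazard
    survival = np.concatenate([[1.0], np.cumprod(1.0 - h)])[:-1]
    mass = survival * h
    mass /= mass.sum()
    idx = rng.choice(len(grid), p=mass)
    return float(grid[idx] + rng.uniform(0.0, 1.0 / 12.0))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a full cohort plus its ground-truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per patient:
    patient_id, archetype, true_transition_date, recorded_transition_date.
    Archetype counts follow a largest-remainder allocation of the configured
    fractions; the same seed yields a byte-identical cohort.  Per-patient RNG
    streams are spawned from the cohort seed, so individual patients are
    reproducible independently of generation order.
    """
    counts = largest_remainder_allocation(
        config.n_patients,
        (config.frac_rrms_only, config.frac_spms_only, config.frac_transitioning))
    archetypes = [a for a, c in zip(ARCHETYPES, counts) for _ in range(c)]

    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    width = max(len(str(config.n_patients)), 4)
    records = []
    for i, arch in enumerate(archetypes):
        pid = f"P{i:0{width}d}"
        records.append(simulate_patient(arch, config, np.random.default_rng(streams[i]), pid))

    rows = []
    for rec in records:
        recorded = next((v.visit_date for v in rec.visits if v.recorded_course == SPMS), None)
        rows.append({
            "patient_id": rec.patient_id,
            "archetype": rec.archetype,
            "true_transition_date": rec.true_transition_date,
            "recorded_transition_date": recorded,
        })
    truth = pd.DataFrame(rows)
    return records, truth


def recorded_delay_years(records: list[PatientRecord]) -> pd.Series:
    """Per transitioning patient: recorded SPMS label date minus true transition date, in years."""
    out = {}
    for rec in records:
        if rec.archetype != "transitioning" or rec.true_transition_date is None:
            continue
        recorded = next((v.visit_date for v in rec.visits if v.recorded_course == SPMS), None)
        if recorded is not None:
            out[rec.patient_id] = _years_between(rec.true_transition_date, recorded)
    return pd.Series(out, name="label_delay_years")
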