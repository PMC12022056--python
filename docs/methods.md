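# Methods

## Conformal prediction layer

The package implements inductive conformal prediction (ICP) over a binary
RRMS/SPMS visit classifier. The nonconformity of a visit `x` under a
hypothesized label `c` is `α = 1 − P̂(c | x)`, the standard choice for
probabilistic classifiers. The conformal p-value ranks the test score
against the calibration scores with the test point counted as its own
(n+1)-th element and ties counted as `≥`:

```
p = (#{α_cal ≥ α_test} + 1) / (n + 1)
```

This non-smoothed form is deterministic and conservative: p-values
stochastically dominate U(0,1) under exchangeability and can never fall
below `1/(n+1)`. A smoothed variant — ties, including the test point's own,
entering with a shared uniform weight `τ ~ U(0,1)` — is exactly uniform
under exchangeability and is available behind a flag (`smoothed=True`); it
is off by default so repeated predictions are reproducible.

**Mondrian taxonomy.** Calibration scores are kept per true class, and each
class's p-value is ranked only against its own list. This yields per-class
error control (the error rate among true-SPMS visits, not just overall,
stays at or below ε), which is what matters for a screening tool whose two
error directions have very different costs.

**Sets and confidence.** At significance ε the prediction set contains every
label with `p ≥ ε`; with two classes the outcomes are single-label (correct
or not), multiple-label (the model cannot separate the classes — clinically,
a possible transition), and empty (the visit resembles neither class's
calibration data). User surfaces express confidence in percent and convert
internally as `ε = 1 − confidence/100`. "Error" everywhere means the true
label is not in the set, so empty predictions count as errors and
multiple-label predictions never do — the definition under which the
calibration curve's diagonal is the theoretical target. The alternative
convention (multiple = error) would change Fig.-style efficiency summaries
but not the validity guarantee; it is intentionally not used.

**Validity evaluation.** Visits within a patient are strongly dependent, so
validity and uniformity checks are computed on one visit per patient, with
each patient included independently with probability proportional to their
visit count. This keeps the units independent *and* matches the calibration
set's visit-level marginal distribution (uniform per-patient sampling would
under-represent long records and their hard transition-phase visits, biasing
p-values conservative). Observed per-class error is compared against
`ε + 3·sqrt(ε(1−ε)/n)`; smoothed true-class p-values are tested against
U(0,1) with a Kolmogorov–Smirnov test.

## Underlying classifiers

Defaults: random forest (150 trees, Gini, minimum 5 samples per leaf) —
the model used throughout; gradient boosting (50 estimators, minimum split
2, friedman_mse, exponential loss); RBF-SVM (γ = 1e-4, C = 1) with internal
Platt score-to-probability calibration; logistic regression with library
defaults. Hyperparameter search is out of scope: the defaults are fixed,
tuned values, overridable via `ModelSpec`. Cross-validation is 10-fold
grouped by patient id — visits of one patient never straddle folds, which
would otherwise leak within-patient correlation into the score.

## Synthetic cohort generator

The generator emulates the *structure* of a clinical MS registry, not its
epidemiology. Per patient: debut age ~ N(30, 8) clipped to [15, 50]; gamma
inter-visit intervals (mean 9 months, jitter 3); Poisson visit counts
(mean 10); per-stream missingness (MRI 55%, SDMT 45%, MSIS 55% of visits).
Archetype fractions default to 68/19/13 (RRMS-only / SPMS-only /
transitioning), matching the registry-style test-split composition the
pipeline is meant to reproduce.

**Latent transition.** Transitioning patients draw a transition time from a
discrete-time hazard increasing with age and disease duration, restricted to
their observation window; SPMS-only patients transition between debut and
their first recorded visit, with entry into observation spread over 3–14
years after debut so that confirmed-SPMS and transition-phase visits overlap
in disease duration. The observation window of a transitioning patient is
extended until it accommodates the sampled labelling delay plus 1.5 years.

**EDSS dynamics.** RRMS phase: baseline ~ N(1.5, 0.8) plus relapse spikes
(1.5 EDSS points, 75% recovered with a 3-month decay, the rest permanent).
Progressive phase: a saturating gain `A·(1 − exp(−(t−τ)/T))` with
per-patient lognormal amplitude (median 3.5 × class-separation, log-sd 0.6)
and timescale (median 1 year, log-sd 0.5). The saturation is deliberate: a
constant linear drift would make the EDSS level an invertible clock of
time-since-transition, letting a classifier reconstruct the mean labelling
delay and track the *recorded* boundary instead of the disease state — the
opposite of how registry data behaves, where progression rates vary widely
and plateau. Visit EDSS adds N(0, 0.25) noise, rounds to the 0.5 grid and
clips to [0, 10].

**Relapses, treatments, secondary measures.** Relapses follow a thinned
Poisson process (0.45/yr RRMS, dropping toward 0.10/yr after transition),
with category, steroid-treatment and remission flags whose probabilities
shift at the true transition. Treatments: first-line DMT near debut,
possible second-line escalation after repeated relapses, steroid courses at
treated relapses, rare stem-cell therapy. SDMT and MSIS-29 are noisy
functions of the continuous EDSS and age, so all state dependence flows
through the same separation scaling.

**class_separation.** Every state-dependent effect (progression amplitude,
relapse-rate drop, steroid/remission shifts) is multiplied by this scalar.
At 0 the two states are distributionally identical — an exact null used to
test that nothing else leaks label information. Large values (4 is used in
the parameter-recovery tests) give a sharply detectable transition.

**Labelling delay.** The recorded course label switches to SPMS only at the
first visit at or after `τ + delay`, `delay ~ N(3, 1)` truncated at zero —
applied to the *label only*, never to the features. This reproduces the
retrospective-diagnosis confound: a model keyed to the feature state flags
SPMS during the delay window, earlier than the chart.

**What the generator does not emulate** (and hence what passing tests do not
show about real data): calendar trends and centre effects, informative
visit timing, measurement error correlated across streams, PPMS, mortality
and dropout, treatment effects on progression, and realistic incidence or
geography. Results on synthetic cohorts validate the machinery — validity,
nestedness, recovery of planted transitions — not clinical performance.

## Trajectory analytics

The predicted transition is the first visit whose single-label prediction is
SPMS, sustained (SPMS stays in the set for ≥ 2 consecutive visits) and never
followed by a single-label RRMS visit; isolated flips are treated as
unreliable, mirroring the alternation analysis. Offsets are
`predicted − recorded` (visits and years); negative means the model flagged
SPMS before the clinician. Alternation is ≥ 2 consecutive single-SPMS visits
separated by > 3 months that later revert to single-RRMS. The
misclassification taxonomy is a codification of qualitative p-value shapes,
applied in fixed precedence: fluctuating single labels (≥ 3 sign changes) →
cat4; a quiet prefix (≥ 2 visits with p_SPMS < 0.1) followed by the
change-point maximizing the mean-after-minus-before gap, with a rising
Theil–Sen slope after it → cat2; an elevated start (p_SPMS ≥ 0.1) with
positive overall trend (> 0.01/visit) → cat1; a rise that plateaus
(late-window |slope| ≤ 0.01/visit) → cat3; otherwise misc. Thresholds are
configuration (`TaxonomyThresholds`) and are validated on constructed
series only — the category boundaries on real data would be a clinical
judgement, not a property of this code.

A known limitation of the offset analysis: many patients flip exactly at
the recorded visit, creating a large probability atom at offset zero. The
median offset therefore often sits on that atom, and the "model earlier
than registry" direction is more stably visible in the mean offset and in
the early-vs-late fractions than in the median.

## Shapley attributions

Attributions explain the SPMS output (random forest: SPMS probability;
gradient boosting: log-odds margin) as base value + per-feature signed
contributions; local accuracy is asserted on every attribution at 1e-6.
For tree ensembles the values are exact: for each leaf, the conditional
value function factorizes over the unique features on its root path — a
feature contributes its split indicator when present in the coalition and
its product of node cover ratios when absent — reducing the Shapley sum to
weighted elementary symmetric polynomials, O(path²) per leaf. The
implementation is verified in the tests against brute-force subset
enumeration over an independent recursive value function. Exact symmetry
between duplicated features is not guaranteed by path-dependent attribution
(the tree picks one duplicate to split on); the tests assert approximate
symmetry only. Non-tree models use a seeded interventional
permutation-sampling estimator over a background set; telescoping within
each permutation preserves exact additivity at any sample count, while more
permutations only reduce the variance of the split between features.

## Numerical and design choices

- Ages and durations are `(date − birth)/365.25`, reported at 0.1-year
  resolution; all dates are ISO-8601; ages are derived, never stored.
- Tail pruning removes the anchoring last visit as well (its endpoint is
  as undetermined as the rest of the window); removals are logged so the
  alternative convention is auditable.
- Treatment is encoded both as the current category (ordinal 1–5) and as
  per-category ever-flags; before any treatment is observed both are −1.
- Largest-remainder rounding allocates archetypes and split memberships,
  with deterministic tie-breaking; per-patient RNG streams are spawned from
  the cohort seed, so cohorts are byte-identical given a seed and patients
  are reproducible independently of generation order.
- Peak-confidence ties break toward the smaller significance (higher
  confidence). The ε grid is 0.01–0.50 in steps of 0.01.
- Split outputs, JSON artifacts and reports are written with sorted keys and
  sorted id lists so runs are byte-identical across processes.
- Calibration pools scores per visit (the calibration unit is the hospital
  visit); the leakage guard rejects any overlap between calibration and
  training patients.

## Problem sizes

The test suite exercises cohorts of 150–1000 patients (validity,
uniformity, coherence) and 3800 patients (transition-timing recovery, so
that ≥ 100 transitioning patients fall in the 25% test split and retain a
defined offset); the acceptance script uses the same sizes. The full suite
runs in well under a minute on one CPU.
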