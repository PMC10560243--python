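# Methods

This note documents the models, the synthetic-cohort generator, the
numerical conventions, and the design choices made where the procedure was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The estimation problem

Each participant i is seen at visits v = 1..7 (3-month spacing). At each
visit a wearable-sensor session yields ~122 kinematic features x_iv and a
clinician rates the MDS-UPDRS-III motor items (ordinal 0–4). The analysis
estimates the total motor score y_iv from x_iv with one of seven
configurations, selects the most accurate by cross-validation, and then asks
whether the *estimated* score series detects a progression across visits
that the observed ordinal score does not.

## Synthetic cohort generator

No clinical data ship with the package; the generator produces cohorts with
the statistical structure the analysis assumes. The generative model, per
participant i:

- gait-observable severity `gait_i(v) = g_i + m_i (v−1)` with
  `g_i ~ N(24, 7²)` and slope `m_i ~ N(0.4, 0.25²)` score units per visit;
- clinical severity `s_i(v) = gait_i(v) + q_i`, `q_i ~ N(0, 7²)` a
  participant-constant clinical-only offset (the parts of the motor exam —
  tremor, rigidity, upper-limb bradykinesia — that gait and sway sensors do
  not see);
- clinician items: `s_i(v)` plus visit-level rater/state noise `N(0, 7²)`
  is split equally over the 16 retained items, jittered (sd 0.15) and
  rounded to 0–4. Two extra items (speech, facial expression) are generated
  as severity-unrelated ordinals and later dropped by preprocessing;
- features: 29 of 122 features couple to gait severity through a signed
  loading in (0.3, 1.0). The *between-person* link is the identity or, for
  70% of progressing features, a banded sigmoid `w·tanh((g−c)/w)`
  (c ~ U(12,36), w ~ U(4,10)): a kinematic measure with floor/ceiling
  behaviour, informative only over a band of severities. The *within-person*
  drift `m_i (v−1)` enters linearly — change over 18 months is small, so it
  is treated as locally linear. Noise has three parts, all shared within
  equicorrelated feature blocks (10 blocks, ρ = 0.5): a stable
  participant-by-feature intercept (sd 6; anatomy and gait style), visit
  level noise (sd 3), and rare large sensor artifacts (2% of cells,
  sd 25);
- progression is planted in the symptom-relative frame: the truth names
  relabelled features (Ipsilateral_X / Contralateral_X), and the physical
  Left/Right column carrying the loading depends on each participant's
  onset side. Planting on physical columns instead would dilute group
  trends once left- and right-onset participants are pooled;
- missed visits: Bernoulli(0.05) per participant-visit, then repaired so no
  run exceeds 2 consecutive misses, the two endpoint visits are never both
  missing, and every participant keeps ≥ 2 observed visits.

All draws consume one `numpy` Generator in a fixed order, so a (config,
seed) pair yields a bit-identical cohort.

### Why these numbers

The parameters were chosen once, as a coherent scenario, from three
constraints a realistic cohort must satisfy simultaneously: (i) the
clinical score is centred near 24 with cross-sectional SD ≈ 12 (7² + 7² +
7² ≈ 12.2² across the three variance components); (ii) wearable features
can explain only a minority of score variance — a perfect recovery of gait
severity still leaves the clinical-only offset and rater noise
(√(7²+7²) ≈ 10 RMSE floor), and single features predict weakly
(cross-sectional r ≈ 0.3); (iii) the per-visit drift (0.4 points) is small
against the visit-level clinical noise (7 points), so the raw score shows
no significant pairwise progression over 7 visits while the feature signal,
whose visit-level noise is far smaller, does. The banded nonlinear links and
the artifact cells give the scenario its "nonlinear, collinear, contaminated"
character: they are what makes a forest on raw features the right tool
rather than a linear model or a PCA rotation (see *Model comparison*).

### What the generator does not emulate

Medication state and ON/OFF fluctuations, dropout-for-cause, learning or
fatigue effects across visits, non-Gaussian feature distributions, item
-specific rater profiles, and any raw-signal-level structure (the features
are abstract numbers, not re-derived from accelerometry). Passing tests
therefore demonstrate that the *pipeline* behaves correctly under the
assumed structure, not that real cohorts have that structure.

## Preprocessing conventions

- Exclusion: a participant is dropped when the longest run of consecutive
  missed visits exceeds 2 (trailing and leading runs count).
- Imputation: interior gaps are linearly interpolated on visit index; a gap
  at the first or last visit has no bracketing pair, and the nearest
  observation is carried back/forward instead — extrapolating a slope would
  manufacture trends. Imputed cells stay flagged. Clinical totals are
  imputed the same way by default (`impute_scores=False` drops those rows
  from the score table instead).
- Score assembly: total = sum of all items except 3.1/3.2; gait-posture
  aggregate = items 3.10–3.13. The item set is configurable; only the two
  aggregation rules matter.
- Stride-length features (name pattern `StrideLength`, configurable) are
  divided by height in metres; a flag prevents double division.
- Relabeling maps the leading Left/Right token to Ipsilateral (onset side)
  or Contralateral per participant. It is a bijection on side-specific
  names and idempotent.

## Progressing-feature screen

Feature values are averaged across participants per visit; OLS of the 7
mean points on visit index gives a slope and a two-sided t-test p-value
(df = 5). Degenerate fits use the convention: zero residual with zero slope
→ p = 1 (constant feature, no trend); zero residual with nonzero slope →
p = 0 (exact trend). The screen is invariant to participant relabeling and
to affine rescaling of a feature.

## Forward selection

Leave-one-visit-out: for each held-out visit, start from the feature with
the lowest screen p-value, and at each step add the candidate that most
reduces the validation RMSE of an OLS fit on the other six visits' rows;
stop when no candidate improves by more than `min_improvement` (default 0,
with a 1e-12 relative guard against float jitter). Ties break by screen
p-value rank, then name. The consensus set keeps features accepted in ≥ k
of the 7 folds (default k = 5). Fold RMSE traces are strictly decreasing by
construction.

## PCA factorisation

Features are z-scored with training-set statistics before the decomposition
(the feature set mixes units; unscaled PCA would rank features by unit
choice). Retained component count = smallest k whose cumulative explained
variance ratio reaches the threshold (default 0.90). Inside
cross-validation the factor model is fitted on the training fold only;
`pca_leakage_compat=True` reproduces a single pre-split fit for comparison
with analyses that factorised once.

## Model comparison

The 5-fold split is at the row (participant-visit) level by default,
mirroring a pooled random split of all 518 rows; this leaks within-person
correlation between training and validation, so a participant-level split
(`split_unit="participant"`) is provided and recommended when an unbiased
generalisation estimate is the goal. Reported spread is the sample standard
deviation (ddof = 1) over fold RMSEs. The winner minimises mean RMSE, ties
broken by lower std, then lower model id. Forests use 500 trees by default
(squared-error criterion, unrestricted depth, fixed seed); analysis scripts
and the acceptance runner use 60–300 trees, which is ample for stable RMSE
rankings at 518 rows while keeping runtimes in seconds.

## Estimated score series

The longitudinal estimate for each participant-visit is the winning model's
out-of-fold prediction from a *participant-level* 5-fold split: every visit
of a participant is predicted by one model that never saw that participant.
Two alternatives were rejected: in-sample predictions of a model refitted on
all rows partially memorise the clinical noise (defeating the denoising
purpose), and row-level out-of-fold predictions score a participant's visits
with different fold models, so participant-level model error does not cancel
in the paired vs-baseline tests.

## Progression statistics

Per series: per-visit median and IQR (75th − 25th percentile), per-visit
Shapiro-Wilk p (error outside 3 ≤ n ≤ 5000 or on constant samples),
Friedman omnibus (mid-ranks, tie-corrected, χ² with V−1 df), Wilcoxon
signed-rank of each visit v > 1 against visit 1 (zeros dropped — Wilcoxon's
original policy; exact null for ≤ 25 untied differences, else normal
approximation with tie correction; all-zero differences give p = 1 with a
warning), Benjamini-Hochberg step-up across the 6 pairwise p-values at 1%
FDR, applied separately per series. Tests are two-sided. The median rate of
change is the OLS slope of the 7 per-visit medians on visit index. The
earliest significant visit is the smallest BH-flagged visit.

## Pipeline and reproducibility

`run_pipeline` executes simulate/ingest → preprocess → screen → select →
compare → progression, writing every intermediate table plus a manifest
(config hash, sub-seeds, stage counts, winner, earliest significant
visits). All randomness derives from one master seed through named
`SeedSequence` children (simulation, CV split, forest, estimate split); JSON
artifacts are written with sorted keys and no timestamps, so identical
configurations reproduce byte-identical outputs. On a null cohort (nothing
progressing) the pipeline still completes, falling back to the two lowest-p
features so all seven configurations can be built.

## Calibration scenario

The type-I-error check of the trend screen simulates cohorts with no
planted progression *and* independent features
(`within_block_correlation=0`): the binomial reference distribution for the
flagged fraction assumes independent trials, and the check targets the
screen's level, not the generator's correlation structure. With correlated
features the flagged fraction has the same mean but inflated variance, and
a binomial interval would be invalid.

## Problem sizes in tests and the acceptance runner

Unit tests run on reduced cohorts (e.g. 24 × 7 × 24) that preserve the full
structure; calibration uses 200 null cohorts of 40 participants × 60
features; the headline contrast uses 100 replicate cohorts at full size
with 60-tree forests; the model-ordering check averages 5 replicate
comparisons with 100-tree forests. These sizes give stable Monte-Carlo
estimates at interactive runtimes.

## Known limitations

- The row-level default CV split matches the pooled-split study design but
  overstates accuracy relative to a participant-level split; both are
  implemented.
- The screen tests only linear group-mean trends; monotone nonlinear drifts
  or heterogeneous per-participant slopes are attenuated. Mixed-effects
  screens would be the natural extension and are deliberately out of scope.
- The Wilcoxon statistic is invariant to positive affine rescaling of the
  scores but not to general monotone transforms (magnitude ranks of paired
  differences change); the suite asserts the affine property.
- With ~20 detected features and a 7-point noise floor, the model-ordering
  result (forest on raw progressing features first) is a statistical
  regularity across replicate cohorts, not a per-seed certainty; the
  acceptance runner therefore averages RMSEs over replicates.
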