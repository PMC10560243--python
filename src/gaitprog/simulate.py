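"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a wearable-sensor Parkinson's cohort:
~74 participants seen at 7 visits spaced 3 months apart, 122 kinematic
features per participant-visit, a subset of features drifting with a latent
motor-severity trajectory, blockwise collinearity among features, an ordinal
clinician score that is a noisy, coarse rendering of severity, and sporadic
missed visits.

Generative model
----------------
Participant i carries a gait-observable severity trajectory and a
participant-constant clinical-only offset,

    gait_i(v) = g_i + m_i (v - 1),   g_i ~ N(mu_b, sd_b),  m_i ~ N(mu_m, sd_m)
    s_i(v)    = gait_i(v) + q_i,     q_i ~ N(0, sd_q)

both in clinical-score units. The wearable features respond to gait_i only
(sensors capture gait and sway, while the clinical score also rates functions
they cannot see); the clinician score renders s_i. A progressing feature f
couples to the baseline severity through a monotone link h_f — identity, or
a banded sigmoid ``w_f * tanh((x - c_f)/w_f)`` for a configurable fraction
(kinematic measures with floor/ceiling behaviour, informative only over a
severity band) — while the within-person drift enters linearly (change over
18 months is small, so it is locally linear):

    x_{ivf} = mu_f + c_f [ h_f(g_i) + m_i (v - 1) ] + u_{if} + e_{ivf} + a_{ivf}

with a signed loading c_f, a stable participant-by-feature intercept u
(between-person anatomical/style differences), visit-level noise e (both
noise terms equicorrelated within feature blocks), and rare large sensor
artifacts a. Progression is planted in the symptom-relative frame: truth
names a relabelled feature (Ipsilateral_X / Contralateral_X) and the
physical Left/Right column that carries its loading depends on the
participant's side of symptom onset.

Clinician items add a visit-level rater/state noise to s_i, split the result
equally across the retained ordinal items, jitter each item and round to the
0-4 scale. All draws consume a single numpy Generator in a fixed, documented
order, so identical (config, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitprog.cohort import ClinicalScoreTable, CohortTable

# Lateral gait measures: each yields Left/Right x Mean/SD feature columns.
LATERAL_MEASURES = [
    "StrideLength", "StepLength", "StrideVelocity", "SwingPhase", "StancePhase",
    "SingleSupport", "DoubleSupport", "TerminalDoubleSupport", "InitialDoubleSupport",
    "FootStrikeAngle", "ToeOffAngle", "ToeOutAngle", "CircumductionAmplitude",
    "ElevationAtMidswing", "StepDuration", "GaitCycleDuration", "Cadence",
    "LateralStepVariability", "ArmSwingAmplitude", "ArmSwingVelocity",
    "ShankRangeOfMotion", "ThighRangeOfMotion", "KneeRangeOfMotion",
    "TrunkRotationRange", "FootFlatRatio", "PushOffAcceleration",
]
# Non-lateral postural-sway measures: Mean/SD each.
SWAY_MEASURES = [
    "MediolateralSwayVelocity", "AnteroposteriorSwayVelocity", "SwayArea",
    "SwayPathLength", "SwayJerk", "MediolateralSwayRange",
    "AnteroposteriorSwayRange", "SwayFrequency", "TurnVelocity",
]

RETAINED_ITEMS = [f"3.{i}" for i in range(3, 19)]  # 3.3 .. 3.18
OMITTED_ITEMS = ["3.1", "3.2"]  # speech, facial expression


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the analysis assumes: a 74-person
    cohort over 7 three-monthly visits; 122 features of which 29 drift with
    severity; a clinician score centred near 24 with cross-sectional SD ~12,
    of which the wearable features can explain only a minority share (gait
    severity SD 7 against a 7-point clinical-only offset and 7 points of
    visit-to-visit rater/state noise); and a per-visit drift (0.4 points)
    small against that visit-level noise, so progression is hard to see in
    the raw ordinal score but accessible through the denoised feature signal.
    """

    n_participants: int = 74
    n_visits: int = 7
    visit_interval_months: float = 3.0
    n_features: int = 122
    n_progressing: int = 29

    severity_baseline_mean: float = 24.0
    severity_baseline_sd: float = 7.0    # gait-observable baseline spread
    clinical_offset_sd: float = 7.0      # participant-constant, invisible to sensors
    severity_slope_mean: float = 0.4     # score units per visit
    severity_slope_sd: float = 0.25

    feature_loading_range: tuple[float, float] = (0.3, 1.0)
    nonlinear_fraction: float = 0.7      # share of progressing features with sigmoid links
    n_collinear_blocks: int = 10
    within_block_correlation: float = 0.5
    feature_intercept_sd: float = 6.0    # stable participant-by-feature offsets
    feature_noise_sd: float = 3.0        # visit-level feature noise
    artifact_rate: float = 0.02          # sporadic sensor-artifact cells
    artifact_sd: float = 25.0            # artifact magnitude, feature units

    clinical_noise_sd: float = 7.0       # visit-level rater/state noise, score units
    item_noise_sd: float = 0.15          # per-item jitter before rounding
    missing_visit_rate: float = 0.05
    max_consecutive_missing: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_visits": self.n_visits,
            "n_features": self.n_features,
            "n_progressing": self.n_progressing,
            "n_collinear_blocks": self.n_collinear_blocks,
            "max_consecutive_missing": self.max_consecutive_missing,
        }
        for name, v in counts.items():
            if int(v) != v or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_collinear_blocks < 1:
            raise ConfigError("n_collinear_blocks must be >= 1")
        if self.n_progressing > self.n_features:
            raise ConfigError(
                f"n_progressing ({self.n_progressing}) exceeds n_features ({self.n_features})"
            )
        for name in ("missing_visit_rate", "within_block_correlation", "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1), got {v!r}")
        if not (0.0 <= self.nonlinear_fraction <= 1.0):
            raise ConfigError(
                f"nonlinear_fraction must lie in [0, 1], got {self.nonlinear_fraction!r}"
            )
        for name in (
            "severity_baseline_sd", "clinical_offset_sd", "severity_slope_sd",
            "feature_intercept_sd", "feature_noise_sd", "clinical_noise_sd",
            "item_noise_sd", "artifact_sd",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v!r}")
        lo, hi = self.feature_loading_range
        if not (0 <= lo <= hi):
            raise ConfigError(
                f"feature_loading_range must satisfy 0 <= lo <= hi, got {(lo, hi)!r}"
            )
        if self.visit_interval_months <= 0:
            raise ConfigError("visit_interval_months must be positive")

    @classmethod
    def noise_free(cls, **overrides) -> "CohortConfig":
        """Deterministic limit: no noise, no missingness, linear links only.

        Every progressing feature is then exactly linear in visit index for
        every participant, and the clinical score is non-decreasing.
        """
        base = dict(
            feature_intercept_sd=0.0, feature_noise_sd=0.0, clinical_noise_sd=0.0,
            item_noise_sd=0.0, artifact_rate=0.0, missing_visit_rate=0.0,
            severity_slope_sd=0.0,
            nonlinear_fraction=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """No planted progression and independent features.

        Used for type-I-error calibration of the trend screen, where the
        binomial reference distribution assumes independent features.
        """
        base = dict(n_progressing=0, within_block_correlation=0.0)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_loading_range"] = list(self.feature_loading_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "feature_loading_range" in d:
            d["feature_loading_range"] = tuple(d["feature_loading_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort, for parameter-recovery tests.

    severity : participants x visits clinical severity (gait + offset),
        including visits later dropped as missing.
    gait_severity : the sensor-visible component the features load on.
    progressing_features : relabelled (Ipsilateral/Contralateral) names of
        the features coupled to severity — directly comparable with the
        preprocessed cohort's columns.
    loadings : per-feature signed loading, link kind and block id.
    """

    severity: pd.DataFrame
    gait_severity: pd.DataFrame
    progressing_features: list[str]
    loadings: pd.DataFrame
    config: CohortConfig = field(repr=False)


def feature_catalogue(n_features: int) -> pd.DataFrame:
    """Feature name catalogue with side/task/statistic structure.

    Returns a frame with columns name, lateral (carries a Left/Right token),
    measure, statistic. Lateral gait measures are emitted in complete
    Left/Right x Mean/SD quadruples so relabeling stays a bijection; sway
    measures in Mean/SD pairs; any remainder is padded with single
    non-lateral auxiliary features.
    """
    rows: list[tuple[str, bool, str, str]] = []
    lat = iter(LATERAL_MEASURES)
    sway = iter(SWAY_MEASURES)
    while len(rows) + 4 <= n_features:
        try:
            m = next(lat)
        except StopIteration:
            break
        for side in ("Left", "Right"):
            for stat in ("Mean", "SD"):
                rows.append((f"{side}_{m}_{stat}", True, m, stat))
    while len(rows) + 2 <= n_features:
        try:
            m = next(sway)
        except StopIteration:
            break
        for stat in ("Mean", "SD"):
            rows.append((f"{m}_{stat}", False, m, stat))
    i = 0
    while len(rows) < n_features:
        i += 1
        rows.append((f"AuxiliaryFeature{i:03d}_Mean", False, f"AuxiliaryFeature{i:03d}", "Mean"))
    return pd.DataFrame(rows, columns=["name", "lateral", "measure", "statistic"])


def _draw_missing_mask(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    """Boolean (participants x visits) mask, True = missing.

    Runs longer than max_consecutive_missing are broken, the two endpoint
    visits are never both missing, and every participant keeps >= 2 observed
    visits (so interior interpolation is well defined).
    """
    p, v = cfg.n_participants, cfg.n_visits
    miss = rng.random((p, v)) < cfg.missing_visit_rate
    if cfg.missing_visit_rate == 0 or v == 0:
        return np.zeros((p, v), dtype=bool)
    for i in range(p):
        run = 0
        for j in range(v):
            if miss[i, j]:
                run += 1
                if run > cfg.max_consecutive_missing:
                    miss[i, j] = False
                    run = 0
            else:
                run = 0
        if v >= 2 and miss[i, 0] and miss[i, -1]:
            miss[i, 0] = False
        j = 0
        while v - miss[i].sum() < min(2, v):
            if miss[i, j]:
                miss[i, j] = False
            j += 1
    return miss


def generate_cohort(
    config: CohortConfig,
) -> tuple[CohortTable, ClinicalScoreTable, SyntheticTruth]:
    """Generate one synthetic cohort.

    Returns the long-format feature table with metadata, the per-item
    clinical score table, and the ground truth. Missed visits are absent from
    both observed tables but present in the truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p, v, f = cfg.n_participants, cfg.n_visits, cfg.n_features

    # --- draw order is part of the reproducibility contract ---
    # 1. participant metadata
    ids = [f"P{i + 1:03d}" for i in range(p)]
    height = rng.normal(1.72, 0.096, size=p)
    onset = np.where(rng.random(p) < 0.43, "right", "left")
    sex = np.where(rng.random(p) < 42 / 74, "M", "F")
    age = rng.normal(64.6, 7.8, size=p)
    metadata = pd.DataFrame(
        {
            "height_m": np.round(height, 4),
            "onset_side": onset,
            "sex": sex,
            "age": np.round(age, 1),
        },
        index=pd.Index(ids, name="participant_id"),
    )

    # 2. latent trajectories
    g = rng.normal(cfg.severity_baseline_mean, cfg.severity_baseline_sd, size=p)
    q = rng.normal(0.0, cfg.clinical_offset_sd, size=p)
    m = rng.normal(cfg.severity_slope_mean, cfg.severity_slope_sd, size=p)
    visits = np.arange(1, v + 1)
    gait_sev = g[:, None] + m[:, None] * (visits - 1)[None, :]   # (p, v)
    severity = gait_sev + q[:, None]

    # 3. feature structure (see module docstring: progression lives in the
    # symptom-relative frame; `swap` maps a physical column to its partner)
    cat = feature_catalogue(f)
    names = cat["name"].to_numpy()
    relabeled = np.array(
        [
            n.replace("Left_", "Ipsilateral_", 1).replace("Right_", "Contralateral_", 1)
            for n in names
        ]
    )
    pos = {n: i for i, n in enumerate(names)}
    swap = np.arange(f)
    for i, n in enumerate(names):
        if n.startswith("Left_"):
            swap[i] = pos["Right_" + n[5:]]
        elif n.startswith("Right_"):
            swap[i] = pos["Left_" + n[6:]]
    prog_idx = np.sort(rng.choice(f, size=cfg.n_progressing, replace=False))
    loading_lo, loading_hi = cfg.feature_loading_range
    loadings = np.zeros(f)
    loadings[prog_idx] = rng.uniform(loading_lo, loading_hi, size=cfg.n_progressing)
    signs = np.ones(f)
    signs[prog_idx] = rng.choice([-1.0, 1.0], size=cfg.n_progressing)
    nonlinear = np.zeros(f, dtype=bool)
    if cfg.n_progressing:
        nonlinear[prog_idx] = rng.random(cfg.n_progressing) < cfg.nonlinear_fraction
    centers = np.zeros(f)
    widths = np.ones(f)
    n_sat = int(nonlinear.sum())
    if n_sat:
        # sigmoid response bands spanning the plausible severity range
        centers[nonlinear] = rng.uniform(12.0, 36.0, size=n_sat)
        widths[nonlinear] = rng.uniform(4.0, 10.0, size=n_sat)
    blocks = rng.integers(0, cfg.n_collinear_blocks, size=f)
    offsets = rng.normal(30.0, 15.0, size=f)

    # 4. noise fields: participant-stable intercepts and visit-level noise,
    # both equicorrelated within blocks
    u_block = rng.standard_normal((p, cfg.n_collinear_blocks))
    u_feat = rng.standard_normal((p, f))
    z_block = rng.standard_normal((p, v, cfg.n_collinear_blocks))
    eps = rng.standard_normal((p, v, f))

    rho = cfg.within_block_correlation
    intercepts = cfg.feature_intercept_sd * (
        np.sqrt(rho) * u_block[:, blocks] + np.sqrt(1.0 - rho) * u_feat
    )
    noise = cfg.feature_noise_sd * (
        np.sqrt(rho) * z_block[:, :, blocks] + np.sqrt(1.0 - rho) * eps
    )
    if cfg.artifact_rate > 0 and cfg.artifact_sd > 0:
        # sporadic sensor/extraction artifacts: rare, large, isolated cells
        artifact_mask = rng.random((p, v, f)) < cfg.artifact_rate
        artifact_vals = rng.normal(0.0, cfg.artifact_sd, size=(p, v, f))
        noise = noise + artifact_mask * artifact_vals
    signal = np.zeros((p, v, f))
    if cfg.n_progressing:
        lam = signs * loadings  # indexed by relabelled feature position
        drift = gait_sev - g[:, None]  # within-person change, linear in visit
        # onset left: Left == Ipsilateral, physical column i carries lam[i];
        # onset right: sides swap, column i carries lam[swap[i]].
        for side, perm in (("left", np.arange(f)), ("right", swap)):
            who = onset == side
            if not who.any():
                continue
            lam_s, nl_s = lam[perm], nonlinear[perm]
            c_s, w_s = centers[perm], widths[perm]
            # between-person response to baseline severity is banded for
            # sigmoid-link features; within-person drift is locally linear
            base = np.repeat(g[who][:, None], f, axis=1)  # (p_side, f)
            idx = np.nonzero(nl_s)[0]
            if len(idx):
                base[:, idx] = w_s[idx] * np.tanh(
                    (g[who][:, None] - c_s[idx]) / w_s[idx]
                )
            resp = base[:, None, :] + drift[who][:, :, None]
            signal[who] = resp * lam_s[None, None, :]
    values = offsets[None, None, :] + signal + intercepts[:, None, :] + noise

    # 5. clinical items
    n_items = len(RETAINED_ITEMS)
    state_noise = (
        rng.normal(0.0, cfg.clinical_noise_sd, size=(p, v))
        if cfg.clinical_noise_sd
        else np.zeros((p, v))
    )
    jitter = (
        rng.normal(0.0, cfg.item_noise_sd, size=(p, v, n_items))
        if cfg.item_noise_sd
        else np.zeros((p, v, n_items))
    )
    share = (severity + state_noise)[:, :, None] / n_items + jitter
    retained_items = np.clip(np.rint(share), 0, 4).astype(int)  # (p, v, n_items)
    omitted_vals = np.clip(
        np.rint(rng.normal(1.0, 0.6, size=(p, v, len(OMITTED_ITEMS)))), 0, 4
    ).astype(int)

    # 6. missingness
    miss = _draw_missing_mask(rng, cfg)

    obs = ~miss
    pi, vi = np.nonzero(obs)
    feat_long = pd.DataFrame(
        {
            "participant_id": np.repeat(np.asarray(ids)[pi], f),
            "visit": np.repeat(visits[vi], f),
            "feature": np.tile(names, len(pi)),
            "value": values[pi, vi, :].ravel(),
        }
    )

    item_ids = OMITTED_ITEMS + RETAINED_ITEMS
    all_items = np.concatenate([omitted_vals, retained_items], axis=2)
    score_long = pd.DataFrame(
        {
            "participant_id": np.repeat(np.asarray(ids)[pi], len(item_ids)),
            "visit": np.repeat(visits[vi], len(item_ids)),
            "item_id": np.tile(np.asarray(item_ids), len(pi)),
            "item_value": all_items[pi, vi, :].ravel(),
        }
    )

    truth = SyntheticTruth(
        severity=pd.DataFrame(
            severity, index=metadata.index, columns=pd.Index(visits, name="visit")
        ),
        gait_severity=pd.DataFrame(
            gait_sev, index=metadata.index, columns=pd.Index(visits, name="visit")
        ),
        progressing_features=list(relabeled[prog_idx]),
        loadings=pd.DataFrame(
            {
                "loading": signs * loadings,
                "link": np.where(nonlinear, "saturating", "linear"),
                "block": blocks,
                "progressing": np.isin(np.arange(f), prog_idx),
            },
            index=pd.Index(relabeled, name="feature"),
        ),
        config=cfg,
    )
    cohort = CohortTable(features=feat_long, metadata=metadata, n_visits=v)
    scores = ClinicalScoreTable(items=score_long)
    return cohort, scores, truth


def write_cohort(
    cohort: CohortTable,
    scores: ClinicalScoreTable,
    truth: SyntheticTruth | None,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a cohort (and optional truth) as CSV files plus a config sidecar.

    Round-trips losslessly through :func:`gaitprog.io.read_cohort` /
    :func:`gaitprog.io.read_scores`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": directory / "features.csv",
        "metadata": directory / "metadata.csv",
        "scores": directory / "scores.csv",
    }
    cohort.features.to_csv(paths["features"], index=False)
    cohort.metadata.to_csv(paths["metadata"])
    scores.items.to_csv(paths["scores"], index=False)
    if truth is not None:
        paths["truth_severity"] = directory / "truth_severity.csv"
        paths["truth_features"] = directory / "truth_features.csv"
        truth.severity.to_csv(paths["truth_severity"])
        truth.loadings.to_csv(paths["truth_features"])
        paths["config"] = directory / "config.json"
        with open(paths["config"], "w") as fh:
            json.dump(truth.config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    manifest = {"n_visits": cohort.n_visits}
    paths["cohort_info"] = directory / "cohort_info.json"
    with open(paths["cohort_info"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
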