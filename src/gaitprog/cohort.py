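"""In-memory containers for longitudinal cohort data.

The canonical on-disk representation is long format (one row per
participant-visit-feature value); wide matrices are in-memory views built by
the preprocessing stage. Visits are 1-based integers matching the V1..V7
labelling of the study schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ["participant_id", "visit", "feature", "value"]
SCORE_COLUMNS = ["participant_id", "visit", "item_id", "item_value"]

#: ordinal bounds of a single clinician-rated motor item
ITEM_MIN, ITEM_MAX = 0, 4


class CohortValidationError(ValueError):
    """A table violates a structural invariant (duplicate keys, bad bounds, ...)."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{what} is missing columns {missing}")


@dataclass
class CohortTable:
    """Long-format kinematic feature table plus participant metadata.

    Parameters
    ----------
    features : DataFrame with columns participant_id, visit, feature, value.
    metadata : DataFrame indexed by participant_id with at least height_m
        (metres, > 0) and onset_side ("left"/"right").
    n_visits : planned number of visits in the schedule (visits are 1..n_visits).
    """

    features: pd.DataFrame
    metadata: pd.DataFrame
    n_visits: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.features, FEATURE_COLUMNS, "feature table")
        feats = self.features
        if len(feats):
            if not np.issubdtype(np.asarray(feats["value"]).dtype, np.number):
                bad = feats[pd.to_numeric(feats["value"], errors="coerce").isna()]
                raise CohortValidationError(
                    f"non-numeric feature values at rows {list(bad.index[:10])}"
                )
            dup = feats.duplicated(subset=["participant_id", "visit", "feature"])
            if dup.any():
                keys = feats.loc[dup, ["participant_id", "visit", "feature"]].head(10)
                raise CohortValidationError(
                    "duplicate (participant, visit, feature) keys: "
                    + "; ".join(map(str, keys.itertuples(index=False, name=None)))
                )
            visits = feats["visit"].to_numpy()
            if visits.min() < 1 or visits.max() > self.n_visits:
                raise CohortValidationError(
                    f"visit indices must lie in 1..{self.n_visits}; "
                    f"saw [{visits.min()}, {visits.max()}]"
                )
            participants = set(feats["participant_id"])
            known = set(self.metadata.index)
            orphans = sorted(participants - known)
            if orphans:
                raise CohortValidationError(f"participants without metadata: {orphans}")

    @property
    def participants(self) -> list:
        return list(self.metadata.index)

    def observed_visits(self) -> pd.Series:
        """Sorted unique visit list per participant (participants with data)."""
        return self.features.groupby("participant_id")["visit"].agg(
            lambda v: sorted(set(v))
        )

    def to_wide(self) -> pd.DataFrame:
        """Pivot to a (participant, visit) x feature matrix; absent visits absent."""
        return self.features.pivot_table(
            index=["participant_id", "visit"],
            columns="feature",
            values="value",
            aggfunc="first",
        ).rename_axis(columns=None)


@dataclass
class ClinicalScoreTable:
    """Per-item clinician scores, optionally with derived aggregate columns.

    ``derived`` is filled by preprocessing: one row per participant-visit with
    total_motor_score (sum of all items except the speech and facial-expression
    items) and gait_posture_aggregate (sum of the gait, freezing-of-gait,
    postural-stability and posture items).
    """

    items: pd.DataFrame
    derived: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.items, SCORE_COLUMNS, "clinical score table")
        items = self.items
        if not len(items):
            return
        vals = pd.to_numeric(items["item_value"], errors="coerce")
        if vals.isna().any():
            raise CohortValidationError(
                f"non-numeric item values at rows {list(items.index[vals.isna()][:10])}"
            )
        if (vals != vals.round()).any():
            raise CohortValidationError("item values must be integers")
        out = items[(vals < ITEM_MIN) | (vals > ITEM_MAX)]
        if len(out):
            keys = out[["participant_id", "visit", "item_id", "item_value"]]
            raise CohortValidationError(
                f"item values outside the ordinal range {ITEM_MIN}..{ITEM_MAX}: "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )
        dup = items.duplicated(subset=["participant_id", "visit", "item_id"])
        if dup.any():
            keys = items.loc[dup, ["participant_id", "visit", "item_id"]].head(10)
            raise CohortValidationError(
                "duplicate (participant, visit, item) keys: "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )


@dataclass
class PreprocessedCohort:
    """Complete wide cohort after exclusion, imputation and normalisation.

    values : (participant_id, visit)-indexed matrix of feature values, no NaN.
    imputed : same-shaped boolean mask flagging cells filled by interpolation.
    scores : (participant_id, visit)-indexed clinical totals
        (total_motor_score, gait_posture_aggregate) plus an imputed flag.
    metadata : per-participant metadata (height_m, onset_side, ...).
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    scores: pd.DataFrame
    metadata: pd.DataFrame
    n_visits: int
    stride_normalized: bool = False  # guards against double height division

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise CohortValidationError("preprocessed cohort contains missing values")
        if self.values.shape != self.imputed.shape:
            raise CohortValidationError("imputed mask shape mismatch")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def score_matrix(self, column: str = "total_motor_score") -> pd.DataFrame:
        """Participants x visits matrix of one clinical score."""
        return self.scores[column].unstack("visit")
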