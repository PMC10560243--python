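"""Cohort construction rules: exclusion, imputation, score assembly, normalisation.

The order of operations mirrors the study protocol: participants with long
gaps are excluded, remaining missed visits are filled by linear interpolation
between the neighbouring observed visits, clinical totals are assembled from
the per-item scores, stride-length features are height-normalised, and
side-specific features are relabelled relative to the side of symptom onset.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from gaitprog.cohort import (
    ClinicalScoreTable,
    CohortTable,
    CohortValidationError,
    PreprocessedCohort,
)

#: items excluded from the total motor score (speech, facial expression)
OMITTED_FROM_TOTAL = frozenset({"3.1", "3.2"})
#: items forming the gait & posture aggregate (gait, freezing of gait,
#: postural stability, posture)
GAIT_POSTURE_ITEMS = frozenset({"3.10", "3.11", "3.12", "3.13"})
#: feature-name pattern marking stride-length features for height normalisation
STRIDE_PATTERN = r"StrideLength"

_SIDE_TOKENS = {"Left": "Ipsilateral", "Right": "Contralateral"}


def longest_missing_run(observed: set[int], n_visits: int) -> int:
    """Length of the longest run of consecutive missed visits in 1..n_visits."""
    longest = run = 0
    for v in range(1, n_visits + 1):
        if v in observed:
            run = 0
        else:
            run += 1
            longest = max(longest, run)
    return longest


def exclude_participants(
    cohort: CohortTable, max_consecutive_missing: int = 2
) -> tuple[CohortTable, pd.DataFrame]:
    """Drop participants with more than ``max_consecutive_missing`` consecutive missed visits.

    Returns the retained cohort and an exclusion log with one row per
    participant (longest_missing_run, excluded flag).
    """
    observed = cohort.observed_visits()
    rows = []
    for pid in cohort.participants:
        seen = set(observed.get(pid, []))
        run = longest_missing_run(seen, cohort.n_visits)
        rows.append((pid, len(seen), run, run > max_consecutive_missing))
    log = pd.DataFrame(
        rows, columns=["participant_id", "n_observed", "longest_missing_run", "excluded"]
    ).set_index("participant_id")
    keep = log.index[~log["excluded"]]
    retained = CohortTable(
        features=cohort.features[
            cohort.features["participant_id"].isin(keep)
        ].reset_index(drop=True),
        metadata=cohort.metadata.loc[cohort.metadata.index.isin(keep)],
        n_visits=cohort.n_visits,
    )
    return retained, log


def _full_grid(participants, n_visits: int) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [participants, range(1, n_visits + 1)], names=["participant_id", "visit"]
    )


def _interpolate_frame(frame: pd.DataFrame, n_visits: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing (participant, visit) rows of a wide frame.

    Interior gaps: linear interpolation on the visit index between the nearest
    earlier and later observed visits. Edge gaps (no bracketing pair): nearest
    observation carried back/forward. Returns (filled, imputed-mask).
    """
    participants = frame.index.get_level_values("participant_id").unique()
    full = frame.reindex(_full_grid(participants, n_visits))
    mask = full.isna()

    def per_participant(g: pd.DataFrame) -> pd.DataFrame:
        g = g.droplevel("participant_id")
        g.index = g.index.astype(float)  # visit index drives the interpolation
        filled = g.interpolate(method="index", limit_area="inside")
        return filled.ffill().bfill()

    filled = full.groupby(level="participant_id", group_keys=False, sort=False).apply(
        per_participant
    )
    filled.index = full.index
    return filled, mask


def impute_missing(
    cohort: CohortTable,
    scores: ClinicalScoreTable | None = None,
    impute_scores: bool = True,
) -> PreprocessedCohort:
    """Build the complete wide cohort, filling missed visits by interpolation.

    Every participant must have at least two observed visits. If ``scores``
    (with derived totals, see :func:`assemble_scores`) is given, clinical
    totals for missed visits are interpolated the same way when
    ``impute_scores`` is true, otherwise carried as NaN rows are dropped from
    the score table (the visit stays imputed on the feature side).
    """
    observed = cohort.observed_visits()
    too_few = [pid for pid in cohort.participants if len(observed.get(pid, [])) < 2]
    if too_few:
        raise CohortValidationError(
            f"participants with fewer than 2 observed visits: {too_few}"
        )
    wide = cohort.to_wide()
    filled, mask = _interpolate_frame(wide, cohort.n_visits)

    if scores is not None:
        derived = scores.derived
        if derived is None:
            scores = assemble_scores(scores)
            derived = scores.derived
        totals = derived.set_index(["participant_id", "visit"])[
            ["total_motor_score", "gait_posture_aggregate"]
        ]
        totals = totals[totals.index.get_level_values("participant_id").isin(
            cohort.metadata.index
        )]
        if impute_scores:
            score_filled, score_mask = _interpolate_frame(totals, cohort.n_visits)
            score_df = score_filled
            score_df["imputed"] = score_mask.any(axis=1)
        else:
            score_df = totals.copy()
            score_df["imputed"] = False
    else:
        score_df = pd.DataFrame(
            columns=["total_motor_score", "gait_posture_aggregate", "imputed"],
            index=filled.index[:0],
        )

    pre = PreprocessedCohort(
        values=filled,
        imputed=mask,
        scores=score_df,
        metadata=cohort.metadata,
        n_visits=cohort.n_visits,
    )
    pre.validate()
    return pre


def assemble_scores(scores: ClinicalScoreTable) -> ClinicalScoreTable:
    """Fill the derived totals: total motor score and gait & posture aggregate.

    The total sums every item except the speech and facial-expression items;
    the aggregate sums the gait, freezing-of-gait, postural-stability and
    posture items. Every participant-visit must rate the same item set.
    """
    items = scores.items
    wide = items.pivot_table(
        index=["participant_id", "visit"],
        columns="item_id",
        values="item_value",
        aggfunc="first",
    )
    holes = wide.isna()
    if holes.any().any():
        where = [
            (pid, visit, item)
            for (pid, visit), row in holes.iterrows()
            for item in wide.columns[row]
        ][:10]
        raise CohortValidationError(f"missing item scores at {where}")
    retained = [c for c in wide.columns if c not in OMITTED_FROM_TOTAL]
    gait_cols = [c for c in wide.columns if c in GAIT_POSTURE_ITEMS]
    derived = pd.DataFrame(
        {
            "total_motor_score": wide[retained].sum(axis=1),
            "gait_posture_aggregate": wide[gait_cols].sum(axis=1),
        }
    ).reset_index()
    return ClinicalScoreTable(items=items, derived=derived)


def normalize_and_lateralize(
    pre: PreprocessedCohort, stride_pattern: str = STRIDE_PATTERN
) -> PreprocessedCohort:
    """Height-normalise stride-length features and relabel sides by symptom onset.

    Stride-length features (matched by ``stride_pattern``) are divided by the
    participant's height in metres, making them dimensionless. Features whose
    name starts with a Left/Right token are renamed Ipsilateral (side of
    symptom onset) or Contralateral. Idempotent: already-relabelled names are
    left untouched.
    """
    values = pre.values.copy()
    meta = pre.metadata
    pat = re.compile(stride_pattern)
    lateral_cols = [c for c in values.columns if c.split("_", 1)[0] in _SIDE_TOKENS]

    stride_cols = [] if pre.stride_normalized else [
        c for c in values.columns if pat.search(c)
    ]
    if stride_cols:
        missing = [
            pid
            for pid in values.index.get_level_values("participant_id").unique()
            if pid not in meta.index or not (meta.loc[pid].get("height_m", np.nan) > 0)
        ]
        if missing:
            raise CohortValidationError(f"missing height for participants {missing}")
        heights = meta["height_m"].reindex(
            values.index.get_level_values("participant_id")
        )
        values[stride_cols] = values[stride_cols].div(heights.to_numpy(), axis=0)

    imputed = pre.imputed.copy()
    if lateral_cols:
        sides = meta.get("onset_side")
        if sides is None or sides.isna().any() or not sides.isin(["left", "right"]).all():
            bad = (
                list(meta.index[~meta.get("onset_side", pd.Series(dtype=object)).isin(["left", "right"])])
                if sides is not None
                else list(meta.index)
            )
            raise CohortValidationError(f"missing or invalid onset side for {bad}")

        def rename_map(onset: str) -> dict[str, str]:
            # the onset side becomes Ipsilateral
            first = {"left": "Left", "right": "Right"}[onset]
            out = {}
            for c in lateral_cols:
                tok, rest = c.split("_", 1)
                label = "Ipsilateral" if tok == first else "Contralateral"
                out[c] = f"{label}_{rest}"
            return out

        def relabel(frame: pd.DataFrame) -> pd.DataFrame:
            pieces = []
            for onset, grp in frame.groupby(
                sides.reindex(frame.index.get_level_values("participant_id")).to_numpy()
            ):
                pieces.append(grp.rename(columns=rename_map(onset)))
            out = pd.concat(pieces).sort_index()
            return out[sorted(out.columns)]

        values = relabel(values)
        imputed = relabel(imputed)
    else:
        values = values[sorted(values.columns)]
        imputed = imputed[sorted(imputed.columns)]

    return PreprocessedCohort(
        values=values,
        imputed=imputed,
        scores=pre.scores,
        metadata=pre.metadata,
        n_visits=pre.n_visits,
        stride_normalized=True,
    )


def preprocess(
    cohort: CohortTable,
    scores: ClinicalScoreTable,
    max_consecutive_missing: int = 2,
    impute_scores: bool = True,
    stride_pattern: str = STRIDE_PATTERN,
) -> tuple[PreprocessedCohort, pd.DataFrame]:
    """Run the full preprocessing chain; returns the cohort and the exclusion log."""
    retained, log = exclude_participants(cohort, max_consecutive_missing)
    assembled = assemble_scores(scores)
    pre = impute_missing(retained, assembled, impute_scores=impute_scores)
    pre = normalize_and_lateralize(pre, stride_pattern=stride_pattern)
    return pre, log
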