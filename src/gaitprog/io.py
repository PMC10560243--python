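"""Readers and writers for cohort tables, score tables and JSON reports."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from gaitprog.cohort import (
    ClinicalScoreTable,
    CohortTable,
    CohortValidationError,
    FEATURE_COLUMNS,
    SCORE_COLUMNS,
)

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("gaitprog")


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


def _read_csv(
    path: str | Path, columns: list[str], what: str, dtype: dict | None = None
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, dtype=dtype)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{what} {path} is missing columns {missing}")
    return df


def read_cohort(
    features_path: str | Path,
    metadata_path: str | Path,
    n_visits: int | None = None,
) -> CohortTable:
    """Read a long-format feature CSV plus a metadata CSV into a CohortTable.

    ``n_visits`` defaults to the largest visit index present; pass it
    explicitly when trailing visits may be entirely missing. Non-numeric
    values are reported with their 1-based data-row numbers.
    """
    feats = _read_csv(features_path, FEATURE_COLUMNS, "feature")
    numeric = pd.to_numeric(feats["value"], errors="coerce")
    bad = feats.index[numeric.isna() & feats["value"].notna()]
    if len(bad):
        rows = [int(i) + 2 for i in bad[:10]]  # +2: header line + 1-based
        raise CohortValidationError(
            f"non-numeric feature values in {features_path} at lines {rows}"
        )
    feats["value"] = numeric
    feats = feats.dropna(subset=["value"]).reset_index(drop=True)
    meta = _read_csv(metadata_path, ["participant_id"], "metadata").set_index(
        "participant_id"
    )
    if "height_m" in meta.columns:
        heights = pd.to_numeric(meta["height_m"], errors="coerce")
        nonpos = meta.index[~(heights > 0)]
        if len(nonpos):
            raise CohortValidationError(
                f"non-positive or missing heights for participants {list(nonpos)}"
            )
    if n_visits is None:
        info = Path(features_path).parent / "cohort_info.json"
        if info.exists():
            with open(info) as fh:
                n_visits = json.load(fh).get("n_visits")
    if n_visits is None:
        n_visits = int(feats["visit"].max()) if len(feats) else 0
    return CohortTable(features=feats, metadata=meta, n_visits=int(n_visits))


def read_scores(path: str | Path) -> ClinicalScoreTable:
    """Read a per-item clinical score CSV (validated on construction)."""
    # item ids like "3.10" must stay strings ("3.1" != "3.10")
    items = _read_csv(path, SCORE_COLUMNS, "clinical score", dtype={"item_id": str})
    return ClinicalScoreTable(items=items)


def read_cohort_dir(directory: str | Path) -> tuple[CohortTable, ClinicalScoreTable]:
    """Read the features/metadata/scores file set written by ``write_cohort``."""
    directory = Path(directory)
    cohort = read_cohort(directory / "features.csv", directory / "metadata.csv")
    scores = read_scores(directory / "scores.csv")
    return cohort, scores


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize an analysis report as deterministic JSON with a schema tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return path


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) pipeline configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
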