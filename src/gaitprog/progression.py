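"""Nonparametric detection of progression in a per-participant score series.

The procedure mirrors standard repeated-measures practice for ordinal or
non-normal scores: per-visit normality check (Shapiro-Wilk), an omnibus
Friedman test across visits, Wilcoxon signed-rank comparisons of every visit
against baseline, and Benjamini-Hochberg control of the false discovery rate
across those pairwise comparisons. Per-visit medians and interquartile
ranges summarise central tendency and noise; the median rate of change is
the OLS slope of the per-visit group medians on visit index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gaitprog.selection import trend_test


@dataclass
class ScoreSeries:
    """Complete participants x visits matrix of one score type."""

    matrix: pd.DataFrame  # index participant, columns visit (1..V)
    label: str = "score"

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError(f"score series {self.label!r} has missing cells")
        self.matrix = self.matrix[sorted(self.matrix.columns)]

    @classmethod
    def from_long(cls, scores: pd.DataFrame, column: str, label: str | None = None) -> "ScoreSeries":
        """Build from a (participant_id, visit)-indexed frame of totals."""
        return cls(matrix=scores[column].unstack("visit"), label=label or column)

    @property
    def visits(self) -> list[int]:
        return [int(v) for v in self.matrix.columns]


def shapiro_wilk(sample) -> float:
    """Shapiro-Wilk p-value for the normality null (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def friedman_test(series: ScoreSeries) -> tuple[float, float]:
    """Friedman omnibus test for a visit effect on within-participant ranks.

    Mid-ranks for ties; the statistic is asymptotically chi-squared with
    (visits - 1) degrees of freedom.
    """
    m = series.matrix
    if m.shape[1] < 2 or m.shape[0] < 2:
        raise ValueError("Friedman test needs >= 2 visits and >= 2 participants")
    if m.to_numpy().std(axis=1).max() == 0:
        return 0.0, 1.0  # no within-participant variation anywhere
    stat, p = stats.friedmanchisquare(*[m[c].to_numpy() for c in m.columns])
    return float(stat), float(p)


def wilcoxon_vs_baseline(series: ScoreSeries) -> pd.DataFrame:
    """Wilcoxon signed-rank test of every visit against the first visit.

    Zero differences are dropped (Wilcoxon's original policy). The exact null
    distribution is used for n <= 25 untied differences; otherwise the normal
    approximation with tie correction. All-zero differences give p = 1 with a
    warning rather than an error.
    """
    m = series.matrix
    visits = series.visits
    base = m[visits[0]].to_numpy(dtype=float)
    rows = []
    for v in visits[1:]:
        d = m[v].to_numpy(dtype=float) - base
        nz = d[d != 0]
        if len(nz) == 0:
            warnings.warn(
                f"all differences zero for visit {v} vs baseline; p set to 1",
                stacklevel=2,
            )
            rows.append((v, 0.0, 1.0))
            continue
        ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not ties) else "approx"
        res = stats.wilcoxon(
            nz, zero_method="wilcox", alternative="two-sided", method=method
        )
        rows.append((v, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["visit", "statistic", "p_raw"]).set_index("visit")


def benjamini_hochberg(p_values, fdr: float = 0.01) -> np.ndarray:
    """Step-up false-discovery-rate flags, in the input order.

    Sort ascending, find the largest i with p_(i) <= (i/m) * fdr, flag all
    hypotheses with rank <= i.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    flags = np.zeros(m, dtype=bool)
    if m == 0:
        return flags
    order = np.argsort(p, kind="mergesort")
    thresh = (np.arange(1, m + 1) / m) * fdr
    passing = np.nonzero(p[order] <= thresh)[0]
    if len(passing):
        flags[order[: passing[-1] + 1]] = True
    return flags


@dataclass
class ProgressionReport:
    """All progression statistics for one score series."""

    label: str
    medians: pd.Series          # per visit
    iqrs: pd.Series             # per visit, 75th - 25th percentile
    shapiro_p: pd.Series        # per visit
    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame      # visit-indexed: statistic, p_raw, significant (BH)
    fdr: float
    rate_of_change: float       # OLS slope of per-visit medians on visit index

    @property
    def earliest_significant_visit(self) -> int | None:
        flagged = self.pairwise.index[self.pairwise["significant"]]
        return int(flagged.min()) if len(flagged) else None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "medians": {int(k): float(v) for k, v in self.medians.items()},
            "iqrs": {int(k): float(v) for k, v in self.iqrs.items()},
            "shapiro_p": {int(k): float(v) for k, v in self.shapiro_p.items()},
            "friedman_statistic": self.friedman_statistic,
            "friedman_p": self.friedman_p,
            "pairwise": {
                int(v): {
                    "statistic": float(r["statistic"]),
                    "p_raw": float(r["p_raw"]),
                    "significant": bool(r["significant"]),
                }
                for v, r in self.pairwise.iterrows()
            },
            "fdr": self.fdr,
            "rate_of_change": self.rate_of_change,
            "earliest_significant_visit": self.earliest_significant_visit,
        }


def progression_report(series: ScoreSeries, fdr: float = 0.01) -> ProgressionReport:
    """Assemble the full per-series progression analysis."""
    m = series.matrix
    visits = series.visits
    medians = m.median(axis=0)
    iqrs = m.quantile(0.75, axis=0) - m.quantile(0.25, axis=0)
    shapiro_p = pd.Series(
        {
            v: (shapiro_wilk(m[v]) if np.ptp(m[v].to_numpy()) > 0 else np.nan)
            for v in visits
        }
    )
    fr_stat, fr_p = friedman_test(series)
    pairwise = wilcoxon_vs_baseline(series)
    pairwise["significant"] = benjamini_hochberg(pairwise["p_raw"].to_numpy(), fdr=fdr)
    slope, _ = trend_test(medians.to_numpy(), np.asarray(visits, dtype=float))
    return ProgressionReport(
        label=series.label,
        medians=medians,
        iqrs=iqrs,
        shapiro_p=shapiro_p,
        friedman_statistic=fr_stat,
        friedman_p=fr_p,
        pairwise=pairwise,
        fdr=fdr,
        rate_of_change=float(slope),
    )


def compare_reports(observed: ProgressionReport, estimated: ProgressionReport) -> dict:
    """Contrast two series: detection latency and per-visit noise ratio."""
    iqr_ratio = (estimated.iqrs / observed.iqrs).replace([np.inf, -np.inf], np.nan)
    return {
        "observed_label": observed.label,
        "estimated_label": estimated.label,
        "observed_earliest_significant_visit": observed.earliest_significant_visit,
        "estimated_earliest_significant_visit": estimated.earliest_significant_visit,
        "iqr_ratio_per_visit": {int(k): float(v) for k, v in iqr_ratio.items()},
        "estimated_iqr_smaller_at_every_visit": bool(
            (estimated.iqrs.to_numpy() < observed.iqrs.to_numpy()).all()
        ),
    }
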