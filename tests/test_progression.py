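"""Repeated-measures statistics: oracles, degenerate cases, report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gaitprog.progression import (
    ProgressionReport,
    ScoreSeries,
    benjamini_hochberg,
    compare_reports,
    friedman_test,
    progression_report,
    shapiro_wilk,
    wilcoxon_vs_baseline,
)


def series(matrix, label="s"):
    m = np.asarray(matrix, dtype=float)
    return ScoreSeries(
        matrix=pd.DataFrame(
            m,
            index=pd.Index([f"p{i}" for i in range(m.shape[0])], name="participant_id"),
            columns=pd.Index(range(1, m.shape[1] + 1), name="visit"),
        ),
        label=label,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def friedman_bruteforce(matrix: np.ndarray) -> float:
    """Mid-rank Friedman chi-square with tie correction, from first principles."""
    n, k = matrix.shape
    ranks = np.array([stats.rankdata(row) for row in matrix])  # mid-ranks
    col_sums = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction as used by standard references
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    return chi / correction if correction > 0 else 0.0


def friedman_permutation_p(matrix: np.ndarray) -> float:
    """Exact permutation p-value over all within-row orderings."""
    n, k = matrix.shape
    observed = friedman_bruteforce(matrix)
    count = total = 0
    for perms in itertools.product(itertools.permutations(range(k)), repeat=n):
        permuted = np.array([matrix[i, list(p)] for i, p in enumerate(perms)])
        total += 1
        if friedman_bruteforce(permuted) >= observed - 1e-12:
            count += 1
    return count / total


def wilcoxon_sign_enumeration_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    total = w_plus_dist = 0
    stats_all = []
    for signs in itertools.product([0, 1], repeat=n):
        stats_all.append(ranks[np.array(signs, dtype=bool)].sum())
    stats_all = np.array(stats_all)
    mean = ranks.sum() / 2
    obs_dev = abs(w_plus - mean)
    return float(np.mean(np.abs(stats_all - mean) >= obs_dev - 1e-12))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestShapiro:
    def test_bounds(self):
        with pytest.raises(ValueError, match="3 <= n"):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_error(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([2.0] * 10)

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=74)) < 0.01 for _ in range(50)
        )
        assert rejections >= 49  # power ~1 for exponential data at n=74

    def test_gaussian_rejection_rate_calibrated(self):
        """Under Gaussian data the test rejects at its nominal level."""
        rng = np.random.default_rng(1)
        n = 400
        rejections = sum(shapiro_wilk(rng.normal(size=74)) < 0.05 for _ in range(n))
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rejections / n - 0.05) <= half_width


class TestFriedman:
    def test_identical_rows_no_effect(self):
        s = series([[3, 3, 3], [5, 5, 5], [1, 1, 1]])
        stat, p = friedman_test(s)
        assert stat == 0.0
        assert p == 1.0

    @pytest.mark.parametrize(
        "matrix",
        [
            [[1, 2, 3], [2, 3, 1], [3, 1, 2]],
            [[1.2, 2.4, 0.5], [0.1, 0.9, 2.2], [3.0, 2.0, 1.0]],
            [[1, 1, 2], [2, 2, 2], [3, 1, 1]],  # ties
            [[4, 2, 3, 1], [1, 2, 4, 3], [2, 1, 3, 4], [4, 3, 2, 1]],
        ],
    )
    def test_statistic_matches_bruteforce_ranks(self, matrix):
        m = np.array(matrix, dtype=float)
        stat, _ = friedman_test(series(m))
        assert stat == pytest.approx(friedman_bruteforce(m), rel=1e-9)

    def test_asymptotic_p_close_to_exact_permutation(self):
        m = np.array([[1.0, 2.0, 3.5], [2.0, 4.0, 3.0], [1.5, 3.0, 4.0], [1.0, 3.0, 2.0]])
        _, p_asym = friedman_test(series(m))
        p_exact = friedman_permutation_p(m)
        assert abs(p_asym - p_exact) < 0.15  # known small-sample bias of chi2

    def test_incomplete_matrix_error(self):
        s = series([[1, 2, 3], [2, 3, 4]])
        s.matrix.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(ScoreSeries(matrix=s.matrix.fillna(s.matrix), label="x"))
        with pytest.raises(ValueError, match="missing"):
            ScoreSeries(matrix=s.matrix.mask(s.matrix == 1), label="x")


class TestWilcoxon:
    def test_all_positive_diffs_exact(self):
        base = np.zeros(5)
        m = np.column_stack([base, base + [1, 2, 3, 4, 5]])
        out = wilcoxon_vs_baseline(series(m))
        assert out.loc[2, "p_raw"] == pytest.approx(0.0625)

    def test_all_zero_diffs_p_one_with_warning(self):
        m = np.tile([[2.0], [3.0]], (1, 3))
        with pytest.warns(UserWarning, match="zero"):
            out = wilcoxon_vs_baseline(series(m))
        assert (out["p_raw"] == 1.0).all()

    def test_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = rng.normal(0.4, 1.0, size=8)  # continuous: no tied magnitudes
            m = np.column_stack([np.zeros(len(d)), d])
            out = wilcoxon_vs_baseline(series(m))
            assert out.loc[2, "p_raw"] == pytest.approx(
                wilcoxon_sign_enumeration_p(d), abs=1e-9
            )

    def test_invariant_under_positive_affine_transform(self):
        """Rescaling the score scale leaves the rank statistic unchanged."""
        rng = np.random.default_rng(3)
        m = rng.normal(10, 2, size=(12, 3))
        out1 = wilcoxon_vs_baseline(series(m))
        out2 = wilcoxon_vs_baseline(series(3.5 * m + 40.0))
        np.testing.assert_allclose(out1["statistic"], out2["statistic"])
        np.testing.assert_allclose(out1["p_raw"], out2["p_raw"])

    def test_one_comparison_per_non_baseline_visit(self):
        m = np.random.default_rng(4).normal(size=(10, 7))
        out = wilcoxon_vs_baseline(series(m))
        assert list(out.index) == [2, 3, 4, 5, 6, 7]


class TestBenjaminiHochberg:
    def test_all_ones_no_flags(self):
        assert not benjamini_hochberg([1.0, 1.0, 1.0]).any()

    def test_stepup_hand_example(self):
        flags = benjamini_hochberg([0.001, 0.004, 0.2, 0.9], fdr=0.01)
        # 0.004 <= (2/4)*0.01 so ranks 1 and 2 flag
        assert flags.tolist() == [True, True, False, False]

    def test_single_hypothesis_reduces_to_threshold(self):
        assert benjamini_hochberg([0.009], fdr=0.01).tolist() == [True]
        assert benjamini_hochberg([0.011], fdr=0.01).tolist() == [False]

    def test_out_of_range_error(self):
        with pytest.raises(ValueError, match="0, 1"):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.integers(0, 11))
    def test_lowering_a_flagged_p_never_unflags(self, ps, which):
        flags = benjamini_hochberg(ps, fdr=0.05)
        which = which % len(ps)
        lowered = list(ps)
        lowered[which] = lowered[which] / 2
        flags2 = benjamini_hochberg(lowered, fdr=0.05)
        assert flags2.sum() >= flags.sum()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_statsmodels_stepup(self, ps):
        from statsmodels.stats.multitest import multipletests

        flags = benjamini_hochberg(ps, fdr=0.05)
        ref = multipletests(ps, alpha=0.05, method="fdr_bh")[0]
        assert flags.tolist() == ref.tolist()


class TestProgressionReport:
    def test_monotone_series_flags_every_visit(self):
        rng = np.random.default_rng(5)
        base = rng.normal(20, 5, size=30)
        m = np.column_stack([base + 2.0 * v for v in range(7)])
        rep = progression_report(series(m), fdr=0.01)
        assert rep.pairwise["significant"].all()
        assert rep.earliest_significant_visit == 2
        assert rep.rate_of_change == pytest.approx(2.0, abs=1e-9)

    def test_rate_of_change_slope_identity(self):
        # medians on an exact 0.33/visit line
        m = np.tile(0.33 * np.arange(1, 8), (9, 1))
        m += np.random.default_rng(6).normal(0, 1e-12, m.shape)
        rep = progression_report(series(m))
        assert rep.rate_of_change == pytest.approx(0.33, abs=1e-6)

    def test_iqr_definition(self):
        m = np.column_stack([np.arange(1, 10.0)] * 3)
        rep = progression_report(series(m))
        expected = np.percentile(np.arange(1, 10.0), 75) - np.percentile(
            np.arange(1, 10.0), 25
        )
        assert np.allclose(rep.iqrs.to_numpy(), expected)

    def test_report_invariant_under_participant_permutation(self):
        rng = np.random.default_rng(7)
        m = rng.normal(20, 6, size=(25, 7)) + 0.5 * np.arange(7)
        s1 = series(m)
        s2 = ScoreSeries(matrix=s1.matrix.sample(frac=1.0, random_state=8), label="s")
        r1, r2 = progression_report(s1), progression_report(s2)
        assert r1.friedman_statistic == pytest.approx(r2.friedman_statistic)
        pd.testing.assert_frame_equal(r1.pairwise, r2.pairwise)

    def test_compare_reports_contrast(self):
        rng = np.random.default_rng(9)
        base = rng.normal(20, 2, size=40)
        drift = np.arange(7) * 1.0
        tight = np.column_stack([base + d for d in drift])
        noisy = tight + rng.normal(0, 8, size=tight.shape)
        rep_e = progression_report(series(tight, "estimated"))
        rep_o = progression_report(series(noisy, "observed"))
        out = compare_reports(rep_o, rep_e)
        assert out["estimated_iqr_smaller_at_every_visit"]
        assert out["estimated_earliest_significant_visit"] == 2
        assert set(out["iqr_ratio_per_visit"]) == set(range(1, 8))
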