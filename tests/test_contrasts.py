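"""Per-bin contrasts: t-tests, effect sizes, CIs, onset/peak summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emgreact.contrasts import (
    bonferroni_threshold,
    cohens_d_paired,
    contrast_summary,
    contrast_table,
    cousineau_morey_ci,
    mean_difference_course,
    paired_t,
    printed_contrast_course,
    printed_mean_difference,
)


class TestPairedT:
    def test_identical_cells(self):
        x = np.array([100.0, 105.0, 98.0, 101.0])
        res = paired_t(x, x)
        assert res.t == 0.0 and res.p == 1.0 and res.mean_diff == 0.0

    def test_toy_pairs_match_textbook_formula(self):
        a = np.array([10.0, 12.0, 11.0, 14.0, 13.0])
        b = np.array([9.0, 10.0, 12.0, 11.0, 12.0])
        diff = a - b
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 4)
        res = paired_t(a, b)
        assert res.t == pytest.approx(t_oracle)
        assert res.p == pytest.approx(p_oracle)
        assert res.df == 4

    def test_pairwise_deletion(self):
        a = pd.Series([1.0, 2.0, np.nan, 4.0, 3.0], index=list("abcde"))
        b = pd.Series([1.5, 1.0, 2.0, np.nan, 2.5], index=list("abcde"))
        assert paired_t(a, b).n == 3

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            paired_t(np.array([1.0, 2.0]), np.array([2.0, 1.0]))

    def test_type_one_error_rate_under_null(self, rng):
        # 1,000 null datasets of 156 pairs; rejections at the
        # Bonferroni-adjusted level 0.003125 should stay in the binomial
        # 95% band around 1000 * 0.003125
        alpha = bonferroni_threshold(0.05, 16)
        reps, n = 1000, 156
        rejections = 0
        for _ in range(reps):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            rejections += paired_t(a, b).p < alpha
        lo = stats.binom.ppf(0.025, reps, alpha)
        hi = stats.binom.ppf(0.975, reps, alpha)
        assert lo <= rejections <= hi

    def test_antisymmetry(self, rng):
        a = 100 + rng.standard_normal(20)
        b = 100 + rng.standard_normal(20)
        ab, ba = paired_t(a, b), paired_t(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.p == pytest.approx(ba.p)


class TestCohensD:
    def test_identical_cells_zero_sd_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="zero SD"):
            cohens_d_paired(x, x)

    def test_unit_effect_by_construction(self):
        # shifting differences so mean(diff) == sd(diff) forces dz = 1
        diff = np.array([0.0, 1.0, 2.0, 3.0])
        shifted = diff + (diff.std(ddof=1) - diff.mean())
        res = cohens_d_paired(shifted, np.zeros(4))
        assert res.d == pytest.approx(1.0)

    def test_dav_variant_uses_average_condition_sd(self, rng):
        a = 10 + 2 * rng.standard_normal(50)
        b = 8 + 4 * rng.standard_normal(50)
        dav = cohens_d_paired(a, b, variant="dav")
        expected = (a - b).mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
        assert dav.d == pytest.approx(expected)
        with pytest.raises(ValueError, match="variant"):
            cohens_d_paired(a, b, variant="dx")

    def test_recovery_of_true_half_standardised_effect(self, rng):
        # 500 replicates at n = 156 with true dz = 0.5
        reps, n, true = 500, 156, 0.5
        ds = []
        for _ in range(reps):
            diff = rng.standard_normal(n) + true
            ds.append(cohens_d_paired(diff, np.zeros(n)).d)
        assert np.mean(ds) == pytest.approx(true, abs=0.05)

    def test_ci_contains_d_and_shrinks_with_n(self, rng):
        small = cohens_d_paired(rng.standard_normal(20) + 0.5, np.zeros(20))
        large = cohens_d_paired(rng.standard_normal(500) + 0.5, np.zeros(500))
        assert small.ci_low < small.d < small.ci_high
        assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 16, 0.003125), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _cells_from_matrix(values, muscle="corrugator", conditions=("a", "b", "c"), bin=1):
    """participants x conditions score matrix -> long cells frame."""
    rows = []
    for p, row in enumerate(np.atleast_2d(values), start=1):
        for cond, v in zip(conditions, row):
            rows.append({"participant": p, "condition": cond, "muscle": muscle,
                         "bin": bin, "score": float(v)})
    return pd.DataFrame(rows)


class TestCousineauMorey:
    def test_no_within_subject_variance_gives_zero_width(self):
        # every participant shows the same condition profile, offset by a
        # participant constant: normalisation removes all variance
        base = np.array([100.0, 90.0, 80.0])
        values = np.vstack([base + off for off in (0.0, 10.0, -5.0, 20.0)])
        widths = cousineau_morey_ci(_cells_from_matrix(values), "corrugator", 1, ("a", "b", "c"))
        assert all(abs(w) < 1e-9 for w in widths.values())

    def test_two_condition_toy_matches_hand_formula(self):
        values = np.array([[10.0, 11.0], [12.0, 15.0], [14.0, 13.0], [16.0, 19.0]])
        widths = cousineau_morey_ci(_cells_from_matrix(values, conditions=("a", "b")),
                                    "corrugator", 1, ("a", "b"))
        normalised = values - values.mean(axis=1, keepdims=True) + values.mean()
        expected = (
            stats.t.ppf(0.975, 3) * normalised.std(axis=0, ddof=1) / 2.0 * np.sqrt(2.0)
        )
        assert widths["a"] == pytest.approx(expected[0])
        assert widths["b"] == pytest.approx(expected[1])

    def test_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (20, 80, 320):
            values = rng.standard_normal((n, 3)) + rng.standard_normal((n, 1)) * 3
            w = cousineau_morey_ci(_cells_from_matrix(values), "corrugator", 1, ("a", "b", "c"))
            widths.append(np.mean(list(w.values())))
        assert widths[0] > widths[1] > widths[2]

    def test_single_condition_rejected(self, rng):
        values = rng.standard_normal((5, 1))
        with pytest.raises(ValueError, match=">= 2 conditions"):
            cousineau_morey_ci(_cells_from_matrix(values, conditions=("a",)), "corrugator", 1, ("a",))


class TestContrastTableAndSummary:
    def test_full_table_on_simulated_cells(self, full_cells):
        ct = contrast_table(full_cells, "transform", "no_regulation", "corrugator")
        assert len(ct) == 16
        assert ct["p"].between(0, 1).all()
        assert (ct["significant"] == (ct["p"] < 0.003125)).all()
        # Bonferroni flags are a subset of the unadjusted ones
        assert ct["significant"].sum() <= (ct["p"] < 0.05).sum()

    def test_antisymmetry_of_pair_order(self, full_cells):
        ab = contrast_table(full_cells, "transform", "neutralize", "zygomaticus")
        ba = contrast_table(full_cells, "neutralize", "transform", "zygomaticus")
        np.testing.assert_allclose(ab["mean_diff"], -ba["mean_diff"])
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-12)
        np.testing.assert_allclose(ab["d"], -ba["d"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)

    def test_no_significant_bins_summary(self):
        table = pd.DataFrame(
            {"bin": [1, 2], "time_ms": [500, 1000], "mean_diff": [0.5, -1.0],
             "d": [0.05, -0.1], "significant": [False, False]}
        )
        s = contrast_summary(table)
        assert s.first_significant_bin is None
        assert s.peak_bin == 2  # largest |d|

    @pytest.mark.parametrize(
        "pair,muscle,peak_ms,peak_diff",
        [
            (("neutralize", "no_regulation"), "corrugator", 3500, 7.2),
            (("neutralize", "no_regulation"), "zygomaticus", 7000, -32.3),
            (("transform", "no_regulation"), "corrugator", 6500, 23.6),
            (("transform", "no_regulation"), "zygomaticus", 4500, -34.1),
            (("transform", "neutralize"), "corrugator", 7500, 21.4),
        ],
    )
    def test_peaks_from_printed_fixtures(self, pair, muscle, peak_ms, peak_diff):
        s = contrast_summary(printed_contrast_course(pair, muscle))
        assert s.peak_ms == peak_ms
        assert s.peak_difference == pytest.approx(peak_diff)


class TestSimulatedGroupPattern:
    def test_condition_ordering_matches_published_pattern(self, full_cells):
        # simulated group means reproduce the published ordering: on the
        # zygomaticus, no-regulation stays above both regulation goals
        # (which track each other) from 1,500 ms on; on the corrugator the
        # transform goal rises above no-regulation
        means = full_cells.groupby(["muscle", "condition", "bin"])["score"].mean()
        for b in range(3, 17):
            noreg = means["zygomaticus", "no_regulation", b]
            neut = means["zygomaticus", "neutralize", b]
            trans = means["zygomaticus", "transform", b]
            assert noreg > neut and noreg > trans
            assert abs(neut - trans) < 0.5 * (noreg - min(neut, trans))
        for b in range(5, 17):
            assert (
                means["corrugator", "transform", b]
                > means["corrugator", "no_regulation", b]
            )


class TestPrintedDifferences:
    @pytest.mark.parametrize(
        "pair,muscle,time_ms,expected",
        [
            (("neutralize", "no_regulation"), "corrugator", 2500, 6.1),
            (("neutralize", "no_regulation"), "corrugator", 3500, 7.2),
            (("neutralize", "no_regulation"), "zygomaticus", 1000, -12.0),
            (("neutralize", "no_regulation"), "zygomaticus", 7000, -32.3),
            (("transform", "no_regulation"), "corrugator", 6500, 23.6),
            (("transform", "no_regulation"), "zygomaticus", 1500, -22.2),
            (("transform", "no_regulation"), "zygomaticus", 4500, -34.1),
            (("transform", "neutralize"), "corrugator", 2500, 7.7),
            (("transform", "neutralize"), "corrugator", 7500, 21.4),
        ],
    )
    def test_in_text_magnitudes(self, pair, muscle, time_ms, expected):
        assert printed_mean_difference(pair, muscle, time_ms) == pytest.approx(expected)

    def test_unknown_bin_rejected(self):
        with pytest.raises(KeyError):
            printed_mean_difference(("transform", "neutralize"), "corrugator", 250)

    def test_course_covers_all_bins(self):
        course = mean_difference_course(("transform", "no_regulation"), "corrugator")
        assert len(course) == 16
        assert course.loc[6500] == pytest.approx(23.6)
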