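"""Statistics engine: paired tests, adjustment, Spearman, KDE, ROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spaudit import (
    EvalConfig,
    EvaluationReport,
    adjust_pvalues,
    evaluate_all,
    kde_curve,
    operating_point_at_fpr,
    operating_point_at_threshold,
    paired_t_test,
    roc_points,
    spearman_correlation,
)


def concordance_auc(pos, neg):
    """Brute-force oracle: P(random positive outscores random negative),
    ties counted one half."""
    pos, neg = np.asarray(pos), np.asarray(neg)
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * equal) / (pos.size * neg.size)


class TestPairedT:
    def test_worked_example_matches_closed_form(self):
        # d = modified - original = [-0.1, -0.2, -0.1]
        original, modified = [0.5, 0.6, 0.7], [0.4, 0.4, 0.6]
        mean_diff, t, df, p, flags = paired_t_test(original, modified)
        d = np.array(modified) - np.array(original)
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert t == pytest.approx(t_oracle) and abs(t) == pytest.approx(4.0)
        assert df == 2 and mean_diff == pytest.approx(-0.4 / 3)
        assert p == pytest.approx(0.0572, abs=2e-4)
        assert not flags

    def test_identical_vectors_degenerate_p_one(self):
        mean_diff, t, df, p, flags = paired_t_test([0.2, 0.4], [0.2, 0.4])
        assert (mean_diff, t, p) == (0.0, 0.0, 1.0) and flags

    def test_constant_nonzero_difference_p_zero(self):
        mean_diff, t, df, p, flags = paired_t_test([0.2, 0.4], [0.3, 0.5])
        assert p == 0.0 and t == math.inf and flags

    def test_swapping_vectors_negates_t_and_mean(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(20), rng.random(20)
        m1, t1, _, p1, _ = paired_t_test(a, b)
        m2, t2, _, p2, _ = paired_t_test(b, a)
        assert m1 == pytest.approx(-m2) and t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_t_test([0.1, 0.2], [0.1])


class TestAdjustment:
    def test_bonferroni_examples(self):
        assert adjust_pvalues([0.002, 0.03]) == pytest.approx([0.004, 0.06])
        assert adjust_pvalues([0.02]) == pytest.approx([0.02])
        assert adjust_pvalues([0.9, 0.9, 0.9]) == pytest.approx([1, 1, 1])

    def test_holm_is_never_more_conservative_than_bonferroni(self):
        p = [0.001, 0.02, 0.04, 0.3]
        assert (adjust_pvalues(p, "holm") <= adjust_pvalues(p, "bonferroni") + 1e-15).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_at_least_raw(self, p):
        adjusted = adjust_pvalues(p)
        assert (adjusted >= np.asarray(p) - 1e-15).all()
        assert (adjusted <= 1.0).all()

    def test_significance_monotone_in_raw_p(self):
        p = np.array([0.0005, 0.002, 0.004, 0.008, 0.9])
        base = adjust_pvalues(p) <= 0.01
        lowered = p.copy()
        lowered[1] /= 10
        after = adjust_pvalues(lowered) <= 0.01
        assert not np.any(base & ~after)


class TestSpearman:
    def test_monotone_relations(self):
        x = [0.1, 0.4, 0.2, 0.9]
        assert spearman_correlation(x, x)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_worked_rank_example(self):
        # rank-formula oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)), sum(d^2)=2
        rho, n, flags = spearman_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(1 - 6 * 2 / (4 * 15)) == pytest.approx(0.8)

    def test_constant_vector_flagged_not_raised(self):
        rho, n, flags = spearman_correlation([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and flags == ["constant_input"]


class TestKDE:
    def test_constant_scores_peak_at_the_value(self):
        curve = kde_curve([0.5] * 10, bandwidth=0.05)
        grid = np.array(curve.grid)
        density = np.array(curve.density)
        assert abs(grid[density.argmax()] - 0.5) < 0.01
        # symmetry about 0.5
        assert density[np.abs(grid - 0.4).argmin()] == pytest.approx(
            density[np.abs(grid - 0.6).argmin()], rel=0.05
        )

    def test_duplicating_the_sample_leaves_the_curve_unchanged(self):
        scores = [0.2, 0.5, 0.8, 0.3]
        a = kde_curve(scores, bandwidth=0.1)
        b = kde_curve(scores * 2, bandwidth=0.1)
        assert np.allclose(a.density, b.density)

    def test_two_separated_clusters_give_two_modes(self):
        scores = [0.1, 0.12, 0.11, 0.9, 0.88, 0.91]
        curve = kde_curve(scores, bandwidth=0.04)
        grid, density = np.array(curve.grid), np.array(curve.density)
        # direct kernel-sum oracle at each grid point
        h = curve.bandwidth
        oracle = np.mean(
            [np.exp(-0.5 * ((grid - s) / h) ** 2) / (h * math.sqrt(2 * math.pi))
             for s in scores],
            axis=0,
        )
        assert np.allclose(density, oracle, atol=1e-12)
        assert density[np.abs(grid - 0.11).argmin()] > density[np.abs(grid - 0.5).argmin()]
        assert density[np.abs(grid - 0.9).argmin()] > density[np.abs(grid - 0.5).argmin()]

    def test_integrates_to_one_over_the_extended_grid(self):
        rng = np.random.default_rng(1)
        curve = kde_curve(rng.random(50))
        integral = np.trapezoid(curve.density, curve.grid)
        assert abs(integral - 1.0) < 0.02

    def test_matches_scipy_gaussian_kde_with_scott_rule(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        curve = kde_curve(scores)
        oracle = stats.gaussian_kde(scores)(np.array(curve.grid))
        assert np.allclose(curve.density, oracle, atol=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            kde_curve([0.5])
        with pytest.raises(ValueError, match="bandwidth"):
            kde_curve([0.5, 0.5, 0.5])  # constant, no explicit bandwidth


class TestROC:
    def test_perfect_separation(self):
        roc = roc_points([0.9, 0.8], [0.7, 0.1])
        assert roc.auc == pytest.approx(1.0)

    def test_worked_example_three_of_four_pairs_concordant(self):
        roc = roc_points([0.9, 0.4], [0.6, 0.1])
        assert roc.auc == pytest.approx(0.75)
        assert roc.auc == pytest.approx(concordance_auc([0.9, 0.4], [0.6, 0.1]))

    def test_identical_distributions_give_half(self):
        v = [0.2, 0.5, 0.9]
        assert roc_points(v, v).auc == pytest.approx(0.5)

    def test_curve_monotone_with_endpoints(self):
        rng = np.random.default_rng(0)
        roc = roc_points(rng.random(50), rng.random(60))
        fpr, tpr, thr = np.array(roc.fpr), np.array(roc.tpr), np.array(roc.thresholds)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert (np.diff(thr) < 0).all()  # sorted by decreasing threshold
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert math.isinf(thr[0])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=60)
    def test_trapezoidal_auc_equals_concordance_probability(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(1, 200, size=2)
        # mix continuous scores with coarse ones so ties occur
        pos = np.round(rng.random(n_pos), rng.integers(1, 4))
        neg = np.round(rng.random(n_neg), rng.integers(1, 4))
        assert roc_points(pos, neg).auc == pytest.approx(
            concordance_auc(pos, neg), abs=1e-12
        )

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_points([], [0.1])


class TestOperatingPoints:
    def test_perfect_classifier_hits_the_corner(self):
        roc = roc_points([0.9, 0.8], [0.2, 0.1])
        op = operating_point_at_fpr(roc, 0.05)
        assert (op.fpr, op.tpr) == (0.0, 1.0)

    def test_nine_negatives_force_fpr_zero(self):
        # 1/9 > 0.05, so only FPR=0 qualifies: threshold above the max negative
        neg = [round(0.1 * k, 1) for k in range(1, 10)]
        roc = roc_points([0.95, 0.5], neg)
        op = operating_point_at_fpr(roc, 0.05)
        assert op.fpr == 0.0 and op.threshold > max(neg)
        assert op.tpr == pytest.approx(0.5)

    def test_alpha_one_reaches_full_tpr(self):
        roc = roc_points([0.9, 0.4], [0.6, 0.1])
        assert operating_point_at_fpr(roc, 1.0).tpr == 1.0

    def test_returned_fpr_never_exceeds_alpha(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            roc = roc_points(rng.random(30), rng.random(30))
            alpha = float(rng.random())
            assert operating_point_at_fpr(roc, alpha).fpr <= alpha

    def test_threshold_point_exact_match(self):
        roc = roc_points([0.9, 0.6], [0.4, 0.1])
        op = operating_point_at_threshold(roc, 0.6)
        assert op.threshold == pytest.approx(0.6)

    def test_threshold_below_all_scores_returns_the_one_one_corner(self):
        roc = roc_points([0.9, 0.6], [0.4, 0.2])
        op = operating_point_at_threshold(roc, 0.01)
        assert (op.fpr, op.tpr) == (1.0, 1.0)

    def test_midway_tie_prefers_the_higher_threshold(self):
        roc = roc_points([0.8], [0.4])
        op = operating_point_at_threshold(roc, 0.6)  # midway between 0.4 and 0.8
        assert op.threshold == pytest.approx(0.8)


class TestEvaluateAll:
    def test_report_cardinality(self, small_study):
        report = small_study.report
        assert len(report.rocs) == 6
        assert len(report.paired_tests) == 12  # 6 kinds x 2 classes
        assert len(report.correlations) == 12
        assert len(report.densities) == 12
        for roc in report.rocs:
            assert len(roc.operating_points) == 3  # fpr<=alpha, thr 0.5, thr 0.6

    def test_report_json_round_trip(self, small_study, tmp_path):
        path = tmp_path / "report.json"
        small_study.report.to_json(path)
        back = EvaluationReport.from_json(path)
        assert back.to_json_dict() == small_study.report.to_json_dict()

    def test_missing_kind_is_an_error(self, small_study):
        from spaudit.scoring import ScoreTable

        crippled = ScoreTable(
            table=small_study.score_table.table.query("kind != 'reverse'").copy()
        )
        with pytest.raises(ValueError, match="reverse"):
            evaluate_all(crippled, small_study.labels)

    def test_adjusted_p_at_least_raw_and_original_flagged(self, small_study):
        for t in small_study.report.paired_tests:
            assert t.p_adj >= t.p_raw - 1e-15
            if t.kind == "original":
                assert "self_comparison" in t.flags and t.p_raw == 1.0
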