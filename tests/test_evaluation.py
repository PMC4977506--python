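import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sapdetect.evaluation import (
    ConfusionCounts,
    auc_trapezoid,
    basic_metrics,
    confusion,
    consensus,
    counts_from_rates,
    f_score,
    icc_two_way_average,
    mcc,
    optimize_thresholds,
    roc_over_grid,
    wald_ci,
)
from sapdetect.posture import DetectionParams, FrameTrack, detect_sap

# Open-field benchmark: P=337, N=2663 seconds with sensitivity 84.9 % and
# specificity 91.2 % gives tp=286, fn=51, tn=2429, fp=234.
OF_COUNTS = counts_from_rates(337, 2663, 0.849, 0.912)
EPM_COUNTS = counts_from_rates(2059, 3341, 0.860, 0.853)


def make_track(ecc, speed, fps=10.0):
    n = len(ecc)
    return FrameTrack(
        eccentricity=np.asarray(ecc, dtype=float),
        speed_cms=np.asarray(speed, dtype=float),
        valid=np.ones(n, dtype=bool),
        centroid_x_cm=np.zeros(n),
        centroid_y_cm=np.zeros(n),
        fps=fps,
    )


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,expected",
        [([1, 1, 0, 1, 0], 1), ([0, 0, 1, 0, 0], 0), ([1, 1, 0, 0], 0)],  # even tie -> 0
    )
    def test_majority_with_conservative_tie(self, votes, expected):
        panel = np.array(votes)[:, None]
        assert consensus(panel)[0] == expected

    def test_idempotent_under_duplicating_the_panel(self):
        rng = np.random.default_rng(0)
        panel = (rng.random((5, 40)) < 0.4).astype(int)
        doubled = np.vstack([panel, panel])
        assert np.array_equal(consensus(panel), consensus(doubled))


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        truth = np.array([1, 1, 0, 0, 0])
        c = confusion(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 3, 0, 0)
        c2 = confusion(1 - truth, truth)
        assert (c2.tp, c2.tn) == (0, 0)

    def test_direct_count(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            confusion([1, 0], [1, 0, 1])


class TestBasicMetrics:
    def test_open_field_benchmark_row(self):
        assert (OF_COUNTS.tp, OF_COUNTS.fn, OF_COUNTS.fp, OF_COUNTS.tn) == (286, 51, 234, 2429)
        m = basic_metrics(OF_COUNTS)
        assert m.accuracy == pytest.approx(0.905, abs=5e-4)
        assert m.sensitivity == pytest.approx(0.849, abs=5e-4)
        assert m.specificity == pytest.approx(0.912, abs=5e-4)

    def test_elevated_plus_maze_benchmark_row(self):
        m = basic_metrics(EPM_COUNTS)
        assert m.accuracy == pytest.approx(0.856, abs=5e-4)

    def test_perfect_prediction(self):
        m = basic_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=20))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
    def test_accuracy_is_prevalence_weighted_mean_of_rates(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        m = basic_metrics(c)
        p, n = c.positives, c.negatives
        expected = (m.sensitivity * p + m.specificity * n) / (p + n)
        assert m.accuracy == pytest.approx(expected, abs=1e-12)


class TestWald:
    def test_closed_form_half_width(self):
        ci = wald_ci(50, 100, 0.95)
        assert ci.upper - ci.estimate == pytest.approx(1.959964 * 0.05, abs=1e-4)

    def test_degenerate_p_equal_one_clamps(self):
        ci = wald_ci(40, 40, 0.95)
        assert ci.upper == 1.0
        assert ci.lower <= ci.estimate <= ci.upper

    def test_99_percent_upper_bound(self):
        assert wald_ci(2715, 3000, 0.99).upper == pytest.approx(0.919, abs=5e-4)

    def test_width_scales_as_inverse_sqrt_n(self):
        w100 = wald_ci(50, 100).upper - wald_ci(50, 100).lower
        w400 = wald_ci(200, 400).upper - wald_ci(200, 400).lower
        assert w100 / w400 == pytest.approx(2.0, abs=1e-9)


class TestFScoreAndMcc:
    def test_open_field_f_score(self):
        assert f_score(OF_COUNTS) == pytest.approx(0.667, abs=5e-4)

    def test_perfect_prediction_gives_one(self):
        perfect = ConfusionCounts(tp=10, fp=0, fn=0, tn=30)
        assert f_score(perfect) == 1.0
        assert mcc(perfect) == 1.0

    def test_zero_tp_gives_zero(self):
        assert f_score(ConfusionCounts(tp=0, fp=5, fn=7, tn=10)) == 0.0

    def test_no_predicted_positives_warns(self):
        c = ConfusionCounts(tp=0, fp=0, fn=7, tn=10)
        with pytest.warns(UserWarning):
            assert f_score(c) == 0.0

    def test_open_field_mcc(self):
        assert mcc(OF_COUNTS) == pytest.approx(0.635, abs=5e-4)

    def test_independence_gives_zero(self):
        assert mcc(ConfusionCounts(tp=6, fp=3, fn=4, tn=2)) == 0.0  # tp*tn == fp*fn

    def test_degenerate_margin_returns_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, fn=5, tn=5)) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_bounded_and_antisymmetric_under_label_swap(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        m = mcc(c)
        assert -1 <= m <= 1
        swapped = ConfusionCounts(tp=fn, fp=tn, fn=tp, tn=fp)  # invert predictions
        assert mcc(swapped) == pytest.approx(-m, abs=1e-12)


class TestAucTrapezoid:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0), (1, 1)], 0.5),
            ([(0, 0), (0, 1), (1, 1)], 1.0),
            # 0.2*0.3 + 0.3*0.75 + 0.5*0.95
            ([(0, 0), (0.2, 0.6), (0.5, 0.9), (1, 1)], 0.76),
        ],
    )
    def test_hand_computed_curves(self, points, expected):
        assert auc_trapezoid(points) == pytest.approx(expected, abs=1e-12)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            auc_trapezoid([(0, 0), (0.6, 0.5), (0.3, 0.9), (1, 1)])

    def test_matches_fine_grid_integration_on_random_monotone_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = rng.integers(3, 12)
            x = np.sort(np.concatenate([[0, 1], rng.random(k)]))
            y = np.sort(np.concatenate([[0, 1], rng.random(k)]))
            pts = list(zip(x, y))
            # oracle: dense piecewise-linear interpolation + rectangle sum
            xx = np.linspace(0, 1, 200001)
            yy = np.interp(xx, x, y)
            oracle = float(np.sum((yy[:-1] + yy[1:]) / 2) * (xx[1] - xx[0]))
            assert auc_trapezoid(pts) == pytest.approx(oracle, abs=1e-9)


class TestRocOverGrid:
    def test_truth_from_detector_is_self_consistent(self):
        rng = np.random.default_rng(1)
        ecc = rng.uniform(0.7, 1.0, 600)
        speed = rng.uniform(0, 20, 600)
        track = make_track(ecc, speed)
        params = DetectionParams(0.90, 12.0, fps=10.0)
        truth = detect_sap(track, params).second_flags
        scan = roc_over_grid([track], [truth], [0.85, 0.90, 0.95], [8.0, 12.0], 10.0)
        i, j = 1, 1  # the generating pair
        assert scan.mcc[i, j] == pytest.approx(1.0)
        assert scan.fpr[i, j] == 0.0
        assert scan.tpr[i, j] == 1.0

    def test_random_truth_gives_chance_auc(self):
        rng = np.random.default_rng(7)
        n = 30000  # 3000 seconds at 10 fps
        track = make_track(rng.uniform(0.7, 1.0, n), rng.uniform(0, 20, n))
        truth = (rng.random(3000) < 0.5).astype(int)
        scan = roc_over_grid(
            [track], [truth], np.arange(0.80, 0.981, 0.02), [8.0, 12.0, 16.0], 10.0
        )
        assert scan.roc.auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_grid_gives_anchors_plus_one_point(self):
        ecc = np.array([0.95] * 30 + [0.5] * 30)
        track = make_track(ecc, [0.0] * 60)
        truth = np.array([1, 1, 1, 0, 0, 0])
        scan = roc_over_grid([track], [truth], [0.90], [12.0], 10.0)
        assert len(scan.roc.fpr) == 3
        assert scan.mcc[0, 0] == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        track = make_track([0.95] * 10, [0.0] * 10)
        with pytest.raises(ValueError, match="non-empty"):
            roc_over_grid([track], [np.ones(1, dtype=int)], [], [12.0], 10.0)


class TestOptimizeThresholds:
    def _scan(self, surface, ecc_grid, speed_grid):
        from sapdetect.evaluation import RocCurve, ThresholdScan

        surface = np.asarray(surface, dtype=float)
        roc = RocCurve(np.array([0, 1.0]), np.array([0, 1.0]), (None, None), 0.5)
        return ThresholdScan(
            np.asarray(ecc_grid, dtype=float), np.asarray(speed_grid, dtype=float),
            surface, np.zeros_like(surface), np.zeros_like(surface), roc,
        )

    def test_unique_maximum(self):
        scan = self._scan([[0.1, 0.3], [0.8, 0.2]], [0.89, 0.90], [8, 12])
        assert optimize_thresholds(scan) == (0.90, 8.0)

    def test_ties_resolve_to_higher_thresholds(self):
        scan = self._scan([[0.8, 0.8], [0.8, 0.8]], [0.89, 0.90], [8, 12])
        assert optimize_thresholds(scan) == (0.90, 12.0)


class TestIcc:
    def test_identical_raters_give_exactly_one(self):
        row = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=float)
        panel = np.vstack([row] * 5)
        assert icc_two_way_average(panel).icc == 1.0

    def test_constant_panel_is_degenerate(self):
        res = icc_two_way_average(np.ones((3, 10)))
        assert res.degenerate

    def test_disagreement_lowers_reliability(self):
        rng = np.random.default_rng(3)
        base = (rng.random(400) < 0.3).astype(float)
        agree = np.vstack([base] * 4)
        noisy = agree.copy()
        noisy[3] = (rng.random(400) < 0.3).astype(float)  # one independent rater
        assert icc_two_way_average(noisy).icc < icc_two_way_average(agree).icc

    def test_recovers_known_variance_components(self):
        # two-way random model: x_rs = subj_s + rater_r + noise;
        # sigma2_subject=1, sigma2_rater=0.2, sigma2_error=0.5, k=2 raters
        k, s2s, s2r, s2e = 2, 1.0, 0.2, 0.5
        expected = s2s / (s2s + (s2r + s2e) / k)
        rng = np.random.default_rng(11)
        n = 4000
        subj = rng.normal(0, np.sqrt(s2s), n)
        rater = rng.normal(0, np.sqrt(s2r), k)
        panel = subj[None, :] + rater[:, None] + rng.normal(0, np.sqrt(s2e), (k, n))
        assert icc_two_way_average(panel).icc == pytest.approx(expected, abs=0.05)

    def test_cross_check_against_pingouin_icc2k(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        panel = rng.normal(size=(4, 60)) + rng.normal(size=60)[None, :]
        r, s = panel.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(s), r),
                "raters": np.tile(np.arange(r), s),
                "scores": panel.T.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        mask = ref["Type"].isin(["ICC2k", "ICC(A,k)"])
        icc2k = ref.loc[mask, "ICC"].iloc[0]
        assert icc_two_way_average(panel).icc == pytest.approx(icc2k, abs=1e-9)
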