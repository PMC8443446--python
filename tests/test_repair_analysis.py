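"""Single-cell repair pipeline: gating, detection, event timing, statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from recadim import repair_analysis as ra
from recadim import synthetic_data as sd


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        out = ra.subtract_background(np.full((64, 64), 37.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_spot_preserved_offset_removed(self):
        img = sd.generate_spot_image([(32.0, 32.0, 400.0)], background=500.0,
                                     poisson=False, gaussian_sd=0.0, seed=0)
        out = ra.subtract_background(img.image.astype(float))
        assert abs(np.median(out)) < 5.0           # offset gone
        assert out[32, 32] > 300.0                 # peak contrast kept

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            ra.subtract_background(np.zeros(10))


class TestFociDetection:
    def test_noiseless_single_spot_subpixel_accuracy(self):
        img = sd.generate_spot_image([(30.3, 21.6, 500.0)], poisson=False,
                                     gaussian_sd=0.0, seed=0)
        spots = ra.detect_foci(ra.subtract_background(img.image.astype(float)))
        assert len(spots) == 1
        assert spots.x_px.iloc[0] == pytest.approx(30.3, abs=0.05)
        assert spots.y_px.iloc[0] == pytest.approx(21.6, abs=0.05)

    def test_snr10_fixture_recall_and_precision(self, snr10_fixture):
        img = snr10_fixture
        found = ra.detect_foci(ra.subtract_background(img.image.astype(float)))
        truth = img.truth
        matched = 0
        for _, t in truth.iterrows():
            d = np.hypot(found.x_px - t.x_px, found.y_px - t.y_px)
            if (d < 2.0).any():
                matched += 1
        recall = matched / len(truth)
        precision = matched / max(len(found), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_background_subtraction_does_not_hurt_detection(self, snr10_fixture):
        img = snr10_fixture.image.astype(float)

        def f1(frame):
            found = ra.detect_foci(frame)
            truth = snr10_fixture.truth
            tp = sum(
                (np.hypot(found.x_px - t.x_px, found.y_px - t.y_px) < 2.0).any()
                for _, t in truth.iterrows())
            prec = tp / max(len(found), 1)
            rec = tp / len(truth)
            return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

        assert f1(ra.subtract_background(img)) >= f1(img)

    def test_blank_noise_frame_yields_no_spots(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(0, 3.0, (64, 64))
        assert len(ra.detect_foci(frame)) == 0


class TestBackboneMapping:
    def test_midpoint_of_straight_cell(self):
        backbone = np.array([[0.0, 0.0], [4.0, 0.0]])
        pos = ra.map_to_backbone([[2.0, 0.3]], backbone)
        assert pos[0] == pytest.approx(2.0)

    def test_flip_mirrors_position(self):
        backbone = np.array([[0.0, 0.0], [4.0, 0.0]])
        pos = ra.map_to_backbone([[1.0, 0.0]], backbone, flip=True)
        assert pos[0] == pytest.approx(3.0)

    def test_projection_onto_bent_backbone(self):
        backbone = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0]])
        pos = ra.map_to_backbone([[2.2, 1.0]], backbone)
        assert pos[0] == pytest.approx(3.0, abs=1e-6)

    def test_degenerate_backbone_rejected(self):
        with pytest.raises(ValueError):
            ra.map_to_backbone([[0, 0]], np.array([[0.0, 0.0]]))


class TestSosGate:
    def test_fold_threshold(self):
        t = np.arange(20.0)
        up = np.concatenate([np.full(10, 100.0), np.full(10, 450.0)])
        assert ra.gate_sos(t, up).gated
        mild = np.concatenate([np.full(10, 100.0), np.full(10, 350.0)])
        assert not ra.gate_sos(t, mild).gated

    def test_half_max_crossing_interpolated(self):
        t = np.arange(11.0)
        cfp = np.interp(t, [0, 4, 6, 10], [100, 100, 900, 900])
        call = ra.gate_sos(t, cfp)
        # half-max = 450, crossing of the linear ramp at t = 4 + 350/400·2
        assert call.induction_time == pytest.approx(4 + 2 * 350 / 800)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ra.gate_sos(np.arange(5.0), np.array([0.0, 0, 0, 2, 3]))


class TestRepairEvent:
    def test_loss_and_reappearance(self):
        t = np.arange(10.0)
        present = np.array([1, 1, 1, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        ev = ra.extract_repair_event(t, present)
        assert ev.status == "event"
        assert ev.parB_loss == 3.0
        assert ev.reappear == 6.0
        assert ev.repair_duration == 3.0

    def test_single_frame_dropout_ignored(self):
        t = np.arange(8.0)
        present = np.array([1, 1, 0, 1, 1, 1, 1, 1], dtype=bool)
        assert ra.extract_repair_event(t, present).status == "no_event"

    def test_always_present_is_no_event(self):
        t = np.arange(5.0)
        assert ra.extract_repair_event(t, np.ones(5, bool)).status == "no_event"

    def test_loss_without_reappearance_is_censored(self):
        t = np.arange(6.0)
        present = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        ev = ra.extract_repair_event(t, present)
        assert ev.status == "censored"
        assert ev.parB_loss == 3.0
        assert ev.repair_duration is None


class TestColocalization:
    def test_linear_convergence_crossing(self):
        t = np.arange(0.0, 15.0)
        pos_a = np.full(15, 1.0)
        pos_b = 1.0 + np.maximum(2.0 - 0.2 * t, 0.05)  # crosses 0.25 µm at t=9
        assert ra.colocalization_time(t, pos_a, pos_b, 0.25) == 9.0

    def test_infinite_threshold_colocal_from_origin(self):
        t = np.arange(5.0)
        assert ra.colocalization_time(t, np.zeros(5), np.ones(5), np.inf) == 0.0

    def test_never_colocalizing_is_censored(self):
        t = np.arange(5.0)
        assert ra.colocalization_time(t, np.zeros(5), np.ones(5), 0.25) is None


class TestGammaFit:
    def test_exponential_data_recovers_shape_one(self):
        rng = np.random.default_rng(1)
        fit = ra.fit_gamma(rng.exponential(10.0, 2000))
        assert fit.shape == pytest.approx(1.0, abs=0.1)
        assert fit.mean == pytest.approx(10.0, rel=0.1)

    @pytest.mark.parametrize("mean, sdev, n", [(15.2, 5.0, 765), (9.1, 3.3, 508)])
    def test_recovers_study_population_moments(self, mean, sdev, n):
        x = sd.sample_durations(sd.CohortConfig(), "repair" if mean > 10 else "coloc",
                                n, seed=11)
        fit = ra.fit_gamma(x)
        assert abs(fit.mean - mean) <= 3 * fit.mean_se
        assert fit.mean_ci[0] < fit.mean < fit.mean_ci[1]
        assert fit.sd == pytest.approx(fit.scale * math.sqrt(fit.shape))

    def test_guards(self):
        with pytest.raises(ValueError):
            ra.fit_gamma(np.array([1.0, -2.0] * 10))
        with pytest.raises(ValueError):
            ra.fit_gamma(np.ones(5))


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = ra.correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ra.correlate(np.ones(10), np.arange(10.0))

    def test_null_calibration(self):
        # under independence, r is small and p is approximately uniform
        rng = np.random.default_rng(3)
        rs, ps = [], []
        for _ in range(200):
            r, p = ra.correlate(rng.standard_normal(50), rng.standard_normal(50))
            rs.append(r)
            ps.append(p)
        assert abs(np.mean(rs)) < 0.05
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cohort_lifetime_sos_coupling_recovered(self, cohort):
        ev = cohort["events"]
        cut = ev[ev.cut]
        r, p = ra.correlate(cut.reca_lifetime, cut.sos_fold)
        se = 1.0 / math.sqrt(len(cut) - 3)
        assert abs(r - 0.36) <= 3 * se
        assert p < 0.05


class TestLengthRegression:
    def test_injected_slope_recovered(self):
        rng = np.random.default_rng(4)
        lengths = rng.uniform(2, 5, 300)
        durations = 10 + 2.0 * lengths + rng.normal(0, 2, 300)
        reg = ra.regress_vs_length(durations, lengths)
        lo, hi = reg.slope_ci
        assert lo <= 2.0 <= hi

    def test_independent_durations_slope_ci_contains_zero(self):
        rng = np.random.default_rng(5)
        reg = ra.regress_vs_length(rng.normal(15, 5, 300), rng.uniform(2, 5, 300))
        lo, hi = reg.slope_ci
        assert lo <= 0.0 <= hi

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            ra.regress_vs_length(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestCohortPipeline:
    def test_gated_fraction_matches_cut_fraction(self, cohort, cohort_results):
        res = cohort_results["results"]
        n = res.counts["cells"]
        frac = res.counts["gated"] / n
        p = cohort["config"].cut_fraction
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_event_times_match_truth_within_one_frame(self, cohort, cohort_results):
        dt = cohort["config"].frame_interval
        m = cohort_results["merged"]
        ev = m.dropna(subset=["repair_duration", "repair_duration_truth"])
        assert len(ev) > 50
        assert (ev.parB_loss - ev.parB_loss_truth).abs().max() <= dt + 1e-9
        assert (ev.repair_duration - ev.repair_duration_truth).abs().max() <= dt + 1e-9
        cl = m.dropna(subset=["coloc_time", "coloc_time_truth"])
        truth_rel = cl.coloc_time_truth - cl.parB_loss_truth
        assert (cl.coloc_time - truth_rel).abs().max() <= dt + 1e-9
        rl = m.dropna(subset=["reca_lifetime", "reca_lifetime_truth"])
        assert (rl.reca_lifetime - rl.reca_lifetime_truth).abs().max() <= dt + 1e-9

    def test_population_fits_recover_truth(self, cohort_results):
        res = cohort_results["results"]
        assert abs(res.repair_fit.mean - 15.2) <= 3 * res.repair_fit.mean_se + 0.5
        assert abs(res.coloc_fit.mean - 9.1) <= 3 * res.coloc_fit.mean_se + 0.5

    def test_counts_reconcile(self, cohort_results):
        c = cohort_results["results"].counts
        assert c["events"] + c["no_event"] + c["censored"] == c["gated"]

    def test_repair_length_regression_slope_ci_contains_zero(self, cohort_results):
        reg = cohort_results["results"].length_regression
        lo, hi = reg.slope_ci
        assert lo <= 0.0 <= hi

    def test_censoring_surfaced_for_truncated_movies(self):
        cfg = sd.CohortConfig(n_cells=40, seed=6, movie_length=40.0)
        cells = sd.generate_cohort(cfg)
        res = ra.analyze_cohort(sd.cohort_frames_df(cells), sd.cohort_foci_df(cells))
        assert res.counts["censored"] > 0
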