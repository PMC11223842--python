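import numpy as np
import pytest

from calibrt.calibrator import CalibConfig
from calibrt.exceptions import DegenerateScenarioError
from calibrt.synthetic_bench import (
    BASELINE_METHODS,
    CURVE_TYPES,
    BenchScenario,
    baseline_fit,
    generate_curve,
    mrd,
    run_experiment_matrix,
    subsample_and_add_noise,
    summarize_matrix,
)


class TestGenerateCurve:
    def test_linear_without_jitter_is_exact(self):
        pts = generate_curve("linear", 100, seed=1, jitter_sd_fraction=0.0)
        np.testing.assert_allclose(pts.measured_rt, 1.2 * pts.library_rt + 5.0, atol=1e-9)

    @pytest.mark.parametrize("curve_type", CURVE_TYPES)
    def test_sorted_by_x_is_nondecreasing_up_to_jitter(self, curve_type):
        pts = generate_curve(curve_type, 1000, seed=7)
        order = np.argsort(pts.library_rt)
        y = pts.measured_rt[order]
        y_span = y.max() - y.min()
        # consecutive decreases can only come from jitter (sigma = 0.5% of range)
        assert np.diff(y).min() > -3 * 2 * 0.005 * y_span

    @pytest.mark.parametrize("curve_type", CURVE_TYPES)
    def test_noise_free_form_is_monotone(self, curve_type):
        pts = generate_curve(curve_type, 500, seed=3, jitter_sd_fraction=0.0)
        order = np.argsort(pts.library_rt)
        assert (np.diff(pts.measured_rt[order]) >= -1e-12).all()

    def test_fixed_seed_reproducible(self):
        a = generate_curve("s_type", 200, seed=11)
        b = generate_curve("s_type", 200, seed=11)
        np.testing.assert_array_equal(a.library_rt, b.library_rt)
        np.testing.assert_array_equal(a.measured_rt, b.measured_rt)

    def test_center_dense_sampling(self):
        pts = generate_curve("linear", 5000, seed=5)
        x = pts.library_rt
        central = ((x > 25) & (x < 75)).mean()
        assert central > 0.6  # a uniform draw would give ~0.5

    def test_unknown_curve_rejected(self):
        with pytest.raises(ValueError):
            generate_curve("zigzag", 10, seed=0)


class TestSubsampleAndAddNoise:
    def test_zero_noise_keeps_only_signal(self):
        truth = generate_curve("linear", 1000, seed=2)
        pts, is_signal = subsample_and_add_noise(truth, 0.5, 0.0, seed=3)
        assert pts.n == 500 and is_signal.all()

    def test_noise_fraction_of_total_within_one_point(self):
        truth = generate_curve("exponential", 2500, seed=4)
        for nf in (0.01, 0.05, 0.35, 0.75):
            pts, is_signal = subsample_and_add_noise(truth, 0.01, nf, seed=5)
            n_noise = int((~is_signal).sum())
            assert abs(n_noise - nf * pts.n) <= 1

    def test_75_percent_noise_bookkeeping(self):
        truth = generate_curve("linear", 2500, seed=6)
        pts, is_signal = subsample_and_add_noise(truth, 0.01, 0.75, seed=7)
        assert is_signal.sum() == 25 and (~is_signal).sum() == 75

    def test_in_range_noise_stays_in_signal_bounding_box(self):
        truth = generate_curve("s_type", 2000, seed=8)
        pts, is_signal = subsample_and_add_noise(truth, 0.3, 0.35, seed=9)
        sx, sy = pts.library_rt[is_signal], pts.measured_rt[is_signal]
        nx, ny = pts.library_rt[~is_signal], pts.measured_rt[~is_signal]
        assert nx.min() >= sx.min() and nx.max() <= sx.max()
        assert ny.min() >= sy.min() and ny.max() <= sy.max()

    def test_extended_x_limit_raises_only_the_upper_bound(self):
        truth = generate_curve("linear", 2000, seed=10)
        pts, is_signal = subsample_and_add_noise(
            truth, 0.3, 0.75, noise_x_limit_factor=1.2, seed=11
        )
        sx = pts.library_rt[is_signal]
        nx = pts.library_rt[~is_signal]
        assert nx.max() <= 1.2 * sx.max() and nx.max() > sx.max()
        assert nx.min() >= sx.min()

    def test_no_signal_left_is_degenerate(self):
        truth = generate_curve("linear", 10, seed=12)
        with pytest.raises(DegenerateScenarioError):
            subsample_and_add_noise(truth, 0.01, 0.5, seed=13)


class TestMRD:
    def test_perfect_prediction_is_zero(self):
        measured = np.array([1.0, 2.0, 3.0])
        assert mrd(measured, measured, np.ones(3, bool)) == 0.0

    def test_hand_computed_value(self):
        assert mrd([1.0, 10.0], [0.0, 10.0], [True, True]) == pytest.approx(0.05)

    def test_noise_deviations_are_ignored(self, rng):
        measured = np.array([0.0, 5.0, 10.0, 50.0])
        predicted = np.array([0.5, 5.0, 10.0, -999.0])
        mask = np.array([True, True, True, False])
        base = mrd(predicted, measured, mask)
        perturbed = predicted.copy()
        perturbed[3] = rng.normal() * 1e6
        assert mrd(perturbed, measured, mask) == base

    def test_zero_signal_range_rejected(self):
        with pytest.raises(ValueError):
            mrd([1.0, 2.0], [5.0, 5.0], [True, True])


class TestBaselines:
    def test_all_methods_match_on_clean_line(self):
        truth = generate_curve("linear", 2000, seed=20, jitter_sd_fraction=0.0)
        pts, is_signal = subsample_and_add_noise(truth, 0.5, 0.0, seed=21)
        from calibrt.calibrator import fit_calibration

        reference = fit_calibration(pts)
        y_cell = (pts.measured_rt.max() - pts.measured_rt.min()) / 100
        for method in BASELINE_METHODS:
            model = baseline_fit(method, pts)
            diff = np.abs(model.predict(pts.library_rt) - reference.predict(pts.library_rt))
            assert diff.max() < y_cell

    def test_ransac_deterministic_under_fixed_seed(self):
        truth = generate_curve("s_type", 2000, seed=22)
        pts, _ = subsample_and_add_noise(truth, 0.1, 0.35, seed=23)
        a = baseline_fit("ransac_loess", pts)
        b = baseline_fit("ransac_loess", pts)
        assert a.to_dict() == b.to_dict()

    def test_unknown_method_rejected(self):
        truth = generate_curve("linear", 100, seed=24)
        with pytest.raises(ValueError):
            baseline_fit("median_loess", truth)


class TestSpanFilterWithOutOfRangeNoise:
    def test_span_filtering_does_not_hurt_when_noise_exceeds_signal_range(self):
        from calibrt.calibrator import fit_calibration
        from calibrt.span_filter import SpanConfig

        results = {False: [], True: []}
        for rep in range(10):
            truth = generate_curve("s_type", 2500, seed=40 + rep)
            pts, is_signal = subsample_and_add_noise(
                truth, 0.1, 0.75, noise_x_limit_factor=1.2, seed=70 + rep
            )
            for enabled in (False, True):
                model = fit_calibration(
                    pts, CalibConfig(span=SpanConfig(enabled=enabled, threshold=0.1))
                )
                results[enabled].append(
                    mrd(model.predict(pts.library_rt), pts.measured_rt, is_signal)
                )
        assert float(np.median(results[True])) <= float(np.median(results[False]))


class TestExperimentMatrix:
    def test_factorial_row_count(self):
        table = run_experiment_matrix(
            curve_types=("linear", "s_type"),
            sampling_rates=(0.1,),
            noise_fractions=(0.05,),
            methods=("calib_rt",),
            n_seeds=2,
            n_truth=500,
        )
        assert len(table) == 2 * 1 * 1 * 1 * 2
        assert set(table.columns) == {
            "method", "curve_type", "sampling_rate", "noise_fraction", "seed", "mrd",
        }

    def test_empty_method_list_gives_empty_table(self):
        table = run_experiment_matrix(methods=(), n_seeds=1, n_truth=200)
        assert table.empty and summarize_matrix(table).empty

    def test_reproducible_for_fixed_base_seed(self, tmp_path):
        kwargs = dict(
            curve_types=("exponential",), sampling_rates=(0.3,), noise_fractions=(0.35,),
            methods=("calib_rt", "raw_loess"), n_seeds=2, n_truth=500, base_seed=9,
        )
        a = run_experiment_matrix(**kwargs, out_tsv=tmp_path / "bench.tsv")
        b = run_experiment_matrix(**kwargs)
        assert a.equals(b)
        assert (tmp_path / "bench.tsv").exists()
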