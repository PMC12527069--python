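"""Preprocessing pipeline: peaks, segmentation, normalization, denoising."""

import math
import statistics

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from ecgkit import (
    DenoiseParams, ECGRecord, SegmentationConfig, SyntheticSpec,
    ValidationError, clean_nonfinite, denoise_dwt, detect_r_peaks,
    estimate_sigma, generate_record, segment_beats, subsample_majority,
    universal_threshold, zscore,
)
from ecgkit.io import BeatDataset
from ecgkit.synthetic import generate_beat_dataset, make_template
from ecgkit.preprocess import hard_threshold, zscore_dataset

UNIFORM = (0.2, 0.2, 0.2, 0.2, 0.2)


class TestRPeakDetection:
    def test_noiseless_recovery_from_annotations(self):
        spec = SyntheticSpec(n_beats=10, class_proportions=UNIFORM,
                             noise_sd=0.0, baseline_amp=0.0, seed=2)
        rec, _ = generate_record(spec, 70.0)
        peaks = detect_r_peaks(rec, use_annotations=True)
        truth = rec.annotation_indices()
        assert peaks.size == 10
        assert np.all(np.abs(peaks - truth) <= 2)

    def test_flat_signal_no_peaks(self):
        rec = ECGRecord(np.zeros(7200), 360.0, [])
        assert detect_r_peaks(rec, use_annotations=False).size == 0

    def test_detector_sensitivity_on_noisy_record(self):
        spec = SyntheticSpec(n_beats=60, class_proportions=UNIFORM,
                             noise_sd=0.05, seed=8)
        rec, _ = generate_record(spec, 72.0)
        peaks = detect_r_peaks(rec, use_annotations=False)
        truth = rec.annotation_indices()
        tol = int(0.05 * rec.fs)
        hits = sum(np.any(np.abs(peaks - t) <= tol) for t in truth)
        assert hits / truth.size >= 0.95

    def test_refractory_constraint(self):
        spec = SyntheticSpec(n_beats=40, class_proportions=UNIFORM,
                             noise_sd=0.08, seed=3)
        rec, _ = generate_record(spec, 72.0)
        peaks = detect_r_peaks(rec, use_annotations=False)
        assert np.all(np.diff(peaks) >= int(0.2 * rec.fs))

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            detect_r_peaks(ECGRecord(np.zeros(100), 360.0, []))


class TestSegmentation:
    def test_boundary_peak_dropped(self):
        rec = ECGRecord(np.arange(1000, dtype=float), 360.0, [])
        cfg = SegmentationConfig(pre_samples=99, post_samples=180)
        ds = segment_beats(rec, np.array([50, 500]), cfg)
        assert len(ds) == 1  # the peak at 50 cannot fit 99 pre-samples

    def test_interior_peaks_fixed_length(self):
        spec = SyntheticSpec(n_beats=12, class_proportions=UNIFORM,
                             noise_sd=0.0, seed=4)
        rec, _ = generate_record(spec, 70.0)
        cfg = SegmentationConfig(pre_samples=99, post_samples=180)
        peaks = detect_r_peaks(rec)
        ds = segment_beats(rec, peaks, cfg)
        assert ds.segment_len == 280
        assert 10 <= len(ds) <= 12  # first/last may fall outside the window

    def test_r_peak_lands_at_pre_samples(self):
        spec = SyntheticSpec(n_beats=12, class_proportions=(1, 0, 0, 0, 0),
                             noise_sd=0.0, baseline_amp=0.0, seed=4)
        rec, _ = generate_record(spec, 70.0)
        cfg = SegmentationConfig(pre_samples=60, post_samples=120)
        ds = segment_beats(rec, detect_r_peaks(rec), cfg)
        for row in ds.segments:
            assert abs(int(np.argmax(row)) - 60) <= 2

    def test_labels_follow_annotations(self):
        spec = SyntheticSpec(n_beats=30, class_proportions=UNIFORM,
                             noise_sd=0.0, seed=5)
        rec, _ = generate_record(spec, 70.0)
        cfg = SegmentationConfig(pre_samples=60, post_samples=120)
        ds = segment_beats(rec, detect_r_peaks(rec), cfg)
        truth = {i: sym for i, sym in rec.annotations}
        from ecgkit.io import AAMI_CLASSES
        # every produced label matches the class of its source annotation
        peaks = [p for p in detect_r_peaks(rec)
                 if cfg.pre_samples <= p <= rec.signal.size - cfg.post_samples - 1]
        for p, lab in zip(peaks, ds.labels):
            assert AAMI_CLASSES[lab] == truth[p]


class TestZscore:
    def test_constant_input_maps_to_zeros(self):
        np.testing.assert_array_equal(zscore(np.ones(4)), np.zeros(4))

    def test_two_point_population_sd(self):
        np.testing.assert_allclose(zscore(np.array([0.0, 2.0])), [-1.0, 1.0])

    def test_random_vector_standardized(self, rng):
        out = zscore(rng.normal(2.0, 3.0, size=500))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_idempotence(self, rng):
        x = rng.normal(size=128)
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            zscore(np.array([1.0, np.nan, 2.0]))


class TestSubsampling:
    def _ds(self, n_majority=1000, n_other=50):
        labels = np.r_[np.zeros(n_majority, int), np.full(n_other, 2)]
        return BeatDataset(np.ones((labels.size, 8)), labels)

    def test_keep_prob_one_is_identity(self):
        ds = self._ds()
        out = subsample_majority(ds, keep_prob=1.0, seed=0)
        assert len(out) == len(ds)

    def test_keep_prob_zero_removes_all_targets(self):
        out = subsample_majority(self._ds(), keep_prob=0.0, seed=0)
        assert out.class_counts[0] == 0
        assert out.class_counts[2] == 50

    def test_minority_classes_untouched(self):
        ds = self._ds()
        out = subsample_majority(ds, keep_prob=0.15, seed=3)
        assert out.class_counts[2] == ds.class_counts[2]

    def test_retention_rate_within_binomial_bound(self):
        n = 100_000
        ds = BeatDataset(np.ones((n, 4)), np.zeros(n, int))
        bound = 3 * math.sqrt(0.15 * 0.85 / n)
        for seed in range(10):
            kept = len(subsample_majority(ds, keep_prob=0.15, seed=seed)) / n
            assert abs(kept - 0.15) < bound

    def test_order_preserved(self, rng):
        labels = rng.integers(0, 5, size=200)
        segs = np.arange(200, dtype=float)[:, None] * np.ones((1, 4))
        out = subsample_majority(BeatDataset(segs, labels), 0.3, seed=1)
        assert np.all(np.diff(out.segments[:, 0]) > 0)


class TestCleanNonfinite:
    def test_all_finite_identity(self, balanced_dataset):
        out = clean_nonfinite(balanced_dataset)
        assert len(out) == len(balanced_dataset)

    def test_exactly_corrupted_rows_removed(self, rng):
        segs = rng.normal(size=(50, 16))
        bad = [3, 17, 40]
        segs[3, 5] = np.nan
        segs[17, 0] = np.inf
        segs[40, 15] = -np.inf
        out = clean_nonfinite(BeatDataset(segs, np.zeros(50, int)))
        assert len(out) == 47
        assert np.all(np.isfinite(out.segments))


class TestDonohoThreshold:
    def test_sigma_zero_coefficients(self):
        assert estimate_sigma([0.0, 0.0, 0.0]) == 0.0

    def test_sigma_constant_magnitude(self):
        assert estimate_sigma([0.6745, -0.6745, 0.6745]) == pytest.approx(1.0)

    def test_sigma_hand_computed(self):
        # median(|1, -1, 2, -2|) = 1.5 via an independent median routine
        cd = [1.0, -1.0, 2.0, -2.0]
        expected = statistics.median([abs(c) for c in cd]) / 0.6745
        assert estimate_sigma(cd) == pytest.approx(expected, abs=1e-15)

    def test_sigma_empty_rejected(self):
        with pytest.raises(ValidationError):
            estimate_sigma([])

    def test_threshold_n_one_is_zero(self):
        assert universal_threshold(3.7, 1) == 0.0

    def test_threshold_sigma_zero(self):
        assert universal_threshold(0.0, 1024) == 0.0

    def test_threshold_hand_computed(self):
        assert universal_threshold(1.0, 1024) == pytest.approx(
            math.sqrt(2.0 * math.log(1024)), abs=1e-15)

    def test_threshold_invalid_n(self):
        with pytest.raises(ValidationError):
            universal_threshold(1.0, 0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=64),
           st.floats(0, 5))
    def test_hard_threshold_is_contraction(self, coeffs, lam):
        out = hard_threshold(np.array(coeffs), lam)
        assert np.all(np.abs(out) <= np.abs(np.array(coeffs)) + 1e-15)
        # at-threshold coefficients are zeroed
        assert np.all(out[np.abs(np.array(coeffs)) <= lam] == 0.0)


class TestDenoise:
    def test_lambda_zero_perfect_reconstruction(self, rng):
        seg = rng.normal(size=280)
        out = denoise_dwt(seg, DenoiseParams(lam=0.0))
        assert np.max(np.abs(out - seg)) < 1e-8

    def test_all_zero_segment(self):
        out = denoise_dwt(np.zeros(128))
        np.testing.assert_array_equal(out, np.zeros(128))

    def test_output_length_preserved(self, rng):
        for n in (100, 128, 280):
            assert denoise_dwt(rng.normal(size=n)).size == n

    def test_unknown_wavelet_rejected(self):
        from ecgkit import ConfigurationError
        with pytest.raises(ConfigurationError, match="wavelet"):
            denoise_dwt(np.zeros(128), DenoiseParams(wavelet_name="nosuch9"))

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            denoise_dwt(np.zeros(4), DenoiseParams(levels=3))

    def test_mse_reduction_on_noisy_templates(self):
        clean = make_template("N").waveform
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0.0, 0.1, size=clean.size)
            den = denoise_dwt(noisy)
            if np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2):
                wins += 1
        assert wins == 50  # paired comparison: denoising always helps here

    def test_matches_independent_recomposition(self, rng):
        # oracle: decompose with pywt directly, contract the detail bands
        # at the universal threshold by hand, and invert
        from ecgkit.preprocess import estimate_denoise_params
        seg = rng.normal(size=280)
        params = DenoiseParams()
        w = pywt.Wavelet(params.wavelet_name)
        coeffs = pywt.wavedec(seg, w, level=params.levels, mode="symmetric")
        lam = estimate_denoise_params(seg, params).lam
        expected_coeffs = [coeffs[0]] + [
            np.where(np.abs(c) <= lam, 0.0, c) for c in coeffs[1:]
        ]
        for b, a in zip(coeffs[1:], expected_coeffs[1:]):
            assert np.all(np.abs(a) <= np.abs(b) + 1e-15)  # contraction
        expected = pywt.waverec(expected_coeffs, w, mode="symmetric")[:280]
        np.testing.assert_allclose(denoise_dwt(seg, params), expected,
                                   atol=1e-12)


class TestPipelineComposition:
    def test_record_to_labeled_finite_dataset(self):
        from ecgkit.preprocess import run_pipeline
        spec = SyntheticSpec(n_beats=40, noise_sd=0.05, seed=21)
        rec, _ = generate_record(spec, 72.0)
        ds = run_pipeline(rec, seed=0)
        assert len(ds) > 0
        assert ds.segment_len == 280
        assert np.all(np.isfinite(ds.segments))
        # the majority class was thinned relative to the raw mixture
        raw = segment_beats(rec, detect_r_peaks(rec), SegmentationConfig())
        assert ds.class_counts[0] <= raw.class_counts[0]
        np.testing.assert_array_equal(ds.class_counts[1:], raw.class_counts[1:])
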