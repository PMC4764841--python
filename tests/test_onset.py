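"""Onset detection: scan rule, refractory lockout, calibration, models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slowfield as sf
from slowfield.errors import CalibrationError
from slowfield.onset import (
    REFRACTORY_MS,
    ConfidenceStream,
    OnsetDetector,
    calibrate_thresholds,
    detect_onsets,
    evaluate_first_onset,
    train_confidence_models,
)


def stream_at(times, c_svm, c_gpr=None):
    c_svm = np.asarray(c_svm, dtype=float)
    if c_gpr is None:
        c_gpr = c_svm.copy()
    return ConfidenceStream(times_ms=np.asarray(times, dtype=float),
                            c_svm=c_svm, c_gpr=np.asarray(c_gpr, float))


DET = OnsetDetector(threshold_svm=0.5, threshold_gpr=0.5)


class TestDetectOnsets:
    def test_subthreshold_stream_is_silent(self):
        s = stream_at([0, 200, 400], [0.1, 0.2, 0.3])
        assert detect_onsets(s, DET) == []

    def test_refractory_suppresses_second_candidate(self):
        s = stream_at([1000, 2200], [0.9, 0.9])
        assert detect_onsets(s, DET) == [1000.0]

    def test_suppressed_candidates_do_not_extend_lockout(self):
        s = stream_at([1000, 2200, 2600], [0.9, 0.9, 0.9])
        assert detect_onsets(s, DET) == [1000.0, 2600.0]

    def test_exactly_refractory_interval_is_allowed(self):
        s = stream_at([1000, 2500], [0.9, 0.9])
        assert detect_onsets(s, DET) == [1000.0, 2500.0]

    def test_both_streams_must_exceed(self):
        s = stream_at([0], [0.9], [0.1])
        assert detect_onsets(s, DET) == []
        # equality does not trigger (strict inequality)
        s = stream_at([0], [0.5], [0.9])
        assert detect_onsets(s, DET) == []

    def test_supersampling_with_subthreshold_points_is_invariant(self):
        base = stream_at([1000, 3000], [0.9, 0.9])
        dense = stream_at([500, 1000, 1500, 2500, 3000],
                          [0.0, 0.9, 0.0, 0.0, 0.9])
        assert detect_onsets(base, DET) == detect_onsets(dense, DET)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=120),
           st.floats(0.0, 0.95))
    def test_refractory_bound_property(self, confs, thr):
        times = 200.0 * np.arange(len(confs))
        det = OnsetDetector(threshold_svm=thr, threshold_gpr=thr)
        onsets = detect_onsets(stream_at(times, confs), det)
        # inter-onset gaps respect the lockout and the count is bounded
        assert all(b - a >= REFRACTORY_MS
                   for a, b in zip(onsets, onsets[1:]))
        span = times[-1] - times[0] if len(times) > 1 else 0.0
        assert len(onsets) <= int(np.ceil(span / REFRACTORY_MS)) + 1


class TestCalibration:
    def test_huge_target_gives_minimal_thresholds(self, rng):
        streams = [stream_at(200.0 * np.arange(30), rng.uniform(size=30))
                   for _ in range(4)]
        det = calibrate_thresholds(streams, target_fp_per_min=1e9)
        pooled = np.concatenate([s.c_svm for s in streams])
        assert det.threshold_svm == pytest.approx(pooled.min())

    def test_zero_target_silences_rest(self, rng):
        streams = [stream_at(200.0 * np.arange(30), rng.uniform(size=30))
                   for _ in range(4)]
        det = calibrate_thresholds(streams, target_fp_per_min=0.0)
        assert all(len(detect_onsets(s, det)) == 0 for s in streams)
        pooled = np.concatenate([s.c_svm for s in streams])
        assert det.threshold_svm >= pooled.max() - 1e-12

    def test_unattainable_target_reports_best(self, rng):
        streams = [stream_at(200.0 * np.arange(10), rng.uniform(size=10))]
        with pytest.raises(CalibrationError) as exc:
            calibrate_thresholds(streams, target_fp_per_min=-1.0)
        assert exc.value.best_achievable >= 0.0


class TestConfidenceModels:
    def test_fit_separates_epochs_and_is_deterministic(self, small_features):
        m1 = train_confidence_models(small_features, seed=5)
        m2 = train_confidence_models(small_features, seed=5)
        from slowfield.onset import _epoch_examples

        x, y = _epoch_examples(small_features)
        c1, g1 = m1.predict(x)
        c2, g2 = m2.predict(x)
        assert np.array_equal(c1, c2) and np.array_equal(g1, g2)
        assert c1[y == 1].mean() > c1[y == 0].mean()
        assert g1[y == 1].mean() > g1[y == 0].mean()

    def test_null_generator_has_chance_level_auc(self, array84):
        cfg = sf.SimulationConfig(
            seed=21, cues_per_type=8,
            mrcf_amplitude={"grasp": 0.0, "open": 0.0},
            erd_depth_alpha=0.0, erd_depth_beta=0.0)
        ses = sf.simulate_open_loop(cfg, array84)
        stats = sf.compute_baseline_stats(ses)
        fs = sf.feature_set_from_session(ses, stats,
                                         sf.WindowGrid(-2000, 2000, 100))
        from slowfield.decoding import LabeledFeatureSet
        from slowfield.onset import _epoch_examples
        from sklearn.metrics import roc_auc_score

        # held-out predictions on both epochs; in-sample AUC is optimistic
        n = fs.x.shape[0]
        train = LabeledFeatureSet(
            x=fs.x[: n // 2], window_ends_ms=fs.window_ends_ms,
            labels=np.asarray(fs.labels)[: n // 2],
            trial_ids=fs.trial_ids[: n // 2])
        held = LabeledFeatureSet(
            x=fs.x[n // 2:], window_ends_ms=fs.window_ends_ms,
            labels=np.asarray(fs.labels)[n // 2:],
            trial_ids=fs.trial_ids[n // 2:])
        models = train_confidence_models(train, seed=0)
        x, y = _epoch_examples(held)
        c, _ = models.predict(x)
        auc = roc_auc_score(y, c)
        assert 0.3 < auc < 0.7


class TestFirstOnsetEvaluation:
    def test_infinite_thresholds_detect_nothing(self, small_features):
        det = OnsetDetector(threshold_svm=np.inf, threshold_gpr=np.inf)
        hist = evaluate_first_onset(small_features, folds=4, seed=0,
                                    detector=det)
        assert hist.nd_percent == 100.0
        assert np.all(hist.rate_percent == 0.0)

    def test_rates_partition_all_trials(self, small_features):
        hist = evaluate_first_onset(small_features, folds=4, seed=0)
        total = hist.rate_percent.sum() + hist.nd_percent
        assert total == pytest.approx(100.0, abs=1e-9)
        assert hist.n_trials == small_features.x.shape[0]

    def test_capture_fraction_conventions(self, small_features):
        hist = evaluate_first_onset(small_features, folds=4, seed=0)
        all_frac = hist.capture_fraction(among="all")
        det_frac = hist.capture_fraction(among="detected")
        if hist.offsets:
            assert det_frac >= all_frac - 1e-12
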