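"""Preprocessing, I-VT detection, feature formulas, screening, label maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ictd.gaze import (ESEE_FEATURES, SEED_FEATURES, FeatureTable,
                       GazeRecording, OcularEvent, anova_screen,
                       detect_events, extract_esee_features,
                       extract_seed_features, map_to_russell, preprocess)
from ictd.synthetic import GazeStreamSpec, generate_gaze_stream


def _recording(x, y=None, valid=None, rate=100.0, pupil=3.0):
    n = len(x)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y if y is not None else np.zeros(n), dtype=float)
    valid = np.asarray(valid if valid is not None else np.ones(n, bool))
    t = np.arange(n) * 1000.0 / rate
    p = np.full(n, float(pupil))
    return GazeRecording(t, x, y, p.copy(), p.copy(), valid, rate)


class TestPreprocess:
    def test_clean_recording_with_unit_window_unchanged(self):
        rec = _recording(np.arange(10.0))
        out = preprocess(rec, smooth_window=1)
        np.testing.assert_array_equal(out.x, rec.x)
        np.testing.assert_array_equal(out.valid, rec.valid)

    def test_single_gap_linear_midpoint(self):
        x = np.array([2.0, 2.0, 0.0, 4.0, 4.0])
        valid = np.array([1, 1, 0, 1, 1], bool)
        out = preprocess(_recording(x, valid=valid), max_gap_ms=50,
                         smooth_window=1)
        assert out.x[2] == pytest.approx(3.0)
        assert out.valid[2]

    def test_long_gap_left_invalid(self):
        x = np.ones(30)
        valid = np.ones(30, bool)
        valid[5:20] = False              # 150 ms at 100 Hz
        out = preprocess(_recording(x, valid=valid), max_gap_ms=75,
                         smooth_window=1)
        assert not out.valid[5:20].any()

    def test_moving_average_preserves_linear_ramp(self):
        ramp = np.arange(50.0)
        out = preprocess(_recording(ramp), smooth_window=5)
        np.testing.assert_allclose(out.x[2:-2], ramp[2:-2], atol=1e-12)

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            preprocess(_recording(np.ones(5), valid=np.zeros(5, bool)))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            preprocess(_recording(np.ones(5)), smooth_window=4)


class TestDetectEvents:
    def test_planned_stream_counts_and_boundaries(self):
        spec = GazeStreamSpec(
            fixation_plan=((400, 0, 0, 0), (350, 120, 0, 0), (500, 120, 150, 0)),
            saccade_plan=((40, 120), (40, 150)), seed=0)
        rec, gt = generate_gaze_stream(spec)
        events = detect_events(rec)
        fix = [e for e in events if e.kind == "fixation"]
        sac = [e for e in events if e.kind == "saccade"]
        assert len(fix) == 3 and len(sac) == 2
        dt = 1000.0 / spec.sample_rate
        planned = sorted((a, b) for k, a, b in gt.events if k == "fixation")
        got = sorted((e.onset_ms, e.offset_ms) for e in fix)
        for (pa, pb), (ga, gb) in zip(planned, got):
            assert abs(pa - ga) <= dt and abs(pb - gb) <= dt

    def test_stationary_recording_is_one_fixation(self):
        rec = _recording(np.zeros(100))
        events = detect_events(rec)
        assert [e.kind for e in events] == ["fixation"]
        assert events[0].onset_ms == 0.0
        assert events[0].offset_ms == pytest.approx(rec.duration_ms)

    def test_blink_inside_fixation_is_reported_and_fixation_merged(self):
        spec = GazeStreamSpec(fixation_plan=((1000, 0, 0, 0),),
                              blink_plan=((300, 150),))
        rec, _ = generate_gaze_stream(spec)
        events = detect_events(rec)
        kinds = sorted(e.kind for e in events)
        assert kinds == ["blink", "fixation"]

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            GazeRecording(np.array([]), np.array([]), np.array([]),
                          np.array([]), np.array([]), np.array([]), 100.0)

    def test_random_noise_free_plans_recover_exact_counts(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n_fix = int(rng.integers(2, 6))
            centers = rng.uniform(-200, 200, size=(n_fix, 2))
            fixations = tuple(
                (float(rng.integers(5, 26) * 20), cx, cy, 0.0)
                for (cx, cy) in centers)
            saccades = tuple(
                (40.0, float(np.hypot(*(centers[i + 1] - centers[i]))))
                for i in range(n_fix - 1))
            spec = GazeStreamSpec(fixation_plan=fixations,
                                  saccade_plan=saccades, seed=1)
            rec, gt = generate_gaze_stream(spec)
            events = detect_events(rec)
            for kind in ("fixation", "saccade", "blink"):
                assert sum(e.kind == kind for e in events) == gt.count(kind)


def _events_from_durations(kind, durations, gap=100.0, **fields):
    events, t = [], 0.0
    for d in durations:
        events.append(OcularEvent(kind, t, t + d, **fields))
        t += d + gap
    return events


class TestSeedFeatures:
    def test_constant_pupil_moments(self):
        rec = _recording(np.zeros(100), pupil=3.0)
        feats = extract_seed_features(detect_events(rec), rec)
        assert feats["pupil_left_mean"] == pytest.approx(3.0)
        assert feats["pupil_left_std"] == pytest.approx(0.0)

    def test_hand_computed_fixation_statistics(self):
        rec = _recording(np.zeros(1000), rate=100.0)  # 10 s recording
        events = _events_from_durations("fixation", [200.0, 300.0, 400.0],
                                        dispersion_x=1.0, dispersion_y=2.0)
        feats = extract_seed_features(events, rec)
        assert feats["fixation_duration_mean"] == pytest.approx(300.0)
        assert feats["max_fixation_duration"] == pytest.approx(400.0)
        assert feats["fixation_frequency"] == pytest.approx(0.3)
        assert feats["total_fixation_dispersion"] == pytest.approx(9.0)

    def test_no_saccades_yields_missing_saccade_features_only(self):
        rec = _recording(np.zeros(100))
        events = _events_from_durations("fixation", [300.0],
                                        dispersion_x=0.0, dispersion_y=0.0)
        feats = extract_seed_features(events, rec)
        assert np.isnan(feats["saccade_duration_mean"])
        assert np.isnan(feats["avg_saccade_latency"])
        assert not np.isnan(feats["fixation_duration_mean"])

    def test_catalog_complete(self):
        rec = _recording(np.zeros(100))
        feats = extract_seed_features(detect_events(rec), rec)
        assert set(feats) == set(SEED_FEATURES)

    def test_agrees_with_bruteforce_on_random_events(self, rng):
        rec = _recording(rng.normal(size=500), rate=100.0)
        events = []
        t = 0.0
        for _ in range(8):
            d = float(rng.uniform(50, 400))
            events.append(OcularEvent("fixation", t, t + d,
                                      dispersion_x=float(rng.uniform(0, 3)),
                                      dispersion_y=float(rng.uniform(0, 3))))
            t += d
            d = float(rng.uniform(20, 80))
            events.append(OcularEvent("saccade", t, t + d,
                                      amplitude=float(rng.uniform(1, 50)),
                                      distance=float(rng.uniform(1, 60)),
                                      mean_velocity=float(rng.uniform(30, 300)),
                                      peak_velocity=float(rng.uniform(50, 500))))
            t += d
        feats = extract_seed_features(events, rec)
        # naive loop re-implementation
        fix = [e for e in events if e.kind == "fixation"]
        sac = [e for e in events if e.kind == "saccade"]
        fd = [e.offset_ms - e.onset_ms for e in fix]
        assert abs(feats["fixation_duration_mean"] - sum(fd) / len(fd)) < 1e-10
        disp = [e.dispersion_x + e.dispersion_y for e in fix]
        assert abs(feats["total_fixation_dispersion"] - sum(disp)) < 1e-10
        gaps = [b.onset_ms - a.onset_ms for a, b in zip(sac, sac[1:])]
        assert abs(feats["avg_saccade_latency"] - sum(gaps) / len(gaps)) < 1e-10
        assert abs(feats["saccade_frequency"]
                   - len(sac) / (rec.duration_ms / 1000)) < 1e-10


class TestEseeFeatures:
    def test_constant_durations_zero_var_and_cv(self):
        rec = _recording(np.zeros(100))
        events = _events_from_durations("fixation", [250.0] * 4,
                                        dispersion_x=0, dispersion_y=0)
        feats = extract_esee_features(events, rec)
        assert feats["fixation_duration_var"] == pytest.approx(0.0)
        assert feats["fixation_duration_cv"] == pytest.approx(0.0)

    def test_hand_computed_saccade_duration_moments(self):
        rec = _recording(np.zeros(100))
        events = _events_from_durations("saccade", [100.0, 200.0, 300.0],
                                        amplitude=1, distance=1,
                                        mean_velocity=10, peak_velocity=20)
        feats = extract_esee_features(events, rec)
        assert feats["saccade_duration_cv"] == pytest.approx(
            np.sqrt(20000 / 3) / 200, abs=1e-9)   # population sd / mean

    def test_large_sample_normal_speeds_have_small_excess_moments(self):
        rng = np.random.default_rng(8)
        speeds = rng.normal(size=10000)
        events = [OcularEvent("saccade", 10 * i, 10 * i + 5,
                              mean_velocity=float(v), amplitude=1.0,
                              distance=1.0, peak_velocity=1.0)
                  for i, v in enumerate(speeds)]
        rec = _recording(np.zeros(100))
        feats = extract_esee_features(events, rec)
        assert abs(feats["saccade_speed_kurt"]) < 0.1
        assert abs(feats["saccade_speed_skew"]) < 0.1

    def test_zero_mean_cv_is_missing(self):
        # centred (zero-mean) pupil signal: variance defined, CV undefined
        n = 10
        t = np.arange(n) * 10.0
        p = np.tile([3.0, -3.0], n // 2)
        rec = GazeRecording(t, np.zeros(n), np.zeros(n), p, p.copy(),
                            np.ones(n, bool), 100.0)
        feats = extract_esee_features([], rec)
        assert np.isnan(feats["pupil_diameter_cv"])
        assert feats["pupil_diameter_var"] == pytest.approx(9.0)

    def test_catalog_complete(self):
        rec = _recording(np.zeros(100))
        feats = extract_esee_features(detect_events(rec), rec)
        assert set(feats) == set(ESEE_FEATURES)

    def test_agrees_with_scipy_and_bruteforce(self, rng):
        durations = rng.uniform(20, 90, size=40)
        events = _events_from_durations("saccade", durations, amplitude=1.0,
                                        distance=1.0, mean_velocity=10.0,
                                        peak_velocity=20.0)
        rec = _recording(np.zeros(100))
        feats = extract_esee_features(events, rec)
        m = durations.mean()
        v = ((durations - m) ** 2).mean()
        assert abs(feats["saccade_duration_cv"] - np.sqrt(v) / m) < 1e-10
        assert feats["saccade_duration_kurt"] == pytest.approx(
            stats.kurtosis(durations, fisher=True, bias=False), abs=1e-12)


class TestAnovaScreen:
    @staticmethod
    def _table(columns, labels):
        return FeatureTable(pd.DataFrame(columns), np.asarray(labels),
                            np.zeros(len(labels), dtype=int))

    def test_worked_two_group_example(self):
        tab = self._table({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                          [0, 0, 0, 1, 1, 1])
        kept, report = anova_screen(tab, alpha=0.05)
        row = report.iloc[0]
        assert row.F == pytest.approx(13.5)
        assert row.p == pytest.approx(0.02131164, abs=1e-6)
        assert row.retained and "f" in kept.feature_names

    def test_constant_feature_dropped_with_reason(self):
        tab = self._table({"c": [1.0] * 6, "good": [0, 0, 0, 5, 5, 5]},
                          [0, 0, 0, 1, 1, 1])
        kept, report = anova_screen(tab)
        rep = report.set_index("feature")
        assert not rep.loc["c"].retained
        assert rep.loc["c"].reason == "constant feature"
        assert "c" not in kept.feature_names

    def test_class_index_feature_retained(self):
        labels = np.repeat([0, 1, 2], 4)
        tab = self._table({"idx": labels.astype(float)}, labels)
        _, report = anova_screen(tab)
        assert report.iloc[0].retained
        assert report.iloc[0].p < 1e-12

    def test_matches_bruteforce_sum_of_squares(self, rng):
        labels = rng.integers(0, 3, size=60)
        labels[:3] = [0, 1, 2]
        col = rng.normal(size=60) + labels * 0.5
        tab = self._table({"f": col}, labels)
        _, report = anova_screen(tab)
        grand = col.mean()
        groups = [col[labels == c] for c in range(3)]
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb, dfw = 2, len(col) - 3
        f_brute = (ssb / dfb) / (ssw / dfw)
        p_brute = stats.f.sf(f_brute, dfb, dfw)
        assert report.iloc[0].F == pytest.approx(f_brute, abs=1e-10)
        assert report.iloc[0].p == pytest.approx(p_brute, abs=1e-10)

    def test_single_class_rejected(self):
        tab = self._table({"f": [1.0, 2.0]}, [0, 0])
        with pytest.raises(ValueError):
            anova_screen(tab)


class TestRussellMapping:
    @pytest.mark.parametrize("emotion,expected", [
        ("anger", ("HA", "NV")),
        ("disgust", ("HA", "NV")),
        ("sadness", ("LA", "NV")),
        ("tenderness", ("LA", "PV")),
        ("neutral", ("MA", "MV")),
    ])
    def test_circumplex_placement(self, emotion, expected):
        a, v = map_to_russell([emotion])
        assert (a[0], v[0]) == expected

    def test_total_on_five_labels_with_three_classes_each(self):
        labels = ["anger", "disgust", "sadness", "tenderness", "neutral"]
        arousal, valence = map_to_russell(labels)
        assert set(arousal) == {"LA", "MA", "HA"}
        assert set(valence) == {"NV", "MV", "PV"}

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="joy"):
            map_to_russell(["joy"])
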