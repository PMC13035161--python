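"""Signal conditioning chain: filter, masking, onsets, normalization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseage import cohort
from pulseage import preprocess as pre


class TestBandpass:
    def test_dc_rejected(self):
        out = pre.bandpass(np.full(2560, 5.0), 256.0)
        assert np.max(np.abs(out)) < 1e-6 * 5.0

    @pytest.mark.parametrize(
        "freq,min_gain,max_gain",
        [
            (1.0, 0.9, 1.1),  # mid-passband
            (10.0, 0.85, 1.1),
            (0.01, 0.0, 0.032),  # below the 0.05 Hz stopband edge
        ],
    )
    def test_sine_steady_state_gain(self, freq, min_gain, max_gain):
        # oracle: steady-state response of the designed filter measured
        # directly on a long sine, mid-section only
        fs = 256.0
        t = np.arange(0, 400.0, 1 / fs)
        out = pre.bandpass(np.sin(2 * np.pi * freq * t), fs)
        mid = out[len(out) // 3 : 2 * len(out) // 3]
        gain = np.max(np.abs(mid))
        assert min_gain <= gain <= max_gain

    def test_low_rate_rejected(self):
        with pytest.raises(pre.UnsupportedRateError):
            pre.bandpass(np.zeros(100), 40.0)

    def test_preserves_length(self):
        x = np.random.default_rng(0).normal(size=1000)
        assert len(pre.bandpass(x, 256.0)) == 1000


class TestArtifactMask:
    def test_all_zero_signal_unmasked(self):
        assert not pre.artifact_mask(np.zeros(5000), 256.0).any()

    def test_clean_signal_mostly_unmasked(self, participant, clean_config):
        rec = cohort.simulate_recording(
            participant, "fingertip", clean_config, seed=1)
        filt = pre.bandpass(rec.samples, rec.fs)
        mask = pre.artifact_mask(filt, rec.fs)
        assert mask.mean() < 0.01

    def test_injected_artifact_masked(self, participant, clean_config):
        cfg = replace(clean_config, artifact_rate_per_min=2.0,
                      night_duration_s=180.0)
        rec = cohort.simulate_recording(participant, "fingertip", cfg, seed=6)
        assert rec.truth.artifact_spans, "generator must inject artifacts"
        filt = pre.bandpass(rec.samples, rec.fs)
        mask = pre.artifact_mask(filt, rec.fs)
        for a, b in rec.truth.artifact_spans:
            assert mask[a:b].mean() > 0.5, "artifact span must be masked"


class TestSegmentWindows:
    @pytest.mark.parametrize("seconds,expected", [(300, 10), (299, 9)])
    def test_window_count_floor_rule(self, seconds, expected):
        fs = 256.0
        n = int(seconds * fs) + 2
        rec = cohort.RawRecording(
            participant_id="w", device="fingertip", fs=fs,
            samples=np.zeros(n), lights_off=0, lights_on=int(seconds * fs),
        )
        assert len(pre.segment_windows(rec)) == expected

    def test_artifact_flagging(self):
        fs = 256.0
        n = int(90 * fs)
        rec = cohort.RawRecording(
            participant_id="w", device="fingertip", fs=fs,
            samples=np.zeros(n), lights_off=0, lights_on=n,
        )
        mask = np.zeros(n, dtype=bool)
        mask[: int(30 * fs)] = True  # first window fully masked
        wins = pre.segment_windows(rec, mask=mask)
        assert [w.artifact for w in wins] == [True, False, False]

    def test_bad_markers_rejected(self):
        rec = cohort.RawRecording(
            participant_id="w", device="fingertip", fs=10.0,
            samples=np.zeros(100), lights_off=0, lights_on=100,
        )
        rec.lights_on = 500  # corrupt after construction
        with pytest.raises(ValueError):
            pre.segment_windows(rec)


class TestDetectOnsets:
    def test_flat_window_empty(self):
        assert len(pre.detect_onsets(np.zeros(7500), 256.0)) == 0

    @pytest.mark.parametrize("device", ["fingertip", "ring"])
    def test_clean_window_onsets_match_truth(self, device, participant,
                                             clean_config):
        rec = cohort.simulate_recording(participant, device, clean_config,
                                        seed=42)
        filt = pre.bandpass(rec.samples, rec.fs)
        windows = pre.segment_windows(rec, samples=filt)
        for w in windows:
            onsets = pre.detect_onsets(w.samples, w.fs)
            truth = rec.truth.onsets - w.start
            inside = truth[(truth >= 0) & (truth < len(w.samples))]
            assert abs(len(onsets) - len(inside)) <= 1
            tol = 0.040 * w.fs
            for o in onsets:
                assert np.min(np.abs(truth - o)) <= tol

    def test_paired_devices_same_beat_count(self, participant, clean_config):
        counts = {}
        for device in ("fingertip", "ring"):
            rec = cohort.simulate_recording(participant, device, clean_config,
                                            seed=11)
            filt = pre.bandpass(rec.samples, rec.fs)
            w = pre.segment_windows(rec, samples=filt)[1]
            counts[device] = len(pre.detect_onsets(w.samples, w.fs))
        assert abs(counts["fingertip"] - counts["ring"]) <= 1


def brute_force_plausibility(onsets, fs, min_s=0.4, max_s=2.0,
                             max_change=0.40, max_stale=2):
    """Independent literal reimplementation of the interval rules."""
    out = []
    prev = None
    stale = 0
    for i in range(len(onsets) - 1):
        d = (onsets[i + 1] - onsets[i]) / fs
        if d < min_s or d > max_s:
            continue
        ok_rhythm = prev is None or (abs(d - prev) / prev) <= max_change
        if ok_rhythm or stale >= max_stale:
            out.append((int(onsets[i]), int(onsets[i + 1])))
            prev = d
            stale = 0
        else:
            stale += 1
    return out


class TestPlausibilityFilter:
    def test_printed_bound_examples(self):
        fs = 100.0
        onsets = np.cumsum([0, 30, 80, 250])  # intervals 0.3, 0.8, 2.5 s
        kept = pre.plausibility_filter(onsets, fs)
        assert kept == [(30, 110)]  # only the 0.8 s pulse

    def test_forty_percent_rule(self):
        fs = 100.0
        onsets = np.cumsum([0, 100, 100, 145])  # 1.0, 1.0, 1.45 s
        kept = pre.plausibility_filter(onsets, fs)
        assert kept == [(0, 100), (100, 200)]  # 45% change rejected

    def test_single_onset_no_pulses(self):
        assert pre.plausibility_filter(np.array([50]), 100.0) == []

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=260), min_size=0,
                 max_size=40)
    )
    def test_matches_brute_force(self, gaps):
        fs = 100.0
        onsets = np.cumsum([0] + gaps)
        assert pre.plausibility_filter(onsets, fs) == brute_force_plausibility(
            onsets, fs
        )


class TestRemoveBaseline:
    def test_linear_drift_removed(self, morphology):
        fs = 256.0
        beat = cohort.render_pulse(morphology, 1.0, fs)
        sig = np.tile(beat, 10)
        drift = np.linspace(0, 5.0, len(sig))
        onsets = np.arange(10) * len(beat)
        corrected = pre.remove_baseline(sig + drift, onsets)
        # regression slope of the corrected signal at the onset knots
        resid = corrected[onsets]
        slope = np.polyfit(onsets, resid, 1)[0]
        pre_slope = np.polyfit(np.arange(len(sig)), drift, 1)[0]
        assert abs(slope) < 0.01 * pre_slope

    def test_zero_drift_nearly_identity(self, morphology):
        fs = 256.0
        beat = cohort.render_pulse(morphology, 1.0, fs)
        sig = np.tile(beat, 10)
        onsets = np.arange(10) * len(beat)
        corrected = pre.remove_baseline(sig, onsets)
        span = onsets[0], onsets[-1]
        delta = np.abs(corrected[span[0]:span[1]] - sig[span[0]:span[1]])
        assert delta.max() < 0.05 * np.ptp(beat)

    def test_too_few_onsets_rejected(self):
        with pytest.raises(pre.InsufficientOnsetsError):
            pre.remove_baseline(np.zeros(100), np.array([0, 30, 60]))


class TestNormalizePulse:
    def test_linear_ramp_any_length(self):
        for n in (10, 57, 200, 333):
            out = pre.normalize_pulse(np.linspace(3.0, 9.0, n), 1.0)
            assert len(out.values) == 200
            np.testing.assert_allclose(
                out.values, np.linspace(0, 1, 200), atol=1e-6
            )

    def test_flat_segment_rejected(self):
        with pytest.raises(pre.DegeneratePulseError):
            pre.normalize_pulse(np.full(50, 2.0), 1.0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            pre.normalize_pulse(np.arange(5.0), 1.0)

    def test_cross_rate_samplings_agree(self, morphology):
        hi = pre.normalize_pulse(
            cohort.render_pulse(morphology, 0.9, 256.0), 0.9)
        lo = pre.normalize_pulse(
            cohort.render_pulse(morphology, 0.9, 50.0), 0.9)
        r = np.corrcoef(hi.values, lo.values)[0, 1]
        assert r > 0.99


class TestQualityFilter:
    def _pulses(self, n=10):
        rng = np.random.default_rng(0)
        base = np.sin(np.linspace(0, np.pi, 200))
        return [
            pre.NormalizedPulse(values=base + rng.normal(0, 0.005, 200),
                                duration_s=1.0)
            for _ in range(n)
        ]

    def test_identical_pulses_all_accepted(self):
        pulses = self._pulses()
        accepted, report = pre.quality_filter(pulses)
        assert report.n_rejected == 0
        assert len(accepted) == len(pulses)

    def test_noise_pulse_rejected(self):
        pulses = self._pulses()
        rng = np.random.default_rng(1)
        pulses[3] = pre.NormalizedPulse(values=rng.random(200),
                                        duration_s=1.0)
        accepted, report = pre.quality_filter(pulses)
        assert report.n_rejected == 1
        assert all(q is not pulses[3] for q in accepted)

    def test_zero_threshold_accepts_all(self):
        pulses = self._pulses()
        rng = np.random.default_rng(1)
        pulses[3] = pre.NormalizedPulse(values=rng.random(200),
                                        duration_s=1.0)
        accepted, _ = pre.quality_filter(pulses, threshold=-1.0)
        assert len(accepted) == len(pulses)


class TestEndToEnd:
    def test_accepted_pulses_track_truth_beats(self, clean_recording):
        pulses, report, windows = pre.extract_pulses(clean_recording)
        truth = clean_recording.truth.onsets
        for w in windows:
            inside = truth[(truth >= w.start)
                           & (truth < w.start + len(w.samples))]
            got = report.per_window.get(w.index, (0, 0))[0]
            # beats fully inside the window bound the accepted count
            assert abs(got - (len(inside) - 1)) <= 2
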