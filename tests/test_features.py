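"""Dysphonia feature extraction: pitch, pulses, perturbation measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdvoice.features import (
    FULL26_FEATURES,
    OXFORD22_FEATURES,
    ExtractorConfig,
    PulseSequence,
    TooShortError,
    VoiceRecording,
    detect_pitch_frames,
    detect_pulses,
    extract_all,
    harmonicity_features,
    jitter_features,
    pitch_stats,
    shimmer_features,
    voicing_features,
)
from pdvoice.synthetic import VoiceSynthSpec, synth_voice

FS = 22050.0


def make_pulses(periods, amplitudes=None):
    periods = np.asarray(periods, dtype=float)
    times = 0.05 + np.concatenate([[0.0], np.cumsum(periods)])
    if amplitudes is None:
        amplitudes = np.ones(times.size)
    return PulseSequence(pulse_times=times, amplitudes=np.asarray(amplitudes, dtype=float))


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation


def oracle_jitter_local(periods):
    t = np.asarray(periods, dtype=float)
    return np.mean([abs(t[i] - t[i - 1]) for i in range(1, len(t))]) / t.mean()


def oracle_rap(periods):
    t = np.asarray(periods, dtype=float)
    devs = [abs(t[i] - (t[i - 1] + t[i] + t[i + 1]) / 3) for i in range(1, len(t) - 1)]
    return np.mean(devs) / t.mean()


def oracle_ppq5(periods):
    t = np.asarray(periods, dtype=float)
    devs = [abs(t[i] - t[i - 2 : i + 3].mean()) for i in range(2, len(t) - 2)]
    return np.mean(devs) / t.mean()


def oracle_autocorr_peak(x, fs, floor_hz=75.0, ceiling_hz=600.0):
    """Normalised autocorrelation maximum over the pitch lag range."""
    x = x - x.mean()
    full = np.correlate(x, x, "full")[x.size - 1 :]
    r = full / full[0]
    lo, hi = int(fs / ceiling_hz), int(np.ceil(fs / floor_hz))
    return float(r[lo : hi + 1].max())


# ---------------------------------------------------------------------------
# pitch track


class TestDetectPitchFrames:
    def test_pure_sine_fully_voiced_at_150hz(self, sine_recording):
        track = detect_pitch_frames(sine_recording)
        assert track.voiced.all()
        # zero-crossing oracle for the true frequency
        s = sine_recording.samples
        crossings = np.sum((s[:-1] < 0) & (s[1:] >= 0))
        f_true = crossings / sine_recording.duration
        assert np.abs(track.f0[track.voiced] - f_true).max() < 1.0

    def test_silence_is_fully_unvoiced(self):
        track = detect_pitch_frames(VoiceRecording(np.zeros(22050), FS))
        assert not track.voiced.any()
        assert (track.f0 == 0).all()

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        rec = VoiceRecording(rng.normal(size=int(2 * FS)), FS)
        track = detect_pitch_frames(rec, voicing_threshold=0.45)
        assert track.voiced.mean() < 0.2
        # the per-frame strengths agree with a direct autocorrelation of one frame
        n = int(0.04 * FS)
        r_direct = oracle_autocorr_peak(rec.samples[:n], FS)
        assert r_direct < 0.45

    def test_too_short_recording_raises(self):
        with pytest.raises(TooShortError):
            detect_pitch_frames(VoiceRecording(np.zeros(100), FS))

    def test_invalid_pitch_range_raises(self, sine_recording):
        with pytest.raises(ValueError):
            detect_pitch_frames(sine_recording, floor_hz=600, ceiling_hz=75)

    def test_track_invariants(self, clean_voice_track):
        track = clean_voice_track
        assert np.all(np.diff(track.frame_times) > 0)
        assert np.all((track.r_peak >= 0) & (track.r_peak <= 1))
        assert np.all((track.f0 == 0) == ~track.voiced)


# ---------------------------------------------------------------------------
# pulses


class TestDetectPulses:
    def test_counts_match_construction(self, clean_voice, clean_voice_track, clean_voice_pulses):
        _, truth = clean_voice
        assert clean_voice_pulses.n_pulses == truth.n_pulses
        assert clean_voice_pulses.periods.size == clean_voice_pulses.n_pulses - 1

    def test_silence_gives_zero_pulses(self):
        rec = VoiceRecording(np.zeros(22050), FS)
        track = detect_pitch_frames(rec)
        pulses = detect_pulses(rec, track)
        assert pulses.n_pulses == 0

    def test_mean_period_recovered_within_2_percent(self):
        rec, truth = synth_voice(VoiceSynthSpec(f0=100.0, duration=1.5, seed=3))
        track = detect_pitch_frames(rec)
        pulses = detect_pulses(rec, track)
        mean_true = np.diff(truth.pulse_times).mean()
        mean_est = pulses.periods[pulses.valid_period_mask()].mean()
        assert mean_est == pytest.approx(mean_true, rel=0.02)
        assert mean_true == pytest.approx(0.010, rel=0.02)


# ---------------------------------------------------------------------------
# jitter


class TestJitter:
    def test_constant_periods_give_zero(self):
        out = jitter_features(make_pulses([0.01] * 30))
        for value in out.values():
            assert abs(value) < 1e-12  # machine precision of the time grid

    def test_alternating_periods_match_formula(self):
        eps = 0.01
        periods = [0.010 * (1 + eps * (-1) ** i) for i in range(40)]
        out = jitter_features(make_pulses(periods))
        assert out["jitter_local"] == pytest.approx(oracle_jitter_local(periods), rel=1e-12)
        assert out["jitter_local"] == pytest.approx(2 * eps, rel=1e-9)
        assert out["jitter_rap"] == pytest.approx(oracle_rap(periods), rel=1e-12)
        assert out["jitter_ppq5"] == pytest.approx(oracle_ppq5(periods), rel=1e-12)
        assert out["jitter_local_abs"] == pytest.approx(2 * eps * 0.010, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.004, max_value=0.012), min_size=5, max_size=40))
    def test_ddp_is_three_rap_exactly(self, periods):
        out = jitter_features(make_pulses(periods))
        assert out["jitter_ddp"] == 3.0 * out["jitter_rap"]
        assert out["jitter_local"] >= 0

    def test_too_few_periods_flagged_missing(self):
        out = jitter_features(make_pulses([0.01]))
        assert np.isnan(out["jitter_local"])

    def test_breaks_do_not_leak_into_jitter(self):
        # two perfectly steady trains separated by a long gap
        t1 = 0.05 + 0.01 * np.arange(20)
        t2 = t1[-1] + 0.5 + 0.01 * np.arange(20)
        p = PulseSequence(
            pulse_times=np.concatenate([t1, t2]),
            amplitudes=np.ones(40),
            min_period=1 / 600,
            max_period=1.25 / 75,
        )
        assert jitter_features(p)["jitter_local"] < 1e-12


# ---------------------------------------------------------------------------
# shimmer


class TestShimmer:
    def test_constant_amplitudes_give_zero(self):
        out = shimmer_features(make_pulses([0.01] * 30, np.full(31, 0.8)))
        for value in out.values():
            assert abs(value) < 1e-12

    def test_alternating_amplitudes_local_db(self):
        amps = [1.0 if i % 2 == 0 else 1.1 for i in range(31)]
        out = shimmer_features(make_pulses([0.01] * 30, amps))
        assert out["shimmer_local_db"] == pytest.approx(20 * np.log10(1.1), rel=1e-9)
        assert out["shimmer_local"] == pytest.approx(0.1 / np.mean(amps), rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.1, max_value=2.0), min_size=5, max_size=40))
    def test_dda_is_three_apq3_exactly(self, amps):
        out = shimmer_features(make_pulses([0.01] * (len(amps) - 1), amps))
        assert out["shimmer_dda"] == 3.0 * out["shimmer_apq3"]
        assert out["shimmer_local"] >= 0

    def test_zero_amplitude_only_kills_local_db(self):
        amps = [1.0, 0.0, 1.0, 1.0, 1.0, 1.0]
        out = shimmer_features(make_pulses([0.01] * 5, amps))
        assert np.isnan(out["shimmer_local_db"])
        assert np.isfinite(out["shimmer_local"])


# ---------------------------------------------------------------------------
# harmonicity, pitch stats, voicing


class TestHarmonicity:
    def test_half_strength_gives_zero_db(self, clean_voice_track):
        track = clean_voice_track
        import dataclasses

        r = np.where(track.voiced, 0.5, 0.0)
        mod = dataclasses.replace(track, r_peak=r)
        out = harmonicity_features(mod)
        assert out["hnr"] == pytest.approx(0.0, abs=1e-9)
        assert out["nhr"] == pytest.approx(1.0, rel=1e-9)

    def test_pure_sine_exceeds_20db(self, sine_recording):
        track = detect_pitch_frames(sine_recording)
        assert harmonicity_features(track)["hnr"] > 20.0

    def test_nhr_hnr_consistency(self, clean_voice_track):
        out = harmonicity_features(clean_voice_track)
        r = np.clip(clean_voice_track.r_peak[clean_voice_track.voiced], 1e-6, 1 - 1e-6)
        # per-frame identity NHR * (r/(1-r)) = 1 implies the means match oracles
        assert out["nhr"] == pytest.approx(np.mean((1 - r) / r), rel=1e-12)
        assert out["hnr"] == pytest.approx(np.mean(10 * np.log10(r / (1 - r))), rel=1e-12)

    def test_no_voiced_frames_gives_nan(self):
        track = detect_pitch_frames(VoiceRecording(np.zeros(22050), FS))
        assert all(np.isnan(v) for v in harmonicity_features(track).values())


class TestPitchStats:
    def test_constant_track(self, sine_recording):
        track = detect_pitch_frames(sine_recording)
        out = pitch_stats(track)
        assert out["min_pitch"] <= out["median_pitch"] <= out["max_pitch"]
        assert out["mean_pitch"] == pytest.approx(150.0, abs=0.5)
        assert out["sd_pitch"] < 0.5

    def test_two_level_track_matches_formula(self):
        import dataclasses

        track = detect_pitch_frames(VoiceRecording(np.zeros(22050), FS))
        f0 = np.array([100.0, 200.0] * (track.n_frames // 2) + [100.0] * (track.n_frames % 2))
        mod = dataclasses.replace(track, f0=f0, voiced=np.ones(track.n_frames, bool))
        out = pitch_stats(mod)
        assert out["mean_pitch"] == pytest.approx(f0.mean(), rel=1e-12)
        assert out["sd_pitch"] == pytest.approx(np.std(f0, ddof=1), rel=1e-12)


class TestVoicing:
    def test_steady_vowel_fully_voiced(self, clean_voice_track, clean_voice_pulses):
        out = voicing_features(clean_voice_track, clean_voice_pulses)
        assert out["frac_unvoiced"] < 0.1
        assert out["n_voice_breaks"] == 0
        assert out["degree_voice_breaks"] == 0.0

    def test_single_break_detected(self):
        rec, _ = synth_voice(
            VoiceSynthSpec(duration=2.5, break_intervals=((1.0, 1.5),), seed=4)
        )
        track = detect_pitch_frames(rec)
        pulses = detect_pulses(rec, track)
        out = voicing_features(track, pulses)
        assert out["n_voice_breaks"] == 1
        assert 0.0 < out["degree_voice_breaks"] <= 1.0

    def test_all_silence_convention(self):
        rec = VoiceRecording(np.zeros(22050), FS)
        track = detect_pitch_frames(rec)
        pulses = detect_pulses(rec, track)
        out = voicing_features(track, pulses)
        assert out["frac_unvoiced"] == 1.0
        assert out["n_voice_breaks"] == 0


# ---------------------------------------------------------------------------
# full battery


class TestExtractAll:
    def test_full_profile_has_26_named_features(self, clean_voice):
        rec, _ = clean_voice
        vector = extract_all(rec, profile="full26")
        assert len(vector) == 26
        assert vector.names == FULL26_FEATURES

    def test_oxford_profile_has_22_features(self, clean_voice):
        rec, _ = clean_voice
        vector = extract_all(rec, profile="oxford22")
        assert len(vector) == 22
        assert vector.names == OXFORD22_FEATURES

    def test_deterministic(self, clean_voice):
        rec, _ = clean_voice
        v1 = extract_all(rec)
        v2 = extract_all(rec)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_unknown_profile_rejected(self, clean_voice):
        with pytest.raises(ValueError, match="profile"):
            extract_all(clean_voice[0], profile="mdvp")

    def test_silence_keeps_all_features_with_missing_flags(self):
        vector = extract_all(VoiceRecording(np.zeros(22050), FS))
        assert len(vector) == 26
        assert np.isnan(vector["jitter_local"])
        assert vector["frac_unvoiced"] == 1.0


# ---------------------------------------------------------------------------
# extraction-level invariants on synthetic audio


def test_jitter_monotone_in_programmed_sigma():
    extracted = []
    for sigma in (0.005, 0.01, 0.02, 0.04):
        rec, _ = synth_voice(VoiceSynthSpec(jitter_sigma=sigma, seed=2))
        track = detect_pitch_frames(rec)
        extracted.append(jitter_features(detect_pulses(rec, track))["jitter_local"])
    assert all(b > a for a, b in zip(extracted, extracted[1:]))


def test_hnr_decreases_with_additive_noise():
    values = []
    for snr in (40.0, 20.0, 10.0, 5.0):
        rec, _ = synth_voice(VoiceSynthSpec(noise_snr_db=snr, seed=5))
        track = detect_pitch_frames(rec)
        values.append(harmonicity_features(track)["hnr"])
    assert all(b < a for a, b in zip(values, values[1:]))
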