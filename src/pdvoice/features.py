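"""Dysphonia feature extraction from sustained-vowel voice recordings.

Parkinsonian dysphonia shows up in a voice recording as cycle-to-cycle
instability of the glottal source: period perturbation (jitter), amplitude
perturbation (shimmer), increased turbulent noise (lower harmonics-to-noise
ratio), reduced pitch variability and interrupted phonation (voice breaks).
This module measures a fixed battery of 26 such features, organised in six
groups — frequency, harmonicity, pulse, amplitude, pitch and voicing — from a
mono recording, via three intermediate representations:

1. a frame-level pitch/voicing track (:func:`detect_pitch_frames`), computed
   with a windowed, window-autocorrelation-normalised autocorrelation method;
2. a glottal pulse sequence (:func:`detect_pulses`), one waveform peak per
   glottal cycle inside voiced regions;
3. the perturbation statistics themselves, which follow the standard Praat
   conventions for jitter/shimmer quotients (ratio features are reported as
   fractions, not percent; periods in seconds).

The 26-feature battery and a configurable 22-feature subset are assembled by
:func:`extract_all`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from scipy.signal.windows import hann

__all__ = [
    "VoiceRecording",
    "FrameTrack",
    "PulseSequence",
    "DysphoniaVector",
    "ExtractorConfig",
    "TooShortError",
    "FULL26_FEATURES",
    "OXFORD22_FEATURES",
    "detect_pitch_frames",
    "detect_pulses",
    "jitter_features",
    "shimmer_features",
    "harmonicity_features",
    "pitch_stats",
    "voicing_features",
    "extract_all",
]

#: Canonical feature order: Table groups frequency, harmonicity, pulse,
#: amplitude, pitch, voicing.  This order is the schema of every feature
#: table the package writes.
FULL26_FEATURES: tuple[str, ...] = (
    "jitter_local",
    "jitter_local_abs",
    "jitter_rap",
    "jitter_ppq5",
    "jitter_ddp",
    "autocorrelation",
    "nhr",
    "hnr",
    "n_pulses",
    "mean_period",
    "n_periods",
    "sd_period",
    "shimmer_local",
    "shimmer_apq3",
    "shimmer_local_db",
    "shimmer_apq5",
    "shimmer_dda",
    "shimmer_apq11",
    "median_pitch",
    "mean_pitch",
    "min_pitch",
    "max_pitch",
    "sd_pitch",
    "frac_unvoiced",
    "n_voice_breaks",
    "degree_voice_breaks",
)

#: Default 22-feature subset: the full battery minus the two derived
#: redundancies (ddp = 3*rap, dda = 3*apq3) and the two raw counts that scale
#: with recording length.  Configurable in :func:`extract_all`.
OXFORD22_FEATURES: tuple[str, ...] = tuple(
    name
    for name in FULL26_FEATURES
    if name not in ("jitter_ddp", "shimmer_dda", "n_pulses", "n_periods")
)


class TooShortError(ValueError):
    """Recording shorter than a single analysis frame."""


@dataclass(frozen=True)
class VoiceRecording:
    """A mono voice recording: amplitude samples plus sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("VoiceRecording.samples must be one-dimensional (mono)")
        if samples.size < 1:
            raise ValueError("VoiceRecording needs at least one sample")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        """Length in seconds: n_samples / rate."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FrameTrack:
    """Per-frame pitch and voicing decisions.

    ``f0`` is zero exactly on unvoiced frames; ``r_peak`` is the normalised
    autocorrelation maximum in [0, 1] (periodicity strength); ``duration`` is
    the analysed recording length in seconds, carried so that downstream
    voicing statistics can be expressed as fractions of it.
    """

    frame_times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    r_peak: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        for name in ("frame_times", "f0", "r_peak"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        object.__setattr__(self, "voiced", np.asarray(self.voiced, dtype=bool))
        n = self.frame_times.size
        if not (self.f0.size == n and self.voiced.size == n and self.r_peak.size == n):
            raise ValueError("FrameTrack arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any((self.f0 == 0) != ~self.voiced):
            raise ValueError("f0 must be zero exactly on unvoiced frames")
        if np.any((self.r_peak < 0) | (self.r_peak > 1)):
            raise ValueError("r_peak must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass(frozen=True)
class PulseSequence:
    """Glottal pulse events: one time/amplitude pair per detected cycle peak.

    ``periods`` are all successive pulse-time differences; a period is *valid*
    (belongs to an uninterrupted stretch of phonation) when it lies inside
    ``[min_period, max_period]``.  Perturbation measures use valid periods
    only, so a long silent gap between two voiced stretches does not leak
    into jitter.
    """

    pulse_times: np.ndarray
    amplitudes: np.ndarray
    min_period: float | None = None
    max_period: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulse_times", np.asarray(self.pulse_times, dtype=np.float64))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=np.float64))
        if self.pulse_times.size != self.amplitudes.size:
            raise ValueError("pulse_times and amplitudes must align")
        if self.pulse_times.size > 1 and not np.all(np.diff(self.pulse_times) > 0):
            raise ValueError("pulse_times must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("per-cycle amplitudes must be non-negative")

    @property
    def n_pulses(self) -> int:
        return self.pulse_times.size

    @property
    def periods(self) -> np.ndarray:
        """All successive inter-pulse intervals, seconds."""
        return np.diff(self.pulse_times)

    def valid_period_mask(self) -> np.ndarray:
        t = self.periods
        mask = np.ones(t.size, dtype=bool)
        if self.min_period is not None:
            mask &= t >= self.min_period
        if self.max_period is not None:
            mask &= t <= self.max_period
        return mask

    @property
    def n_periods(self) -> int:
        """Number of valid (within-phonation) periods."""
        return int(self.valid_period_mask().sum())


@dataclass(frozen=True)
class DysphoniaVector(Mapping):
    """Named, ordered feature vector for one recording.

    Missing features (too few glottal cycles to evaluate a quotient) are
    encoded as NaN — the designated sentinel throughout the package; consumers
    impute with the training-set median.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size != len(self.names):
            raise ValueError("values must align with names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))

    def __getitem__(self, key: str) -> float:
        try:
            return float(self.values[self.names.index(key)])
        except ValueError as exc:
            raise KeyError(key) from exc

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


@dataclass(frozen=True)
class ExtractorConfig:
    """Analysis parameters for the full extraction pipeline.

    Defaults follow common practice for sustained-vowel analysis: 40 ms Hann
    frames every 10 ms, pitch search range 75–600 Hz, voicing threshold 0.45
    on the normalised autocorrelation peak, and a voice-break threshold of
    1.25 maximum periods (1.25 / floor_hz seconds).
    """

    floor_hz: float = 75.0
    ceiling_hz: float = 600.0
    frame_s: float = 0.04
    hop_s: float = 0.01
    voicing_threshold: float = 0.45
    max_period_factor: float = 1.25
    silence_threshold: float = 0.01


# ---------------------------------------------------------------------------
# pitch / voicing track


def _parabolic_vertex(ym1: float, y0: float, yp1: float) -> tuple[float, float]:
    """Sub-sample offset and value of the parabola through three points."""
    denom = ym1 - 2.0 * y0 + yp1
    if denom >= 0 or not np.isfinite(denom):
        return 0.0, y0
    delta = 0.5 * (ym1 - yp1) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = y0 - 0.25 * (ym1 - yp1) * delta
    return delta, float(value)


def detect_pitch_frames(
    rec: VoiceRecording,
    floor_hz: float = 75.0,
    ceiling_hz: float = 600.0,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    voicing_threshold: float = 0.45,
    silence_threshold: float = 0.01,
) -> FrameTrack:
    """Frame-level F0 and voicing by normalised autocorrelation.

    Each 40 ms frame is mean-subtracted, Hann-windowed and autocorrelated;
    the raw autocorrelation is divided by the window's own autocorrelation
    (removing the triangular taper bias, so a perfectly periodic frame scores
    close to 1).  The maximum over candidate lags in
    ``[rate/ceiling_hz, rate/floor_hz]`` is refined by parabolic
    interpolation; the frame is voiced iff the refined peak reaches
    ``voicing_threshold`` and the frame is not silent relative to the
    recording's global peak.
    """
    fs = rec.rate
    if not (0 < floor_hz < ceiling_hz < fs / 2):
        raise ValueError(
            f"need 0 < floor_hz < ceiling_hz < rate/2; got {floor_hz}, {ceiling_hz}, rate {fs}"
        )
    if frame_s * floor_hz < 2.0:
        raise ValueError(
            f"frame_s={frame_s} too short to hold two periods at floor {floor_hz} Hz"
        )
    n_frame = int(round(frame_s * fs))
    n_hop = max(1, int(round(hop_s * fs)))
    x = rec.samples
    if x.size < n_frame:
        raise TooShortError(
            f"recording of {x.size} samples is too short for one {n_frame}-sample frame"
        )

    lag_lo = max(2, int(np.floor(fs / ceiling_hz)))
    lag_hi = min(n_frame - 2, int(np.ceil(fs / floor_hz)))
    # octave-cost bonus: prefer the shorter-lag candidate when a period and
    # its double are near-equally strong (sub-harmonic ambiguity)
    lags = np.arange(lag_lo, lag_hi + 1)
    octave_bonus = 0.03 * np.log2(fs / (lags * floor_hz))

    starts = np.arange(0, x.size - n_frame + 1, n_hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, n_frame)[starts]
    frames = frames - frames.mean(axis=1, keepdims=True)
    w = hann(n_frame, sym=False)
    windowed = frames * w

    nfft = 1 << int(np.ceil(np.log2(2 * n_frame)))
    spectra = np.fft.rfft(windowed, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spectra) ** 2, nfft, axis=1)[:, :n_frame]
    w_ac = np.fft.irfft(np.abs(np.fft.rfft(w, nfft)) ** 2, nfft)[:n_frame]
    w_ac = w_ac / w_ac[0]

    global_peak = np.max(np.abs(x))
    frame_peaks = np.max(np.abs(frames), axis=1)

    n = starts.size
    f0 = np.zeros(n)
    voiced = np.zeros(n, dtype=bool)
    r_peak = np.zeros(n)
    for i in range(n):
        if global_peak == 0 or frame_peaks[i] < silence_threshold * global_peak:
            continue
        e0 = ac[i, 0]
        if e0 <= 0:
            continue
        r = ac[i] / e0 / w_ac
        seg = r[lag_lo : lag_hi + 1]
        j = int(np.argmax(seg + octave_bonus)) + lag_lo
        delta, value = _parabolic_vertex(r[j - 1], r[j], r[j + 1])
        value = float(np.clip(value, 0.0, 1.0))
        r_peak[i] = value
        if value >= voicing_threshold:
            voiced[i] = True
            f0[i] = fs / (j + delta)

    frame_times = (starts + n_frame / 2.0) / fs
    return FrameTrack(
        frame_times=frame_times,
        f0=f0,
        voiced=voiced,
        r_peak=r_peak,
        duration=rec.duration,
    )


# ---------------------------------------------------------------------------
# glottal pulses


def _voiced_runs(voiced: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) frame-index pairs of maximal voiced stretches."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = voiced.size
    while i < n:
        if voiced[i]:
            j = i
            while j + 1 < n and voiced[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _refine_peak(x: np.ndarray, ip: int, fs: float) -> tuple[float, float]:
    """Sub-sample peak time and amplitude via a parabola on the signed wave."""
    sign = 1.0 if x[ip] >= 0 else -1.0
    if 0 < ip < x.size - 1:
        delta, value = _parabolic_vertex(sign * x[ip - 1], sign * x[ip], sign * x[ip + 1])
    else:
        delta, value = 0.0, sign * x[ip]
    return (ip + delta) / fs, abs(value)


def detect_pulses(
    rec: VoiceRecording,
    track: FrameTrack,
    floor_hz: float = 75.0,
    ceiling_hz: float = 600.0,
    max_period_factor: float = 1.25,
    min_amp_fraction: float = 0.2,
) -> PulseSequence:
    """Locate one waveform peak per glottal cycle in each voiced region.

    Within every maximal run of voiced frames the detector starts at the
    strongest waveform extremum, then marches outward cycle by cycle: the
    next pulse is the largest |x| inside a search window 0.75-1.35 local
    periods away (local period from the interpolated F0 track).  Marching
    stops when the found peak drops below ``min_amp_fraction`` of the run's
    maximum — which rejects the decaying vocal-tract ringing past the final
    glottal cycle.  Peak times and per-cycle amplitudes are refined to
    sub-sample precision by parabolic interpolation of the signed waveform.
    No voiced frames → empty sequence.
    """
    fs = rec.rate
    x = rec.samples
    margin = 0.02  # marching may overshoot the frame grid by this much, s
    times: list[float] = []
    amps: list[float] = []
    for i0, i1 in _voiced_runs(track.voiced):
        f0_frames = track.f0[i0 : i1 + 1]
        f0_times = track.frame_times[i0 : i1 + 1]
        good = f0_frames > 0
        if not good.any():
            continue
        # run-median period: robust to isolated octave errors in the track
        # (adequate for sustained phonation, where F0 is near-constant)
        period = 1.0 / float(np.median(f0_frames[good]))
        t_lo = max(0.0, f0_times[0] - margin)
        t_hi = min(rec.duration, f0_times[-1] + margin)
        s0 = int(np.floor(t_lo * fs))
        s1 = min(x.size, int(np.ceil(t_hi * fs)))
        if s1 - s0 < 3:
            continue
        region = np.abs(x[s0:s1])
        region_peak = region.max()
        if region_peak == 0:
            continue
        floor_amp = min_amp_fraction * region_peak

        i_star = s0 + int(np.argmax(region))
        t_star, a_star = _refine_peak(x, i_star, fs)
        found = [(t_star, a_star)]
        for direction in (+1, -1):
            t = t_star
            while True:
                if direction > 0:
                    w0, w1 = t + 0.75 * period, t + 1.35 * period
                else:
                    w0, w1 = t - 1.35 * period, t - 0.75 * period
                j0 = max(s0, int(np.floor(w0 * fs)))
                j1 = min(s1, int(np.ceil(w1 * fs)) + 1)
                if j1 - j0 < 1:
                    break
                jp = j0 + int(np.argmax(np.abs(x[j0:j1])))
                if np.abs(x[jp]) < floor_amp:
                    break
                t, a = _refine_peak(x, jp, fs)
                found.append((t, a))
        found.sort()
        times.extend(t for t, _ in found)
        amps.extend(a for _, a in found)

    order = np.argsort(times)
    times_arr = np.asarray(times, dtype=float)[order]
    amps_arr = np.asarray(amps, dtype=float)[order]
    # de-duplicate pulses found twice where adjacent regions overlap
    if times_arr.size:
        keep = np.ones(times_arr.size, dtype=bool)
        last = times_arr[0]
        for k in range(1, times_arr.size):
            if times_arr[k] - last < 0.5 / ceiling_hz:
                keep[k] = False
            else:
                last = times_arr[k]
        times_arr, amps_arr = times_arr[keep], amps_arr[keep]
    return PulseSequence(
        pulse_times=times_arr,
        amplitudes=amps_arr,
        min_period=1.0 / ceiling_hz,
        max_period=max_period_factor / floor_hz,
    )


# ---------------------------------------------------------------------------
# perturbation measures

def _valid_runs(values: np.ndarray, valid: np.ndarray) -> list[np.ndarray]:
    """Split a period (or spanned-amplitude) sequence into maximal valid runs."""
    runs: list[np.ndarray] = []
    start = None
    for i, ok in enumerate(valid):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append(values[start:i])
            start = None
    if start is not None:
        runs.append(values[start:])
    return runs


def _ppq(runs: list[np.ndarray], npoints: int, mean_value: float) -> float:
    """N-point period (or amplitude) perturbation quotient over valid runs."""
    half = npoints // 2
    num = 0.0
    count = 0
    for run in runs:
        if run.size < npoints:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(run, npoints)
        centers = run[half : run.size - half]
        num += float(np.sum(np.abs(centers - windows.mean(axis=1))))
        count += centers.size
    if count == 0 or mean_value == 0:
        return float("nan")
    return num / count / mean_value


def jitter_features(p: PulseSequence) -> dict[str, float]:
    """Five frequency-perturbation measures from the glottal periods.

    local      mean absolute difference of consecutive periods over the mean
               period (fraction);
    local_abs  the same numerator in seconds;
    rap        3-point relative average perturbation;
    ppq5       5-point period perturbation quotient;
    ddp        3 × rap (identically).

    Quotients that need more periods than available come back NaN.
    """
    t_all = p.periods
    valid = p.valid_period_mask()
    t = t_all[valid]
    out = {k: float("nan") for k in ("jitter_local", "jitter_local_abs", "jitter_rap", "jitter_ppq5", "jitter_ddp")}
    if t.size < 2:
        return out
    mean_t = float(t.mean())
    runs = _valid_runs(t_all, valid)

    num = 0.0
    count = 0
    for run in runs:
        if run.size >= 2:
            num += float(np.sum(np.abs(np.diff(run))))
            count += run.size - 1
    if count > 0:
        out["jitter_local_abs"] = num / count
        if mean_t > 0:
            out["jitter_local"] = num / count / mean_t

    out["jitter_rap"] = _ppq(runs, 3, mean_t)
    out["jitter_ppq5"] = _ppq(runs, 5, mean_t)
    out["jitter_ddp"] = 3.0 * out["jitter_rap"]
    return out


def shimmer_features(p: PulseSequence) -> dict[str, float]:
    """Six amplitude-perturbation measures from the per-cycle peak amplitudes.

    Amplitude pairs/windows only count when every period they span is valid
    (no voice break inside the window).  ``local_db`` is NaN if a used
    amplitude is zero; ``dda = 3 × apq3`` identically.
    """
    a = p.amplitudes
    keys = ("shimmer_local", "shimmer_local_db", "shimmer_apq3", "shimmer_apq5", "shimmer_apq11", "shimmer_dda")
    out = {k: float("nan") for k in keys}
    if a.size < 2:
        return out
    valid = p.valid_period_mask()
    # amplitude run k..m is usable when periods k..m-1 are all valid
    amp_runs: list[np.ndarray] = []
    start = None
    for i, ok in enumerate(valid):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            amp_runs.append(a[start : i + 1])
            start = None
    if start is not None:
        amp_runs.append(a[start:])
    usable = [run for run in amp_runs if run.size >= 2]
    if not usable:
        return out
    mean_a = float(np.concatenate(usable).mean())

    num = 0.0
    ndb = 0.0
    count = 0
    db_ok = True
    for run in usable:
        d = np.diff(run)
        num += float(np.sum(np.abs(d)))
        count += d.size
        if np.any(run == 0):
            db_ok = False
        else:
            ndb += float(np.sum(np.abs(20.0 * np.log10(run[1:] / run[:-1]))))
    if count > 0 and mean_a > 0:
        out["shimmer_local"] = num / count / mean_a
    if count > 0 and db_ok:
        out["shimmer_local_db"] = ndb / count

    out["shimmer_apq3"] = _ppq(usable, 3, mean_a)
    out["shimmer_apq5"] = _ppq(usable, 5, mean_a)
    out["shimmer_apq11"] = _ppq(usable, 11, mean_a)
    out["shimmer_dda"] = 3.0 * out["shimmer_apq3"]
    return out


def harmonicity_features(track: FrameTrack) -> dict[str, float]:
    """Mean autocorrelation, noise-to-harmonics and harmonics-to-noise ratio.

    Per voiced frame with periodicity strength r (clipped to
    [1e-6, 1 - 1e-6]): HNR = 10 log10(r / (1 - r)) dB and NHR = (1 - r) / r;
    both averaged over voiced frames.  NaN throughout if nothing is voiced.
    """
    r = track.r_peak[track.voiced]
    if r.size == 0:
        return {"autocorrelation": float("nan"), "nhr": float("nan"), "hnr": float("nan")}
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    return {
        "autocorrelation": float(r.mean()),
        "nhr": float(np.mean((1.0 - r) / r)),
        "hnr": float(np.mean(10.0 * np.log10(r / (1.0 - r)))),
    }


def pitch_stats(track: FrameTrack) -> dict[str, float]:
    """Median/mean/min/max/sd of F0 over voiced frames (Hz; sd uses n-1)."""
    f0 = track.f0[track.voiced]
    if f0.size == 0:
        return {k: float("nan") for k in ("median_pitch", "mean_pitch", "min_pitch", "max_pitch", "sd_pitch")}
    return {
        "median_pitch": float(np.median(f0)),
        "mean_pitch": float(f0.mean()),
        "min_pitch": float(f0.min()),
        "max_pitch": float(f0.max()),
        "sd_pitch": float(np.std(f0, ddof=1)) if f0.size > 1 else float("nan"),
    }


def voicing_features(
    track: FrameTrack,
    p: PulseSequence,
    floor_hz: float = 75.0,
    max_period_factor: float = 1.25,
) -> dict[str, float]:
    """Fraction of unvoiced frames, number and degree of voice breaks.

    A voice break is an inter-pulse gap longer than
    ``max_period_factor / floor_hz`` seconds; the degree is the summed break
    time over the analysed duration.  A fully silent recording has, by
    convention, fraction-unvoiced 1 and zero breaks.
    """
    frac_unvoiced = float((~track.voiced).mean()) if track.n_frames else 1.0
    threshold = max_period_factor / floor_hz
    gaps = p.periods
    breaks = gaps[gaps > threshold]
    degree = float(breaks.sum() / track.duration) if breaks.size else 0.0
    return {
        "frac_unvoiced": frac_unvoiced,
        "n_voice_breaks": float(breaks.size),
        "degree_voice_breaks": min(degree, 1.0),
    }


# ---------------------------------------------------------------------------
# full battery


def extract_all(
    rec: VoiceRecording,
    profile: str = "full26",
    config: ExtractorConfig | None = None,
    subset: tuple[str, ...] | None = None,
) -> DysphoniaVector:
    """Extract the complete dysphonia battery from one recording.

    ``profile`` selects ``"full26"`` (all features, canonical order) or
    ``"oxford22"`` (the 22-feature subset; override the membership with
    ``subset``).  Features whose preconditions fail are NaN, never dropped.
    Deterministic: the same recording and configuration give bit-identical
    vectors.
    """
    cfg = config or ExtractorConfig()
    if profile not in ("full26", "oxford22"):
        raise ValueError(f"unknown profile {profile!r}; expected 'full26' or 'oxford22'")

    track = detect_pitch_frames(
        rec,
        floor_hz=cfg.floor_hz,
        ceiling_hz=cfg.ceiling_hz,
        frame_s=cfg.frame_s,
        hop_s=cfg.hop_s,
        voicing_threshold=cfg.voicing_threshold,
        silence_threshold=cfg.silence_threshold,
    )
    pulses = detect_pulses(
        rec,
        track,
        floor_hz=cfg.floor_hz,
        ceiling_hz=cfg.ceiling_hz,
        max_period_factor=cfg.max_period_factor,
    )

    t = pulses.periods[pulses.valid_period_mask()]
    pulse_group = {
        "n_pulses": float(pulses.n_pulses),
        "mean_period": float(t.mean()) if t.size else float("nan"),
        "n_periods": float(pulses.n_periods),
        "sd_period": float(np.std(t, ddof=1)) if t.size > 1 else float("nan"),
    }

    values = {}
    values.update(jitter_features(pulses))
    values.update(harmonicity_features(track))
    values.update(pulse_group)
    values.update(shimmer_features(pulses))
    values.update(pitch_stats(track))
    values.update(voicing_features(track, pulses, cfg.floor_hz, cfg.max_period_factor))

    if profile == "full26":
        names = FULL26_FEATURES
    else:
        names = subset if subset is not None else OXFORD22_FEATURES
        unknown = set(names) - set(FULL26_FEATURES)
        if unknown:
            raise ValueError(f"subset contains unknown features: {sorted(unknown)}")
    return DysphoniaVector(names=names, values=np.array([values[n] for n in names]))
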