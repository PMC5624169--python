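"""Ground-truth generators: pathological voices and two-class feature cohorts.

Every downstream stage is testable without any external recording because the
generators here produce inputs whose answer is known by construction:

* :func:`synth_voice` renders a sustained /a/-like vowel as a glottal pulse
  train (Rosenberg flow derivative excitation through a two-formant filter)
  whose per-cycle periods and amplitudes carry *programmed* jitter and
  shimmer; the exact pulse times and amplitudes are returned alongside the
  waveform, so extractor output can be compared against the perturbation
  actually synthesised.
* :func:`gen_cohort` draws two-class multivariate-normal feature tables in
  the shapes of the two public Parkinson's speech corpora this package
  emulates: a 195-row, 22-feature single-file layout ("oxford") and a
  1040-training / 168-testing row, 26-feature layout with subject structure
  ("istanbul").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import lfilter

from .dataset import LabeledDataset
from .features import FULL26_FEATURES, OXFORD22_FEATURES, PulseSequence, VoiceRecording

__all__ = [
    "VoiceSynthSpec",
    "CohortSpec",
    "IstanbulCohort",
    "synth_voice",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# voice synthesis


@dataclass(frozen=True)
class VoiceSynthSpec:
    """Recipe for one synthetic sustained vowel.

    ``jitter_sigma`` and ``shimmer_sigma`` are the fractional standard
    deviations of the per-cycle period and amplitude; ``noise_snr_db`` adds
    white noise at that signal-to-noise ratio (None = clean);
    ``break_intervals`` lists (start, end) stretches in seconds that are
    silenced after synthesis, emulating voice breaks.
    """

    f0: float = 150.0
    duration: float = 2.0
    rate: float = 22050.0
    jitter_sigma: float = 0.0
    shimmer_sigma: float = 0.0
    noise_snr_db: float | None = None
    break_intervals: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.shimmer_sigma < 0:
            raise ValueError("perturbation sigmas must be non-negative")
        if not 2.0 * self.f0 < self.rate / 2.0:
            raise ValueError(
                f"f0={self.f0} Hz too high for rate {self.rate} (need 2*f0 < rate/2)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


#: Two-formant /a/-like vowel filter: (centre Hz, bandwidth Hz).
_VOWEL_FORMANTS: tuple[tuple[float, float], ...] = ((700.0, 130.0), (1220.0, 70.0))


def _rosenberg_derivative(tau: np.ndarray, t_open: float, t_close: float) -> np.ndarray:
    """Derivative of the Rosenberg glottal-flow pulse on [0, t_open + t_close]."""
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau < t_open)
    out[rising] = (np.pi / (2.0 * t_open)) * np.sin(np.pi * tau[rising] / t_open)
    falling = (tau >= t_open) & (tau < t_open + t_close)
    out[falling] = -(np.pi / (2.0 * t_close)) * np.sin(
        np.pi * (tau[falling] - t_open) / (2.0 * t_close)
    )
    return out


def synth_voice(spec: VoiceSynthSpec) -> tuple[VoiceRecording, PulseSequence]:
    """Render a vowel with programmed perturbations; return waveform + truth.

    The returned :class:`PulseSequence` holds the *programmed* glottal onset
    times and cycle amplitudes (ground truth), not extractor output.  Pulses
    falling inside a break interval are silenced and removed from the truth.
    Pure function of the spec: same spec, same waveform.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.rate
    t0_nominal = 1.0 / spec.f0
    margin = max(0.03, 2.0 * t0_nominal)

    # programmed cycle sequence
    times = [margin]
    amps = []
    while True:
        z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        w = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        period = t0_nominal * (1.0 + spec.jitter_sigma * z)
        amps.append(max(0.05, 1.0 + spec.shimmer_sigma * w))
        nxt = times[-1] + period
        if nxt > spec.duration - margin:
            break
        times.append(nxt)
    pulse_times = np.asarray(times)
    amplitudes = np.asarray(amps[: len(times)])

    # excitation: scaled Rosenberg flow derivative at each glottal onset
    n = int(round(spec.duration * fs))
    grid = np.arange(n) / fs
    excitation = np.zeros(n)
    t_open, t_close = 0.40 * t0_nominal, 0.16 * t0_nominal
    width = int(np.ceil((t_open + t_close) * fs)) + 2
    for t_i, a_i in zip(pulse_times, amplitudes):
        k0 = int(np.floor(t_i * fs))
        k1 = min(n, k0 + width)
        tau = grid[k0:k1] - t_i
        excitation[k0:k1] += a_i * _rosenberg_derivative(tau, t_open, t_close)

    # vowel tract: cascade of two second-order resonators
    signal = excitation
    for freq, bw in _VOWEL_FORMANTS:
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * freq / fs
        signal = lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], signal)

    if spec.noise_snr_db is not None:
        rms = float(np.sqrt(np.mean(signal**2)))
        sigma = rms * 10.0 ** (-spec.noise_snr_db / 20.0)
        signal = signal + rng.normal(0.0, sigma, n)

    keep = np.ones(pulse_times.size, dtype=bool)
    for start, end in spec.break_intervals:
        i0, i1 = int(max(0, start * fs)), int(min(n, end * fs))
        signal[i0:i1] = 0.0
        keep &= ~((pulse_times >= start) & (pulse_times <= end))

    peak = np.max(np.abs(signal))
    if peak > 0:
        signal = signal * (0.9 / peak)

    truth = PulseSequence(
        pulse_times=pulse_times[keep],
        amplitudes=amplitudes[keep],
        min_period=1.0 / 600.0,
        max_period=1.25 / 75.0,
    )
    return VoiceRecording(samples=signal, rate=fs), truth


# ---------------------------------------------------------------------------
# feature-table cohorts

#: Plausible sustained-vowel baselines (healthy speakers) for the 26 features.
_BASE_MEAN = {
    "jitter_local": 0.008,
    "jitter_local_abs": 5.0e-5,
    "jitter_rap": 0.004,
    "jitter_ppq5": 0.0045,
    "jitter_ddp": 0.012,
    "autocorrelation": 0.92,
    "nhr": 0.10,
    "hnr": 18.0,
    "n_pulses": 180.0,
    "mean_period": 0.0065,
    "n_periods": 178.0,
    "sd_period": 3.0e-4,
    "shimmer_local": 0.040,
    "shimmer_apq3": 0.020,
    "shimmer_local_db": 0.35,
    "shimmer_apq5": 0.025,
    "shimmer_dda": 0.060,
    "shimmer_apq11": 0.030,
    "median_pitch": 155.0,
    "mean_pitch": 155.0,
    "min_pitch": 120.0,
    "max_pitch": 200.0,
    "sd_pitch": 25.0,
    "frac_unvoiced": 0.15,
    "n_voice_breaks": 1.0,
    "degree_voice_breaks": 0.05,
}

_BASE_SD = {name: 0.35 * abs(mean) if mean != 0 else 1.0 for name, mean in _BASE_MEAN.items()}

#: Signed dysphonia pattern: +1 where Parkinsonian voices run high (jitter,
#: shimmer, noise, interrupted voicing), -1 where they run low (harmonicity,
#: pitch variability).  Zero elsewhere.
_PD_DIRECTION = {
    "jitter_local": 1.0,
    "jitter_local_abs": 1.0,
    "jitter_rap": 1.0,
    "jitter_ppq5": 1.0,
    "jitter_ddp": 1.0,
    "autocorrelation": -1.0,
    "nhr": 1.0,
    "hnr": -1.0,
    "shimmer_local": 1.0,
    "shimmer_apq3": 1.0,
    "shimmer_local_db": 1.0,
    "shimmer_apq5": 1.0,
    "shimmer_dda": 1.0,
    "shimmer_apq11": 1.0,
    "sd_pitch": -1.0,
    "frac_unvoiced": 1.0,
    "n_voice_breaks": 1.0,
    "degree_voice_breaks": 1.0,
}

#: Feature-group index blocks (frequency, harmonicity, pulse, amplitude,
#: pitch, voicing) in the canonical 26-feature order.
_GROUP_SLICES = (slice(0, 5), slice(5, 8), slice(8, 12), slice(12, 18), slice(18, 23), slice(23, 26))


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-class feature cohort.

    ``effect_size`` scales the signed dysphonia pattern in pooled-standard-
    deviation units (0 = indistinguishable classes; the default 2.0 gives a
    clearly separable cohort).  ``effect_pattern`` overrides the per-feature
    signed multipliers.  Features within a group correlate at
    ``within_group_corr``; each subject adds a shared random offset of
    ``subject_sd`` standard deviations across all their recordings.
    """

    layout: str = "oxford"
    n_pd: int | None = None
    n_healthy: int | None = None
    samples_per_subject: int | None = None
    test_n_pd: int = 14
    test_n_healthy: int = 14
    test_samples_per_subject: int = 6
    effect_size: float = 2.0
    effect_pattern: tuple[float, ...] | None = None
    within_group_corr: float = 0.6
    subject_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("oxford", "istanbul"):
            raise ValueError(f"unknown layout {self.layout!r}")
        for name in ("n_pd", "n_healthy", "samples_per_subject"):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise ValueError(f"{name} must be >= 1")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")

    def resolved_counts(self) -> tuple[int, int, int]:
        """(n_pd, n_healthy, samples_per_subject) with layout defaults."""
        if self.layout == "oxford":
            return (self.n_pd or 147, self.n_healthy or 48, self.samples_per_subject or 1)
        return (self.n_pd or 20, self.n_healthy or 20, self.samples_per_subject or 26)


class IstanbulCohort(NamedTuple):
    train: LabeledDataset
    test: LabeledDataset


def _cohort_distribution(
    names: tuple[str, ...], spec: CohortSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(healthy mean, PD mean, sd vector, covariance Cholesky factor)."""
    full_index = {name: i for i, name in enumerate(FULL26_FEATURES)}
    mean = np.array([_BASE_MEAN[n] for n in names])
    sd = np.array([_BASE_SD[n] for n in names])
    if spec.effect_pattern is not None:
        if len(spec.effect_pattern) != len(names):
            raise ValueError("effect_pattern length must match feature count")
        direction = np.asarray(spec.effect_pattern, dtype=float)
    else:
        direction = np.array([_PD_DIRECTION.get(n, 0.0) for n in names])
    pd_mean = mean + spec.effect_size * direction * sd

    group_of = np.empty(len(FULL26_FEATURES), dtype=int)
    for g, block in enumerate(_GROUP_SLICES):
        group_of[block] = g
    groups = np.array([group_of[full_index[n]] for n in names])
    corr = np.where(groups[:, None] == groups[None, :], spec.within_group_corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sd, sd)
    return mean, pd_mean, sd, np.linalg.cholesky(cov)


def _draw_block(
    rng: np.random.Generator,
    n_subjects: int,
    samples_per_subject: int,
    label: int,
    class_mean: np.ndarray,
    sd: np.ndarray,
    chol: np.ndarray,
    spec: CohortSpec,
    id_prefix: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    d = class_mean.size
    rows = np.empty((n_subjects * samples_per_subject, d))
    ids: list[str] = []
    for s in range(n_subjects):
        offset = spec.subject_sd * sd * rng.standard_normal(d)
        z = rng.standard_normal((samples_per_subject, d))
        rows[s * samples_per_subject : (s + 1) * samples_per_subject] = (
            class_mean + offset + z @ chol.T
        )
        ids.extend([f"{id_prefix}{s:03d}"] * samples_per_subject)
    labels = np.full(n_subjects * samples_per_subject, label)
    return rows, labels, ids


def gen_cohort(spec: CohortSpec) -> LabeledDataset | IstanbulCohort:
    """Draw a synthetic two-class cohort in the requested layout.

    ``oxford`` layout returns one :class:`LabeledDataset` (defaults: 147 PD +
    48 healthy rows, 22 features, one recording per subject).  ``istanbul``
    layout returns an :class:`IstanbulCohort` with a training table
    (defaults: 20 + 20 subjects x 26 recordings = 1040 rows, 26 features)
    and a disjoint test table (defaults: 28 subjects x 6 recordings = 168
    rows).  Class assignment is at subject level.  Pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    names = OXFORD22_FEATURES if spec.layout == "oxford" else FULL26_FEATURES
    mean_h, mean_pd, sd, chol = _cohort_distribution(names, spec)
    n_pd, n_healthy, per_subject = spec.resolved_counts()

    def build(n_pd_s: int, n_h_s: int, k: int, prefix: str) -> LabeledDataset:
        x_pd, y_pd, id_pd = _draw_block(rng, n_pd_s, k, 1, mean_pd, sd, chol, spec, f"{prefix}pd")
        x_h, y_h, id_h = _draw_block(rng, n_h_s, k, 0, mean_h, sd, chol, spec, f"{prefix}hc")
        return LabeledDataset(
            features=np.vstack([x_pd, x_h]),
            labels=np.concatenate([y_pd, y_h]),
            feature_names=names,
            subject_ids=np.array(id_pd + id_h),
        )

    if spec.layout == "oxford":
        return build(n_pd, n_healthy, per_subject, "ox-")
    train = build(n_pd, n_healthy, per_subject, "tr-")
    test = build(spec.test_n_pd, spec.test_n_healthy, spec.test_samples_per_subject, "te-")
    return IstanbulCohort(train=train, test=test)
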