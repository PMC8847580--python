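"""Synthetic multi-subject EEG-like cohorts.

Each subject owns a stationary spectral signature: a set of oscillators whose
center frequencies are drawn from a subject-specific band, disjoint between
subjects.  Sessions of the same subject share the signature but redraw phases
and noise, mimicking session-to-session variability of a rest-state
recording.  A channel-mixing matrix controls inter-channel redundancy and
``noise_sd`` dials separability, so channel selection, training, threshold
calibration, and open-set evaluation are all testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CohortSpecError
from .preprocess import WindowParams
from .signal_io import EegRecording

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "planted_selection_cohort",
    "subject_ids",
    "sessions_of",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Subject ``i`` receives the ``i``-th of ``n_subjects`` equal disjoint
    sub-bands of ``freq_band_hz``; every channel of that subject carries
    ``oscillators_per_channel`` sinusoids at frequencies drawn (once, from
    the subject seed) inside that sub-band, plus harmonic overtones.
    ``mixing`` (optional ``n_channels x n_channels`` matrix) linearly mixes
    the per-channel latent sources to create redundancy; ``noise_sd`` scales
    i.i.d. session noise added on top.
    """

    n_subjects: int
    n_channels: int
    duration_s: float
    sample_rate_hz: float = 160.0
    seed: int = 0
    n_sessions: int = 2
    freq_band_hz: tuple[float, float] = (4.0, 40.0)
    oscillators_per_channel: int = 3
    harmonic_gain: float = 0.5
    phase_jitter: float = 0.03
    mixing: np.ndarray | None = None
    noise_sd: float = 0.1
    informative_channel: int | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortSpecError("a cohort needs at least 2 subjects")
        if self.n_channels < 1:
            raise CohortSpecError("n_channels must be >= 1")
        if self.duration_s <= 0:
            raise CohortSpecError("duration_s must be positive")
        n_samples = int(round(self.duration_s * self.sample_rate_hz))
        if n_samples < 2 * WindowParams().gamma:
            raise CohortSpecError(
                "duration too short for two disjoint default-length windows "
                f"({n_samples} samples < 2 x {WindowParams().gamma})"
            )
        if self.mixing is not None:
            m = np.asarray(self.mixing)
            if m.shape != (self.n_channels, self.n_channels):
                raise CohortSpecError(
                    f"mixing matrix shape {m.shape} != "
                    f"({self.n_channels}, {self.n_channels})"
                )
        if self.informative_channel is not None and not (
            0 <= self.informative_channel < self.n_channels
        ):
            raise CohortSpecError("informative_channel out of range")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise CohortSpecError("channel_names length != n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def band_of(self, subject: int) -> tuple[float, float]:
        # sub-bands are assigned through a seed-derived permutation so that a
        # subject-index split (first n = training cohort) still leaves the
        # held-out subjects spectrally interspersed with the trained ones
        lo, hi = self.freq_band_hz
        width = (hi - lo) / self.n_subjects
        perm = np.random.default_rng((self.seed, 77)).permutation(self.n_subjects)
        b = int(perm[subject])
        return lo + b * width, lo + (b + 1) * width


def _default_channel_names(n: int) -> list[str]:
    return [f"CH{i:02d}" for i in range(n)]


def subject_ids(spec_or_n) -> list[str]:
    n = spec_or_n.n_subjects if isinstance(spec_or_n, CohortSpec) else int(spec_or_n)
    return [f"S{i:03d}" for i in range(n)]


def sessions_of(cohort: list[EegRecording], subject_id: str) -> list[EegRecording]:
    """All recordings of one subject, ordered by session index."""
    recs = [r for r in cohort if r.subject_id == subject_id]
    return sorted(recs, key=lambda r: r.meta.get("session", 0))


def _subject_signature(spec: CohortSpec, subject: int) -> tuple[np.ndarray, np.ndarray]:
    """Session-stable oscillator set of one subject.

    Frequencies are drawn inside the subject's sub-band; per-oscillator
    amplitudes in [0.5, 1.5] give each subject a stable spectral shape that
    survives the per-session phase redraws.  Returns ``(freqs, amps)`` of
    shape ``(n_channels, oscillators_per_channel)``.
    """
    rng = np.random.default_rng((spec.seed, 1000 + subject))
    lo, hi = spec.band_of(subject)
    freqs = rng.uniform(lo, hi, size=(spec.n_channels, spec.oscillators_per_channel))
    amps = rng.uniform(0.5, 1.5, size=freqs.shape)
    return freqs, amps


def _latent_sources(spec: CohortSpec, freqs: np.ndarray, amps: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-channel oscillator sources for one session, shape (C, n_samples)."""
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    latent = np.zeros((spec.n_channels, spec.n_samples))
    for c in range(spec.n_channels):
        for f, a in zip(freqs[c], amps[c]):
            phase = rng.uniform(0, 2 * np.pi)
            drift = np.cumsum(rng.normal(0.0, spec.phase_jitter, spec.n_samples))
            latent[c] += a * np.sin(2 * np.pi * f * t + phase + drift)
            if spec.harmonic_gain > 0:
                phase2 = rng.uniform(0, 2 * np.pi)
                latent[c] += a * spec.harmonic_gain * np.sin(
                    2 * np.pi * 2 * f * t + phase2 + drift
                )
    return latent


def generate_cohort(spec: CohortSpec) -> list[EegRecording]:
    """Generate ``n_subjects x n_sessions`` recordings, subject-major.

    Fully reproducible from ``spec.seed``: the subject sub-seed fixes the
    oscillator frequencies (the signature), the session sub-seed redraws
    phases and noise.
    """
    names = list(spec.channel_names or _default_channel_names(spec.n_channels))
    mixing = None if spec.mixing is None else np.asarray(spec.mixing, dtype=np.float64)
    cohort: list[EegRecording] = []
    for s, sid in enumerate(subject_ids(spec)):
        freqs, amps = _subject_signature(spec, s)
        for sess in range(spec.n_sessions):
            rng = np.random.default_rng((spec.seed, 2000 + s, sess))
            latent = _latent_sources(spec, freqs, amps, rng)
            data = latent if mixing is None else mixing @ latent
            if spec.noise_sd > 0:
                data = data + rng.normal(0.0, spec.noise_sd, data.shape)
            cohort.append(EegRecording(
                subject_id=sid,
                sample_rate_hz=spec.sample_rate_hz,
                channel_names=list(names),
                data=data,
                meta={"session": sess, "seed": spec.seed},
            ))
    return cohort


def planted_selection_cohort(
    n_subjects: int,
    n_channels: int,
    informative_channel: int | None,
    seed: int,
    duplicate_channel: int | None = None,
    duration_s: float = 12.0,
    sample_rate_hz: float = 160.0,
    n_sessions: int = 1,
    noise_sd: float = 0.15,
    weak_channel_gain: float = 0.0,
    weak_channel_noise_sd: float = 1.0,
) -> list[EegRecording]:
    """Cohort where only one channel carries subject-specific signal.

    The informative channel holds the subject's oscillators (plus weak
    noise); every other channel is i.i.d. Gaussian noise independent of the
    subject.  ``informative_channel=None`` yields a noise-only cohort (chance
    -level separability everywhere).  ``duplicate_channel`` makes that channel
    an exact copy of the informative one, for redundancy tests; setting
    ``weak_channel_gain > 0`` additionally buries an attenuated copy of
    subject signal in the remaining noise channels, so they carry real (if
    weak) incremental information that a fully redundant duplicate lacks.
    """
    if informative_channel is not None and not 0 <= informative_channel < n_channels:
        raise CohortSpecError("informative_channel out of range")
    if duplicate_channel is not None:
        if informative_channel is None:
            raise CohortSpecError("duplicate_channel requires an informative channel")
        if duplicate_channel == informative_channel or not (
            0 <= duplicate_channel < n_channels
        ):
            raise CohortSpecError("duplicate_channel invalid")

    spec = CohortSpec(
        n_subjects=n_subjects,
        n_channels=n_channels,
        duration_s=duration_s,
        sample_rate_hz=sample_rate_hz,
        seed=seed,
        n_sessions=n_sessions,
        noise_sd=noise_sd,
    )
    names = _default_channel_names(n_channels)
    cohort: list[EegRecording] = []
    for s, sid in enumerate(subject_ids(spec)):
        freqs, amps = _subject_signature(spec, s)
        for sess in range(n_sessions):
            rng = np.random.default_rng((seed, 2000 + s, sess))
            data = rng.normal(0.0, 1.0, (n_channels, spec.n_samples))
            if informative_channel is not None:
                latent = _latent_sources(spec, freqs, amps, rng)
                if weak_channel_gain > 0:
                    data = weak_channel_gain * latent + rng.normal(
                        0.0, weak_channel_noise_sd, data.shape
                    )
                data[informative_channel] = latent[informative_channel] + rng.normal(
                    0.0, noise_sd, spec.n_samples
                )
                if duplicate_channel is not None:
                    data[duplicate_channel] = data[informative_channel].copy()
            cohort.append(EegRecording(
                subject_id=sid,
                sample_rate_hz=sample_rate_hz,
                channel_names=list(names),
                data=data,
                meta={"session": sess, "seed": seed,
                      "informative_channel": informative_channel,
                      "duplicate_channel": duplicate_channel},
            ))
    return cohort
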