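"""Synthetic EEG cohorts with controlled per-band power.

Each recording is a sum of band-limited Gaussian noise components — one per
EEG band, each scaled so its RMS is proportional to the square root of the
requested relative power — plus an optional mains sinusoid and broadband
white noise. Band-limited noise (rather than pure tones) keeps the wavelet
entropy features informative instead of degenerate.

The default class profiles are a synthetic convention, not a physiological
claim: the "apnea-like" profile shifts power toward the slow delta/theta
bands, the "normal" profile toward alpha/beta. Per-recording lognormal
jitter makes features vary within a class, and a jitter of 0 with identical
profiles gives an exchangeable null cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .io import Recording, write_edf
from .wpd import BAND_NAMES, DEFAULT_BANDS

__all__ = [
    "SynthSpec",
    "CohortSpec",
    "APNEA_PROFILE",
    "NORMAL_PROFILE",
    "generate_recording",
    "generate_cohort",
    "export_cohort_edf",
]

#: Class-conditional relative band powers (synthetic convention).
APNEA_PROFILE: dict[str, float] = {
    "delta": 3.0, "theta": 2.0, "alpha": 0.5, "beta": 0.3, "gamma": 0.1,
}
NORMAL_PROFILE: dict[str, float] = {
    "delta": 0.8, "theta": 0.6, "alpha": 2.5, "beta": 1.8, "gamma": 0.3,
}

_BAND_EDGES = {b.name: (b.lo, b.hi) for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class SynthSpec:
    """One synthetic recording: rate, duration, band powers, artifacts, seed.

    ``band_power`` maps band name to nonnegative relative power (need not
    sum to 1); ``mains_amplitude`` is the peak amplitude (µV) of an injected
    50 Hz artifact; ``noise_sd`` the σ of added broadband white noise.
    """

    fs: float = 200.0
    duration_s: float = 30.0
    band_power: Mapping[str, float] = field(default_factory=lambda: dict(NORMAL_PROFILE))
    mains_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be > 0")
        if any(v < 0 for v in self.band_power.values()):
            raise ValueError("band powers must be nonnegative")
        unknown = set(self.band_power) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")


@dataclass(frozen=True)
class CohortSpec:
    """A labeled two-class cohort of synthetic recordings.

    ``jitter_sigma`` is the σ of per-recording lognormal jitter applied to
    each band power, so features vary within a class.
    """

    n_per_class: int = 20
    class_profiles: Mapping[str, SynthSpec] = field(default_factory=lambda: {
        "apnea": SynthSpec(band_power=dict(APNEA_PROFILE)),
        "normal": SynthSpec(band_power=dict(NORMAL_PROFILE)),
    })
    jitter_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if set(self.class_profiles) != {"apnea", "normal"}:
            raise ValueError("class_profiles must have exactly the labels 'apnea' and 'normal'")


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi) Hz (zero-phase)."""
    nyq = fs / 2
    hi = min(hi, 0.99 * nyq)
    lo = max(lo, 0.0)
    x = rng.standard_normal(n)
    if lo <= 0.05:
        sos = signal.butter(4, hi, btype="lowpass", fs=fs, output="sos")
    elif hi >= 0.99 * nyq - 1e-9:
        sos = signal.butter(4, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / rms if rms > 0 else y


def generate_recording(spec: SynthSpec, subject_id: str = "synth",
                       channel: str = "C3-A2",
                       label: str | None = None) -> Recording:
    """Generate one recording from a :class:`SynthSpec`; seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration_s))
    x = np.zeros(n)
    nyq = spec.fs / 2
    for band in BAND_NAMES:  # fixed order => reproducible rng stream
        power = float(spec.band_power.get(band, 0.0))
        if power <= 0:
            continue
        lo, hi = _BAND_EDGES[band]
        if lo >= nyq:
            warnings.warn(
                f"band {band} [{lo}, {hi}) Hz lies above Nyquist ({nyq} Hz); skipped",
                stacklevel=2,
            )
            continue
        x += np.sqrt(power) * _band_noise(rng, n, spec.fs, lo, hi)
    if spec.mains_amplitude > 0:
        t = np.arange(n) / spec.fs
        x += spec.mains_amplitude * np.sin(2 * np.pi * 50.0 * t)
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(n)
    return Recording(subject_id=subject_id, channel=channel, fs=spec.fs,
                     samples=x, label=label)


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``n_per_class`` recordings per label with per-recording jitter.

    Child seeds are spawned deterministically from ``spec.seed``; recordings
    are returned grouped by label, in subject-id order.
    """
    out: list[Recording] = []
    for label in ("apnea", "normal"):
        profile = spec.class_profiles[label]
        # independent, reproducible per-recording streams
        ss = np.random.SeedSequence([spec.seed, 0 if label == "apnea" else 1])
        seeds = ss.generate_state(2 * spec.n_per_class)
        for i in range(spec.n_per_class):
            jit_rng = np.random.default_rng(int(seeds[2 * i]))
            powers = {
                b: float(p * np.exp(jit_rng.normal(0.0, spec.jitter_sigma)))
                for b, p in profile.band_power.items()
            }
            rec_spec = replace(profile, band_power=powers,
                               seed=int(seeds[2 * i + 1]) % (2 ** 31))
            out.append(generate_recording(
                rec_spec, subject_id=f"{label}_{i:03d}", label=label))
    return out


def export_cohort_edf(recordings: Sequence[Recording], out_dir: str | Path) -> Path:
    """Write each recording as ``<subject_id>.edf`` plus a ``labels.csv`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_edf(out_dir / f"{rec.subject_id}.edf", rec)
        rows.append(f"{rec.subject_id},{rec.label or ''}")
    (out_dir / "labels.csv").write_text(
        "subject_id,label\n" + "\n".join(rows) + "\n")
    return out_dir
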