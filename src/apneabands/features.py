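"""Per-band entropy/energy features and band-ratio indices.

Fourteen features per recording: Shannon wavelet entropy and energy of each
of the five EEG bands, plus four named band-energy ratios — "heart rate"
theta/alpha, "brain perfusion" alpha/delta, "neural activity" beta/theta and
"synchronization" delta/theta.

Entropy is computed on unit-L2-normalized coefficients, so the squared
coefficients form a probability distribution and H lies in [0, ln N]; the
unnormalized variant would be scale-dependent and could go negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .wpd import BAND_NAMES, BandCoefficients

__all__ = [
    "FEATURE_COLUMNS",
    "RATIO_NAMES",
    "FeatureVector",
    "entropy",
    "energy",
    "band_ratios",
    "feature_vector",
    "aggregate_recording",
    "features_table",
]

RATIO_NAMES = (
    "heart_rate_ratio",
    "brain_perfusion_ratio",
    "neural_activity_ratio",
    "synchronization_ratio",
)

#: Fixed column order of the 14 numeric features in tables and CSV output.
FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"entropy_{b}" for b in BAND_NAMES)
    + tuple(f"energy_{b}" for b in BAND_NAMES)
    + RATIO_NAMES
)

#: Guard added to ratio denominators so degenerate (all-zero) bands yield 0/eps.
RATIO_EPS = 1e-12


@dataclass
class FeatureVector:
    """The 14 named features of one epoch or one recording."""

    subject_id: str
    label: str | None
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_COLUMNS) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"subject_id": self.subject_id, "label": self.label,
             **{c: self.values[c] for c in FEATURE_COLUMNS}}
        )


def entropy(coeffs: Sequence[float], base: float = math.e) -> float:
    """Shannon wavelet entropy of a coefficient vector.

    Coefficients are normalized to unit L2 norm so q_i = p_i^2 is a
    probability distribution; returns -sum q_i log q_i with 0·log 0 := 0.
    An all-zero vector has entropy 0 (a degenerate point distribution).
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("entropy of an empty coefficient vector is undefined")
    total = np.dot(c, c)
    if total == 0.0:
        return 0.0
    q = c * c / total
    nz = q[q > 0]
    return float(-np.sum(nz * np.log(nz)) / math.log(base))


def energy(coeffs: Sequence[float]) -> float:
    """Band energy: the sum of squared coefficients (empty band -> 0)."""
    c = np.asarray(coeffs, dtype=float)
    return float(np.dot(c, c))


def band_ratios(band_energies: Mapping[str, float],
                eps: float = RATIO_EPS) -> dict[str, float]:
    """The four named band-energy ratios, denominators guarded by ``eps``."""
    missing = set(BAND_NAMES) - set(band_energies)
    if missing:
        raise KeyError(f"missing band energies: {sorted(missing)}")
    e = band_energies
    return {
        "heart_rate_ratio": e["theta"] / (e["alpha"] + eps),
        "brain_perfusion_ratio": e["alpha"] / (e["delta"] + eps),
        "neural_activity_ratio": e["beta"] / (e["theta"] + eps),
        "synchronization_ratio": e["delta"] / (e["theta"] + eps),
    }


def feature_vector(bc: BandCoefficients, subject_id: str,
                   label: str | None = None) -> FeatureVector:
    """Assemble the 14-feature vector from one epoch's band coefficients."""
    missing = set(BAND_NAMES) - set(bc.coeffs)
    if missing:
        raise ValueError(f"missing bands: {sorted(missing)}")
    values: dict[str, float] = {}
    energies: dict[str, float] = {}
    for b in BAND_NAMES:
        c = bc.coeffs[b]
        values[f"entropy_{b}"] = entropy(c) if c.size else 0.0
        energies[b] = energy(c)
        values[f"energy_{b}"] = energies[b]
    values.update(band_ratios(energies))
    return FeatureVector(subject_id=subject_id, label=label, values=values)


def aggregate_recording(per_epoch: Sequence[FeatureVector]) -> FeatureVector:
    """Recording-level features: the per-feature mean across its epochs."""
    if not per_epoch:
        raise ValueError("cannot aggregate an empty epoch sequence")
    subjects = {fv.subject_id for fv in per_epoch}
    if len(subjects) != 1:
        raise ValueError(f"epochs from multiple subjects: {sorted(subjects)}")
    labels = {fv.label for fv in per_epoch}
    if len(labels) != 1:
        raise ValueError("epochs carry inconsistent labels")
    mean = {
        c: float(np.mean([fv.values[c] for fv in per_epoch]))
        for c in FEATURE_COLUMNS
    }
    return FeatureVector(subject_id=per_epoch[0].subject_id,
                         label=per_epoch[0].label, values=mean)


def features_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical feature table."""
    if not vectors:
        return pd.DataFrame(columns=["subject_id", "label", *FEATURE_COLUMNS])
    return pd.DataFrame([fv.as_series() for fv in vectors]).reset_index(drop=True)
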