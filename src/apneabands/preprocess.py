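"""Powerline-interference removal.

A second-order IIR notch (design from center frequency and quality factor)
applied forward-backward, so the filtered epoch stays phase-aligned with the
raw one — wavelet coefficients downstream are not shifted by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Epoch

__all__ = ["NotchSpec", "apply_notch"]


@dataclass(frozen=True)
class NotchSpec:
    """Notch configuration: center frequency f0 (Hz), quality factor q, rate fs.

    Defaults target 50 Hz mains; set ``f0=60`` for 60 Hz regions. Larger q
    narrows the stopband (q = f0 / bandwidth at -3 dB).
    """

    f0: float = 50.0
    q: float = 30.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.fs / 2:
            raise ValueError(
                f"notch frequency must lie in (0, Nyquist={self.fs / 2} Hz), got {self.f0}"
            )
        if self.q <= 0:
            raise ValueError("quality factor must be > 0")


def apply_notch(epoch: Epoch, spec: NotchSpec) -> Epoch:
    """Return the epoch with the mains component suppressed, same length."""
    if spec.fs != epoch.fs:
        raise ValueError(f"spec.fs={spec.fs} does not match epoch.fs={epoch.fs}")
    b, a = signal.iirnotch(spec.f0, spec.q, fs=spec.fs)
    filtered = signal.filtfilt(b, a, np.asarray(epoch.samples, dtype=float))
    return Epoch(epoch.parent_subject_id, epoch.index, epoch.fs, filtered)
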