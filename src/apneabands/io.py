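"""EDF ingestion, label sidecars, and epoch segmentation.

Recordings are single-channel EEG time series in microvolts. EDF files are
read through :mod:`mne`; a minimal plain-EDF writer is provided so synthetic
cohorts can be exported and round-tripped (no installed library writes EDF).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Epoch",
    "read_recording",
    "read_labels",
    "segment_epochs",
    "write_edf",
]

VALID_LABELS = frozenset({"apnea", "normal"})


def _canon(name: str) -> str:
    """Channel-label canonical form: casefolded, internal whitespace collapsed."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass
class Recording:
    """A labeled single-channel EEG time series.

    Parameters
    ----------
    subject_id : str
        Identifier used to join the label sidecar.
    channel : str
        Montage label, e.g. ``"C3-A2"``.
    fs : float
        Sampling frequency in Hz, > 0.
    samples : ndarray
        Amplitudes in microvolts.
    label : str or None
        ``"apnea"`` or ``"normal"`` when known.
    """

    subject_id: str
    channel: str
    fs: float
    samples: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Epoch:
    """A fixed-length window of a recording (30 s in sleep-scoring convention)."""

    parent_subject_id: str
    index: int
    fs: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.index < 0:
            raise ValueError("epoch index must be >= 0")


def read_recording(path: str | Path, channel: str, subject_id: str | None = None,
                   label: str | None = None) -> Recording:
    """Read one channel of an EDF file as a :class:`Recording`.

    Channel matching is case-insensitive with internal whitespace collapsed,
    because public sleep databases label montages inconsistently. Amplitudes
    are returned in microvolts using the EDF physical scaling.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    wanted = _canon(channel)
    match = None
    for name in raw.ch_names:
        if _canon(name) == wanted:
            match = name
            break
    if match is None:
        raise KeyError(
            f"channel {channel!r} not found in {path.name}; "
            f"available channels: {', '.join(raw.ch_names)}"
        )
    data = raw.get_data(picks=[match])[0] * 1e6  # mne stores volts
    return Recording(
        subject_id=subject_id or path.stem,
        channel=match,
        fs=float(raw.info["sfreq"]),
        samples=data,
        label=label,
    )


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read the two-column label sidecar (``subject_id,label``)."""
    df = pd.read_csv(path, dtype=str)
    expected = {"subject_id", "label"}
    if not expected.issubset(df.columns):
        raise ValueError(f"label file must have columns {sorted(expected)}, got {list(df.columns)}")
    bad = set(df["label"]) - VALID_LABELS
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected one of {sorted(VALID_LABELS)}")
    return df[["subject_id", "label"]]


def segment_epochs(rec: Recording, epoch_seconds: float = 30.0) -> list[Epoch]:
    """Split a recording into consecutive fixed-length epochs.

    Returns ``floor(duration / epoch_seconds)`` epochs; a trailing partial
    segment is discarded so all epochs of a recording share one length.
    A recording shorter than one epoch yields an empty list.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be > 0")
    n = int(round(rec.fs * epoch_seconds))
    if n < 1:
        raise ValueError("epoch shorter than one sample")
    count = len(rec.samples) // n
    return [
        Epoch(rec.subject_id, i, rec.fs, rec.samples[i * n:(i + 1) * n])
        for i in range(count)
    ]


def write_edf(path: str | Path, recordings: Recording | Sequence[Recording]) -> Path:
    """Write one or more equal-rate, equal-length channels to a plain EDF file.

    16-bit EDF with one-second data records; the physical range is set
    symmetrically from each channel's absolute maximum, so quantization error
    is bounded by the 16-bit grid. The sampling rate must be a whole number
    of samples per second and the signal is truncated to whole records.
    """
    if isinstance(recordings, Recording):
        recordings = [recordings]
    if not recordings:
        raise ValueError("nothing to write")
    fs = recordings[0].fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9 or spr < 1:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    if any(r.fs != fs or len(r.samples) != len(recordings[0].samples) for r in recordings):
        raise ValueError("all channels must share sampling rate and length")

    n_rec = len(recordings[0].samples) // spr
    if n_rec < 1:
        raise ValueError("signal shorter than one 1-s data record")
    ns = len(recordings)
    dmin, dmax = -32768, 32767
    pmaxs = [max(float(np.max(np.abs(r.samples))), 1e-6) for r in recordings]

    def fixed(values, width: int) -> bytes:
        out = b""
        for v in values:
            s = str(v).encode("ascii")[:width]
            out += s.ljust(width)
        return out

    path = Path(path)
    with open(path, "wb") as f:
        f.write(b"0".ljust(8))                      # version
        f.write(b"X".ljust(80))                     # patient id
        f.write(b"X".ljust(80))                     # recording id
        f.write(b"01.01.00")                        # start date
        f.write(b"00.00.00")                        # start time
        f.write(str(256 * (ns + 1)).encode().ljust(8))
        f.write(b" " * 44)                          # reserved
        f.write(str(n_rec).encode().ljust(8))
        f.write(b"1".ljust(8))                      # record duration, seconds
        f.write(str(ns).encode().ljust(4))
        f.write(fixed([r.channel for r in recordings], 16))
        f.write(fixed([""] * ns, 80))               # transducer
        f.write(fixed(["uV"] * ns, 8))
        f.write(fixed([f"{-p:.6g}" for p in pmaxs], 8))
        f.write(fixed([f"{p:.6g}" for p in pmaxs], 8))
        f.write(fixed([dmin] * ns, 8))
        f.write(fixed([dmax] * ns, 8))
        f.write(fixed([""] * ns, 80))               # prefiltering
        f.write(fixed([spr] * ns, 8))
        f.write(fixed([""] * ns, 32))               # reserved
        for rec_i in range(n_rec):
            for r, pmax in zip(recordings, pmaxs):
                chunk = r.samples[rec_i * spr:(rec_i + 1) * spr]
                dig = np.round((chunk + pmax) / (2 * pmax) * (dmax - dmin) + dmin)
                f.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())
    return path
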