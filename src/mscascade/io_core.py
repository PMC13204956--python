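"""Reading, referencing, filtering, resampling and epoching of scalp EEG.

Everything downstream (microstate extraction, classifier training) consumes
the :class:`Recording` container defined here: an ordered channel × sample
matrix in microvolts with its montage names, sampling rate and diagnostic
label.  File I/O for the standard clinical formats (EDF, BrainVision, a
BIDS-like directory layout) is delegated to :mod:`mne`; a minimal EDF
writer is provided so synthetic cohorts can be exported to a format any
EEG toolbox reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "BandSpec",
    "BANDS",
    "EpochSet",
    "read_recording",
    "write_edf",
    "rereference_average",
    "bandpass",
    "resample",
    "epoch",
    "n_epochs",
]

GROUPS = ("AD", "FTD", "HC", "unknown")


@dataclass
class Recording:
    """One subject's multichannel EEG.

    data is channels × samples in microvolts; ``reference`` is a free-text
    provenance tag recording what referencing has been applied.
    """

    subject_id: str
    group: str
    channels: tuple[str, ...]
    rate: float
    data: np.ndarray
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz (half-open interest range low < high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: need 0 < low < high")


#: The canonical analysis bands.
BANDS: dict[str, BandSpec] = {
    "broadband": BandSpec("broadband", 0.5, 45.0),
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
}


@dataclass
class EpochSet:
    """Sliding-window segments of one subject's (band-filtered) recording."""

    subject_id: str
    band: str
    epochs: list[np.ndarray]
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError("all epochs must share one shape")

    def __len__(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# file I/O


def read_recording(
    path: str | Path,
    format: str = "edf",
    subject_id: str | None = None,
    group: str = "unknown",
) -> Recording:
    """Read one EEG file (or a BIDS-like subject directory) into a Recording.

    ``format`` is one of ``edf``, ``brainvision`` or ``bids_dir``.  For
    ``bids_dir`` the path is a subject directory laid out as
    ``sub-XXX/eeg/<file>`` and the first readable EEG file inside is used.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")

    if format == "bids_dir":
        eeg_dir = path / "eeg" if (path / "eeg").is_dir() else path
        candidates = sorted(eeg_dir.glob("*.edf")) + sorted(eeg_dir.glob("*.vhdr"))
        if not candidates:
            raise FileNotFoundError(f"no EDF/BrainVision file under {eeg_dir}")
        inner = candidates[0]
        fmt = "edf" if inner.suffix == ".edf" else "brainvision"
        sid = subject_id or path.name
        return read_recording(inner, fmt, subject_id=sid, group=group)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if format == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported format {format!r}")

    if len(raw.ch_names) < 2:
        raise ValueError("recording declares fewer than 2 channels")
    data_uv = raw.get_data() * 1e6  # mne holds Volts internally
    return Recording(
        subject_id=subject_id or path.stem,
        group=group,
        channels=tuple(raw.ch_names),
        rate=float(raw.info["sfreq"]),
        data=data_uv,
        reference="as-recorded",
    )


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a plain EDF file (16-bit, 1-second records).

    Requires an integer sampling rate.  Samples beyond the last whole
    second are dropped (EDF stores fixed-duration data records).
    """
    path = Path(path)
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // rate
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_rec * rate != rec.n_samples:
        logger.warning("write_edf: truncating %d trailing samples", rec.n_samples - n_rec * rate)
    ns = rec.n_channels
    data = rec.data[:, : n_rec * rate]

    # per-channel physical scaling onto the full 16-bit digital range
    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767
    scaled = np.clip(np.round(data / pmax[:, None] * dig_max), dig_min, dig_max).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            f("0", 8),
            f(rec.subject_id, 80),
            f(f"Startdate 01-JAN-2000 {rec.reference}", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (ns + 1)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),
            f(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(f(ch, 16) for ch in rec.channels),
            b"".join(f("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(f("uV", 8) for _ in range(ns)),
            b"".join(f(f"{-pmax[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(f(f"{pmax[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(f(str(dig_min), 8) for _ in range(ns)),
            b"".join(f(str(dig_max), 8) for _ in range(ns)),
            b"".join(f("", 80) for _ in range(ns)),
            b"".join(f(str(rate), 8) for _ in range(ns)),
            b"".join(f("", 32) for _ in range(ns)),
        ]
    )
    records = scaled.reshape(ns, n_rec, rate).transpose(1, 0, 2)  # (rec, ch, samp)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())


# ---------------------------------------------------------------------------
# referencing / filtering / resampling / epoching


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous spatial mean from every channel.

    Average reference makes the spatial mean zero at each sample, the
    convention under which GFP and topographic correlations are defined.
    Idempotent; preserves GFP exactly.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


def bandpass(rec: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward–backward)."""
    nyq = rec.rate / 2
    if band.high >= nyq:
        raise ValueError(f"band {band.name} ({band.high} Hz) exceeds Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [band.low, band.high], btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=np.ascontiguousarray(data))


def resample(rec: Recording, target_rate: float) -> Recording:
    """Polyphase anti-aliased resampling to ``target_rate`` Hz.

    Output length is round(n_samples · target_rate / rate).  Upsampling is
    allowed but logged, as it adds no information.
    """
    if not target_rate > 0:
        raise ValueError("target rate must be positive")
    if target_rate == rec.rate:
        return replace(rec, data=rec.data.copy())
    if target_rate > rec.rate:
        logger.warning("resample: target %g Hz above original %g Hz", target_rate, rec.rate)
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_out = int(round(rec.n_samples * target_rate / rec.rate))
    if out.shape[1] > n_out:
        out = out[:, :n_out]
    elif out.shape[1] < n_out:
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])), mode="edge")
    return replace(rec, data=out, rate=float(target_rate))


def n_epochs(n_samples: int, window: int, step: int) -> int:
    """Number of sliding windows whose end lies strictly inside the record.

    A window starting at k·step covers [k·step, k·step + window); it is kept
    only if k·step + window < n_samples, i.e. the window ending exactly at
    the record boundary is excluded.  This reproduces 58 windows for a
    300-second record at 256 Hz with a 10 s window and 5 s step.
    """
    if n_samples <= window:
        return 0
    return (n_samples - window - 1) // step + 1


def epoch(
    rec: Recording, window_s: float = 10.0, step_s: float = 5.0, band: str = "broadband"
) -> EpochSet:
    """Cut a recording into overlapping fixed-length windows."""
    if not (window_s > 0 and step_s > 0):
        raise ValueError("window and step must be positive")
    w = int(round(window_s * rec.rate))
    s = int(round(step_s * rec.rate))
    count = n_epochs(rec.n_samples, w, s)
    if count == 0:
        warnings.warn(
            f"recording {rec.subject_id}: {rec.n_samples} samples shorter than "
            f"one {w}-sample window; empty epoch set",
            stacklevel=2,
        )
    epochs = [rec.data[:, k * s : k * s + w] for k in range(count)]
    return EpochSet(rec.subject_id, band, epochs, window_s, step_s)
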