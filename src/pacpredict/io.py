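"""Reading, writing and windowing of intracranial EEG recordings.

Signals are kept in memory as a ``channels x samples`` float array in
microvolts, together with the sampling rate and a list of clinical seizure
annotations (onset seconds from record start).  On disk, the signal matrix
lives in a plain 16-bit EDF file and the annotations in a small CSV sidecar
with columns ``onset_s,label`` — the minimal open substitute for the
proprietary annotation protocols of clinical acquisition systems.

EDF files are read through :mod:`mne`; writing uses a minimal EDF encoder
implemented here (16-bit, one-second data records, per-channel physical
scaling over the data range).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SeizureAnnotation",
    "Recording",
    "read_recording",
    "write_recording",
    "segment_windows",
]

#: Sampling rates of the acquisition systems the pipeline was designed for.
KNOWN_SAMPLING_RATES = (256, 400, 512, 1024)


@dataclass(frozen=True)
class SeizureAnnotation:
    """A clinically annotated seizure onset.

    Parameters
    ----------
    onset : float
        Seconds from the start of the recording.
    label : str
        Free-text label, ``"seizure"`` by default.
    """

    onset: float
    label: str = "seizure"


@dataclass
class Recording:
    """Multichannel EEG recording with seizure annotations.

    ``signals`` has shape ``(n_channels, n_samples)`` in microvolts.  All
    channels share the sampling rate ``fs`` (Hz).  ``start_time`` is an
    absolute timestamp in seconds (only carried through; all analysis uses
    record-relative seconds).
    """

    signals: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if round(self.fs) not in KNOWN_SAMPLING_RATES:
            warnings.warn(
                f"unusual sampling rate {self.fs} Hz (expected one of "
                f"{KNOWN_SAMPLING_RATES})",
                stacklevel=3,
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        self.annotations = sorted(self.annotations, key=lambda a: a.onset)
        onsets = [a.onset for a in self.annotations]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("annotation onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] > self.duration):
            raise ValueError(
                f"annotation onset outside [0, {self.duration:.1f}] s"
            )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def seizure_onsets(self) -> np.ndarray:
        return np.array([a.onset for a in self.annotations], dtype=float)


def segment_windows(
    recording: Recording, window_s: float
) -> list[tuple[int, int, int]]:
    """Consecutive non-overlapping analysis windows.

    Returns ``(window_index, start_sample, end_sample)`` triples with
    half-open 0-based sample ranges.  A trailing partial window is discarded
    so every window carries the same number of samples.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    wlen = int(round(window_s * recording.fs))
    n_win = recording.n_samples // wlen
    return [(i, i * wlen, (i + 1) * wlen) for i in range(n_win)]


# ---------------------------------------------------------------------------
# EDF container
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` to ``path`` as EDF plus a CSV sidecar.

    The sidecar is ``<path stem>.annotations.csv`` with columns
    ``onset_s,label``.  Samples are stored as 16-bit integers scaled over
    each channel's physical range, so a round trip preserves values to
    within one quantization step.
    """
    path = Path(path)
    sig = np.asarray(recording.signals, dtype=np.float64)
    if not np.isfinite(sig).all():
        raise ValueError("cannot write non-finite samples to EDF")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))

    n_ch = recording.n_channels
    record_len = 1.0  # seconds per data record
    spr = fs  # samples per record per channel
    n_rec = math.ceil(recording.n_samples / spr)
    pad = n_rec * spr - recording.n_samples
    if pad:
        sig = np.pad(sig, ((0, 0), (0, pad)), mode="edge")

    # Per-channel physical scaling over the data range (with a symmetric
    # floor so constant channels stay representable).
    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    span = phys_max - phys_min
    degenerate = span <= 0
    phys_min[degenerate] -= 1.0
    phys_max[degenerate] += 1.0
    if np.any(np.abs(phys_min) > 1e7) or np.any(np.abs(phys_max) > 1e7):
        raise ValueError("signal amplitude exceeds representable EDF range")

    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round(
        (sig - phys_min[:, None]) * gain[:, None] + _EDF_DIG_MIN
    ).astype("<i2")

    header = bytearray()
    header += _edf_field("0", 8)  # version
    header += _edf_field("X X X X", 80)  # patient id (anonymous)
    header += _edf_field("Startdate X X X X", 80)  # recording id
    header += _edf_field("01.01.00", 8)  # start date
    header += _edf_field("00.00.00", 8)  # start time
    header += _edf_field(str(256 * (n_ch + 1)), 8)  # header bytes
    header += _edf_field("", 44)  # reserved
    header += _edf_field(str(n_rec), 8)
    header += _edf_field(f"{record_len:g}", 8)
    header += _edf_field(str(n_ch), 4)

    def _per_channel(values: list[str], width: int) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    labels = [lab[:16] for lab in recording.channel_labels]
    header += _per_channel(labels, 16)
    header += _per_channel(["intracranial EEG"] * n_ch, 80)  # transducer
    header += _per_channel(["uV"] * n_ch, 8)  # physical dimension
    header += _per_channel([f"{v:.6g}" for v in phys_min], 8)
    header += _per_channel([f"{v:.6g}" for v in phys_max], 8)
    header += _per_channel([str(_EDF_DIG_MIN)] * n_ch, 8)
    header += _per_channel([str(_EDF_DIG_MAX)] * n_ch, 8)
    header += _per_channel([""] * n_ch, 80)  # prefiltering
    header += _per_channel([str(spr)] * n_ch, 8)
    header += _per_channel([""] * n_ch, 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # EDF interleaves: for each record, all samples of ch0, then ch1, ...
        blocks = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            fh.write(blocks[:, r, :].tobytes())

    sidecar = annotation_sidecar_path(path)
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "label"])
        for ann in recording.annotations:
            writer.writerow([f"{ann.onset:.6f}", ann.label])
    return path


def annotation_sidecar_path(edf_path: str | Path) -> Path:
    edf_path = Path(edf_path)
    return edf_path.with_suffix(".annotations.csv")


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read a CSV annotation sidecar (columns ``onset_s,label``)."""
    out: list[SeizureAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SeizureAnnotation(
                    onset=float(row["onset_s"]),
                    label=row.get("label") or "seizure",
                )
            )
    return out


def read_recording(
    path: str | Path, annotation_path: str | Path | None = None
) -> Recording:
    """Read an EDF/EDF+ file (via :mod:`mne`) and its annotation sidecar.

    When ``annotation_path`` is omitted, ``<stem>.annotations.csv`` next to
    the EDF file is used if present; otherwise the recording carries no
    annotations.  Channel order is preserved from the file.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise ValueError(f"unreadable EDF file {path}: {exc}") from exc
    signals_uv = raw.get_data() * 1e6  # mne returns volts for EEG channels

    if annotation_path is None:
        candidate = annotation_sidecar_path(path)
        annotations = read_annotations(candidate) if candidate.exists() else []
    else:
        annotations = read_annotations(annotation_path)

    return Recording(
        signals=signals_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        annotations=annotations,
    )
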