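"""Reading, writing and segmenting mandibular-movement (MM) signals.

The MM signal is the chin–forehead distance recorded by a mid-sagittal
magnetometer during sleep, sampled at 10 Hz with 0.1 mm resolution.  By
convention 0 mm corresponds to a completely closed mouth and the signal is
processed so that a *more negative* value means a *more open* mouth; quiet
breathing therefore oscillates a fraction of a millimetre below a slightly
open baseline.

Signals travel as :class:`MMSignal`; recordings are cut into fixed-length
scoring fragments (:class:`Segment`, default 180 s) by
:func:`segment_signal`.  EDF is used for signals and plain CSV for
segment/event annotations.  The EDF writer stores samples as int16 with a
physical scale of 0.01 mm per digital unit, so the 0.1 mm hardware
quantization round-trips exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ChannelNotFoundError, FormatError

__all__ = [
    "MMSignal",
    "Segment",
    "AnnotationSet",
    "read_mm_edf",
    "write_mm_edf",
    "segment_signal",
    "read_annotations",
    "write_annotations",
]

#: CSV schema for per-segment annotations.
SEGMENT_COLUMNS = ["segment_id", "start_s", "end_s", "true_csb", "true_lpm", "true_spm"]
#: CSV schema for per-event annotations.
EVENT_COLUMNS = ["event_type", "start_s", "end_s"]

_BOOL_COLUMNS = ("true_csb", "true_lpm", "true_spm")


@dataclass(frozen=True)
class MMSignal:
    """A uniformly sampled mandibular-displacement trace.

    Parameters
    ----------
    samples
        Displacement in mm.  ``0`` = mouth fully closed; more negative =
        mouth more open.  Values are expected to be (close to) integer
        multiples of ``resolution_mm``.
    sampling_rate
        Samples per second (the magnetometer emits 10 Hz).
    resolution_mm
        Quantization step of the hardware distance computation.
    start_time
        Offset of the first sample, in seconds from recording start.
    """

    samples: np.ndarray
    sampling_rate: float = 10.0
    resolution_mm: float = 0.1
    start_time: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if self.resolution_mm <= 0:
            raise FormatError("resolution_mm must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise FormatError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise FormatError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def quantized(self) -> "MMSignal":
        """Return a copy with samples rounded to ``resolution_mm``."""
        q = np.round(self.samples / self.resolution_mm) * self.resolution_mm
        return replace(self, samples=q)


@dataclass(frozen=True)
class Segment:
    """A fixed-length scoring fragment: a view into a parent recording.

    Time coordinates are 0-based seconds from recording start, intervals
    half-open ``[start_s, end_s)``.
    """

    segment_id: int
    start_s: float
    end_s: float
    parent: MMSignal = field(repr=False)

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise FormatError("segment end must be after start")

    @property
    def sampling_rate(self) -> float:
        return self.parent.sampling_rate

    @property
    def samples(self) -> np.ndarray:
        fs = self.parent.sampling_rate
        i0 = int(round((self.start_s - self.parent.start_time) * fs))
        i1 = int(round((self.end_s - self.parent.start_time) * fs))
        return self.parent.samples[i0:i1]

    def as_signal(self) -> MMSignal:
        return MMSignal(
            samples=self.samples.copy(),
            sampling_rate=self.parent.sampling_rate,
            resolution_mm=self.parent.resolution_mm,
            start_time=self.start_s,
        )

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class AnnotationSet:
    """Ground-truth labels for a recording.

    ``segments`` has one row per scoring fragment with columns
    ``segment_id, start_s, end_s, true_csb, true_lpm, true_spm``; ``events``
    lists individual simulated/scored events (``event_type`` in
    ``{"LPM_run", "MMS", "apnea", "obstructive"}``) with half-open second
    intervals.
    """

    segments: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
        if missing:
            raise FormatError(f"segment table missing columns: {missing}")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        self.segments = self.segments[SEGMENT_COLUMNS].reset_index(drop=True)
        self.events = self.events[EVENT_COLUMNS].reset_index(drop=True)
        for col in _BOOL_COLUMNS:
            self.segments[col] = self.segments[col].astype(int).astype(bool)
        if len(self.events) and not (self.events["start_s"] < self.events["end_s"]).all():
            raise FormatError("event intervals must satisfy start_s < end_s")
        ids = self.segments["segment_id"]
        if ids.duplicated().any():
            raise FormatError("duplicate segment_id in annotation set")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# EDF I/O
#
# EDF: 256-byte fixed-field ASCII header, one 256-byte header per signal,
# then int16 little-endian data records.  We write a single channel with
# physical range [-327.68, 327.67] mm over digital [-32768, 32767], i.e.
# 0.01 mm per bit, which represents 0.1 mm-quantized data exactly.

_PHYS_MIN, _PHYS_MAX = -327.68, 327.67
_DIG_MIN, _DIG_MAX = -32768, 32767
_SCALE = (_PHYS_MAX - _PHYS_MIN) / (_DIG_MAX - _DIG_MIN)  # 0.01 mm / bit


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def write_mm_edf(signal: MMSignal, path, channel_label: str = "MM") -> None:
    """Write a single-channel EDF file holding an MM trace.

    If the sample count is a whole number of seconds, 1-s data records are
    used; otherwise one sample per record (record duration ``1/fs``).
    """
    path = Path(path)
    fs = signal.sampling_rate
    n = signal.n_samples
    if n % round(fs) == 0 and abs(fs - round(fs)) < 1e-9:
        spr = int(round(fs))
        record_dur = 1.0
    else:
        spr = 1
        record_dur = 1.0 / fs
    n_records = n // spr

    dur_str = f"{record_dur:.6f}".rstrip("0").rstrip(".") if record_dur != int(record_dur) else str(int(record_dur))
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * 2), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(dur_str, 8),
            _pad("1", 4),
            # per-signal fields
            _pad(channel_label, 16),
            _pad("magnetometer", 80),
            _pad("mm", 8),
            _pad(f"{_PHYS_MIN}", 8),
            _pad(f"{_PHYS_MAX}", 8),
            _pad(str(_DIG_MIN), 8),
            _pad(str(_DIG_MAX), 8),
            _pad("", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    phys = signal.samples[: n_records * spr]
    dig = np.round((phys - _PHYS_MIN) / _SCALE).astype(np.int64) + _DIG_MIN
    if dig.min() < _DIG_MIN or dig.max() > _DIG_MAX:
        raise FormatError("signal exceeds EDF physical range [-327.68, 327.67] mm")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.astype("<i2").tobytes())


def _read_header_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_mm_edf(path, channel_label: str = "MM") -> MMSignal:
    """Read one channel of an EDF file as an :class:`MMSignal`.

    Raises
    ------
    ChannelNotFoundError
        If ``channel_label`` is absent (the message lists available labels).
    FormatError
        If the channel's physical dimension is not millimetres.

    Notes
    -----
    Recordings exported with an uninverted sign (raw distance, mostly
    positive) are auto-negated with a warning so that the package's
    "more negative = more open" convention holds.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fh.seek(0)
        version = _read_header_field(fh, 8)
        if version != "0":
            raise FormatError(f"not an EDF file (version field {version!r})")
        fh.seek(8 + 80 + 80 + 8 + 8)
        _header_bytes = _read_header_field(fh, 8)
        fh.seek(44, 1)  # reserved
        n_records = int(_read_header_field(fh, 8))
        record_dur = float(_read_header_field(fh, 8))
        ns = int(_read_header_field(fh, 4))

        labels = [_read_header_field(fh, 16) for _ in range(ns)]
        fh.seek(80 * ns, 1)  # transducer
        dims = [_read_header_field(fh, 8) for _ in range(ns)]
        pmins = [float(_read_header_field(fh, 8)) for _ in range(ns)]
        pmaxs = [float(_read_header_field(fh, 8)) for _ in range(ns)]
        dmins = [int(_read_header_field(fh, 8)) for _ in range(ns)]
        dmaxs = [int(_read_header_field(fh, 8)) for _ in range(ns)]
        fh.seek(80 * ns, 1)  # prefiltering
        sprs = [int(_read_header_field(fh, 8)) for _ in range(ns)]
        fh.seek(32 * ns, 1)  # reserved

        if channel_label not in labels:
            raise ChannelNotFoundError(
                f"channel {channel_label!r} not found; available: {labels}"
            )
        ch = labels.index(channel_label)
        if dims[ch].lower() != "mm":
            raise FormatError(
                f"channel {channel_label!r} has physical dimension "
                f"{dims[ch]!r}, expected 'mm'"
            )

        rec_len = sum(sprs)
        raw = np.frombuffer(fh.read(2 * rec_len * n_records), dtype="<i2")
    if raw.size != rec_len * n_records:
        raise FormatError("EDF data section truncated")
    raw = raw.reshape(n_records, rec_len)
    off = sum(sprs[:ch])
    dig = raw[:, off : off + sprs[ch]].reshape(-1).astype(float)
    gain = (pmaxs[ch] - pmins[ch]) / (dmaxs[ch] - dmins[ch])
    phys = pmins[ch] + (dig - dmins[ch]) * gain
    fs = sprs[ch] / record_dur

    if phys.size and np.mean(phys > 0) > 0.5:
        warnings.warn(
            "more than half of the MM samples are positive; negating to match "
            "the closed-mouth-zero / negative-opening sign convention",
            UserWarning,
            stacklevel=2,
        )
        phys = -phys
    return MMSignal(samples=phys, sampling_rate=fs)


# ---------------------------------------------------------------------------
# Segmentation


def segment_signal(signal: MMSignal, segment_length_s: float = 180.0) -> list[Segment]:
    """Cut a recording into contiguous fixed-length scoring fragments.

    Returns ``floor(duration / segment_length_s)`` segments starting at
    ``signal.start_time``; a trailing partial fragment is dropped.  The
    segments partition a prefix of the recording: contiguous, disjoint,
    half-open intervals.
    """
    if segment_length_s <= 0:
        raise ValueError("segment_length_s must be positive")
    n_seg = math.floor(signal.duration_s / segment_length_s + 1e-9)
    return [
        Segment(
            segment_id=k,
            start_s=signal.start_time + k * segment_length_s,
            end_s=signal.start_time + (k + 1) * segment_length_s,
            parent=signal,
        )
        for k in range(n_seg)
    ]


# ---------------------------------------------------------------------------
# Annotation CSV I/O


def write_annotations(annotations: AnnotationSet, segments_path, events_path=None) -> None:
    """Write annotations to CSV (booleans serialized as 0/1).

    ``events_path`` defaults to ``<segments_path stem>_events.csv``.
    """
    segments_path = Path(segments_path)
    if events_path is None:
        events_path = segments_path.with_name(segments_path.stem + "_events.csv")
    seg = annotations.segments.copy()
    for col in _BOOL_COLUMNS:
        seg[col] = seg[col].astype(int)
    seg.to_csv(segments_path, index=False)
    annotations.events.to_csv(Path(events_path), index=False)


def read_annotations(segments_path, events_path=None) -> AnnotationSet:
    """Read annotations written by :func:`write_annotations`.

    A missing events file yields an empty event table; a malformed segment
    table raises :class:`~mmcsb.exceptions.FormatError` naming the missing
    columns.
    """
    segments_path = Path(segments_path)
    if events_path is None:
        events_path = segments_path.with_name(segments_path.stem + "_events.csv")
    seg = pd.read_csv(segments_path)
    missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing:
        raise FormatError(f"annotation file missing columns: {missing}")
    events_path = Path(events_path)
    if events_path.exists():
        ev = pd.read_csv(events_path)
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise FormatError(f"event file missing columns: {missing}")
    else:
        ev = pd.DataFrame(columns=EVENT_COLUMNS)
    return AnnotationSet(segments=seg, events=ev)
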