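"""Rule-based scoring of mandibular-movement signals.

Implements the MM vocabulary used to recognise Cheyne-Stokes breathing
from the chin-magnetometer trace alone:

* **breaths** — oscillatory mandibular displacements at the respiratory
  frequency, delimited around troughs (mouth-opening excursions) of the
  detrended signal;
* **MML / large breaths** — breaths whose peak-to-trough amplitude is
  >= 0.3 mm, the signature of increased respiratory effort;
* **MMS** — sharp large mouth-closure movements (> 3 mm excursion toward
  zero completed within a short rise window), the signature of a cortical
  arousal;
* **LPM runs** — >= 5 consecutive large breaths whose amplitude envelope
  waxes to a single zenith and wanes (crescendo–decrescendo), the MM
  signature of a CSB hyperpnea;
* the **segment periodicity rule** — a 3-min fragment is LPM-positive when
  at least three runs recur at a physiologically plausible, regular period;
  SPM-positive when at least one MMS is present.

All rules operate on amplitudes of the detrended signal, so detector
output is invariant under constant offsets and slow baseline drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import ConfigError
from .io import MMSignal, Segment, segment_signal

__all__ = [
    "DetectorConfig",
    "Breath",
    "MMSEvent",
    "LPMRun",
    "SegmentFeatures",
    "detrend",
    "detect_breaths",
    "detect_mms",
    "detect_lpm",
    "score_segment",
    "measure_cycle_length",
    "extract_features",
]

_EPS = 1e-9
_SMOOTH_S = 0.5  # moving-average width for extrema/amplitude estimation
_MERGE_GAP_S = 0.5  # MMS candidate regions closer than this are one event


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and gates of the rule-based detector.

    Defaults encode the published rule set: 0.3 mm large-movement (MML)
    threshold, 3 mm sharp-movement (MMS) threshold with the 200 %
    baseline-ratio recorded, >= 5 breaths per crescendo–decrescendo run,
    and >= 3 periodic runs per 3-min fragment.
    """

    mml_threshold_mm: float = 0.3
    mms_threshold_mm: float = 3.0
    mms_baseline_ratio: float = 2.0
    mms_max_rise_s: float = 2.0
    min_breaths_per_run: int = 5
    min_periodic_events: int = 3
    breath_duration_bounds_s: tuple[float, float] = (1.5, 10.0)
    envelope_tolerance_mm: float = 0.1
    period_band_s: tuple[float, float] = (20.0, 120.0)
    period_cv_max: float = 0.5
    spm_min_events: int = 1
    min_breath_amp_mm: float = 0.15
    min_breath_prominence_mm: float = 0.1

    def __post_init__(self):
        if not 0 < self.mml_threshold_mm < self.mms_threshold_mm:
            raise ConfigError("need 0 < mml_threshold_mm < mms_threshold_mm")
        if self.min_breaths_per_run < 1 or self.min_periodic_events < 1:
            raise ConfigError("run/periodicity counts must be >= 1")
        if self.min_breaths_per_run < 5:
            warnings.warn(
                "min_breaths_per_run < 5 relaxes the published >=5-breath "
                "crescendo-decrescendo rule",
                UserWarning,
                stacklevel=2,
            )
        lo, hi = self.breath_duration_bounds_s
        if not 0 < lo < hi:
            raise ConfigError("breath_duration_bounds_s must satisfy 0 < min < max")
        lo, hi = self.period_band_s
        if not 0 < lo < hi:
            raise ConfigError("period_band_s must satisfy 0 < min < max")
        if self.mms_max_rise_s <= 0 or self.envelope_tolerance_mm < 0:
            raise ConfigError("mms_max_rise_s must be > 0 and tolerance >= 0")
        if self.spm_min_events < 1:
            raise ConfigError("spm_min_events must be >= 1")


@dataclass(frozen=True)
class Breath:
    """One respiratory cycle of the mandible."""

    t_start: float
    t_end: float
    t_center: float  # trough (maximum opening) time
    amplitude_mm: float
    is_large: bool

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class MMSEvent:
    """A sharp large mouth-closure movement (cortical-arousal marker)."""

    t_peak: float
    excursion_mm: float
    rise_s: float
    baseline_amp_mm: float | None
    ratio_to_baseline: float | None


@dataclass(frozen=True)
class LPMRun:
    """A crescendo–decrescendo run of large breaths (one CSB hyperpnea)."""

    breaths: tuple[Breath, ...]
    t_start: float
    t_end: float
    zenith_amp_mm: float
    zenith_t: float
    n_breaths: int
    monotone_flat: bool = False


@dataclass(frozen=True)
class SegmentFeatures:
    """Per-fragment binary predictors (the classifier's feature row)."""

    segment_id: int
    lpm_present: bool
    spm_present: bool
    n_lpm_runs: int
    n_mms: int
    mean_cycle_length_s: float | None = None
    csb_label: bool | None = None


# ---------------------------------------------------------------------------
# Preprocessing


def _signal_of(signal: MMSignal | Segment) -> MMSignal:
    return signal.as_signal() if isinstance(signal, Segment) else signal


def detrend(signal: MMSignal | Segment, config: DetectorConfig | None = None) -> np.ndarray:
    """High-pass the trace by subtracting a centred rolling median.

    The window equals the upper edge of the CSB period band so breath
    oscillations and event morphology pass while baseline drift and
    postural offsets are removed.
    """
    config = config or DetectorConfig()
    sig = _signal_of(signal)
    win = int(round(config.period_band_s[1] * sig.sampling_rate)) | 1
    med = (
        pd.Series(sig.samples)
        .rolling(win, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return sig.samples - med


def _smooth(y: np.ndarray, fs: float) -> np.ndarray:
    win = max(1, int(round(_SMOOTH_S * fs))) | 1
    return pd.Series(y).rolling(win, center=True, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# Breath detection


def detect_breaths(
    signal: MMSignal | Segment, config: DetectorConfig | None = None
) -> list[Breath]:
    """Delimit respiratory cycles around troughs of the detrended signal.

    Each candidate trough owns a window reaching halfway to its neighbours
    (capped at half the maximum breath duration).  Its amplitude is the
    smaller of the two flanking maxima minus the trough — the local
    peak-to-trough of the oscillation, insensitive to monotone trends such
    as the progressive opening of an obstructive event.  Candidates whose
    raw excursion exceeds the sharp-movement threshold are routed to
    :func:`detect_mms` instead; candidates failing the duration or
    amplitude gates are discarded.  Too-short inputs yield an empty list.
    """
    config = config or DetectorConfig()
    sig = _signal_of(signal)
    fs = sig.sampling_rate
    lo, hi = config.breath_duration_bounds_s
    if sig.duration_s < 2 * lo:
        return []
    y = detrend(sig, config)
    ys = _smooth(y, fs)
    # breaths cannot recur faster than the minimum breath duration; the
    # distance floor also merges double detections on flat quantized troughs
    troughs, _ = find_peaks(
        -ys,
        prominence=config.min_breath_prominence_mm,
        distance=max(1, int(round(lo * fs))),
    )
    if troughs.size == 0:
        return []

    half_cap = int(round(hi / 2 * fs))
    n = y.size
    breaths: list[Breath] = []
    for j, idx in enumerate(troughs):
        left_gap = (idx - troughs[j - 1]) // 2 if j > 0 else half_cap
        right_gap = (troughs[j + 1] - idx) // 2 if j + 1 < troughs.size else half_cap
        i0 = max(0, idx - min(left_gap, half_cap))
        i1 = min(n, idx + min(right_gap, half_cap) + 1)
        duration = (i1 - 1 - i0) / fs
        if not (lo - _EPS <= duration <= hi + _EPS):
            continue
        # sharp-movement exclusion uses the raw excursion in the window
        raw_exc = float(np.max(y[i0:i1]) - np.min(y[i0:i1]))
        if raw_exc > config.mms_threshold_mm:
            continue
        left = ys[i0 : idx + 1]
        right = ys[idx : i1]
        side_maxes = [float(np.max(s)) for s in (left, right) if s.size > 1]
        if not side_maxes:
            continue
        amplitude = min(side_maxes) - float(ys[idx])
        if amplitude < config.min_breath_amp_mm:
            continue
        t0 = sig.start_time
        breaths.append(
            Breath(
                t_start=t0 + i0 / fs,
                t_end=t0 + (i1 - 1) / fs,
                t_center=t0 + idx / fs,
                amplitude_mm=amplitude,
                is_large=amplitude >= config.mml_threshold_mm - _EPS,
            )
        )
    return breaths


# ---------------------------------------------------------------------------
# Sharp-movement (MMS) detection


def detect_mms(
    signal: MMSignal | Segment,
    breaths: list[Breath] | None = None,
    config: DetectorConfig | None = None,
) -> list[MMSEvent]:
    """Detect sharp large mouth-closure movements.

    An MMS is an upward (toward closure) excursion exceeding
    ``mms_threshold_mm`` completed within the trailing sharpness window
    ``mms_max_rise_s`` — a slow rise of the same magnitude is not sharp and
    is rejected.  The surrounding breathing amplitude (median of the
    nearest 10 breaths not overlapping the event) is recorded together
    with the excursion/baseline ratio; per the published rule the ratio is
    reported, not gating.
    """
    config = config or DetectorConfig()
    sig = _signal_of(signal)
    fs = sig.sampling_rate
    y = detrend(sig, config)
    w = max(1, int(round(config.mms_max_rise_s * fs)))
    roll_min = pd.Series(y).rolling(w + 1, min_periods=1).min().to_numpy()
    swing = y - roll_min
    mask = swing > config.mms_threshold_mm
    if not mask.any():
        return []

    # contiguous candidate regions, merging near-adjacent fragments
    idx = np.flatnonzero(mask)
    gaps = np.flatnonzero(np.diff(idx) > int(round(_MERGE_GAP_S * fs)))
    groups = np.split(idx, gaps + 1)

    events: list[MMSEvent] = []
    for g in groups:
        i_pk = int(g[np.argmax(swing[g])])
        excursion = float(swing[i_pk])
        j0 = max(0, i_pk - w)
        i_min = j0 + int(np.argmin(y[j0 : i_pk + 1]))
        rise_s = (i_pk - i_min) / fs
        t_peak = sig.start_time + i_pk / fs
        t_min = sig.start_time + i_min / fs
        baseline = _baseline_amp(breaths or [], t_min, t_peak)
        ratio = excursion / baseline if baseline and baseline > 0 else None
        events.append(
            MMSEvent(
                t_peak=t_peak,
                excursion_mm=excursion,
                rise_s=rise_s,
                baseline_amp_mm=baseline,
                ratio_to_baseline=ratio,
            )
        )
    return events


def _baseline_amp(
    breaths: list[Breath], t_min: float, t_peak: float, k: int = 10
) -> float | None:
    """Median amplitude of the k breaths nearest the event, excluding any
    breath overlapping the event window."""
    candidates = [
        b for b in breaths if not (b.t_start < t_peak and b.t_end > t_min)
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda b: abs(b.t_center - 0.5 * (t_min + t_peak)))
    return float(np.median([b.amplitude_mm for b in candidates[:k]]))


# ---------------------------------------------------------------------------
# LPM run detection


def _is_unimodal(amps: np.ndarray, tol: float) -> bool:
    """Rises to a single zenith then falls, each step within ``tol``."""
    k = int(np.argmax(amps))
    rising = all(amps[i + 1] >= amps[i] - tol - _EPS for i in range(k))
    falling = all(amps[i + 1] <= amps[i] + tol + _EPS for i in range(k, amps.size - 1))
    return rising and falling


def detect_lpm(
    breaths: list[Breath], config: DetectorConfig | None = None
) -> list[LPMRun]:
    """Find crescendo–decrescendo runs of large breaths.

    Runs are maximal groups of consecutive large breaths — consecutive in
    the breath list and separated by no more than the maximum breath
    duration (a longer quiescent gap, e.g. a central apnea, splits runs).
    A group qualifies when it has >= ``min_breaths_per_run`` breaths and
    its amplitude sequence is unimodal within ``envelope_tolerance_mm``;
    an all-flat plateau is accepted as a degenerate envelope but flagged
    ``monotone_flat``.
    """
    config = config or DetectorConfig()
    max_gap = config.breath_duration_bounds_s[1]
    tol = config.envelope_tolerance_mm

    groups: list[list[Breath]] = []
    current: list[Breath] = []
    for b in breaths:
        if not b.is_large:
            if current:
                groups.append(current)
                current = []
            continue
        if current and (b.t_start - current[-1].t_end) > max_gap + _EPS:
            groups.append(current)
            current = []
        current.append(b)
    if current:
        groups.append(current)

    runs: list[LPMRun] = []
    for g in groups:
        if len(g) < config.min_breaths_per_run:
            continue
        amps = np.array([b.amplitude_mm for b in g])
        if not _is_unimodal(amps, tol):
            continue
        k = int(np.argmax(amps))
        runs.append(
            LPMRun(
                breaths=tuple(g),
                t_start=g[0].t_start,
                t_end=g[-1].t_end,
                zenith_amp_mm=float(amps[k]),
                zenith_t=g[k].t_center,
                n_breaths=len(g),
                monotone_flat=bool(amps.max() - amps.min() <= tol + _EPS),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Segment scoring


def measure_cycle_length(lpm_runs: list[LPMRun]) -> float | None:
    """Mean zenith-to-zenith interval of successive runs; ``None`` when
    fewer than two runs are available."""
    if len(lpm_runs) < 2:
        return None
    zeniths = np.sort([r.zenith_t for r in lpm_runs])
    return float(np.mean(np.diff(zeniths)))


def score_segment(
    segment: Segment,
    lpm_runs: list[LPMRun],
    mms_events: list[MMSEvent],
    config: DetectorConfig | None = None,
    csb_label: bool | None = None,
) -> SegmentFeatures:
    """Apply the segment-level periodicity rule.

    LPM is present when at least ``min_periodic_events`` runs start inside
    the fragment *and* the run-onset intervals fall in the physiological
    period band with coefficient of variation <= ``period_cv_max`` (the
    runs recur regularly, not just often).  SPM is present when at least
    ``spm_min_events`` sharp movements occur.  Events are assigned to the
    fragment containing their onset.
    """
    config = config or DetectorConfig()
    runs_in = sorted(
        (r for r in lpm_runs if segment.contains(r.t_start)), key=lambda r: r.t_start
    )
    mms_in = [m for m in mms_events if segment.contains(m.t_peak - m.rise_s)]

    lpm_present = len(runs_in) >= config.min_periodic_events
    if lpm_present and len(runs_in) >= 2:
        onsets = np.array([r.t_start for r in runs_in])
        intervals = np.diff(onsets)
        lo, hi = config.period_band_s
        in_band = bool(np.all((intervals >= lo - _EPS) & (intervals <= hi + _EPS)))
        mean = float(np.mean(intervals))
        cv = float(np.std(intervals) / mean) if mean > 0 else np.inf
        lpm_present = in_band and cv <= config.period_cv_max + _EPS

    return SegmentFeatures(
        segment_id=segment.segment_id,
        lpm_present=lpm_present,
        spm_present=len(mms_in) >= config.spm_min_events,
        n_lpm_runs=len(runs_in),
        n_mms=len(mms_in),
        mean_cycle_length_s=measure_cycle_length(runs_in),
        csb_label=csb_label,
    )


def extract_features(
    signal: MMSignal,
    config: DetectorConfig | None = None,
    segment_length_s: float = 180.0,
    annotations=None,
) -> pd.DataFrame:
    """Run the full detector over a recording and score every fragment.

    Detection (breaths, MMS, runs) happens once over the whole recording;
    events are then assigned to fragments by onset.  When ``annotations``
    (an :class:`~mmcsb.io.AnnotationSet`) is given, its ``true_csb`` column
    is merged in as ``csb_label``.

    Returns a tidy frame with one row per fragment: ``segment_id,
    start_s, end_s, lpm_present, spm_present, n_lpm_runs, n_mms,
    mean_cycle_length_s[, csb_label]``.
    """
    config = config or DetectorConfig()
    segments = segment_signal(signal, segment_length_s)
    breaths = detect_breaths(signal, config)
    mms = detect_mms(signal, breaths, config)
    runs = detect_lpm(breaths, config)

    labels = {}
    if annotations is not None:
        labels = dict(
            zip(annotations.segments["segment_id"], annotations.segments["true_csb"])
        )
    rows = []
    for seg in segments:
        feats = score_segment(
            seg, runs, mms, config, csb_label=labels.get(seg.segment_id)
        )
        rows.append(
            {
                "segment_id": seg.segment_id,
                "start_s": seg.start_s,
                "end_s": seg.end_s,
                "lpm_present": feats.lpm_present,
                "spm_present": feats.spm_present,
                "n_lpm_runs": feats.n_lpm_runs,
                "n_mms": feats.n_mms,
                "mean_cycle_length_s": feats.mean_cycle_length_s,
                **({"csb_label": feats.csb_label} if annotations is not None else {}),
            }
        )
    return pd.DataFrame(rows)
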