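"""Synthetic mandibular-movement recordings with ground-truth annotations.

The generator emulates the MM patterns a chin magnetometer records during
sleep, at the device's native 10 Hz / 0.1 mm quantization:

* quiet breathing — oscillations at the respiratory frequency with
  peak-to-trough amplitude <= 0.3 mm around a slightly open baseline;
* Cheyne-Stokes cycles — a central apnea (flat trace) followed by a
  hyperpnea of >= 5 breaths whose amplitudes wax and wane (raised-cosine
  envelope peaking at ``csb_peak_amp_mm``), repeating with a cycle length
  of ~35-90 s depending on aetiology;
* sharp mouth-closure movements (MMS) at cortical arousals — a brief
  opening dip followed by a sharp (> 3 mm) closure toward zero;
* obstructive-event morphology — breathing riding on a progressively more
  negative baseline (mouth opening under increasing effort) terminated by
  one sharp closure; a negative-class confounder whose terminal closure is
  nonetheless a genuine MMS;
* white measurement noise, slow sinusoidal baseline drift, and rounding of
  every emitted sample to the 0.1 mm hardware resolution.

``simulate_recording`` assembles whole multi-segment cohorts with exact,
seed-reproducible prevalence allocation and per-segment/per-event truth
tables (:class:`~mmcsb.io.AnnotationSet`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import EVENT_COLUMNS, SEGMENT_COLUMNS, AnnotationSet, MMSignal

__all__ = [
    "SimConfig",
    "simulate_normal_breathing",
    "simulate_csb_cycle",
    "simulate_obstructive_event",
    "simulate_recording",
]

_DRIFT_PERIOD_S = 300.0  # slow baseline wander, well below the CSB period band


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic MM generator.

    Amplitudes are peak-to-trough in mm; the defaults encode the device
    constants (10 Hz sampling, 0.1 mm resolution) and the physiological
    regime the detection rules assume: normal breaths <= 0.3 mm, CSB
    hyperpnea breaths >= 0.3 mm with a 1.0 mm zenith, arousal closures of
    4 mm (> 3 mm rule), and a 60 s cycle length (within the 35-90 s band
    spanning non-heart-failure to systolic-heart-failure periodic
    breathing).
    """

    sampling_rate: float = 10.0
    resolution_mm: float = 0.1
    resp_freq: float = 0.25
    normal_amp_mm: float = 0.2
    csb_cycle_length_s: float = 60.0
    hyperpnea_fraction: float = 0.6
    breaths_per_hyperpnea: int | None = None
    csb_peak_amp_mm: float = 1.0
    hyperpnea_floor_amp_mm: float = 0.4
    arousal_prob: float = 0.7
    mms_amp_mm: float = 4.0
    mms_duration_s: float = 1.0
    noise_sd_mm: float = 0.02
    drift_amp_mm: float = 0.1
    baseline_mm: float = -1.0
    # cohort composition
    sparse_csb_fraction: float = 0.15
    sparse_cycle_length_s: float = 90.0
    obstructive_fraction: float = 0.08
    obstructive_duration_s: float = 40.0
    seed: int | None = None

    def __post_init__(self):
        pos = {
            "sampling_rate": self.sampling_rate,
            "resolution_mm": self.resolution_mm,
            "resp_freq": self.resp_freq,
            "normal_amp_mm": self.normal_amp_mm,
            "csb_cycle_length_s": self.csb_cycle_length_s,
            "csb_peak_amp_mm": self.csb_peak_amp_mm,
            "hyperpnea_floor_amp_mm": self.hyperpnea_floor_amp_mm,
            "mms_duration_s": self.mms_duration_s,
            "sparse_cycle_length_s": self.sparse_cycle_length_s,
            "obstructive_duration_s": self.obstructive_duration_s,
        }
        for name, value in pos.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.normal_amp_mm > 0.3:
            raise ConfigError(
                "normal_amp_mm must be <= 0.3 mm (normal breaths would cross "
                "the large-movement threshold)"
            )
        if self.csb_peak_amp_mm < 0.3:
            raise ConfigError(
                "csb_peak_amp_mm must be >= 0.3 mm (hyperpnea zenith would be "
                "indistinguishable from normal breathing)"
            )
        if not 0.3 <= self.hyperpnea_floor_amp_mm <= self.csb_peak_amp_mm:
            raise ConfigError(
                "hyperpnea_floor_amp_mm must lie in [0.3, csb_peak_amp_mm]"
            )
        if self.mms_amp_mm <= 3.0:
            raise ConfigError("mms_amp_mm must exceed the 3 mm sharp-movement threshold")
        if not 0.0 < self.hyperpnea_fraction < 1.0:
            raise ConfigError("hyperpnea_fraction must be in (0, 1)")
        for name, value in (
            ("arousal_prob", self.arousal_prob),
            ("sparse_csb_fraction", self.sparse_csb_fraction),
            ("obstructive_fraction", self.obstructive_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.noise_sd_mm < 0 or self.drift_amp_mm < 0:
            raise ConfigError("noise_sd_mm and drift_amp_mm must be non-negative")
        if self.baseline_mm > 0:
            raise ConfigError("baseline_mm must be <= 0 (closed mouth is the zero)")
        if self.breaths_per_hyperpnea is not None and self.breaths_per_hyperpnea < 5:
            raise ConfigError("breaths_per_hyperpnea must be >= 5")

    def n_hyperpnea_breaths(self, cycle_length_s: float | None = None) -> int:
        """Breath count per hyperpnea (explicit, or derived from the cycle)."""
        if self.breaths_per_hyperpnea is not None:
            return self.breaths_per_hyperpnea
        cycle = self.csb_cycle_length_s if cycle_length_s is None else cycle_length_s
        n = math.floor(self.hyperpnea_fraction * cycle * self.resp_freq + 1e-9)
        if n < 5:
            raise ConfigError(
                "derived hyperpnea breath count is < 5; increase "
                "csb_cycle_length_s, hyperpnea_fraction or resp_freq"
            )
        return n


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _quantize(x: np.ndarray, resolution_mm: float) -> np.ndarray:
    return np.round(x / resolution_mm) * resolution_mm


def _noise_and_drift(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / config.sampling_rate
    out = np.zeros(n)
    if config.drift_amp_mm > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += config.drift_amp_mm * np.sin(2 * np.pi * t / _DRIFT_PERIOD_S + phase)
    if config.noise_sd_mm > 0:
        out += rng.normal(0.0, config.noise_sd_mm, n)
    return out


def _finalize(raw: np.ndarray, config: SimConfig, rng: np.random.Generator) -> MMSignal:
    samples = _quantize(raw + _noise_and_drift(raw.size, config, rng), config.resolution_mm)
    return MMSignal(
        samples=samples,
        sampling_rate=config.sampling_rate,
        resolution_mm=config.resolution_mm,
    )


# ---------------------------------------------------------------------------
# Clean (noise-free, un-quantized) fragment builders


def _normal_raw(duration_s: float, config: SimConfig) -> np.ndarray:
    """Quiet breathing: baseline with sub-0.3 mm respiratory dips.

    Each breath dips from the baseline toward opening and returns, so the
    trace meets the flat apneic baseline continuously at fragment edges.
    """
    n = int(round(duration_s * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    osc = -(config.normal_amp_mm / 2.0) * (1.0 - np.cos(2 * np.pi * config.resp_freq * t))
    return config.baseline_mm + osc


def _mms_waveform(config: SimConfig) -> np.ndarray:
    """Arousal closure: brief opening dip to -mms_amp, sharp linear closure
    to 0 over mms_duration/2, then relaxation back to the baseline.

    The closure excursion (dip trough to closed-mouth zero) is exactly
    ``mms_amp_mm`` and completes well inside the sharpness window.
    """
    fs = config.sampling_rate
    half = max(1, int(round(config.mms_duration_s / 2.0 * fs)))
    relax = max(1, int(round(1.0 * fs)))
    down = np.linspace(config.baseline_mm, -config.mms_amp_mm, half, endpoint=False)
    up = np.linspace(-config.mms_amp_mm, 0.0, half, endpoint=False)
    back = np.linspace(0.0, config.baseline_mm, relax, endpoint=False)
    return np.concatenate([down, up, back])


def _hyperpnea_amplitudes(n_breaths: int, config: SimConfig) -> np.ndarray:
    """Crescendo-decrescendo (raised-cosine) peak-to-trough amplitudes.

    Scaled so every breath is >= ``hyperpnea_floor_amp_mm`` (> 0.3 mm rule)
    and the zenith equals ``csb_peak_amp_mm`` exactly.
    """
    k = np.arange(1, n_breaths + 1)
    w = np.sin(np.pi * k / (n_breaths + 1)) ** 2
    w = w / w.max()
    return config.hyperpnea_floor_amp_mm + (config.csb_peak_amp_mm - config.hyperpnea_floor_amp_mm) * w


def _csb_cycle_raw(
    config: SimConfig,
    rng: np.random.Generator,
    cycle_length_s: float | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """One CSB cycle (apnea then enveloped hyperpnea), event times in
    seconds relative to the cycle start."""
    fs = config.sampling_rate
    cycle = config.csb_cycle_length_s if cycle_length_s is None else cycle_length_s
    apnea_s = (1.0 - config.hyperpnea_fraction) * cycle
    n_breaths = config.n_hyperpnea_breaths(cycle)
    breath_T = 1.0 / config.resp_freq

    n_apnea = int(round(apnea_s * fs))
    apnea = np.full(n_apnea, config.baseline_mm)
    events: list[dict] = [{"event_type": "apnea", "start_s": 0.0, "end_s": n_apnea / fs}]

    # optional arousal closure near the end of the apnea, kept clear of the
    # first hyperpnea breath so event morphologies do not overlap
    if config.arousal_prob > 0 and rng.uniform() < config.arousal_prob:
        wf = _mms_waveform(config)
        margin = int(round(2.0 * fs))
        i1 = n_apnea - margin
        i0 = i1 - wf.size
        if i0 >= 0:
            apnea[i0:i1] = wf
            events.append(
                {"event_type": "MMS", "start_s": i0 / fs, "end_s": i1 / fs}
            )

    amps = _hyperpnea_amplitudes(n_breaths, config)
    n_per_breath = int(round(breath_T * fs))
    tb = np.arange(n_per_breath) / fs
    shape = (1.0 - np.cos(2 * np.pi * config.resp_freq * tb)) / 2.0  # 0 -> 1 -> 0
    hyper = config.baseline_mm - np.concatenate([a * shape for a in amps])
    events.append(
        {
            "event_type": "LPM_run",
            "start_s": n_apnea / fs,
            "end_s": (n_apnea + hyper.size) / fs,
        }
    )
    return np.concatenate([apnea, hyper]), events


def _obstructive_raw(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    """Obstructive-event morphology over ``obstructive_duration_s``.

    Normal-amplitude breathing on a monotonically descending baseline
    (progressive mouth opening), terminated by one sharp closure to 0 and a
    relaxation back to the resting baseline.
    """
    fs = config.sampling_rate
    n = int(round(config.obstructive_duration_s * fs))
    half = max(1, int(round(config.mms_duration_s / 2.0 * fs)))
    relax = max(1, int(round(1.0 * fs)))
    n_ramp = n - half - relax
    if n_ramp <= 0:
        raise ConfigError("obstructive_duration_s too short for the closure waveform")
    t = np.arange(n_ramp) / fs
    ramp = config.baseline_mm - config.mms_amp_mm * t / (n_ramp / fs)
    osc = -(config.normal_amp_mm / 2.0) * (1.0 - np.cos(2 * np.pi * config.resp_freq * t))
    body = ramp + osc
    closure = np.linspace(body[-1], 0.0, half, endpoint=False)
    back = np.linspace(0.0, config.baseline_mm, relax, endpoint=False)
    events = [
        {"event_type": "obstructive", "start_s": 0.0, "end_s": n / fs},
        {"event_type": "MMS", "start_s": n_ramp / fs, "end_s": (n_ramp + half + relax) / fs},
    ]
    return np.concatenate([body, closure, back]), events


# ---------------------------------------------------------------------------
# Public fragment operations (noise + drift + quantization applied)


def simulate_normal_breathing(
    duration_s: float, config: SimConfig | None = None, rng_state=None
) -> MMSignal:
    """Quiet-breathing fragment: respiratory oscillation <= 0.3 mm
    peak-to-trough around a slightly open baseline, plus noise/drift,
    quantized to the device resolution."""
    config = config or SimConfig()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    return _finalize(_normal_raw(duration_s, config), config, rng)


def simulate_csb_cycle(
    config: SimConfig | None = None, rng_state=None, cycle_length_s: float | None = None
) -> tuple[MMSignal, list[dict]]:
    """One Cheyne-Stokes cycle and its event records.

    The cycle is an apneic phase (flat baseline) followed by a hyperpnea of
    ``breaths_per_hyperpnea`` breaths under a raised-cosine envelope; with
    probability ``arousal_prob`` one sharp closure (MMS) is placed at the
    apnea end.  Event times are relative to the fragment start.
    """
    config = config or SimConfig()
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    raw, events = _csb_cycle_raw(config, rng, cycle_length_s)
    return _finalize(raw, config, rng), events


def simulate_obstructive_event(
    config: SimConfig | None = None, rng_state=None
) -> MMSignal:
    """Obstructive-event fragment (negative-class confounder): progressive
    mouth opening under normal-amplitude oscillation, ended by one sharp
    closure."""
    config = config or SimConfig()
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    raw, _ = _obstructive_raw(config, rng)
    return _finalize(raw, config, rng)


# ---------------------------------------------------------------------------
# Whole-recording assembly


def _build_csb_segment(
    seg_len_s: float, config: SimConfig, rng: np.random.Generator, sparse: bool
) -> tuple[np.ndarray, list[dict], int]:
    """A CSB segment: as many whole cycles as fit, then flat padding.

    Returns (samples, events, n_cycles).  ``sparse`` uses the long cycle
    length so fewer than three hyperpneas fit in the segment and the LPM
    periodicity rule cannot fire (SPM-only CSB presentation).
    """
    fs = config.sampling_rate
    cycle_len = config.sparse_cycle_length_s if sparse else None
    pieces, events = [], []
    offset = 0.0
    n_cycles = 0
    n_target = int(round(seg_len_s * fs))
    while True:
        raw, ev = _csb_cycle_raw(config, rng, cycle_len)
        if int(round(offset * fs)) + raw.size > n_target:
            break
        for e in ev:
            events.append(
                {
                    "event_type": e["event_type"],
                    "start_s": e["start_s"] + offset,
                    "end_s": e["end_s"] + offset,
                }
            )
        pieces.append(raw)
        offset += raw.size / fs
        n_cycles += 1
    n_have = sum(p.size for p in pieces)
    pieces.append(np.full(n_target - n_have, config.baseline_mm))
    return np.concatenate(pieces), events, n_cycles


def _build_obstructive_segment(
    seg_len_s: float, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    """Quiet breathing with one embedded obstructive event."""
    fs = config.sampling_rate
    n_target = int(round(seg_len_s * fs))
    body, ev = _obstructive_raw(config, rng)
    max_start = seg_len_s - config.obstructive_duration_s - 10.0
    start_s = rng.uniform(10.0, max(10.0, max_start)) if max_start > 10.0 else 0.0
    i0 = int(round(start_s * fs))
    raw = _normal_raw(seg_len_s, config)[:n_target]
    raw[i0 : i0 + body.size] = body
    events = [
        {
            "event_type": e["event_type"],
            "start_s": e["start_s"] + i0 / fs,
            "end_s": e["end_s"] + i0 / fs,
        }
        for e in ev
    ]
    return raw, events


def simulate_recording(
    n_segments: int,
    csb_prevalence: float,
    config: SimConfig | None = None,
    seed: int | None = None,
    segment_length_s: float = 180.0,
) -> tuple[MMSignal, AnnotationSet]:
    """Simulate a whole labelled cohort of scoring segments.

    Exactly ``round(csb_prevalence * n_segments)`` segments are CSB; the
    allocation (and the sparse-CSB / obstructive sub-allocations) is
    deterministic given ``seed``, with positions shuffled by the seeded
    generator.  Ground truth: ``true_lpm`` is set when at least three
    hyperpnea runs were constructed in the segment, ``true_spm`` when at
    least one sharp closure was placed, ``true_csb`` by construction.

    Returns the concatenated, noise-added, quantized recording and its
    :class:`~mmcsb.io.AnnotationSet`.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if not 0.0 <= csb_prevalence <= 1.0:
        raise ValueError("csb_prevalence must be in [0, 1]")
    config = config or SimConfig()
    rng = _as_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate

    n_csb = int(round(csb_prevalence * n_segments))
    n_sparse = int(round(config.sparse_csb_fraction * n_csb))
    n_neg = n_segments - n_csb
    n_obst = int(round(config.obstructive_fraction * n_neg))
    kinds = (
        ["csb_full"] * (n_csb - n_sparse)
        + ["csb_sparse"] * n_sparse
        + ["obstructive"] * n_obst
        + ["normal"] * (n_neg - n_obst)
    )
    kinds = [kinds[i] for i in rng.permutation(n_segments)]

    pieces: list[np.ndarray] = []
    seg_rows, event_rows = [], []
    for seg_id, kind in enumerate(kinds):
        t0 = seg_id * segment_length_s
        if kind in ("csb_full", "csb_sparse"):
            raw, events, n_cycles = _build_csb_segment(
                segment_length_s, config, rng, sparse=(kind == "csb_sparse")
            )
            true_csb = True
            true_lpm = n_cycles >= 3
        elif kind == "obstructive":
            raw, events = _build_obstructive_segment(segment_length_s, config, rng)
            true_csb = true_lpm = False
        else:
            raw = _normal_raw(segment_length_s, config)
            events = []
            true_csb = true_lpm = False
        true_spm = any(e["event_type"] == "MMS" for e in events)
        pieces.append(raw)
        seg_rows.append(
            {
                "segment_id": seg_id,
                "start_s": t0,
                "end_s": t0 + segment_length_s,
                "true_csb": true_csb,
                "true_lpm": true_lpm,
                "true_spm": true_spm,
            }
        )
        for e in events:
            event_rows.append(
                {
                    "event_type": e["event_type"],
                    "start_s": e["start_s"] + t0,
                    "end_s": e["end_s"] + t0,
                }
            )

    raw_all = np.concatenate(pieces)
    signal = _finalize(raw_all, config, rng)
    annotations = AnnotationSet(
        segments=pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS),
        events=pd.DataFrame(event_rows, columns=EVENT_COLUMNS),
    )
    return signal, annotations
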