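import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sinusoid
from mmcsb import (
    Breath,
    ConfigError,
    DetectorConfig,
    LPMRun,
    MMSignal,
    Segment,
    SimConfig,
    detect_breaths,
    detect_lpm,
    detect_mms,
    measure_cycle_length,
    score_segment,
    simulate_recording,
)
from oracles import brute_force_lpm_windows


def make_breaths(amplitudes, t0=0.0, period=4.0, gap_after=None):
    """Contiguous breaths with given amplitudes; optional index->gap map."""
    breaths = []
    t = t0
    for i, a in enumerate(amplitudes):
        breaths.append(
            Breath(
                t_start=t,
                t_end=t + period,
                t_center=t + period / 2,
                amplitude_mm=a,
                is_large=a >= 0.3 - 1e-9,
            )
        )
        t += period
        if gap_after and i in gap_after:
            t += gap_after[i]
    return breaths


def make_run(onset, zenith_amp=0.8, n=5, period=4.0) -> LPMRun:
    breaths = make_breaths([0.4, 0.6, zenith_amp, 0.6, 0.4][:n], t0=onset, period=period)
    return LPMRun(
        breaths=tuple(breaths),
        t_start=onset,
        t_end=onset + n * period,
        zenith_amp_mm=zenith_amp,
        zenith_t=onset + 2.5 * period,
        n_breaths=n,
    )


class TestDetectorConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            DetectorConfig(mml_threshold_mm=3.5)
        with pytest.raises(ConfigError):
            DetectorConfig(mml_threshold_mm=0.0)

    def test_relaxing_run_length_warns(self):
        with pytest.warns(UserWarning, match="5-breath"):
            DetectorConfig(min_breaths_per_run=3)


class TestDetectBreaths:
    def test_small_sinusoid_fifteen_breaths_none_large(self):
        sig = make_sinusoid(60, 0.25, 0.2)
        breaths = detect_breaths(sig)
        assert len(breaths) == 15
        assert not any(b.is_large for b in breaths)

    def test_large_sinusoid_all_large(self):
        sig = make_sinusoid(60, 0.25, 0.4)
        breaths = detect_breaths(sig)
        assert len(breaths) == 15
        assert all(b.is_large for b in breaths)

    def test_flat_signal_with_noise_yields_no_breaths(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(-1.0, 0.02, 1200) / 0.1) * 0.1
        assert detect_breaths(MMSignal(x, sampling_rate=10.0)) == []

    def test_too_short_input_is_empty(self):
        sig = make_sinusoid(2.0, 0.25, 0.4)
        assert detect_breaths(sig) == []

    def test_breath_durations_within_bounds(self):
        sig = make_sinusoid(120, 0.25, 0.4)
        cfg = DetectorConfig()
        lo, hi = cfg.breath_duration_bounds_s
        for b in detect_breaths(sig, cfg):
            assert lo - 1e-9 <= b.duration_s <= hi + 1e-9

    def test_offset_invariance(self):
        """Amplitude rules must ignore constant mandibular offsets."""
        sig = make_sinusoid(120, 0.25, 0.5, quantize=False)
        shifted = MMSignal(sig.samples - 0.7, sampling_rate=10.0)
        a = detect_breaths(sig)
        b = detect_breaths(shifted)
        assert len(a) == len(b)
        np.testing.assert_allclose(
            [x.amplitude_mm for x in a], [x.amplitude_mm for x in b], atol=1e-9
        )


def spike_signal(excursion_mm=4.0, rise_s=0.5, breath_amp=0.2, fs=10.0):
    """Quiet breathing with one symmetric upward (closure) spike."""
    sig = make_sinusoid(120, 0.25, breath_amp, fs=fs, quantize=False)
    x = sig.samples.copy()
    n_rise = int(rise_s * fs)
    apex = int(60 * fs)
    up = np.linspace(0, excursion_mm, n_rise + 1)  # apex sample reaches the full excursion
    x[apex - n_rise : apex + 1] += up
    x[apex + 1 : apex + n_rise + 1] += up[::-1][1:]
    return MMSignal(x, sampling_rate=fs)


class TestDetectMMS:
    def test_sharp_large_spike_detected_with_ratio(self):
        sig = spike_signal(4.0, 0.5, 0.2)
        breaths = detect_breaths(sig)
        events = detect_mms(sig, breaths)
        assert len(events) == 1
        ev = events[0]
        assert ev.excursion_mm == pytest.approx(4.0, abs=0.3)
        assert ev.rise_s <= 2.0
        assert ev.ratio_to_baseline == pytest.approx(20.0, rel=0.1)

    def test_subthreshold_spike_ignored(self):
        sig = spike_signal(2.0, 0.5)
        assert detect_mms(sig, detect_breaths(sig)) == []

    def test_slow_rise_fails_sharpness(self):
        sig = spike_signal(3.5, 8.0)
        assert detect_mms(sig, detect_breaths(sig)) == []

    def test_mms_scale_excursions_not_counted_as_breaths(self):
        sig = spike_signal(4.0, 0.5)
        for b in detect_breaths(sig):
            assert b.amplitude_mm < 3.0


class TestDetectLPM:
    def test_crescendo_decrescendo_run(self):
        breaths = make_breaths([0.32, 0.45, 0.80, 0.45, 0.32])
        runs = detect_lpm(breaths)
        assert len(runs) == 1
        assert runs[0].zenith_amp_mm == pytest.approx(0.80)
        assert runs[0].n_breaths == 5
        assert not runs[0].monotone_flat

    def test_four_breaths_insufficient(self):
        assert detect_lpm(make_breaths([0.4, 0.5, 0.6, 0.7])) == []

    def test_flat_plateau_accepted_but_flagged(self):
        runs = detect_lpm(make_breaths([0.5] * 8))
        assert len(runs) == 1
        assert runs[0].monotone_flat

    def test_bimodal_envelope_rejected(self):
        assert detect_lpm(make_breaths([0.4, 0.8, 0.4, 0.8, 0.4, 0.8])) == []

    def test_small_breath_splits_runs(self):
        amps = [0.4, 0.6, 0.8, 0.6, 0.4, 0.2, 0.4, 0.6, 0.8, 0.6, 0.4]
        runs = detect_lpm(make_breaths(amps))
        assert len(runs) == 2

    def test_long_quiescent_gap_splits_runs(self):
        breaths = make_breaths(
            [0.4, 0.6, 0.8, 0.6, 0.4] * 2, gap_after={4: 24.0}
        )
        runs = detect_lpm(breaths)
        assert len(runs) == 2

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_agrees_with_brute_force_window_scan(self, data):
        """Oracle equivalence on random amplitude sequences (<=30 breaths)."""
        n = data.draw(st.integers(2, 30))
        amps = data.draw(
            st.lists(st.floats(0.1, 1.2, allow_nan=False), min_size=n, max_size=n)
        )
        gap_positions = data.draw(st.sets(st.integers(0, n - 1), max_size=3))
        breaths = make_breaths(
            [round(a, 2) for a in amps], gap_after={i: 30.0 for i in gap_positions}
        )
        cfg = DetectorConfig()
        got = [
            (breaths.index(r.breaths[0]), breaths.index(r.breaths[-1]))
            for r in detect_lpm(breaths, cfg)
        ]
        assert got == brute_force_lpm_windows(breaths, cfg)

    def test_raising_threshold_never_adds_runs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            amps = np.round(rng.uniform(0.1, 1.0, rng.integers(5, 25)), 2)
            lo = len(detect_lpm(make_breaths(amps), DetectorConfig(mml_threshold_mm=0.3)))
            hi = len(detect_lpm(make_breaths(amps), DetectorConfig(mml_threshold_mm=0.5)))
            assert hi <= lo


class TestScoreSegment:
    @pytest.fixture()
    def segment(self) -> Segment:
        parent = MMSignal(np.zeros(1800), sampling_rate=10.0)
        return Segment(segment_id=0, start_s=0.0, end_s=180.0, parent=parent)

    def test_three_periodic_runs_fire_the_rule(self, segment):
        runs = [make_run(0.0), make_run(60.0), make_run(120.0)]
        feats = score_segment(segment, runs, [])
        assert feats.lpm_present
        assert feats.n_lpm_runs == 3
        assert feats.mean_cycle_length_s == pytest.approx(60.0)

    def test_two_runs_insufficient(self, segment):
        feats = score_segment(segment, [make_run(0.0), make_run(60.0)], [])
        assert not feats.lpm_present
        assert feats.mean_cycle_length_s == pytest.approx(60.0)

    def test_sharp_movement_alone_sets_spm_only(self, segment):
        from mmcsb import MMSEvent

        mms = [MMSEvent(t_peak=50.0, excursion_mm=4.0, rise_s=0.5,
                        baseline_amp_mm=0.2, ratio_to_baseline=20.0)]
        feats = score_segment(segment, [], mms)
        assert not feats.lpm_present
        assert feats.spm_present
        assert feats.n_mms == 1

    def test_irregular_intervals_fail_periodicity(self, segment):
        # intervals 20, 60, 90 s -> CV ~ 0.51 > 0.5
        runs = [make_run(t) for t in (0.0, 20.0, 80.0, 170.0)]
        feats = score_segment(segment, runs, [])
        assert not feats.lpm_present
        assert feats.n_lpm_runs == 4

    def test_out_of_band_interval_fails_periodicity(self, segment):
        runs = [make_run(t, period=1.0) for t in (0.0, 10.0, 20.0)]  # 10 s < band
        assert not score_segment(segment, runs, []).lpm_present

    def test_raising_min_periodic_events_never_adds_positives(self, segment):
        runs = [make_run(t) for t in (0.0, 60.0, 120.0)]
        relaxed = score_segment(segment, runs, [], DetectorConfig(min_periodic_events=3))
        strict = score_segment(segment, runs, [], DetectorConfig(min_periodic_events=4))
        assert relaxed.lpm_present and not strict.lpm_present


class TestCycleLength:
    def test_mean_zenith_interval(self):
        runs = [make_run(t - 10.0) for t in (10.0, 70.0, 130.0)]
        assert measure_cycle_length(runs) == pytest.approx(60.0)

    def test_single_run_undefined(self):
        assert measure_cycle_length([make_run(0.0)]) is None

    def test_recovered_from_simulated_recording(self):
        cfg = SimConfig(csb_cycle_length_s=45.0, sparse_csb_fraction=0.0)
        from mmcsb import extract_features

        sig, ann = simulate_recording(6, 1.0, cfg, seed=11)
        feats = extract_features(sig, annotations=ann)
        measured = feats["mean_cycle_length_s"].dropna()
        assert len(measured)
        # the generator builds whole breaths, so the realised cycle is the
        # configured one rounded down to a whole number of breath periods
        assert np.abs(measured - 45.0).max() <= 4.5
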