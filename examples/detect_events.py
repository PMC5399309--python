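"""Score one Cheyne-Stokes cycle with the rule-based detector.

Simulates a single noise-free 60-s CSB cycle (24 s central apnea, then a
9-breath crescendo-decrescendo hyperpnea with an arousal closure), runs
breath / sharp-movement / run detection, and prints what each rule found.
"""

from mmcsb import SimConfig, detect_breaths, detect_lpm, detect_mms, simulate_csb_cycle

config = SimConfig(noise_sd_mm=0.0, drift_amp_mm=0.0, arousal_prob=1.0)
signal, truth = simulate_csb_cycle(config, rng_state=0)

breaths = detect_breaths(signal)
mms = detect_mms(signal, breaths)
runs = detect_lpm(breaths)

print(f"cycle: {signal.duration_s:.0f} s "
      f"({[e['event_type'] for e in truth]} constructed)")
print(f"breaths detected: {len(breaths)}")
print("  amplitudes (mm):", [round(b.amplitude_mm, 2) for b in breaths])
# all breaths are 'large' (>= 0.3 mm) and the envelope waxes then wanes,
# so they form a single LPM run — the MM signature of one hyperpnea
for run in runs:
    print(f"LPM run: {run.n_breaths} breaths, "
          f"zenith {run.zenith_amp_mm:.2f} mm at t={run.zenith_t:.1f} s")
for ev in mms:
    print(f"MMS: {ev.excursion_mm:.1f} mm closure in {ev.rise_s:.1f} s at "
          f"t={ev.t_peak:.1f} s (>{3} mm and sharp -> arousal marker)")
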