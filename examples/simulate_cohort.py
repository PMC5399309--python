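"""Generate a labelled synthetic cohort of mandibular-movement segments.

Builds a 30-segment recording at the study prevalence, writes it to EDF +
CSV, and prints the ground-truth composition.  Each 3-min segment is either
Cheyne-Stokes breathing (repeated apnea/hyperpnea cycles, optionally with
arousal closures), quiet breathing, or quiet breathing with one embedded
obstructive event.
"""

from pathlib import Path

from mmcsb import SimConfig, simulate_recording, write_annotations, write_mm_edf

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)

config = SimConfig()  # 10 Hz, 0.1 mm, 60 s CSB cycles, 4 mm arousal closures
signal, annotations = simulate_recording(30, csb_prevalence=0.5, config=config, seed=7)

write_mm_edf(signal, out / "recording.edf")
write_annotations(annotations, out / "annotations.csv", out / "events.csv")

seg = annotations.segments
print(f"recording: {signal.duration_s:.0f} s at {signal.sampling_rate:.0f} Hz")
print(f"segments : {len(seg)} total, {int(seg.true_csb.sum())} CSB")
print(f"  LPM-positive truth: {int(seg.true_lpm.sum())} "
      "(CSB segments with >= 3 hyperpnea cycles)")
print(f"  SPM-positive truth: {int(seg.true_spm.sum())} "
      "(segments containing a sharp >3 mm closure)")
print(f"events   : {annotations.events.event_type.value_counts().to_dict()}")
print(f"files in {out}/")
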