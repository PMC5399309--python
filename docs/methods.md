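# Methods

This note documents the models and procedures implemented in `mmcsb`, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not show.

## Signal model and conventions

The mandibular-movement (MM) signal is the chin-forehead distance of a
mid-sagittal magnetometer, sampled at 10 Hz and quantized to 0.1 mm.  The
zero of the scale is a completely closed mouth and the signal is processed
so that opening the mouth makes it *more negative*; quiet sleep breathing
oscillates ≤ 0.3 mm peak-to-trough around a slightly open baseline.  All
package rules are amplitude rules on a detrended signal, so detector
output is invariant under constant offsets; readers auto-negate
mostly-positive (raw-distance) exports with a warning.  Time is 0-based
seconds from recording start with half-open `[start, end)` intervals, and
recordings are cut into contiguous 3-min scoring fragments (configurable;
5-min fragments are also in clinical use), dropping a trailing partial
fragment.

## Rule-based event detection

**Preprocessing.**  The trace is high-passed by subtracting a centred
rolling median whose window equals the upper edge of the periodic-breathing
band (120 s).  A rolling median tracks slow drift and removes linear
trends exactly while leaving breath-scale oscillation intact.  Extrema are
located on a lightly smoothed copy (0.5 s moving average) so that
single-sample quantization steps do not split or spawn extrema.

**Breaths.**  Breath candidates are troughs (maximum-opening excursions)
with prominence of at least one quantization step, no closer together than
the minimum breath duration (1.5 s).  Each trough owns a window reaching
halfway to its neighbours, capped at half the maximum breath duration
(10 s / 2).  Its amplitude is the *smaller* of the two flanking maxima
minus the trough.  This local peak-to-trough measure was chosen over the
raw max-min of the window because it is insensitive to monotone trends:
during the progressive mouth opening of an obstructive event the raw
max-min would inflate normal breaths past the 0.3 mm large-movement
threshold, while the two-sided measure correctly suppresses them.
Candidates outside the 1.5–10 s duration bounds or below a 0.15 mm
amplitude floor are discarded; candidates whose raw window excursion
exceeds the 3 mm sharp-movement threshold are routed to MMS detection
instead of the breath list.  A breath is **large (MML)** when its
amplitude is ≥ 0.3 mm.

**Sharp movements (MMS).**  An MMS is an excursion toward closure —
`signal − trailing-2-s minimum` — exceeding 3 mm.  The trailing window
*is* the sharpness rule: a 3.5 mm rise spread over 8 s never accumulates
3 mm of swing inside 2 s and is rejected.  This swing formulation was
chosen over peak prominence because the canonical obstructive closure
returns only to baseline after a deep opening dip and therefore has
near-zero prominence while being a textbook sharp closure.  The ratio of
the excursion to the baseline mandibular motion (median amplitude of the
10 nearest non-overlapping breaths) is recorded for each event but is not
an additional gate, since in practice the > 3 mm criterion already implies
a ratio far above 200 %.

**LPM runs.**  Runs are maximal groups of consecutive large breaths
(adjacent in the breath list, with no quiescent gap longer than the
maximum breath duration — a central apnea always splits runs) with at
least 5 breaths whose amplitude sequence is unimodal: non-decreasing to a
single zenith then non-increasing, each comparison tolerating one
quantization step (0.1 mm).  An all-flat plateau is accepted as a
degenerate crescendo-decrescendo but flagged `monotone_flat`.  Run
detection is verified against an exhaustive brute-force window scan that
applies this definition literally.

**Segment rule.**  A fragment is **LPM-positive** when ≥ 3 runs start
inside it *and* the run-onset intervals lie within 20–120 s (the 35–90 s
physiological cycle-length band with margin) with coefficient of variation
≤ 0.5 — the runs must recur regularly, not merely often.  It is
**SPM-positive** when ≥ 1 MMS occurs (the "at least one sharp movement"
rule; the count is configurable for stricter periodic-SPM variants).
Events are assigned to the fragment containing their onset.  The **cycle
length** is the mean zenith-to-zenith interval of successive runs,
undefined below two runs.

## Classification and validation

The per-fragment features are two booleans (LPM, SPM); the label is CSB.

**Logistic model.**  `logit P(CSB) = β₀ + β₁·LPM + β₂·SPM`, fitted by
IRLS on the aggregated 2×2×2 count table (identical likelihood to the
per-observation fit).  Odds ratios are `exp(β)`, intervals are Wald at a
configurable level (default 95 %), and the log-likelihood/AIC are computed
on the Bernoulli scale, matching a per-observation glm.  With two binary
predictors, complete or quasi-separation is *expected* in clean data
(e.g. every LPM-positive training segment is CSB).  It is detected as
non-convergence within 50 iterations or any |β| > 15 and reported as a
flag; the coefficient vector is then rescaled so its largest entry is 15,
which keeps reported magnitudes finite while exactly preserving the fitted
decision boundary.  The classification threshold is P = 0.5.

**CART.**  Greedy binary partitioning on Gini impurity over the two
features, with a zero-gain guard, ties broken in feature order (LPM
first), and leaves labelled by majority class (ties → negative) with
their training error rate.  Splits whose leaves agree on the predicted
class are pruned, leaving the minimal readable rule with identical
predictions.  Depth is naturally ≤ 2.  Cross-checked against
scikit-learn's tree on random tables (cell-wise predictions).

**Metrics.**  TPR, TNR, PPV, NPV, BAC = (TPR+TNR)/2, rank-based AUC
(ties ½), FNR = 1−TPR, FPR = 1−TNR, MMCE = (FP+FN)/n, BER = (FNR+FPR)/2,
and Cohen's kappa with the classical large-sample interval
`κ ± z·√(p₀(1−p₀)/(n(1−pₑ)²))`.  Undefined metrics (zero denominators)
are reported as absent, never as 0.

**Harness.**  A seeded uniform 50/50 split (odd observation to the test
set) and repeated k-fold cross-validation (default 10 × 10: each repeat
re-partitions the training half into 10 near-equal blocks, each block
tests once; the 100 fold-wise metric sets are averaged, skipping folds
where a metric is undefined).

## Synthetic data generator

The generator emulates the regimes the rules assume, at the device's
native sampling and quantization.  Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| sampling rate / resolution | 10 Hz / 0.1 mm | device constants |
| respiratory frequency | 0.25 Hz | ~15 breaths/min sleep eupnea |
| normal breath amplitude | 0.2 mm | below the 0.3 mm MML threshold |
| CSB cycle length | 60 s | centre of the 45–90 s heart-failure band; 35–90 s supported |
| hyperpnea fraction | 0.6 | breathing 60 % of the cycle |
| hyperpnea envelope | raised cosine, floor 0.4 mm, zenith 1.0 mm | smooth crescendo-decrescendo; every hyperpnea breath safely above 0.3 mm, zenith well clear of it (the literature fixes only the ≥ 0.3 mm bound) |
| arousal probability | 0.7 per cycle | arousals accompany many but not all hyperpneas |
| MMS | 4 mm, 1 s | above the 3 mm rule, sharp |
| noise / drift | 0.02 mm white, 0.1 mm slow sine | sub-quantization measurement noise plus baseline wander |
| baseline | −1.0 mm | slightly open mouth during sleep |

An arousal closure is modelled as a brief opening dip to −4 mm followed by
a sharp closure to 0 and relaxation to baseline.  A one-sided spike from
the −1 mm baseline toward closure cannot reach 4 mm without crossing the
closed-mouth zero, so the dip-then-closure shape is the physically
consistent realisation of a "> 3 mm sharp closure" and matches recordings
where the arousal terminates a period of mouth opening.  The obstructive
confounder is normal-amplitude breathing on a monotonically descending
baseline (progressive opening under mounting effort) ending in exactly
such a closure — it contains a genuine MMS but no crescendo-decrescendo
run.

Cohorts mix four segment types.  CSB segments repeat whole cycles (3 per
3-min segment at the 60 s default, so the ≥ 3 periodicity rule can fire);
a configurable 15 % of CSB segments instead use a 90 s cycle so only two
hyperpneas fit — these are SPM-only presentations whose arousal may also
be absent, producing realistic false negatives.  Non-CSB segments are
quiet breathing, with 8 % containing one obstructive event whose terminal
closure makes them SPM-positive — realistic false positives.  Without
these minority cells the 2×2×2 table would be degenerate and the
logistic/CART comparison vacuous.  Prevalence allocation is deterministic
(`round(p·n)` positives, positions shuffled by the seed) so cohort
composition is exactly reproducible.  Ground truth is recorded per
segment (CSB / LPM / SPM) and per event.

**What the simulation does not model:** REM atonia fading the MM signal,
bruxism/chewing/swallowing artefacts, magnetic interference, flow or
effort channels, and patient-level heterogeneity (all segments of a class
share one parameter set).  Passing the synthetic end-to-end check
therefore demonstrates the internal consistency of the rules, the
estimators and the harness under the stated assumptions — not clinical
performance on patient recordings.

## Numerical choices and degenerate inputs

* Quantization comparisons carry a 1e-9 slack so that 0.1 mm grid values
  compare exactly in floating point.
* Too-short signals yield empty breath lists; fewer than two runs yield an
  absent cycle length; all-zero confusion matrices are rejected;
  single-class labels are a fit error for the logistic model and a
  single-leaf tree for CART.
* The EDF writer stores int16 at 0.01 mm/bit (physical range ±327.67 mm),
  so 0.1 mm-quantized data round-trip exactly; non-whole-second recordings
  fall back to one-sample records.
* Byte-identical reports: all randomness flows through explicit seeds
  recorded in the run manifest.

## Problem sizes

The shipped validation uses the study-scale cohort (1,970 three-minute
segments, ≈ 3.5 M samples) for the end-to-end check, 200 segments for the
noise-free separability check, 200 random sequences for the detector
oracle and 50 random tables for the logistic oracle; these sizes keep a
full run around a minute on one CPU while exercising every rule at the
scale of the original validation study.
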