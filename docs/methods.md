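# Methods

This note documents the models, conventions, parameters and numerical
choices behind `orthosync`: the export dialects and time base, the
marker-based syncing and union merge, the contraction detector and
amplitude summary, the assessment simulator, and the visualization rules.
It also states what the simulator does and does not emulate, and therefore
what passing tests do and do not establish about real recordings.

## Time base and export dialects

All timestamps are stored as **int64 microseconds** from stream-local
recording start. This makes union joins and marker alignment exact integer
operations — whether two samples coincide is never decided by float
equality — and bounds every representational error by one quantum (1 µs).
CSV exports print time at 6 decimals, exactly one quantum.

Five export dialects are defined, one per instrument file:

| stream | time column | rate | data variables |
|---|---|---|---|
| `NOVA_BASIC` | `time_s` | beat-to-beat | 9 (SBP, DBP, MAP, HR, IBI, finger pressure, reconstructed brachial pressure, height correction, cuff-calibration flag) |
| `NOVA_ADV` | `time_s` | beat-to-beat | 13 (CO, CI, SV, SVI, TPR, TPRI, LVET, PP, dP/dt, aortic impedance, windkessel compliance, baroreflex sensitivity, aortic flow) |
| `NIRS` | `sample_n` | 50 Hz | 22 (2 optodes × [3 distances × {O2Hb, HHb, tHb}] + TSI + TSI quality) |
| `EMG_LEFT` / `EMG_RIGHT` | `time_s` | 1024 Hz | 12 each (2 EMG channels, 3-axis accelerometer / gyroscope / magnetometer, battery) |

The NIRS time axis is derived from the sample-number column as *n*/50 s.
Beat-to-beat timestamps are systolic upstroke times; their `IBI` column is
the inter-beat interval, so `HR = 60/IBI` row by row.

**Markers as rows.** Event markers (the manual key presses) are written as
dedicated rows: the time cell carries the press time, data cells are empty,
and the trailing `marker` column carries the label. The alternative —
stamping the label onto the nearest sample row — would quantize marker
times to the sample grid (20 ms for NIRS, a full cardiac cycle for the
beat-to-beat files) and make exact offset recovery impossible. On NIRS
marker rows the sample number is fractional, printed at 5 decimals (1 µs at
50 Hz). Fixed-rate spacing invariants apply to data rows; gaps equal to an
integer number of sample periods are tolerated (dropped packets).

**Round-trip exactness.** `read(write(frame))` is an identity, including
NaN cells. Two pitfalls are handled explicitly: the general write path
prints floats at `%.17g` (pandas' default formatter can be one ulp short of
a round-trip repr) and reads parse with `float_precision="round_trip"`
(pandas' default float conversion is also ulp-inexact). Data already
quantized to 6 decimals — everything the simulator emits, emulating export
precision — takes a fast columnar write path, verified exact for such
values.

## The protocol

The default schedule is: 10 min supine rest, 3 min active stand, 3 min
break, 10 min supine rest, 10 min head-up tilt, with four 10 s prompted
maximum thigh contractions — at the midpoints of the two rests and 30 s
after the stand and the tilt — for six labelled events and a total of
~37 min (within the 35–40 min recording window the protocol prescribes).
The break length and the post-stand squeeze latency are not tightly
specified by the protocol; 3 min and 30 s are pinned defaults, both
configurable. The ~10 s tilt-table travel to 70° is modelled inside the
tilt event. `validate_schedule` returns violations (count, durations,
overlaps, ordering, total length) rather than raising, so it doubles as a
report.

## Syncing and merging

**Stage 1 — instrument level.** Within one instrument group (the two
hemodynamic files; the two EMG loggers) the first file is the reference and
every other file is shifted so its marker for the chosen event coincides
with the reference's. Offsets are exact integer-microsecond differences of
marker times; residual misalignment for the syncing event is identically
zero.

**Stage 2 — full frame.** Each group's reference is then shifted onto the
global reference, pinned to the basic hemodynamic file when present: the
beat-to-beat pressure timeline is the clinical anchor of the assessment
figure. When no event is specified, the earliest marker shared by all
frames is used; with jitter-free markers any shared event yields the same
alignment, and with real key presses the choice only redistributes the
residual human jitter.

**Stage 3 — cross-participant.** Fully synced assessments are merged for
comparison by aligning a chosen event across participants on the reference
participant's clock, suffixing columns per participant. The operation
composes: an already-merged pair can be merged with a third participant
(pass `None` for the suffix it already carries), associatively up to column
order.

**Union merge.** The master timeline is the sorted set union of all sample
timestamps; each channel's values sit at their own timestamps and are
missing elsewhere. No resampling or interpolation occurs anywhere in the
pipeline — missingness is the contract, and the merged frame stores samples
per source (values plus master-row positions) so that a multi-million-row
assessment costs far less than a dense table; dense columns are
materialized on demand.

**Marker columns.** A merged frame carries exactly two marker columns:
`marker_ref`, the reference frame's marker stream, and `marker_other`, the
consolidation of every non-reference marker stream. This rule is closed
under all three merge stages and fixes the default manifest at
9 + 13 + 22 + 24 + 2 = **70 data variables**. After syncing, the
`marker_other` entries for the syncing event coincide with `marker_ref`'s;
entries for other events retain per-stream key-press jitter — real
information about marking precision, not an alignment error.

What marker-based syncing can and cannot fix: clock offsets between files
are removed exactly (injected offsets at the microsecond quantum are
recovered with zero residual), but the per-stream reaction-time jitter of
the key presses (~0.15 s SD in the simulator) is inherited by the aligned
timelines and is irreducible by any shifting method.

## Contraction detection and amplitude summary

Detection is amplitude-based, matching the role of EMG in this assessment
(activation timing, not spectral analysis):

1. full-wave rectification;
2. moving RMS over a **100 ms** window (centered);
3. threshold = baseline median + **5 × MAD**, baseline = first **60 s** of
   the series (supine rest);
4. bridge sub-threshold gaps shorter than **0.25 s**, then discard
   excursions shorter than **0.5 s**;
5. classify an event as *prompted* when its onset falls within **±5 s** of a
   scheduled squeeze.

All parameters live in `DetectorParams`. The threshold additionally gets a
floor of 10⁻⁶ × peak envelope: on a perfectly silent baseline the nominal
threshold is zero while the moving-average accumulator leaves ~√ε × peak
rounding residue in silent stretches; without the floor those residues
would read as one long detection. One millionth of the peak envelope is
never a physiological burst.

Epochs are raw 30 s slices (10 s before the prompt, the 10 s contraction,
10 s after), anchored on the event marker — the recorded prompt — with an
optional detected-onset anchor. No filtering or normalization touches the
stored samples; the envelope exists only inside the detector and the
summary. For fixed-rate channels an epoch is defined as exactly
`round(30 × rate)` consecutive samples starting at the first sample in the
window (with a coverage check): a half-open time slice would contain
30 720 *or* 30 721 EMG samples depending on the sub-sample phase of the
jittered prompt against the rounded grid, whereas the fixed-count
definition is deterministic. Squeezes whose marker is missing or whose
window is not fully covered (early termination of the tilt) are skipped
with a logged notice.

The amplitude summary averages the envelope over each of the 10 contraction
seconds and fits a line to the **interior eight** per-second values
(seconds 1–8), excluding the first and last second, which contain the
prompt rise and release ramps. The reported decay fraction is
−slope × (contraction − 1 s) / (fitted amplitude at 0.5 s). For a burst
whose plateau amplitude declines linearly from *A* to *A*(1 − *d*) between
the 0.5 s ramps, the per-second means are *A*(1 − *d·k*/9), the fit gives
slope −*A·d*/9 and amplitude *A* at 0.5 s, and the estimate returns *d*
exactly in the noiseless limit. With the default simulator noise the
estimate scatters by ~0.03 per epoch (envelope estimation noise through an
8-point fit), so recovery within 10% of a programmed 50% decay holds
per-assessment (averaging the four epochs) rather than per-epoch.

## The simulator

The generator's defaults are the study conditions; waveforms are minimal
phenomenological shapes reproducing each qualitative feature of the
assessment, not mechanistic cardiovascular models.

* **Heart rate** (baseline 70 bpm): on standing, a logistic rise of
  +30 bpm peaking within 20 s (≈100 bpm), relaxing to a sustained +15 bpm
  while upright; on tilt, a gradual saturating rise of +20 bpm
  (τ = 120 s). Beats are generated by stepping *t* ← *t* + 60/HR with a
  midpoint evaluation, which keeps the cumulative beat count within ±2
  beats of ∫HR dt/60 on noiseless runs; optional multiplicative IBI jitter
  (2% SD) roughens the beat-to-beat series.
* **Blood pressure** (baseline 120/70 mmHg): a linear fall to a nadir of
  −30/−15 mmHg at 10 s after stand onset, exponential recovery
  (τ = 8 s), and a 10% overshoot above baseline that itself decays
  (τ = 60 s); increased oscillatory variability and a +5 mmHg diastolic
  drift during tilt; +4 mmHg transients during squeezes. Cardiac output
  (baseline 5 L/min) moves opposite to the pressure transient and bumps at
  squeezes (muscle-pump coupling). Advanced-hemodynamics channels are
  derived per beat (SV = CO/HR, TPR = MAP/CO, …) with channel noise.
* **NIRS** (TSI baselines 70% forehead, 68% thigh): orthostatic TSI
  reductions of −5% (fast, τ = 2 s) and −3% (slow, τ = 30 s)
  respectively, recovering after each stand; −2% thigh dips during
  contractions. Magnitudes are order-of-magnitude choices — no
  quantitative values are established for this protocol — and are flagged
  as such in the config. O2Hb/HHb are reconstructed from TSI and a
  constant total hemoglobin per transmitter distance, so
  TSI = O2Hb/(O2Hb+HHb) holds by construction.
* **EMG** (baseline noise SD 0.01 mV): bursts are Gaussian noise whose SD
  follows a trapezoid envelope — 0.5 s ramps, plateau at
  `burst_ratio` (10×) the baseline SD, floored at the resting level — with
  an optional linear within-burst decay; the plateau envelope is exactly
  proportional to the programmed decay. The fatigued / non-fatigued
  presets differ **only** in this decay (50% vs 0%). Optional non-prompted
  bursts (ratio 6×, 1–3 s) are placed during the tilt, kept clear of
  squeezes (±15 s) and of each other. Inertial channels encode posture
  (supine vs 70° upright) with noise; battery drains slowly.
* **Logistics**: per-stream clock offsets uniform in ±2 s around a 2.5 s
  recording-start pad; per-stream per-event key-press jitter
  N(0, 0.15 s) truncated at ±0.5 s; a pause of the beat-to-beat recording
  during the break (the finger cuff stays mounted but paused, a hard gap
  in both hemodynamic files); cuff-calibration windows in the first
  minutes of rest during which pressure channels are missing but rows
  remain (calibration flag set); optional independent packet drop with
  the surviving fraction reported. `early_stop_s` truncates every stream
  (early termination of the tilt), removing later samples and markers.

Everything stochastic is driven by one seed through independent spawned
generators per stream and purpose, so the same seed yields byte-identical
export files and any subset of streams reproduces the draws of the full
set. Emitted values are rounded to 6 decimals, emulating export precision.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: true cardiovascular dynamics (baroreflex
feedback, respiratory and Mayer-wave variability, arrhythmia), motion and
electrode artifacts in EMG, optode coupling drift and motion artifacts in
NIRS, clock *drift* (rate mismatch) as opposed to constant offset, device
recovery behavior around pauses, and any between-subject amplitude
normalization. Tests against the simulator validate the bookkeeping —
alignment, merging, epoching, detection under the stated noise model — not
physiological fidelity.

## Visualization

The stacked assessment figure draws each channel at its own timestamps on
one shared time axis, in the canonical order EMG Ch1, EMG Ch2, thigh TSI,
forehead TSI, SBP, DBP, CO, HR. One vertical line per event at its synced
master marker time appears in every panel, with labels along the bottom
axis; instrument pauses are shaded (auto-detected as >30 s gaps in the
beat-to-beat reference, or given explicitly). Missing-data runs longer
than 1 s are rendered as line breaks (the threshold is a pinned default;
the underlying rule is simply "do not draw across a pause").

Channels longer than 200 000 points are decimated by per-time-bin min–max
selection (1500 bins): within each bin only the samples attaining the
minimum and maximum survive, in time order, so per-pixel-column extrema —
including transient artifacts — are exactly preserved at any zoom that
maps a bin to at most one pixel. After decimation the gap-break threshold
is widened to three bin widths so that decimation spacing is not mistaken
for missing data. Y-ranges auto-scale per panel.

The epoch grid plots participants × squeeze numbers on a shared −10…+20 s
relative axis, raw samples only, with the contraction span shaded; grid
cells for squeezes a participant did not perform are left blank.

## Problem sizes and runtime

The full default assessment produces ≈ 4.7 M master rows × 70 variables
(two 1024 Hz EMG streams dominate the union; their grids interleave except
where key-press jitter happens to align them). The complete pipeline —
simulate, write the five exports (~580 MB), re-read, two-stage sync, merge
— runs in well under a minute on a single core; the test suite uses a
structurally identical compact schedule (~9 min of recording) for
everything except the checks that are about full scale, and runs in a
couple of minutes.

## Known limitations

* Marker-based alignment corrects offsets only; clock drift over a 40 min
  recording is not estimated (out of scope by design).
* The detector is amplitude-only; co-contraction, partial effort, or slow
  force onsets blur detected onset times, and no spectral fatigue indices
  are computed.
* The 70-variable manifest pins a plausible advanced-hemodynamics column
  set; real exports differ by vendor and firmware, and only the dialect
  layer would need adapting.
* Cross-participant amplitude comparison of raw EMG is intentionally
  unsupported (no normalization is applied anywhere).
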