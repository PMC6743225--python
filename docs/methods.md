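# Methods

## The vigilance model

The pipeline treats vigilance as a two-state latent variable (High / Low)
expressed in the scalp EEG through band-power shifts: slow rhythms (theta,
alpha) strengthen and fast rhythms (beta) weaken as vigilance falls. All
inference is linear and causal so the system can run online:

1. **Filtering.** Each channel is band-pass filtered 1–30 Hz with a
   5th-order Butterworth filter, applied causally (forward only). A
   zero-phase option exists (`filter.zero_phase`) for offline work but is
   never the default: the output at time *t* must depend only on samples up
   to *t*.
2. **Blink correction.** Fpz — recorded solely for ocular artifact
   handling — drives a gated regression: samples where |Fpz| exceeds
   median + 4·MAD (statistics from the leading 30 s, for causality) for at
   least 50 ms mark a blink; intervals are padded 50 ms, and intervals
   closer than 200 ms merge, because the band-pass filter rings after each
   blink and one blink must map to one interval. Within blink intervals
   β·Fpz is subtracted per channel, with β the cumulative least-squares
   coefficient over blink samples seen so far; outside them, the signal
   passes through bit-identical. Blink-free input is returned unchanged.
3. **Epochs.** 2-s windows shifted by 0.125 s (16× overlap):
   floor((T−2)/0.125)+1 epochs for a T-second record. The grid lives on
   sample indices (32-sample step at 256 Hz), so the closed form is exact.
4. **Artifact criteria.** Per channel, OR-ed over channels, on every epoch:
   amplitude beyond ±100 μV; a fitted line with R² > 0.3 *and* |slope| >
   10 μV/s (conjunctive reading, absolute slope — drifts go both ways);
   any consecutive-sample difference above 25 μV. Fpz is excluded from the
   criteria: it is not part of the analyzed data, and its uncorrected blink
   deflections would otherwise flag every blink epoch. Flags are additive
   and idempotent; flagged epochs are removed before training and excluded
   from the smoothing window when scoring.
5. **Spectra and features.** Single-taper Hann periodogram over the whole
   epoch (0.5 Hz bins), computed directly as |FFT(w·x)|²/(fs·Σw²) with
   one-sided doubling — numerically identical to `scipy.signal.periodogram`
   (asserted in the tests) but several times faster on the 16×-overlapping
   epoch stack. Features are natural-log power at each (channel, bin) pair
   in: frontal theta, frontal beta, centro-parietal alpha, parietal theta.
   The log stabilizes variance for a linear discriminant; per-bin features
   (rather than band means) are the default, with `features.band_mean`
   available.
6. **IAF anchoring.** Band edges are offsets from the individual alpha
   frequency: theta [IAF−6, IAF−2], alpha [IAF−2, IAF+2], beta
   [IAF+2, IAF+16] Hz. The IAF is the argmax of the mean parietal-group
   PSD of a ≥ 30 s eyes-closed segment within 7–13 Hz; the peak must exceed
   twice the 1/f background (fitted log–log over 2–20 Hz excluding the
   search range), otherwise a calibration error advises re-recording. Band
   membership is half-open [low, high), making theta/alpha/beta a partition
   of the bin grid at their shared edges.

## Classifier

Training regresses 0/1 labels on the features with forward/backward
stepwise selection. A forward step adds the candidate with the smallest
partial-F p-value when below `p_enter` (0.05); backward steps drop included
features whose t-test p-value exceeds `p_remove` (0.10); selection stops by
itself when no candidate qualifies or `max_features` (30) is reached. The
forward step is implemented by Gram–Schmidt residualization, so each step
is O(n·p) and — as the tests assert against exhaustive search — picks
exactly the feature best-subset selection would pick at that step; with
selection disabled the fit equals the closed-form least-squares solution.
The exact selection rule of the original patented algorithm is unpublished;
this classic stepwise rule with a hard cap is the documented, reproducible
stand-in, and its p-thresholds are declared defaults, not inferred values.

Labels follow the calibration protocol: epochs starting in the first five
minutes of the 15-minute monotonous calibration run are High (1), those in
the last five minutes Low (0), the middle discarded. Scoring is
y = Σ wᵢ fᵢ + b; y is *not* clipped to [0, 1] — the smoother and threshold
operate on raw values. The decision threshold is the midpoint of the two
training class-mean scores (robust to class imbalance after artifact
removal; `threshold.mode=fixed0.5` restores a fixed cut). A trailing 30-s
moving average over non-artifact epochs gives `V_SCORE`; an all-artifact
window carries the last value forward and flags the gap. State is High iff
V_SCORE ≥ threshold; the tie favours the high-automation default.

## Controller

Decisions fall every `controller.period_s` = 300 s. The statistic is the
fraction of Low epochs among non-gap epochs in the trailing window:
strictly more than 50 % Low lowers automation to Level 0, otherwise
Level 2. "Mainly low" is operationalized as epoch majority (not a
mean-score comparison): the two coincide for symmetric score
distributions, and the rule is phrased in terms of shown states. An exact
50/50 split is not "mainly low" and keeps Level 2; an empty window keeps
the previous level; the first interval is always Level 2, the nominal
operating condition. The controller emits the schedule as data and never
feeds back into the EEG processing, so adaptive and reference runs produce
identical traces.

## Gaze

Fixations are maximal runs of consecutive valid samples whose bounding box
fits an axis-aligned square of area 0.002 in normalized screen units (side
≈ 0.0447; a square rather than a circle for an O(1) test) lasting at least
20 ms first-to-last. At 60 Hz a run of n samples spans (n−1)/60 s, so two
samples can never qualify and three can. Assignment interpolates each
object's track at the fixation's *start* time (TTFF is an onset-latency
measure) and takes the nearest object within 0.05 normalized units — a
default chosen at roughly a label's width on a 27-inch display, since no
standard value exists; ties resolve to the nearest, then lowest id.
Objects never fixated are reported missing, never zero; a fixation
preceding its object's onset is excluded with a log message. Full-
resolution timestamps are used throughout; no 1-s database quantization is
emulated.

## Synthetic generator

The generator emulates only the statistical structure the pipeline
exploits; it makes no physiological claims beyond the directions of the
effects.

* Every channel: pink-noise floor (10 μV RMS). Frontal channels add
  band-limited theta (5 μV RMS) and beta (4 μV); centro-parietal channels
  add alpha (8 μV); parietal channels add unmodulated theta (4 μV).
  Oscillations are band-pass-filtered white noise, so PSDs are broad, not
  line spectra. In the Low state, amplitude gains apply per sample:
  frontal theta power ×2.0, centro-parietal alpha ×1.8, frontal beta ×0.7.
* Blinks: 300-ms raised cosines, 150 μV on Fpz, mixed ×0.6 into AF
  channels and ×0.3 into F channels, Poisson at 8/min.
* Artifacts: square-pulse excursions (250–400 μV, 0.25–0.6 s) and
  electrode-pop steps (400–600 μV, fast decay) at 2/min on random non-Fpz
  channels. A slow linear ramp is deliberately *not* used as an artifact
  event: the mandated 1 Hz causal high-pass suppresses it to near zero, so
  it could never be recovered — pops are the realistic "drift" carrier
  that survives the filter. Recovery is scored with a collar, the standard
  convention in event-detection scoring: epochs overlapping an event must
  be flagged; epochs inside a margin (0.5 s before to 1 s after, where the
  filter smears the event) are scored neither as hits nor as false alarms.
* Eyes-closed segments plant a narrow-band alpha resonance (±0.4 Hz around
  the requested IAF) dominant on the parietal group.
* Gaze: alternating fixations and 2-sample saccades at 60 Hz. Mean
  fixation spans are derived from the target rates — with a 2-sample
  saccade the cycle is (n+2) samples, so 4.3 fix/s (High) and 4.6 fix/s
  (Low) imply means of ≈ 0.183 s and ≈ 0.167 s; vigilant operators fixate
  longer and therefore less often. Object onsets are answered by a planted
  first look with latency ~ N(4, 1) s in High and N(5, 1) s in Low,
  truncated at 1 s. Background fixations keep out of a 0.08 radius around
  objects so the planted look is provably the first assigned fixation, and
  the *realized* latency (planted, snapped to the running scanpath grid)
  is the ground truth.

What passing tests show — and don't. The generator's EEG is stationary
within a state, its artifacts are compact and large, and its gaze noise is
small and Gaussian. Success on it demonstrates that the implementation
recovers the structure the method assumes, with honest filtering and
causality; it does not demonstrate performance on real recordings, where
nonstationarity, microsleeps, electrode drift and tracker dropout are the
rule.

## Numerical choices

* Epochs are stored float32 (the 16× overlap makes float64 stacks
  gigabyte-scale on long sessions); all model fitting is float64.
* The EDF writer is self-contained (16-bit, 1-s records, physical
  dimension `uV` required on read; other units are rejected rather than
  silently rescaled). Records are zero-padded to a whole second and the
  true sample count stored in the reserved header field, so read-back
  restores the exact length; quantization error is bounded by
  (2·phys_max)/65535 μV. Model files are versioned JSON; a wrong version
  fails loudly.
* EEG CSV timestamps are written with 9 decimals: 6 would alias the
  1/256-s grid and corrupt the inferred sampling rate.
* Stepwise ties (equal p-values) resolve to the lowest feature index;
  state ties (V_SCORE = threshold) resolve High; assignment ties resolve
  to the lowest object id.
* The trend criterion is evaluated per channel, like the other two; the
  channel scope of the original procedure is not documented, and
  per-channel is the conservative (more sensitive) reading.

## Problem sizes

The test suite calibrates on 900-s synthetic runs and scores 1080-s
sessions for the five-seed recovery check, with shorter (240–420 s) runs
for module-level properties; `scripts/acceptance.py` uses one 900-s
calibration, one 1080-s session and three 300-s gaze sessions per
vigilance state. These sizes give a few thousand labelled epochs per class
— comfortably more observations than the 388 candidate features — while
keeping a full run near a minute.

## Known limitations

* The blink detector and artifact criteria are tuned for the synthetic
  contract; real recordings would need the thresholds re-examined.
* No ICA, channel interpolation or re-referencing; the montage is fixed at
  the 15 named sites and a missing channel is an error, not a warning.
* The controller models exactly two automation levels; intermediate levels
  would need a richer decision rule.
* Transfer across subjects is out of scope: a model is valid only for the
  calibration it came from, and the model file records the band set to
  enforce that.
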