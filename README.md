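# vac — EEG-based vigilance monitoring and adaptive automation

`vac` implements a passive brain–computer-interface pipeline for operators
supervising highly automated systems (the motivating case is an air traffic
controller monitoring a terminal area with near-total automation). Long
stretches of pure supervision erode vigilance — the "out-of-the-loop"
problem — and the pipeline's job is to measure that erosion online from the
EEG and to hand tasks back to the operator before performance degrades.

The package provides, as a library plus a `vac` command-line tool:

* **Preprocessing** — 1–30 Hz causal Butterworth filtering of a 15-channel
  prefrontal/frontal/centro-parietal montage sampled at 256 Hz,
  regression-based eye-blink correction driven by Fpz (no EOG needed),
  overlapping 2-s epochs shifted by 0.125 s, and three artifact criteria:
  amplitude beyond ±100 μV, a linear trend with R² > 0.3 and |slope| >
  10 μV/s, and sample-to-sample jumps above 25 μV.
* **Spectral features** — per-epoch Hann periodograms (0.5 Hz resolution)
  reduced to log-power at every (channel, bin) pair inside the
  vigilance-sensitive band/region combinations. Band edges are anchored to
  the subject's individual alpha frequency (IAF), estimated from a 1-min
  eyes-closed segment: theta = [IAF−6, IAF−2], alpha = [IAF−2, IAF+2],
  beta = [IAF+2, IAF+16] Hz. Features: frontal theta, frontal beta,
  centro-parietal alpha, parietal theta.
* **Classifier** — a self-stopping stepwise linear discriminant trained on
  a calibration run whose first five minutes are labelled High vigilance
  and last five minutes Low. Scoring is linear,

      y(t) = Σᵢ wᵢ · fᵢ(t) + b,

  with y ≈ 1 for High and ≈ 0 for Low; a trailing 30-s moving average
  yields the vigilance index `V_SCORE`, binarized against a calibrated
  threshold.
* **Controller** — every 5 minutes, if strictly more than half of the
  trailing window's epochs are Low, the level of automation drops from
  Level 2 (full automation) to Level 0 (manual re-engagement); otherwise it
  returns to Level 2.
* **Gaze metrics** — dispersion-based fixation detection (0.2 % of the
  screen for ≥ 20 ms at 60 Hz), object assignment, fixations/s and
  time-to-first-fixation (TTFF) per object.
* **Synthetic sessions** — a seeded generator producing EEG, eyes-closed
  and gaze sessions with known latent vigilance state, blink times,
  artifact epochs and fixation lists, so the whole chain is testable
  without recordings.

## Worked example

Generate a synthetic calibration day, train a model, then run a fresh
session through the adaptive controller:

```
$ vac simulate --preset calibration --seed 7 --out calib/
$ vac calibrate --eeg calib/calibration.edf --eyes-closed calib/eyes_closed.edf --out model.json
IAF 10.0 Hz; 30 features selected; threshold 0.497; model -> model.json

$ vac simulate --preset session --seed 8 --out sess/
$ vac run --eeg sess/session.edf --model model.json --adaptive --out out/
2 LOA switches; low-vigilance fraction 39.1%; outputs -> out
```

The session preset holds the latent state High for the first 30 % of the
20-minute run, Low for the middle 40 %, High again at the end — so the true
low-vigilance fraction is 40 %, and the pipeline recovered 39.1 % from the
EEG alone. `out/loa.csv` shows the controller reacting one decision period
after the latent drop:

```
t_s,level,frac_low
0.0000,Level2,
300.0000,Level2,0.0000
600.0000,Level0,0.7422
900.0000,Level0,0.8225
1200.0000,Level2,0.0000
```

`out/trace.csv` carries the per-epoch discriminant output `y`, the smoothed
`v_score`, the binary state and the active automation level;
`out/summary.json` adds the session statistics (mean `V_SCORE` 0.581,
per-5-min window means, vigilance decline between first and last window).

Gaze analysis works the same way from CSV gaze/event streams:

```
$ vac gaze --gaze gaze.csv --events events.csv --out gaze_out/
```

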