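# cartwheel

Consistency analysis of cooperative courtship displays, built around the
cartwheel dance of the swallow-tailed manakin (*Chiroxiphia caudata*).
Males of this species hold display courts in groups of two to six: they
perch in a row and take turns performing a hovering flight at the edge of
the row — roughly 1.9 flights per second — before cycling to the back,
while a visiting female watches from beside the perch. How *consistent*
that collective dance is, and whether females prefer consistent courts,
are questions about the fine temporal structure of a one-dimensional
signal: the vertical position of whichever male currently occupies the
edge of the dance.

The package implements the full measurement chain for researchers working
on display performance and mate choice:

1. **Synthesis** (`cartwheel.synthgen`) — renders display videos and
   vertical-position traces with known ground truth (flight schedule, hop
   heights, per-male timing jitter), plus multi-court datasets of display
   metrics and female visit/copulation counts with configurable effect
   sizes. Everything downstream is testable against these generators.
2. **Tracking** (`cartwheel.tracker`) — extracts the edge male's vertical
   position from video by colour-range scanning: pixels inside an RGB
   range (default `[150, 0, 0]`–`[255, 100, 100]`, the red of the males'
   heads) are counted per grid quadrant, a male is detected where
   coverage ≥ 40%, adjacent detections merge at the coverage-weighted
   centroid, and tracking hands off whenever another male passes the
   tracked one horizontally. Series are downsampled to 15 frames/s.
3. **Consistency metrics** (`cartwheel.rqa`) — recurrence quantification
   analysis on the height series `y`. Two samples recur when
   `|y_i − y_j| ≤ r`. From the binary recurrence matrix `R` the package
   computes the recurrence rate (RR), determinism (DET, diagonal lines),
   laminarity (LAM, vertical lines), and the microstate entropy (MCEntr):
   the Shannon entropy, in nats, of randomly sampled 2×2 sub-blocks of
   `R`. The radius `r` is chosen per series by maximizing MCEntr over a
   candidate grid (maximum-entropy principle). Higher RR and DET with
   lower MCEntr read as a more consistent display.
4. **Display metrics** (`cartwheel.displaymetrics`) — cartwheel flight
   frequency (prominent upward excursions per second) and female
   visitation/copulation rates (counts per recording hour).
5. **Inference** (`cartwheel.inference`) — Spearman correlations among
   metrics, iterative VIF screening of collinear predictors (threshold
   3.5), and Gamma log-link mixed models with a court random intercept,
   fitted by an internal Laplace approximation: one model per metric
   against group size, and visitation/copulation-rate models against the
   standardized display metrics.

Scikit-learn style front-ends (`ColorQuadrantTracker`,
`RecurrenceAnalysis`, `GammaGLMM` in `cartwheel.estimators`) wrap the
fit/transform-shaped stages for use in sklearn pipelines, and a
`cartwheel` command line (`simulate | track | rqa | freq | analyze | run`)
orchestrates everything as a reproducible, manifest-checked pipeline.

## Worked example

```python
import numpy as np
from cartwheel import (DisplayParams, simulate_display_video, TrackerConfig,
                       track_frames, rqa_summary, cartwheel_frequency)

# a noisy 4-male display, 12 s at 30 fps
params = DisplayParams(n_males=4, duration=12.0, fps=30.0,
                       timing_noise_sd=0.04, height_noise_sd=4.0, seed=5)
scene = simulate_display_video(params)

# colour-quadrant tracking, downsampled to 15 fps
series = track_frames(scene.frames, TrackerConfig(), fps=params.fps)
print(f"tracked {len(series)} samples at {series.fps:g} fps")

freq = cartwheel_frequency(series)
print(f"cartwheel frequency: {freq:.2f} Hz")

m = rqa_summary(series.y, seed=0)
print(f"radius r = {m.radius:.1f} px  RR = {m.rr:.1f}%  DET = {m.det:.1f}%  "
      f"LAM = {m.lam:.1f}%  MCEntr = {m.mcentr:.3f} nats")
```

prints

```
tracked 180 samples at 15 fps
cartwheel frequency: 2.00 Hz
radius r = 20.9 px  RR = 47.8%  DET = 72.9%  LAM = 96.7%  MCEntr = 2.476 nats
```

The tracked series has 12 s × 15 fps = 180 samples. The frequency
estimate (2.0 Hz) recovers the generator's flight rate (1.89 Hz) to
within the timing jitter of this particular display. The recurrence
radius that maximizes microstate entropy is ~21 px; at that radius about
half of all sample pairs recur (RR), most recurrent points sit on
diagonal structures (DET — the dance repeats itself), the series spends
long stretches at stable heights (LAM — perched intervals), and the
entropy of 2.476 nats sits between the two analytic anchors: 0 for a
perfectly constant series and ln 16 ≈ 2.773 for structureless noise.

Court-level analysis runs the same way from a dataset:

```python
from cartwheel import CourtSimParams, simulate_court_dataset, run_group_size_analysis

df = simulate_court_dataset(CourtSimParams(n_courts=30, displays_per_court=10, seed=1))
res = run_group_size_analysis(df)["mcentr"]
print(res.table().round(4))
```

fits a Gamma log-link GLMM of microstate entropy on male count with a
court random intercept and reports the estimate, standard error, Wald χ²
and p per coefficient.

## Layout

```
src/cartwheel/
  synthgen.py        display/video/court-dataset generators
  tracker.py         colour-quadrant tracking, calibration, downsampling
  rqa.py             recurrence matrices and consistency metrics
  displaymetrics.py  flight frequency, female rates
  glmm.py            Laplace Gamma log-link mixed model
  inference.py       correlations, VIF screen, model runners
  estimators.py      sklearn-style wrappers
  pipeline.py, cli.py, io.py, series.py
docs/methods.md      modeling and numerical choices, in detail
```
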