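# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic experiments do and do not
establish.

## The display model

A cooperative cartwheel display is modeled as a queue of hovering flights
over `n_males` males. Flight `k` starts at time `t_k`, lasts
`d = 0.8 / flight_rate` seconds (the dance keeps a short perched dwell
between flights), and traces a half-cosine excursion from the perch
height to `perch − A_k` and back, in raster coordinates (y grows
downward, so "up" is smaller y). Inter-flight intervals are
`1/flight_rate` plus two noise terms:

* a per-flight jitter `N(0, timing_noise_sd)`, and
* a per-male tempo offset `N(0, timing_noise_sd)`, drawn once per male.

The tempo offsets implement the hypothesis that group-level irregularity
grows with group size: each handoff inherits the incoming male's personal
tempo, so the interval distribution widens as more distinct tempos enter
the queue. The `group_timing_effect` switch disables the offsets, making
group size null by construction — both regimes are generable, and the
mapping from per-male jitter to group-level entropy remains a modeling
choice of this package rather than an established quantity.

Hover-height imprecision (`height_noise_sd`, px) acts at three scales,
all tied to the one parameter: the per-flight amplitude
(`A_k = hop_amplitude + N(0, sd)`), the perch-return height between
flights (`N(0, 0.5·sd)`, smoothly blended across each flight), and a
per-sample postural wobble (`N(0, 0.5·sd)`) along the whole trajectory.
The rationale: a male that cannot reproduce his hover height also lands
imprecisely and wobbles while flying. Under this mechanism microstate
entropy rises with `height_noise_sd` over realistic levels (0–12 px on
60 px hops). Beyond roughly 15 px, amplitude outliers inflate the series
range and thereby coarsen the range-normalized radius grid, and the
entropy–noise relation is no longer monotone; analyses should stay below
that regime.

Generator defaults encode the emulated field conditions: flight rate
1.89 Hz (the species-typical cartwheel tempo), 30 fps video, hop
amplitude 60 px on a 320×240 frame, male counts 2–6, and court datasets
with a +0.04 log-scale entropy effect per male, rate effects of +0.18
(RR), −0.16 (MCEntr) and −0.04 (male count) on the log visit/copulation
rates, court SD 0.3, and 5 recording hours per court. Display-metric
surrogates in `simulate_court_dataset` are Gamma draws (frequency shape
14, CV ≈ 0.27, matching observed display-to-display spread; other
metrics shape 25); the entropy surrogate is an unconstrained Gamma
variable and may exceed ln 16 — it is a statistical stand-in with the
right log-linear structure, not a computed entropy. DET is generated as
a noisy multiple of LAM (log-SD 0.07) so the pair is collinear, as in
real display data. Court random intercepts are drawn independently per
response channel (entropy, visits, copulations); a shared intercept
would correlate the entropy predictor with the rate models' random
effect and bias their estimates.

## Rendering and tracking

Males are drawn as dark bodies with 12×12 px heads whose colour
(200, 40, 40) lies inside the tracked RGB range [150, 0, 0]–[255, 100,
100]; the female's head (110, 130, 70) lies outside it. The tracker
masks that range inclusively, tiles the frame into quadrants, and
detects a male where coverage ≥ `coverage_threshold` (default 0.40,
confirmed by the calibration sweep over {30, 40, 50, 60, 70}%; ties
break to the smallest candidate). Adjacent detected quadrants
(8-connectivity) merge into one detection at the coverage-weighted
centroid — subpixel and stable, rather than a raw quadrant index (an
integer `cell` output mode exists too).

The default quadrant is 8 px — two thirds of the head size, not equal to
it. A head exactly one cell wide can straddle four cells with 25%
coverage each and vanish below the 40% rule; at 1.5 cells per head some
cell always holds ≥ 56% coverage, so detection cannot drop out from
alignment alone.

Edge-male selection follows the dance geometry: the detection closest to
`female_column` when a female is present, otherwise the extreme detection
toward `dance_direction` (`auto` infers the direction from the sign of
the median frame-to-frame displacement of the detection centroid).
Tracking retains the current male until another detection passes him
strictly (hysteresis `handoff_eps`, default 0 px). Detection dropouts up
to `max_gap` frames (default 3) carry the last value; longer gaps split
the series and the longest segment is returned with a warning. Series
are downsampled by integer decimation (default 30 → 15 fps, keeping the
first sample); non-integer factors are an error rather than a resample.

## Recurrence quantification

The analysis runs directly on the scalar height series — no phase-space
embedding (an optional `(m, τ)` hook exists, off by default). Recurrence
is inclusive, `|y_i − y_j| ≤ r`, so `r = 0` reproduces exact-match
recurrence. Conventions, chosen where the general definitions leave
freedom:

* **RR** counts all cells including the main diagonal:
  `RR = 100 · ΣR / N²`.
* **DET** uses diagonal lines off the main diagonal only (Theiler window
  1), `l_min = 2`. On an all-ones matrix the two corner diagonals are
  genuine length-1 lines, so DET is `100·(N²−N−2)/(N²−N)`, i.e. 99.99%
  at N = 150 — not exactly 100. A flag restores the line of identity for
  comparison with tools that keep it.
* **LAM** uses vertical runs per column with the main-diagonal cell
  *deleted* (not zeroed): the self-recurrence neither extends nor
  interrupts a vertical line. A constant series therefore gives LAM =
  100 exactly, and an identity matrix gives 0. `v_min = 2`.
* Both line histograms satisfy the partition property: Σ length×count
  equals the number of off-diagonal recurrent points.
* **MCEntr** samples 10 000 2×2 block positions uniformly with
  replacement (blocks may straddle the main diagonal), maps each block
  to one of 16 microstates, and returns the plug-in Shannon entropy in
  nats; the range is [0, ln 16 ≈ 2.773]. An exhaustive mode enumerates
  all `(N−1)²` positions and is exact.
* **Radius selection** evaluates MCEntr on 50 candidates evenly spanning
  1–100% of the series range (a constant series has the single candidate
  0), each scored with an identically seeded sampler so Monte-Carlo
  noise does not tip the comparison; the smallest maximizer wins. One
  radius per series is selected and RR/DET/LAM/MCEntr are all computed
  at it.

Oracle status: RR, DET and LAM equal naive loop-based references exactly
on random matrices up to N = 30 and on hand-built cases; sampled MCEntr
hits 0 on the all-ones matrix and ln 16 ± 0.02 on 500×500 symmetrized
Bernoulli(0.5) matrices; exhaustive MCEntr equals the brute-force
plug-in entropy to machine precision up to N = 60.

## Frequency and rates

Cartwheel frequency counts upward local extrema (smaller raster y) with
prominence ≥ 25% of the series range, divided by the covered duration.
The prominence floor makes the count invariant to baseline drift and
small tracking ripple; a constant series has frequency 0. Whether the
field definition counted full cycles or half-cycles is not stated
anywhere authoritative; full upward peaks are used. Visitation and
copulation rates are counts divided by recording hours.

## Mixed models

The inference layer fits `y ~ Gamma(shape k)`,
`log μ = Xβ + b_court`, `b ~ N(0, σ_b²)`, by maximizing the
Laplace-approximated marginal likelihood: the intercept posterior mode
per court comes from a damped Newton step (the log-likelihood is
strictly concave in `b`), vectorized across courts, and L-BFGS-B
optimizes `(β, log σ_b, log k)`. Standard errors come from the central
finite-difference Hessian at the optimum; Wald χ² = (β/se)² on 1 d.f.
(a likelihood-ratio χ² is available behind a flag). The fit is flagged
singular when σ_b < 10⁻³; fewer than two courts, a failed optimization,
or a non-invertible Hessian fall back to a fixed-effects Gamma GLM
(statsmodels) with a warning — flagged, never silent. The implementation
agrees with lme4's `glmer` on the fixed-effect estimate and SE in the
cross-check test.

Zero rates under a Gamma family are replaced by half the smallest
positive observed rate, and the substitution is recorded in the model
result; an all-zero response is an error, since no shift is definable.
Group-size models keep `n_males` on its natural scale (per-male effect
sizes); female-choice models standardize predictors (centred, unit SD),
so their intercept is the log mean rate on null data. Rates are
court-level quantities; the default analysis keeps one row per display
with its court's rate repeated and lets the random intercept absorb the
dependence, with a `court_mean` aggregation mode as the alternative.
DET is pre-excluded from the female-choice predictor set because it
fails the VIF screen against LAM; the screen itself iteratively drops
the largest VIF above 3.5, treating perfect collinearity as infinite.

## Synthetic-experiment scales and what they show

The recovery experiments use 30 courts × 10 displays (bias and 95% CI
coverage of the 0.04 entropy slope over 100 replicates; Wald type-I
error over 200 null replicates), tracker fidelity uses a 10 s, 30 fps,
3-male noise-free video, and the end-to-end reproducibility run uses 2
courts × 2 displays of 10 s video — sizes chosen to exercise every code
path at desk scale. Passing them shows the chain is internally
consistent and statistically calibrated *under the generator's
assumptions*: clean colour separation, a single moving male, no
occlusion or lighting variation, Gamma-distributed metrics, Poisson
counts. Real field video adds occlusion, background reds, camera shake
and detection clutter that the synthetic scenes deliberately omit, so
tracker performance there must be established with the calibration sweep
on labelled clips, not inferred from these tests.

## Known limitations

* The tracker assumes at most mild clutter; it has no appearance model
  and cannot re-identify males (by design — the series is identity-free).
* Laplace approximation with few courts (< ~5) can underestimate σ_b;
  the singular-fit fallback then reports fixed-effects results.
* The microstate entropy of short series (N < ~60) is noticeably biased
  downward by the plug-in estimator; compare series of similar length.
* MP4 export needs an ffmpeg imageio plugin; PNG frame directories are
  the canonical video representation.
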