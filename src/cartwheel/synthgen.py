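"""Synthetic cartwheel displays with known ground truth.

Swallow-tailed manakin males display in courts of two to six: they perch
in a row next to a female and take turns performing a hovering "cartwheel"
flight at the edge of the row, at roughly 1.9 flights per second, before
cycling to the back. Field video of this behaviour is not shippable, so
this module emulates it at three levels:

1. :func:`simulate_display_series` — the edge male's vertical-position
   trace: a baseline punctuated by one smooth (half-cosine) upward
   excursion per flight, with a flight queue over the males and
   controllable timing/height noise.
2. :func:`simulate_display_video` — renders the scene as RGB frames: a
   row of male blobs whose head patches fall inside the red range
   [150, 0, 0]–[255, 100, 100] that the tracker keys on, an optional
   (red-free) female, and a ground-truth trace of the edge male's head.
3. :func:`simulate_court_dataset` — multi-court datasets of RQA-like
   display metrics and female visit/copulation counts with configurable
   effect sizes, used for statistical parameter-recovery experiments.

Every generator is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .series import DisplaySeries

__all__ = [
    "DisplayParams",
    "FlightEvent",
    "SyntheticScene",
    "CourtSimParams",
    "simulate_display_series",
    "simulate_display_video",
    "simulate_court_dataset",
    "HEAD_SIZE",
]

#: rendered head patch edge length, px (square patch)
HEAD_SIZE = 12
#: head colour — inside the tracked red range
HEAD_COLOR = (200, 40, 40)
#: female head colour — G channel above 100, never matched by the tracker
FEMALE_HEAD_COLOR = (110, 130, 70)
BODY_COLOR = (52, 62, 72)
BACKGROUND = (96, 96, 96)
#: fraction of the inter-flight interval spent airborne
FLIGHT_DUTY = 0.8
#: perch-return imprecision as a fraction of height_noise_sd: a male whose
#: hover heights vary also lands at slightly varying perch heights
BASELINE_RETURN_FRAC = 0.5
#: per-sample postural wobble as a fraction of height_noise_sd: imprecision
#: shows up along the whole trajectory, not only at the hover peak
WOBBLE_FRAC = 0.5
#: horizontal spacing between perched birds, px
SLOT_SPACING = 36
MARGIN = 14


@dataclass
class DisplayParams:
    """Parameters of one simulated cooperative display.

    ``flight_rate`` defaults to 1.89 Hz, the typical cartwheel tempo for
    this species; ``timing_noise_sd``/``height_noise_sd`` control how
    irregular the queue and the hover heights are. With
    ``group_timing_effect`` on (default), each male carries a small
    personal tempo offset, so jitter accumulates at queue handoffs and
    larger groups produce slightly more irregular inter-flight intervals;
    switching it off generates the null in which group size has no effect
    on timing.
    """

    n_males: int = 3
    flight_rate: float = 1.89  # Hz
    hop_amplitude: float = 60.0  # px
    baseline_y: float = 170.0  # px, raster orientation
    timing_noise_sd: float = 0.0  # s
    height_noise_sd: float = 0.0  # px
    duration: float = 10.0  # s
    fps: float = 30.0
    frame_size: tuple[int, int] = (320, 240)  # (width, height)
    female_present: bool = False
    dance_direction: Literal["left", "right"] = "left"
    group_timing_effect: bool = True
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_males < 1:
            raise ValueError("n_males must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.flight_rate <= 0:
            raise ValueError("flight_rate must be > 0")
        if self.timing_noise_sd < 0 or self.height_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.hop_amplitude <= 0:
            raise ValueError("hop_amplitude must be > 0")
        if self.dance_direction not in ("left", "right"):
            raise ValueError("dance_direction must be 'left' or 'right'")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["frame_size"] = list(self.frame_size)
        return d


@dataclass(frozen=True)
class FlightEvent:
    """One cartwheel flight: start/peak time (s), amplitude (px), male index."""

    start: float
    peak_time: float
    duration: float
    amplitude: float
    male_index: int


@dataclass
class SyntheticScene:
    """Rendered frames plus the generator's ground truth."""

    frames: np.ndarray  # (T, H, W, 3) uint8
    truth_trace: np.ndarray  # edge male head-center y per frame, px
    truth_events: list[FlightEvent]
    params: DisplayParams

    def __post_init__(self) -> None:
        n = int(round(self.params.duration * self.params.fps))
        if len(self.frames) != n or len(self.truth_trace) != n:
            raise ValueError("frames/truth_trace length must equal round(duration * fps)")


def _flight_schedule(params: DisplayParams, rng: np.random.Generator):
    """Event start times, amplitudes and male indices for one display."""
    d = FLIGHT_DUTY / params.flight_rate  # airborne time per flight
    if params.group_timing_effect and params.timing_noise_sd > 0:
        tempo = rng.normal(0.0, params.timing_noise_sd, size=params.n_males)
    else:
        tempo = np.zeros(params.n_males)
    events: list[FlightEvent] = []
    t = 0.0
    male = 0
    max_amp = params.baseline_y - HEAD_SIZE / 2 - 2  # keep the head inside the frame
    while t + d <= params.duration + 1e-9:
        amp = params.hop_amplitude
        if params.height_noise_sd > 0:
            amp += rng.normal(0.0, params.height_noise_sd)
        amp = float(np.clip(amp, 0.1 * params.hop_amplitude, max_amp))
        events.append(
            FlightEvent(
                start=t, peak_time=t + d / 2, duration=d, amplitude=amp, male_index=male
            )
        )
        interval = 1.0 / params.flight_rate + tempo[male]
        if params.timing_noise_sd > 0:
            interval += rng.normal(0.0, params.timing_noise_sd)
        t += max(interval, d)  # flights never overlap
        male = (male + 1) % params.n_males
    if not events:
        raise ValueError(
            f"duration {params.duration}s too short for one flight at "
            f"{params.flight_rate} Hz"
        )
    return events


def simulate_display_series(
    params: DisplayParams,
) -> tuple[DisplaySeries, list[FlightEvent]]:
    """Ground-truth edge-male trace: baseline plus one excursion per flight.

    Each flight is a half-cosine excursion rising from the perch height to
    ``perch - amplitude`` (raster coordinates: up is smaller y) and back.
    ``height_noise_sd`` models display imprecision at three scales: the
    per-flight hover height, the perch-return height between flights (at
    ``BASELINE_RETURN_FRAC`` of its scale), and a per-sample postural
    wobble along the whole trajectory (at ``WOBBLE_FRAC``). The trace
    encodes only the flight-event sequence — which male flies is recorded
    in the events but leaves no mark on the series.
    """
    rng = np.random.default_rng(params.seed)
    events = _flight_schedule(params, rng)
    n = int(round(params.duration * params.fps))
    t = np.arange(n) / params.fps
    if params.height_noise_sd > 0:
        perch = params.baseline_y + rng.normal(
            0.0, BASELINE_RETURN_FRAC * params.height_noise_sd, size=len(events) + 1
        )
    else:
        perch = np.full(len(events) + 1, params.baseline_y)
    y = np.empty(n)
    prev_end = 0.0
    for k, ev in enumerate(events):
        y[(t >= prev_end) & (t < ev.start)] = perch[k]
        inside = (t >= ev.start) & (t < ev.start + ev.duration)
        phase = (t[inside] - ev.start) / ev.duration
        base_blend = perch[k] * (1 - phase) + perch[k + 1] * phase
        y[inside] = base_blend - ev.amplitude * 0.5 * (1 - np.cos(2 * np.pi * phase))
        prev_end = ev.start + ev.duration
    y[t >= prev_end] = perch[-1]
    if params.height_noise_sd > 0:
        y += rng.normal(0.0, WOBBLE_FRAC * params.height_noise_sd, size=n)
        np.clip(y, HEAD_SIZE / 2 + 1, params.frame_size[1] - HEAD_SIZE / 2 - 17, out=y)
    series = DisplaySeries(
        y=y,
        fps=params.fps,
        meta={"n_males": params.n_males, "source": "synthetic", "seed": params.seed},
    )
    return series, events


def _slot_positions(params: DisplayParams) -> tuple[list[int], int | None]:
    """Horizontal head-center x for each male (edge male first) and the female."""
    width, _ = params.frame_size
    n_slots = params.n_males + (1 if params.female_present else 0)
    needed = 2 * MARGIN + (n_slots - 1) * SLOT_SPACING + HEAD_SIZE
    if needed > width:
        raise ValueError(
            f"frame width {width}px too small for {params.n_males} males"
            + (" and a female" if params.female_present else "")
        )
    xs = [MARGIN + HEAD_SIZE // 2 + k * SLOT_SPACING for k in range(n_slots)]
    if params.dance_direction == "right":
        xs = [width - 1 - x for x in xs]
    # slot 0 sits at the dance edge; the female, when present, takes it
    if params.female_present:
        female_x = xs[0]
        male_xs = xs[1:]
    else:
        female_x = None
        male_xs = xs
    return male_xs, female_x  # male_xs[0] is the edge male


def _stamp_bird(frame: np.ndarray, x: int, y: float, head_color) -> None:
    """Draw head square + body rectangle, clipped to the frame."""
    h, w, _ = frame.shape
    half = HEAD_SIZE // 2
    yi = int(round(y))
    r0, r1 = max(0, yi - half), min(h, yi + half)
    c0, c1 = max(0, x - half), min(w, x + half)
    frame[r0:r1, c0:c1] = head_color
    # body below the head
    b0, b1 = min(h, yi + half), min(h, yi + half + 16)
    frame[b0:b1, max(0, x - 5) : min(w, x + 5)] = BODY_COLOR


def simulate_display_video(params: DisplayParams) -> SyntheticScene:
    """Render a display as RGB frames with a ground-truth edge-male trace.

    Males sit in a horizontal row; the edge male (closest to the female,
    or furthest toward ``dance_direction`` when she is absent) executes
    the current flight while the rest perch at ``baseline_y``. Every head
    patch of a male lies inside the red range the tracker searches for;
    the female's head does not.
    """
    width, height = params.frame_size
    if params.baseline_y + HEAD_SIZE / 2 + 16 > height:
        raise ValueError("baseline_y too low: birds would fall off the frame")
    if params.baseline_y - params.hop_amplitude < -1:
        raise ValueError("hop_amplitude exceeds baseline height")
    series, events = simulate_display_series(params)
    male_xs, female_x = _slot_positions(params)
    n = len(series)
    frames = np.empty((n, height, width, 3), dtype=np.uint8)
    background = np.empty((height, width, 3), dtype=np.uint8)
    background[:] = BACKGROUND
    for i in range(n):
        frame = background.copy()
        if female_x is not None:
            _stamp_bird(frame, female_x, params.baseline_y, FEMALE_HEAD_COLOR)
        # perched males
        for x in male_xs[1:]:
            _stamp_bird(frame, x, params.baseline_y, HEAD_COLOR)
        # edge male at its current flight height
        _stamp_bird(frame, male_xs[0], series.y[i], HEAD_COLOR)
        frames[i] = frame
    return SyntheticScene(
        frames=frames, truth_trace=series.y.copy(), truth_events=events, params=params
    )


# ---------------------------------------------------------------------------
# multi-court datasets for the statistical stage


@dataclass
class CourtSimParams:
    """Effect structure of a simulated multi-court season.

    Effects are on the log scale. Defaults encode the emulated study
    conditions: a small positive group-size effect on microstate entropy
    (0.04 per male), female visit/copulation rates rising with recurrence
    rate and falling with entropy and group size, and moderate court-level
    heterogeneity.
    """

    n_courts: int = 6
    displays_per_court: int = 10
    beta_entropy_vs_males: float = 0.04
    beta_rate_vs_rr: float = 0.18
    beta_rate_vs_entropy: float = -0.16
    beta_rate_vs_males: float = -0.04
    court_sd: float = 0.3
    recording_hours: float = 5.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_courts < 1 or self.displays_per_court < 1:
            raise ValueError("counts must be >= 1")
        if self.court_sd < 0:
            raise ValueError("court_sd must be >= 0")
        if self.recording_hours <= 0:
            raise ValueError("recording_hours must be > 0")


# baseline means and Gamma shapes of the simulated display metrics;
# frequency shape 14 gives CV ~ 0.27, matching observed display-to-display spread
_METRIC_BASE = {
    "frequency": (1.89, 14.0),
    "rr": (20.0, 25.0),
    "lam": (50.0, 25.0),
    "mcentr": (1.5, 25.0),
    "radius": (5.0, 25.0),
}
_DET_OVER_LAM = 1.18  # DET rides on LAM with small extra noise -> high VIF
_VISIT_BASE = 1.0  # visits/h
_COP_BASE = 0.15  # copulations/h


def _gamma_mean(rng: np.random.Generator, mean, shape):
    return rng.gamma(shape, np.asarray(mean) / shape)


def simulate_court_dataset(params: CourtSimParams) -> pd.DataFrame:
    """Per-display metrics joined with female visit/copulation rates.

    For each court an independent Normal(0, ``court_sd``) intercept is
    drawn per response channel (entropy, visits, copulations). Each
    display draws its male count uniformly from {2..6} and Gamma
    distributed metrics whose log-mean is linear in ``n_males`` (slope
    ``beta_entropy_vs_males`` for entropy, zero for the rest; DET is
    generated as a noisy multiple of LAM so the pair is collinear, as it
    is in real displays). Visit and copulation counts are Poisson with
    log-rate linear in the standardized predictors, then divided by
    ``recording_hours`` to give per-hour rates.
    """
    rng = np.random.default_rng(params.seed)
    n_total = params.n_courts * params.displays_per_court
    court_id = np.repeat(np.arange(params.n_courts), params.displays_per_court)
    b_ent, b_visit, b_cop = (
        rng.normal(0.0, params.court_sd, size=(3, params.n_courts))
        if params.court_sd > 0
        else np.zeros((3, params.n_courts))
    )
    n_males = rng.integers(2, 7, size=n_total)

    cols: dict[str, np.ndarray] = {}
    for name, (mean, shape) in _METRIC_BASE.items():
        log_mu = np.log(mean) * np.ones(n_total)
        if name == "mcentr":
            log_mu += params.beta_entropy_vs_males * (n_males - 4) + b_ent[court_id]
        cols[name] = _gamma_mean(rng, np.exp(log_mu), shape)
    cols["det"] = np.clip(
        _DET_OVER_LAM * cols["lam"] * np.exp(rng.normal(0.0, 0.07, size=n_total)),
        None,
        99.9,
    )

    def z(v):
        s = v.std(ddof=0)
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v, dtype=float)

    lin = (
        params.beta_rate_vs_rr * z(cols["rr"])
        + params.beta_rate_vs_entropy * z(cols["mcentr"])
        + params.beta_rate_vs_males * z(n_males.astype(float))
    )
    visits = rng.poisson(params.recording_hours * _VISIT_BASE * np.exp(lin + b_visit[court_id]))
    cops = rng.poisson(params.recording_hours * _COP_BASE * np.exp(lin + b_cop[court_id]))

    df = pd.DataFrame(
        {
            "court_id": court_id,
            "display_id": np.arange(n_total),
            "n_males": n_males,
            "frequency": cols["frequency"],
            "rr": cols["rr"],
            "det": cols["det"],
            "lam": cols["lam"],
            "mcentr": cols["mcentr"],
            "radius": cols["radius"],
            "recording_hours": params.recording_hours,
            "n_visits": visits,
            "n_copulations": cops,
        }
    )
    df["visit_rate"] = df["n_visits"] / df["recording_hours"]
    df["copulation_rate"] = df["n_copulations"] / df["recording_hours"]
    return df
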