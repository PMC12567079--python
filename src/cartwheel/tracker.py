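"""Colour-quadrant tracking of the displaying edge male.

The tracker reproduces a deliberately simple field pipeline: male
swallow-tailed manakins carry red heads, so each video frame is scanned
for pixels inside an RGB range (default [150, 0, 0] to [255, 100, 100]),
the frame is divided into a grid of quadrants, and a male is detected in
a quadrant when at least ``coverage_threshold`` (default 40%) of that
quadrant is covered by the colour. Adjacent detected quadrants are merged
into one detection at the coverage-weighted centroid. Per frame, the male
at the edge of the dance — horizontally closest to the female, or
furthest toward the dance direction when she is absent — is tracked, and
his vertical position forms the display series. Male identity is never
recorded: when another male passes the tracked one horizontally, tracking
hands off to him.

The series is finally downsampled (default to 15 frames per second).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .series import DisplaySeries

__all__ = [
    "TrackerConfig",
    "Detection",
    "color_mask",
    "quadrant_coverage",
    "detect_males",
    "edge_male_series",
    "downsample",
    "calibrate_threshold",
    "track_frames",
]

#: default quadrant edge length, px (two-thirds of the rendered head size,
#: so a head always saturates at least one quadrant at any alignment)
DEFAULT_CELL = 8
#: the candidate coverage thresholds of the calibration sweep
CALIBRATION_THRESHOLDS = (0.30, 0.40, 0.50, 0.60, 0.70)


@dataclass
class TrackerConfig:
    """Configuration of the colour-quadrant tracker."""

    color_lo: tuple[int, int, int] = (150, 0, 0)
    color_hi: tuple[int, int, int] = (255, 100, 100)
    coverage_threshold: float = 0.40
    grid: tuple[int, int] | None = None  # (n_cols, n_rows); None -> ~8 px cells
    target_fps: float = 15.0
    dance_direction: Literal["left", "right", "auto"] = "left"
    female_column: float | None = None
    max_gap: int = 3  # frames a detection dropout may be bridged
    handoff_eps: float = 0.0  # px another male must pass the tracked one by
    output_mode: Literal["centroid", "cell"] = "centroid"

    def __post_init__(self) -> None:
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in (0, 1]")
        if any(lo > hi for lo, hi in zip(self.color_lo, self.color_hi)):
            raise ValueError("color_lo must be <= color_hi componentwise")
        if self.target_fps <= 0:
            raise ValueError("target_fps must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class Detection:
    """One merged male detection: centroid in cell and pixel coordinates."""

    col: float
    row: float
    x: float  # px
    y: float  # px
    coverage: float  # summed coverage of merged quadrants
    n_cells: int


def color_mask(frame: np.ndarray, config: TrackerConfig | None = None) -> np.ndarray:
    """Binary mask of pixels inside the RGB colour range (inclusive)."""
    config = config or TrackerConfig()
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be an RGB raster of shape (H, W, 3)")
    lo = np.asarray(config.color_lo)
    hi = np.asarray(config.color_hi)
    return np.all((frame >= lo) & (frame <= hi), axis=2)


def _grid_edges(n_pixels: int, n_cells: int) -> np.ndarray:
    """Cell boundary offsets: equal-size cells, the last may be smaller."""
    size = -(-n_pixels // n_cells)  # ceil
    edges = np.arange(0, n_cells + 1) * size
    return np.minimum(edges, n_pixels)


def default_grid(frame_shape: tuple[int, int]) -> tuple[int, int]:
    """(n_cols, n_rows) giving ~``DEFAULT_CELL``-pixel quadrants."""
    h, w = frame_shape[:2]
    return max(1, round(w / DEFAULT_CELL)), max(1, round(h / DEFAULT_CELL))


def quadrant_coverage(
    mask: np.ndarray, grid: tuple[int, int]
) -> np.ndarray:
    """Fraction of each quadrant covered by the mask, shape (n_rows, n_cols).

    Quadrants tile the frame in equal-size cells (edge cells may be
    smaller); each fraction uses the actual cell area.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    n_cols, n_rows = grid
    h, w = mask.shape
    if n_cols > w or n_rows > h or n_cols < 1 or n_rows < 1:
        raise ValueError(f"grid {grid} does not fit a {w}x{h} frame")
    row_edges = _grid_edges(h, n_rows)
    col_edges = _grid_edges(w, n_cols)
    counts = np.add.reduceat(np.add.reduceat(mask, row_edges[:-1], axis=0), col_edges[:-1], axis=1)
    areas = np.outer(np.diff(row_edges), np.diff(col_edges))
    # degenerate zero-area edge cells (grid coarser than frame) count as empty
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(areas > 0, counts / np.maximum(areas, 1), 0.0)
    return cov


def detect_males(
    coverages: np.ndarray,
    config: TrackerConfig | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> list[Detection]:
    """Threshold quadrants and merge adjacent ones into male detections.

    A quadrant is detected when its coverage is at least
    ``coverage_threshold``; detected quadrants that touch (8-connectivity)
    merge into a single male at their coverage-weighted centroid. Pixel
    coordinates are derived from the quadrant centers when ``frame_shape``
    is given, else cells are treated as unit squares.
    """
    config = config or TrackerConfig()
    cov = np.asarray(coverages, dtype=float)
    hit = cov >= config.coverage_threshold
    if not hit.any():
        return []
    labels, n_comp = ndimage.label(hit, structure=np.ones((3, 3), dtype=int))
    n_rows, n_cols = cov.shape
    if frame_shape is not None:
        h, w = frame_shape[:2]
        row_edges = _grid_edges(h, n_rows)
        col_edges = _grid_edges(w, n_cols)
        row_centers = (row_edges[:-1] + row_edges[1:]) / 2.0
        col_centers = (col_edges[:-1] + col_edges[1:]) / 2.0
    else:
        row_centers = np.arange(n_rows) + 0.5
        col_centers = np.arange(n_cols) + 0.5
    out: list[Detection] = []
    for k in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == k)
        wgt = cov[rows, cols]
        total = wgt.sum()
        r = float((rows * wgt).sum() / total)
        c = float((cols * wgt).sum() / total)
        y = float((row_centers[rows] * wgt).sum() / total)
        x = float((col_centers[cols] * wgt).sum() / total)
        out.append(Detection(col=c, row=r, x=x, y=y, coverage=float(total), n_cells=rows.size))
    return out


def _edge_score(det: Detection, config: TrackerConfig, direction: str) -> float:
    """Higher score = closer to the edge of the dance."""
    if config.female_column is not None:
        return -abs(det.x - config.female_column)
    return -det.x if direction == "left" else det.x


def _infer_direction(detections: Sequence[Sequence[Detection]]) -> str:
    """Sign of the median frame-to-frame horizontal displacement of the
    detection centroid; ties fall back to 'left'."""
    xs = [np.mean([d.x for d in dets]) for dets in detections if dets]
    if len(xs) < 2:
        return "left"
    med = float(np.median(np.diff(xs)))
    return "right" if med > 0 else "left"


def edge_male_series(
    detections: Sequence[Sequence[Detection]],
    config: TrackerConfig | None = None,
    fps: float = 30.0,
    meta: dict | None = None,
) -> DisplaySeries:
    """Per-frame vertical position of the edge male, with handoff.

    The tracked male is retained until another detection strictly passes
    him toward the edge (by more than ``handoff_eps`` px). Frames without
    detections are bridged by carrying the last value for up to
    ``max_gap`` frames; longer dropouts split the series and the longest
    segment is returned with a warning.
    """
    config = config or TrackerConfig()
    direction = config.dance_direction
    if direction == "auto":
        direction = _infer_direction(detections)
    n_frames = len(detections)
    n_with = sum(1 for dets in detections if dets)
    if n_with == 0:
        raise ValueError("no frames contain a detection; cannot build a series")
    if n_with < 0.5 * n_frames:
        warnings.warn(
            f"detections present in only {n_with}/{n_frames} frames; "
            "series quality will be poor",
            stacklevel=2,
        )

    raw: list[float | None] = []
    current: Detection | None = None
    for dets in detections:
        if not dets:
            raw.append(None)
            continue
        scores = [_edge_score(d, config, direction) for d in dets]
        best = int(np.argmax(scores))
        if current is None:
            current = dets[best]
        else:
            # the continued male = detection nearest the last tracked position
            cont = int(np.argmin([abs(d.x - current.x) for d in dets]))
            if scores[best] > scores[cont] + config.handoff_eps:
                current = dets[best]  # strict pass -> handoff
            else:
                current = dets[cont]
        raw.append(current.y if config.output_mode == "centroid" else round(current.row))

    # bridge short dropouts; split on long ones
    segments: list[list[float]] = []
    seg: list[float] = []
    gap = 0
    for v in raw:
        if v is not None:
            if seg and 0 < gap <= config.max_gap:
                seg.extend([seg[-1]] * gap)
            elif seg and gap > config.max_gap:
                segments.append(seg)
                seg = []
            gap = 0
            seg.append(float(v))
        else:
            if seg:
                gap += 1
    if seg:
        segments.append(seg)
    longest = max(segments, key=len)
    if len(segments) > 1:
        warnings.warn(
            f"series split by {len(segments) - 1} dropout(s) longer than "
            f"max_gap={config.max_gap}; returning the longest segment "
            f"({len(longest)}/{n_frames} frames)",
            stacklevel=2,
        )
    return DisplaySeries(y=np.array(longest), fps=fps, meta=dict(meta or {}))


def downsample(series: DisplaySeries, target_fps: float) -> DisplaySeries:
    """Keep every k-th sample, where k = source fps / target fps (integer).

    30 -> 15 fps keeps every 2nd sample starting with the first; the new
    length is ceil(n / k).
    """
    factor = series.fps / target_fps
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ValueError(
            f"target fps {target_fps} must integer-divide source fps {series.fps}"
        )
    k = int(round(factor))
    if k == 1:
        return DisplaySeries(y=series.y.copy(), fps=series.fps, t0=series.t0, meta=dict(series.meta))
    return DisplaySeries(y=series.y[::k].copy(), fps=target_fps, t0=series.t0, meta=dict(series.meta))


def track_frames(
    frames: Iterable[np.ndarray],
    config: TrackerConfig | None = None,
    fps: float = 30.0,
    meta: dict | None = None,
) -> DisplaySeries:
    """Full per-frame pipeline: mask -> quadrants -> detections -> edge series.

    The result is downsampled to ``config.target_fps`` when the source
    rate is higher.
    """
    config = config or TrackerConfig()
    per_frame: list[list[Detection]] = []
    grid = config.grid
    shape: tuple[int, int] | None = None
    for frame in frames:
        frame = np.asarray(frame)
        if shape is None:
            shape = frame.shape[:2]
            if grid is None:
                grid = default_grid(shape)
        mask = color_mask(frame, config)
        cov = quadrant_coverage(mask, grid)
        per_frame.append(detect_males(cov, config, frame_shape=shape))
    series = edge_male_series(per_frame, config, fps=fps, meta=meta)
    if series.fps > config.target_fps:
        series = downsample(series, config.target_fps)
    return series


def calibrate_threshold(
    scenes: Sequence,
    candidates: Sequence[float] = CALIBRATION_THRESHOLDS,
    config: TrackerConfig | None = None,
) -> tuple[float, list[tuple[float, int]]]:
    """Sweep coverage thresholds against labelled scenes, pick the best.

    For every candidate threshold, every frame of every scene is tracked
    and the error is the count of missed males plus spurious detections
    (the true male count comes from the scene's parameters). Returns the
    candidate with minimal total error — ties break to the smallest
    threshold — together with the full (threshold, error) curve.
    """
    if len(scenes) == 0:
        raise ValueError("calibration needs at least one labelled scene")
    if len(candidates) == 0:
        raise ValueError("no candidate thresholds supplied")
    base = config or TrackerConfig()
    curve: list[tuple[float, int]] = []
    for thr in sorted(candidates):
        cfg = TrackerConfig(
            color_lo=base.color_lo,
            color_hi=base.color_hi,
            coverage_threshold=thr,
            grid=base.grid,
            target_fps=base.target_fps,
            dance_direction=base.dance_direction,
            female_column=base.female_column,
            max_gap=base.max_gap,
        )
        err = 0
        for scene in scenes:
            true_count = scene.params.n_males
            shape = scene.frames[0].shape[:2]
            grid = cfg.grid or default_grid(shape)
            for frame in scene.frames:
                dets = detect_males(
                    quadrant_coverage(color_mask(frame, cfg), grid), cfg, frame_shape=shape
                )
                err += abs(len(dets) - true_count)
        curve.append((thr, err))
    best = min(curve, key=lambda te: (te[1], te[0]))
    return best[0], curve
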