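"""Reading and writing frames, scenes, and parameter files."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .synthgen import DisplayParams, SyntheticScene

__all__ = [
    "write_scene",
    "load_frames",
    "save_params",
    "load_params",
]

_FRAME_PATTERN = "frame_{:05d}.png"
_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}


def write_scene(scene: SyntheticScene, out_dir: str | Path, video: bool = False) -> Path:
    """Write a synthetic scene: PNG frames, truth CSV, params YAML.

    ``video=True`` additionally attempts an MP4 (requires an ffmpeg
    imageio plugin; the PNG directory is always written and is the
    canonical representation).
    """
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(scene.frames):
        iio.imwrite(frames_dir / _FRAME_PATTERN.format(i), frame)
    n = len(scene.truth_trace)
    pd.DataFrame(
        {
            "frame_idx": np.arange(n),
            "time_s": np.arange(n) / scene.params.fps,
            "y_px": scene.truth_trace,
        }
    ).to_csv(out / "truth.csv", index=False)
    pd.DataFrame(
        [
            {
                "start_s": ev.start,
                "peak_s": ev.peak_time,
                "duration_s": ev.duration,
                "amplitude_px": ev.amplitude,
                "male_index": ev.male_index,
            }
            for ev in scene.truth_events
        ]
    ).to_csv(out / "events.csv", index=False)
    save_params(scene.params, out / "params.yaml")
    if video:
        try:
            iio.imwrite(out / "scene.mp4", scene.frames, fps=scene.params.fps)
        except Exception as exc:  # plugin-dependent; the PNGs remain canonical
            import warnings

            warnings.warn(f"could not write MP4 ({exc}); PNG frames written", stacklevel=2)
    return out


def load_frames(path: str | Path) -> np.ndarray:
    """Load RGB frames from a PNG frame directory or a video file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([iio.imread(f)[..., :3] for f in files])
    if path.suffix.lower() in _VIDEO_SUFFIXES:
        return np.asarray(iio.imread(path))[..., :3]
    raise ValueError(f"{path}: expected a frame directory or a video file")


def save_params(params: DisplayParams, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=True)
    return path


def load_params(path: str | Path) -> DisplayParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["frame_size"] = tuple(d["frame_size"])
    return DisplayParams(**d)
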