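"""The 1-D vertical-position time series all downstream analysis runs on."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DisplaySeries"]


@dataclass
class DisplaySeries:
    """Vertical position (raster px, y grows downward) of the edge male.

    Parameters
    ----------
    y : array of float
        Vertical positions in pixels, one per frame, raster orientation
        (smaller y = higher flight).
    fps : float
        Sampling rate in frames per second.
    t0 : float
        Time of the first sample, seconds.
    meta : dict
        Provenance: court id, display id, n_males, source file, ...
    """

    y: np.ndarray
    fps: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.size < 2:
            raise ValueError("a display series needs at least 2 samples")
        if not np.isfinite(self.y).all():
            raise ValueError("display series contains non-finite values")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return self.y.size

    @property
    def duration(self) -> float:
        """Covered time span in seconds (n samples at 1/fps spacing)."""
        return self.y.size / self.fps

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.y.size) / self.fps

    def to_csv(self, path: str | Path) -> Path:
        """Write ``time_s, y_px`` columns."""
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "y_px": self.y}).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "DisplaySeries":
        """Read a ``time_s, y_px`` file; fps inferred from the time column."""
        df = pd.read_csv(path)
        if not {"time_s", "y_px"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns time_s, y_px")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return cls(
            y=df["y_px"].to_numpy(dtype=float),
            fps=1.0 / float(dt[0]),
            t0=float(t[0]),
            meta=dict(meta or {}),
        )
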