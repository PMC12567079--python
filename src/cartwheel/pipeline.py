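"""End-to-end orchestration: simulate -> track -> rqa (+frequency) -> analyze.

Each stage writes plain CSV/JSON artifacts into a run directory and
registers them in a manifest with SHA-256 checksums, so a rerun with the
same configuration and seed reproduces every output bit-identically. A
single global seed fans out deterministically into per-stage,
per-display child seeds, so stages can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .displaymetrics import cartwheel_frequency
from .inference import run_female_choice_analysis, run_group_size_analysis
from .rqa import rqa_summary
from .series import DisplaySeries
from .synthgen import DisplayParams, simulate_display_video
from .tracker import TrackerConfig, track_frames

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cartwheel.pipeline")

#: baseline female rates used when simulating court-level counts
VISIT_RATE_PER_HOUR = 1.0
COPULATION_RATE_PER_HOUR = 0.15


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    out_dir: str = "runs/run0"
    seed: int = 0
    # synthetic-study shape
    n_courts: int = 2
    displays_per_court: int = 4
    duration: float = 10.0
    fps: float = 30.0
    frame_size: tuple[int, int] = (320, 240)
    timing_noise_sd: float = 0.05
    height_noise_sd: float = 3.0
    female_present: bool = False
    recording_hours: float = 5.0
    # stage toggles
    run_simulate: bool = True
    run_track: bool = True
    run_rqa: bool = True
    run_analyze: bool = True
    series_dir: str | None = None  # externally supplied series when track is off
    # tracking + rqa knobs
    coverage_threshold: float = 0.40
    target_fps: float = 15.0
    n_samples_mc: int = 10_000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "frame_size" in d:
            d["frame_size"] = tuple(d["frame_size"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["frame_size"] = list(self.frame_size)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seed(root: int, *key: int) -> int:
    """Deterministic per-stage/display child seed below 2**31."""
    ss = np.random.SeedSequence([root, *key])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return the manifest dict."""
    logging.basicConfig(level=config.log_level)
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    # the stored config is location-independent so reruns elsewhere hash equal
    stored = PipelineConfig(**{**asdict(config), "out_dir": ".", "frame_size": config.frame_size})
    stored.to_yaml(run_dir / "config.yaml")
    artifacts: list[Path] = [run_dir / "config.yaml"]
    display_index: list[dict] = []

    # ---- simulate -------------------------------------------------------
    if config.run_simulate:
        try:
            court_rows = []
            for c in range(config.n_courts):
                rng_court = np.random.default_rng(_child_seed(config.seed, 1, c))
                court_rows.append(
                    {
                        "court_id": c,
                        "recording_hours": config.recording_hours,
                        "n_visits": int(rng_court.poisson(config.recording_hours * VISIT_RATE_PER_HOUR)),
                        "n_copulations": int(
                            rng_court.poisson(config.recording_hours * COPULATION_RATE_PER_HOUR)
                        ),
                    }
                )
                for d in range(config.displays_per_court):
                    seed = _child_seed(config.seed, 2, c, d)
                    n_males = int(np.random.default_rng(seed).integers(2, 7))
                    params = DisplayParams(
                        n_males=n_males,
                        duration=config.duration,
                        fps=config.fps,
                        frame_size=config.frame_size,
                        timing_noise_sd=config.timing_noise_sd,
                        height_noise_sd=config.height_noise_sd,
                        female_present=config.female_present,
                        seed=seed,
                    )
                    scene = simulate_display_video(params)
                    ddir = run_dir / "displays" / f"court{c:02d}_display{d:02d}"
                    cio.write_scene(scene, ddir)
                    display_index.append(
                        {
                            "court_id": c,
                            "display_id": f"{c:02d}_{d:02d}",
                            "dir": str(ddir.relative_to(run_dir)),
                            "n_males": n_males,
                        }
                    )
                    log.info("simulated %s (%d males)", ddir.name, n_males)
            courts = pd.DataFrame(court_rows)
            courts.to_csv(run_dir / "courts.csv", index=False)
            pd.DataFrame(display_index).to_csv(run_dir / "displays.csv", index=False)
            artifacts += [run_dir / "courts.csv", run_dir / "displays.csv"]
            artifacts += sorted((run_dir / "displays").rglob("*.*"))
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
    elif (run_dir / "displays.csv").exists():
        display_index = pd.read_csv(run_dir / "displays.csv").to_dict(orient="records")

    # ---- track ----------------------------------------------------------
    series_dir = run_dir / "series"
    if config.run_track:
        try:
            if not display_index:
                raise ValueError("no displays to track (simulate stage disabled and no displays.csv)")
            series_dir.mkdir(exist_ok=True)
            tcfg = TrackerConfig(
                coverage_threshold=config.coverage_threshold, target_fps=config.target_fps
            )
            for entry in display_index:
                frames = cio.load_frames(run_dir / entry["dir"] / "frames")
                series = track_frames(
                    frames,
                    tcfg,
                    fps=config.fps,
                    meta={"court_id": entry["court_id"], "display_id": entry["display_id"]},
                )
                out_csv = series_dir / f"{entry['display_id']}.csv"
                series.to_csv(out_csv)
                artifacts.append(out_csv)
                log.info("tracked %s -> %d samples", entry["display_id"], len(series))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("track", str(exc)) from exc
    elif config.series_dir is not None:
        series_dir = Path(config.series_dir)

    # ---- rqa + frequency ------------------------------------------------
    if config.run_rqa:
        try:
            rows = []
            csvs = sorted(series_dir.glob("*.csv"))
            if not csvs:
                raise ValueError(f"no series CSVs found in {series_dir}")
            meta_by_id = {e["display_id"]: e for e in display_index}
            for f in csvs:
                series = DisplaySeries.from_csv(f)
                met = rqa_summary(
                    series.y, n_samples=config.n_samples_mc, seed=_child_seed(config.seed, 3)
                )
                entry = meta_by_id.get(f.stem, {})
                rows.append(
                    {
                        "display_id": f.stem,
                        "court_id": entry.get("court_id"),
                        "n_males": entry.get("n_males"),
                        "frequency": cartwheel_frequency(series),
                        **met.as_dict(),
                    }
                )
            metrics = pd.DataFrame(rows)
            metrics.to_csv(run_dir / "metrics.csv", index=False)
            artifacts.append(run_dir / "metrics.csv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("rqa", str(exc)) from exc

    # ---- analyze --------------------------------------------------------
    if config.run_analyze:
        try:
            metrics = pd.read_csv(run_dir / "metrics.csv")
            report: dict = {"group_size": {}, "female_choice": {}}
            if (run_dir / "courts.csv").exists() and metrics["court_id"].notna().all():
                courts = pd.read_csv(run_dir / "courts.csv")
                dataset = metrics.merge(courts, on="court_id", how="left")
                dataset["visit_rate"] = dataset["n_visits"] / dataset["recording_hours"]
                dataset["copulation_rate"] = dataset["n_copulations"] / dataset["recording_hours"]
                dataset.to_csv(run_dir / "dataset.csv", index=False)
                artifacts.append(run_dir / "dataset.csv")
            else:
                dataset = metrics
            present = [r for r in ("frequency", "rr", "det", "lam", "mcentr", "radius") if r in dataset]
            if (
                "n_males" in dataset
                and dataset["n_males"].notna().all()
                and "court_id" in dataset
                and dataset["court_id"].notna().all()
            ):
                for resp, res in run_group_size_analysis(dataset, tuple(present)).items():
                    report["group_size"][resp] = res.to_dict()
            if "visit_rate" in dataset:
                try:
                    visit, cop = run_female_choice_analysis(dataset)
                    report["female_choice"]["visit_rate"] = visit.to_dict()
                    report["female_choice"]["copulation_rate"] = cop.to_dict()
                except ValueError as exc:
                    # e.g. no copulations observed anywhere: report, don't halt
                    report["female_choice"]["error"] = str(exc)
            with open(run_dir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True, default=float)
            artifacts.append(run_dir / "report.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "config": str(run_dir / "config.yaml"),
        "files": {
            str(p.relative_to(run_dir)): _sha256(p) for p in sorted(set(artifacts)) if p.is_file()
        },
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
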