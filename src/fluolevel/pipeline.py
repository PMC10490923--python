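"""Frame sources, run configuration, and the end-to-end stream runner.

The hardware rig streams live video; here the equivalent input is a frame
source — a directory of PNG/JPEG frames (delivered in lexicographic order)
or a single image.  Any object with an ``iter_frames()`` method yielding
``(index, name, image)`` tuples can stand in, so a live or video-backed
source can be added without touching the pipeline.

``run_stream`` ties the stages together: every frame goes through the
detector, every reading through the stabilizer, and — if a calibration
curve is supplied — every accepted reading through the volume estimator.
Outputs are plain CSV files with a version comment header, so repeated
runs on the same inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import CalibrationCurve, estimate_volume
from .detect import DetectConfig, process_frame
from .stabilize import Stabilizer, StabilizerConfig

__all__ = ["FrameSource", "RunConfig", "StreamResult", "run_stream", "load_run_config"]

logger = logging.getLogger("fluolevel")

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class FrameSource:
    """A deterministic, file-backed sequence of frames."""

    path: Path
    kind: str = "auto"  # auto | directory | single_image

    def resolved_kind(self) -> str:
        if self.kind != "auto":
            return self.kind
        return "directory" if Path(self.path).is_dir() else "single_image"

    def iter_frames(self) -> Iterator[tuple[int, str, np.ndarray]]:
        path = Path(self.path)
        kind = self.resolved_kind()
        if kind == "single_image":
            if not path.is_file():
                raise FileNotFoundError(f"no such image: {path}")
            yield 0, path.name, iio.imread(path)
            return
        if kind == "directory":
            if not path.is_dir():
                raise NotADirectoryError(f"no such frame directory: {path}")
            files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
            if not files:
                raise FileNotFoundError(f"no PNG/JPEG frames in {path}")
            for i, f in enumerate(files):
                yield i, f.name, iio.imread(f)
            return
        raise ValueError(f"unknown frame-source kind: {kind!r}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run."""

    detect: DetectConfig = field(default_factory=DetectConfig)
    stabilizer: StabilizerConfig = field(default_factory=StabilizerConfig)
    calibration_curve: Optional[Path] = None
    out_dir: Path = Path(".")
    log_level: str = "INFO"
    seed: Optional[int] = None


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file; keyword overrides win.

    Schema: top-level keys ``detect`` (threshold, min_contour_area,
    closing_radius, center_weight), ``stabilizer`` (buffer_size,
    sigma_max, min_valid_fraction), ``calibration_curve``, ``out_dir``,
    ``log_level``, ``seed``.  All keys optional.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"malformed config file: {path}")
    det = DetectConfig(**raw.get("detect", {}))
    stab = StabilizerConfig(**raw.get("stabilizer", {}))
    cfg = RunConfig(
        detect=det,
        stabilizer=stab,
        calibration_curve=Path(raw["calibration_curve"]) if raw.get("calibration_curve") else None,
        out_dir=Path(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
        seed=raw.get("seed"),
    )
    if overrides:
        from dataclasses import replace

        cfg = replace(cfg, **overrides)
    return cfg


@dataclass
class StreamResult:
    """In-memory result of a stream run (also written as CSV)."""

    readings: pd.DataFrame
    stable: pd.DataFrame
    volumes: Optional[pd.DataFrame]
    n_frames: int

    @property
    def any_stable(self) -> bool:
        return len(self.stable) > 0


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# fluolevel {__version__}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def run_stream(source: FrameSource, config: RunConfig) -> StreamResult:
    """Process every frame of a source through detect -> stabilize -> estimate.

    Writes ``readings.csv`` (one row per frame), ``stable_readings.csv``
    (one row per accepted buffer), and — when a calibration curve is
    configured — ``volumes.csv`` with estimated volumes for each accepted
    reading.  Fails fast on an unreadable source before writing anything.
    """
    logger.setLevel(config.log_level.upper())
    curve = CalibrationCurve.load(config.calibration_curve) if config.calibration_curve else None
    stabilizer = Stabilizer(config.stabilizer)

    readings_rows = []
    stable_rows = []
    volume_rows = []
    n = 0
    for idx, name, image in source.iter_frames():
        n += 1
        reading = process_frame(image, config.detect, frame_index=idx)
        logger.debug("frame %d (%s): valid=%s perimeter=%.2f", idx, name, reading.valid, reading.perimeter)
        readings_rows.append(
            {
                "frame_index": idx,
                "frame_name": name,
                "perimeter_px": reading.perimeter,
                "valid_flag": int(reading.valid),
                "a_px": reading.a,
                "b_px": reading.b,
                "cx": reading.cx,
                "cy": reading.cy,
            }
        )
        stable = stabilizer.update(reading)
        if stable is not None:
            logger.info(
                "stable reading at frame %d: %.2f px (sigma %.3f)",
                stable.frame_index,
                stable.perimeter,
                stable.buffer_sigma,
            )
            stable_rows.append(
                {
                    "frame_index": stable.frame_index,
                    "perimeter_px": stable.perimeter,
                    "sigma_px": stable.buffer_sigma,
                    "n_valid": stable.n_valid,
                }
            )
            if curve is not None:
                est = estimate_volume(curve, stable.perimeter)
                volume_rows.append(
                    {
                        "frame_index": stable.frame_index,
                        "perimeter_px": est.perimeter,
                        "volume_ml": est.volume,
                        "extrapolated": int(est.extrapolated),
                    }
                )

    readings = pd.DataFrame(
        readings_rows,
        columns=["frame_index", "frame_name", "perimeter_px", "valid_flag", "a_px", "b_px", "cx", "cy"],
    )
    stable = pd.DataFrame(
        stable_rows, columns=["frame_index", "perimeter_px", "sigma_px", "n_valid"]
    )
    volumes = (
        pd.DataFrame(volume_rows, columns=["frame_index", "perimeter_px", "volume_ml", "extrapolated"])
        if curve is not None
        else None
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(readings, out / "readings.csv")
    _write_csv(stable, out / "stable_readings.csv")
    if volumes is not None:
        _write_csv(volumes, out / "volumes.csv")
    return StreamResult(readings=readings, stable=stable, volumes=volumes, n_frames=n)
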