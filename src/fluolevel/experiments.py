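"""Canonical end-to-end experiments: simulated fill runs and error tables.

These drive the full chain — synthetic fill sequence, per-frame detection,
rolling-buffer stabilization, six-point calibration, volume estimation —
under one roof, so the same experiment backs the test suite, the
reproduction script and interactive use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibrate import (
    CalibrationCurve,
    ErrorReport,
    evaluate_errors,
    fit_linear_2pt,
    fit_poly_lsq,
    select_calibration_points,
)
from .detect import DetectConfig, process_frame
from .stabilize import Stabilizer, StabilizerConfig
from .synthgen import SceneSpec, WellResponseModel, simulate_fill_sequence

__all__ = ["measure_fill_run", "ErrorTable", "error_table", "DEFAULT_FILL_VOLUMES"]

#: Canonical fill schedule: 25 steps from the first valid reading regime
#: (0.5 ml in a dry well) to overflow (3.4 ml).
DEFAULT_FILL_VOLUMES: tuple[float, ...] = tuple(
    round(float(v), 4) for v in np.linspace(0.5, 3.4, 25)
)


def measure_fill_run(
    model: WellResponseModel | None = None,
    volumes: tuple[float, ...] = DEFAULT_FILL_VOLUMES,
    seed: int = 42,
    frames_per_step: int = 14,
    disturbance_sigma: float = 12.0,
    settle_rate: float = 0.5,
    noise_sigma: float = 5.0,
    axis_ratio: float = 0.9,
    detect_config: DetectConfig | None = None,
    stabilizer_config: StabilizerConfig | None = None,
) -> list[tuple[float, float]]:
    """Run the full sensing chain over a fill schedule.

    Renders every frame, measures it, and keeps the *last* stabilized
    reading of each dispensing step (the settled value after the
    disturbance transient).  Returns (volume, stabilized perimeter) pairs
    for the steps that produced a stable reading.
    """
    model = model or WellResponseModel()
    scene = SceneSpec(true_perimeter=model.p0, noise_sigma=noise_sigma, axis_ratio=axis_ratio)
    frames = simulate_fill_sequence(
        model,
        list(volumes),
        frames_per_step=frames_per_step,
        disturbance_sigma=disturbance_sigma,
        settle_rate=settle_rate,
        seed=seed,
        scene=scene,
    )
    stabilizer = Stabilizer(stabilizer_config or StabilizerConfig())
    cfg = detect_config or DetectConfig()
    last_stable: dict[int, tuple[float, float]] = {}
    for i, f in enumerate(frames):
        stable = stabilizer.update(process_frame(f.image, cfg, frame_index=i))
        if stable is not None:
            last_stable[f.step] = (f.volume, stable.perimeter)
    return [last_stable[k] for k in sorted(last_stable)]


@dataclass(frozen=True)
class ErrorTable:
    """Error reports of all fit families over one or more runs.

    ``full`` pools every held-out measurement; ``linear`` restricts to the
    stable-meniscus volume band.  Keys are "2pt", "order3", "order4",
    "order5".
    """

    full: dict[str, ErrorReport] = field(repr=False)
    linear: dict[str, ErrorReport] = field(repr=False)
    curves: dict[str, CalibrationCurve] = field(repr=False)
    calibration_volumes: tuple[float, ...]

    def mean_pct(self, fit: str, scope: str = "full") -> float:
        return (self.full if scope == "full" else self.linear)[fit].mean_pct


def error_table(
    runs: list[list[tuple[float, float]]],
    model: WellResponseModel | None = None,
    linear_range: tuple[float, float] = (1.0, 2.8),
    orders: tuple[int, ...] = (3, 4, 5),
) -> ErrorTable:
    """Calibrate on the first run's six auto-selected points, evaluate on all.

    The two mid-region points give the 2-point linear fit; the six points
    give the least-squares polynomial fits.  Calibration volumes are held
    out of the evaluation, mirroring how a calibrated sensor is judged on
    measurements it was not fitted to.
    """
    model = model or WellResponseModel()
    pts = select_calibration_points(
        runs[0], (model.v_valid_min, model.v_stable, model.v_B, model.v_C)
    )
    cal_volumes = tuple(p.volume for p in pts)
    held = [[(v, p) for v, p in run if v not in cal_volumes] for run in runs]

    mid = [p for p in pts if p.region == "mid"]
    curves: dict[str, CalibrationCurve] = {"2pt": fit_linear_2pt(mid[0], mid[1])}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # end-of-range wiggles are expected
        for order in orders:
            curves[f"order{order}"] = fit_poly_lsq(pts, order=order)

    full = {name: evaluate_errors(c, held) for name, c in curves.items()}
    linear = {
        name: evaluate_errors(c, held, restrict=linear_range) for name, c in curves.items()
    }
    return ErrorTable(full=full, linear=linear, curves=curves, calibration_volumes=cal_volumes)
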