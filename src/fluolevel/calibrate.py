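"""Perimeter-to-volume calibration curves and error statistics.

The sensing signal is the fitted-ellipse perimeter; calibration turns it
into a volume.  Two fit families are supported:

* an exact two-point linear fit, sufficient inside the stable-meniscus
  (linear) range but badly wrong outside it;
* a least-squares polynomial (orders 3-5) through six calibration points,
  two from each of the low (pre-meniscus), mid (linear) and end (meniscus
  inversion) regions, which captures the whole response.

The polynomial is fitted with volume as a function of perimeter — the
direction in which the curve is evaluated — with the perimeters
standardized (centred and scaled) first for numerical conditioning.  The
standardization is stored with the coefficients, so a serialized curve is
self-contained.  Error reports pool per-measurement percentage errors
across runs, optionally restricted to a volume range such as the linear
1-2.8 ml band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "VolumeEstimate",
    "ErrorReport",
    "MonotonicityWarning",
    "fit_linear_2pt",
    "fit_poly_lsq",
    "estimate_volume",
    "evaluate_errors",
    "select_calibration_points",
]

REGIONS = ("low", "mid", "end")

#: Default stable-meniscus volume band (ml) of a 24-well plate well.
DEFAULT_LINEAR_RANGE = (1.0, 2.8)


class MonotonicityWarning(UserWarning):
    """The fitted curve is not monotone over its perimeter range."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One (volume, perimeter) calibration measurement."""

    volume: float  # ml
    perimeter: float  # px
    region: str = "mid"  # low | mid | end

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.perimeter <= 0:
            raise ValueError("volume and perimeter must be positive")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")


@dataclass(frozen=True)
class VolumeEstimate:
    """An estimated volume, flagged if the perimeter was out of range."""

    volume: float  # ml
    perimeter: float  # px
    extrapolated: bool


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted perimeter -> volume transfer function.

    ``coefficients`` are in ascending powers of the standardized
    perimeter ``z = (p - p_center) / p_scale``.
    """

    kind: str  # "linear_2pt" | "poly_lsq"
    order: int
    coefficients: tuple[float, ...]
    p_center: float
    p_scale: float
    valid_perimeter_range: tuple[float, float]
    linear_volume_range: tuple[float, float] = DEFAULT_LINEAR_RANGE

    def __call__(self, perimeter: float | np.ndarray) -> float | np.ndarray:
        z = (np.asarray(perimeter, dtype=float) - self.p_center) / self.p_scale
        v = npoly.polyval(z, self.coefficients)
        return float(v) if np.isscalar(perimeter) else v

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "order": self.order,
            "coefficients": list(self.coefficients),
            "p_center": self.p_center,
            "p_scale": self.p_scale,
            "valid_perimeter_range": list(self.valid_perimeter_range),
            "linear_volume_range": list(self.linear_volume_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            kind=d["kind"],
            order=int(d["order"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            p_center=float(d["p_center"]),
            p_scale=float(d["p_scale"]),
            valid_perimeter_range=tuple(d["valid_perimeter_range"]),
            linear_volume_range=tuple(d.get("linear_volume_range", DEFAULT_LINEAR_RANGE)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_monotone(curve: CalibrationCurve) -> None:
    lo, hi = curve.valid_perimeter_range
    p = np.linspace(lo, hi, 512)
    v = curve(p)
    if np.any(np.diff(v) <= 0):
        warnings.warn(
            "calibration curve is not strictly increasing over its perimeter range",
            MonotonicityWarning,
            stacklevel=3,
        )


def fit_linear_2pt(p1: CalibrationPoint, p2: CalibrationPoint) -> CalibrationCurve:
    """Exact line through two calibration points (volume vs. perimeter).

    The two points should come from the stable-meniscus (mid) region;
    outside that band the estimate degrades quickly.
    """
    if p1.perimeter == p2.perimeter:
        raise ValueError("calibration points must have distinct perimeters")
    lo, hi = sorted((p1.perimeter, p2.perimeter))
    center = 0.5 * (lo + hi)
    scale = 0.5 * (hi - lo)
    z1, z2 = (p1.perimeter - center) / scale, (p2.perimeter - center) / scale
    slope = (p2.volume - p1.volume) / (z2 - z1)
    intercept = p1.volume - slope * z1
    curve = CalibrationCurve(
        kind="linear_2pt",
        order=1,
        coefficients=(intercept, slope),
        p_center=center,
        p_scale=scale,
        valid_perimeter_range=(lo, hi),
    )
    _check_monotone(curve)
    return curve


def fit_poly_lsq(points: Sequence[CalibrationPoint], order: int) -> CalibrationCurve:
    """Least-squares polynomial volume(perimeter) fit, orders 3-5.

    Requires at least ``order + 1`` points; warns if the points do not
    span all three response regions (the fit then extrapolates over the
    uncovered regime) and if the fitted curve is not monotone over the
    data range.
    """
    if order not in (1, 2, 3, 4, 5):
        raise ValueError("polynomial order must be between 1 and 5")
    if len(points) < order + 1:
        raise ValueError(f"order-{order} fit needs at least {order + 1} points")
    missing = set(REGIONS) - {pt.region for pt in points}
    if missing:
        warnings.warn(
            f"calibration points cover no '{'/'.join(sorted(missing))}' region; "
            "the fit will extrapolate there",
            UserWarning,
            stacklevel=2,
        )
    p = np.array([pt.perimeter for pt in points], dtype=float)
    v = np.array([pt.volume for pt in points], dtype=float)
    center = float(p.mean())
    scale = float(p.std())
    if scale == 0:
        raise ValueError("calibration perimeters are all identical")
    z = (p - center) / scale
    # Guard against a rank-deficient design (e.g. duplicated perimeters).
    vand = npoly.polyvander(z, order)
    if np.linalg.matrix_rank(vand) < order + 1:
        raise ValueError("rank-deficient calibration design; add distinct perimeters")
    coef = npoly.polyfit(z, v, order)
    curve = CalibrationCurve(
        kind="poly_lsq",
        order=order,
        coefficients=tuple(float(c) for c in coef),
        p_center=center,
        p_scale=scale,
        valid_perimeter_range=(float(p.min()), float(p.max())),
    )
    _check_monotone(curve)
    return curve


def estimate_volume(curve: CalibrationCurve, perimeter: float) -> VolumeEstimate:
    """Evaluate the curve at a perimeter; out-of-range inputs are flagged.

    Extrapolation is flagged rather than fatal — an over-range reading
    still tells the caller "more than the calibrated span", which is
    useful for overflow detection.
    """
    lo, hi = curve.valid_perimeter_range
    return VolumeEstimate(
        volume=float(curve(perimeter)),
        perimeter=float(perimeter),
        extrapolated=not lo <= perimeter <= hi,
    )


@dataclass(frozen=True)
class ErrorReport:
    """Pooled percentage-error statistics of a curve over measurement runs."""

    per_point_pct_error: np.ndarray = field(repr=False)
    mean_pct: float
    stdev_pct: float
    mean_abs_ml: float
    n_runs: int
    n_points: int
    restricted_range: tuple[float, float] | None = None


def evaluate_errors(
    curve: CalibrationCurve,
    runs: Iterable[Sequence[tuple[float, float]]],
    restrict: tuple[float, float] | None = None,
) -> ErrorReport:
    """Percentage error of the curve on (true_volume, perimeter) runs.

    Errors are ``100 * |v_est - v_true| / v_true`` per measurement, pooled
    over all runs; ``restrict`` keeps only measurements whose true volume
    falls in a band (e.g. the 1-2.8 ml linear range).  Mean and sample
    standard deviation are over the pooled errors; the mean absolute
    error in ml is reported alongside.
    """
    errors: list[float] = []
    abs_err: list[float] = []
    n_runs = 0
    for run in runs:
        n_runs += 1
        for v_true, perim in run:
            if v_true <= 0:
                raise ValueError("true volumes must be positive")
            if restrict is not None and not restrict[0] <= v_true <= restrict[1]:
                continue
            v_est = float(curve(perim))
            errors.append(100.0 * abs(v_est - v_true) / v_true)
            abs_err.append(abs(v_est - v_true))
    if not errors:
        raise ValueError("no measurements to evaluate")
    arr = np.array(errors)
    return ErrorReport(
        per_point_pct_error=arr,
        mean_pct=float(arr.mean()),
        stdev_pct=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        mean_abs_ml=float(np.mean(abs_err)),
        n_runs=n_runs,
        n_points=len(arr),
        restricted_range=restrict,
    )


def select_calibration_points(
    run: Sequence[tuple[float, float]],
    region_edges: tuple[float, float, float, float],
) -> list[CalibrationPoint]:
    """Pick 2 calibration points per response region from a full run.

    ``region_edges = (v_start, v_low_hi, v_mid_hi, v_end)`` bound the low
    (pre-meniscus), mid (linear) and end (inversion) regions.  Within each
    region the measurements closest to the 25th and 75th percentile of the
    region's volume span are chosen, giving the canonical six-point
    calibration set.  Manual selection is always possible by building
    :class:`CalibrationPoint` lists directly.
    """
    v0, v1, v2, v3 = region_edges
    if not v0 < v1 < v2 < v3:
        raise ValueError("region edges must be strictly increasing")
    bands = {"low": (v0, v1), "mid": (v1, v2), "end": (v2, v3)}
    pts: list[CalibrationPoint] = []
    data = sorted(run)
    for region, (lo, hi) in bands.items():
        in_band = [(v, p) for v, p in data if lo <= v <= hi]
        if len(in_band) < 2:
            raise ValueError(f"need at least 2 measurements in the {region} region")
        chosen_idx: set[int] = set()
        for q in (0.25, 0.75):
            target = lo + q * (hi - lo)
            order = sorted(range(len(in_band)), key=lambda i: abs(in_band[i][0] - target))
            idx = next(i for i in order if i not in chosen_idx)
            chosen_idx.add(idx)
        for i in sorted(chosen_idx):
            v, p = in_band[i]
            pts.append(CalibrationPoint(volume=v, perimeter=p, region=region))
    return pts
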