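"""Synthetic spot images and fill sequences for the sensing pipeline.

The generator emulates what the camera under a transparent well actually
sees: a bright, roughly elliptical image of the overhead LED on a dark
background, whose perimeter responds to fluid volume in four regimes:

* below the film volume, droplets bead up instead of forming a layer and
  readings are meaningless scatter (dry-well regime);
* a sub-linear ramp while the meniscus geometry is still forming (region A);
* a linear response over the stable-meniscus range (region B) — the regime
  the refraction model predicts and the most generalizable one;
* a steeper, super-linear response once surface tension bulges the surface
  into a convex lens near the top of the well (meniscus inversion,
  region C);
* a constant plateau after overflow flattens the meniscus (region D).

On top of that response the generator models sensor noise, partial
occlusion by solid well contents, surface-disturbance transients that decay
after fluid is added, the uniform positive bias of a tilted plate, and the
raised background of a cloudy (e.g. oil-filled) well.  All randomness is
seeded and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .detect import ellipse_perimeter

__all__ = [
    "WellResponseModel",
    "SceneSpec",
    "FillFrame",
    "render_spot",
    "cloudy_scene",
    "volume_to_perimeter",
    "perimeter_to_axes",
    "simulate_perimeter_sequence",
    "simulate_fill_sequence",
]


@dataclass(frozen=True)
class WellResponseModel:
    """Piecewise perimeter response of one well to fluid volume.

    Volumes in ml, perimeters in px.  Defaults describe a 24-well plate
    well (~3.5 ml capacity) filled with water: first coherent reading
    around 0.4 ml, meniscus stable from about 1 ml, linear up to 2.8 ml,
    meniscus inversion until overflow at 3.4 ml.

    Parameters
    ----------
    v_film:
        Volume below which no coherent fluid layer exists in a dry well;
        readings below it are scatter.  A pre-moistened well may lower
        this to ``v_A``.
    v_A:
        Volume of the first valid reading; start of the sub-linear
        pre-meniscus ramp.
    v_stable:
        Volume at which the meniscus geometry stabilizes; start of the
        linear region.
    v_B:
        Onset of meniscus inversion (end of the linear region).
    v_C:
        Overflow volume; the response is constant beyond it.
    p0:
        Perimeter at ``v_A``, px.
    s_A, s_lin, s_inv:
        Slopes (px/ml): initial ramp slope, linear-region slope, and
        inversion-region slope, with ``s_A <= s_lin < s_inv``.
    tilt_bias:
        Additive perimeter offset (px) modeling a tilted plate; a tilt
        shows up as a uniform positive bias, so a flat-surface calibration
        overestimates volume.
    opacity:
        0-1; raises the image background and blurs edges (cloudy fluids
        such as oil), forcing a higher detection threshold.
    """

    v_film: float = 0.5
    v_A: float = 0.4
    v_stable: float = 1.0
    v_B: float = 2.8
    v_C: float = 3.4
    p0: float = 260.0
    s_A: float = 40.0
    s_lin: float = 120.0
    s_inv: float = 360.0
    tilt_bias: float = 0.0
    opacity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.v_A < self.v_stable < self.v_B < self.v_C:
            raise ValueError("breakpoints must satisfy 0 < v_A < v_stable < v_B < v_C")
        if not 0.0 < self.s_A <= self.s_lin < self.s_inv:
            raise ValueError("slopes must satisfy 0 < s_A <= s_lin < s_inv")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must be in [0, 1]")

    @property
    def v_valid_min(self) -> float:
        """Smallest volume with a meaningful reading."""
        return max(self.v_film, self.v_A)


def volume_to_perimeter(model: WellResponseModel, v: float) -> float | None:
    """Expected contour-ellipse perimeter (px) at volume ``v`` (ml).

    Returns ``None`` below the valid threshold (dry-well scatter regime —
    any rendered reading there carries no information).  The map is
    continuous and monotone non-decreasing from ``v_A`` up, constant from
    overflow (``v_C``) on, and carries the tilt bias uniformly.
    """
    if v < 0:
        raise ValueError("volume must be non-negative")
    if v < model.v_valid_min:
        return None
    return _response(model, v) + model.tilt_bias


def _response(model: WellResponseModel, v: float) -> float:
    """Flat-plate piecewise response, defined for v >= v_A (no tilt term)."""
    m = model
    v = min(v, m.v_C)  # region D: overflow plateau
    # Region A: quadratic ramp, slope s_A at v_A growing to s_lin at
    # v_stable (C1-continuous join with the linear region).
    wa = m.v_stable - m.v_A
    p_stable = m.p0 + m.s_A * wa + 0.5 * (m.s_lin - m.s_A) * wa
    if v <= m.v_stable:
        t = v - m.v_A
        return m.p0 + m.s_A * t + 0.5 * (m.s_lin - m.s_A) * t * t / wa
    # Region B: linear, stable meniscus.
    if v <= m.v_B:
        return p_stable + m.s_lin * (v - m.v_stable)
    # Region C: meniscus inversion, steeper.
    p_b = p_stable + m.s_lin * (m.v_B - m.v_stable)
    return p_b + m.s_inv * (v - m.v_B)


@dataclass(frozen=True)
class SceneSpec:
    """One synthetic frame: a bright elliptical spot on a dark background."""

    true_perimeter: float
    image_size: tuple[int, int] = (480, 480)  # (rows, cols)
    spot_center: tuple[float, float] | None = None  # (row, col); None = centre
    axis_ratio: float = 1.0  # b/a in [0.5, 1]
    rotation: float = 0.0  # radians
    background_level: float = 20.0
    spot_level: float = 230.0
    noise_sigma: float = 0.0
    occlusion_fraction: float = 0.0  # fraction of spot area masked, [0, 0.5]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_perimeter <= 0:
            raise ValueError("true_perimeter must be positive")
        if not 0.5 <= self.axis_ratio <= 1.0:
            raise ValueError("axis_ratio must be in [0.5, 1]")
        if not 0.0 <= self.occlusion_fraction <= 0.5:
            raise ValueError("occlusion_fraction must be in [0, 0.5]")
        if self.spot_level <= self.background_level:
            raise ValueError("spot must be brighter than background")
        a, _ = perimeter_to_axes(self.true_perimeter, self.axis_ratio)
        r0, c0 = self.centre
        nr, nc = self.image_size
        if a > min(r0, c0, nr - r0, nc - c0):
            raise ValueError("spot does not fit within the frame")

    @property
    def centre(self) -> tuple[float, float]:
        if self.spot_center is not None:
            return self.spot_center
        return (self.image_size[0] / 2.0, self.image_size[1] / 2.0)


def perimeter_to_axes(perimeter: float, axis_ratio: float) -> tuple[float, float]:
    """Semi-axes (a, b) of an ellipse with the given perimeter and b/a ratio.

    Inverts the Ramanujan perimeter approximation, which is linear under
    uniform scaling, so the inversion is exact with respect to it.
    """
    unit = ellipse_perimeter(1.0, axis_ratio)
    a = perimeter / unit
    return a, a * axis_ratio


def render_spot(spec: SceneSpec, supersample: int = 3) -> np.ndarray:
    """Render one 8-bit grayscale frame for a scene.

    The ellipse is rasterized by ``supersample``-fold area averaging so the
    spot boundary carries sub-pixel coverage information, then Gaussian
    sensor noise is added (seeded; bit-identical for identical specs).
    Occlusion is a dark disc concentric with the spot — solid contents
    such as an organoid resting mid-well — occupying
    ``occlusion_fraction`` of the spot area.
    """
    a, b = perimeter_to_axes(spec.true_perimeter, spec.axis_ratio)
    nr, nc = spec.image_size
    r0, c0 = spec.centre
    img = np.full((nr, nc), spec.background_level, dtype=float)

    # Supersampled coverage, computed only on the spot's bounding box.
    pad = 2
    rlo = max(int(math.floor(r0 - a)) - pad, 0)
    rhi = min(int(math.ceil(r0 + a)) + pad, nr)
    clo = max(int(math.floor(c0 - a)) - pad, 0)
    chi = min(int(math.ceil(c0 + a)) + pad, nc)
    s = supersample
    rr = rlo + (np.arange((rhi - rlo) * s) + 0.5) / s
    cc = clo + (np.arange((chi - clo) * s) + 0.5) / s
    R, C = np.meshgrid(rr - r0, cc - c0, indexing="ij")
    if spec.rotation:
        ct, st = math.cos(spec.rotation), math.sin(spec.rotation)
        R, C = ct * R + st * C, -st * R + ct * C
    inside = (R / a) ** 2 + (C / b) ** 2 <= 1.0
    if spec.occlusion_fraction > 0:
        r_occ = math.sqrt(spec.occlusion_fraction * a * b)
        inside &= R**2 + C**2 > r_occ**2
    cover = inside.reshape(rhi - rlo, s, chi - clo, s).mean(axis=(1, 3))
    img[rlo:rhi, clo:chi] += cover * (spec.spot_level - spec.background_level)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def cloudy_scene(scene: SceneSpec, opacity: float) -> SceneSpec:
    """Imaging conditions through a cloudy fluid (e.g. oil).

    Scattering lifts the background halfway toward the spot and dims the
    spot itself, shrinking the contrast so a threshold tuned for clear
    water may sit above the spot entirely — the measurement then needs
    the threshold adjusted (or Otsu), after which the principle holds.
    """
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must be in [0, 1]")
    contrast = scene.spot_level - scene.background_level
    new_bg = scene.background_level + 0.5 * opacity * contrast
    new_spot = scene.spot_level - 0.25 * opacity * contrast
    return replace(scene, background_level=new_bg, spot_level=new_spot)


@dataclass(frozen=True)
class FillFrame:
    """One frame of a simulated fill sequence."""

    step: int
    frame: int  # frame index within the step
    volume: float  # ml dispensed so far
    true_perimeter: float | None  # model response; None in the scatter regime
    frame_perimeter: float  # perimeter actually rendered (with disturbance)
    image: np.ndarray | None = field(repr=False, default=None)


def simulate_perimeter_sequence(
    model: WellResponseModel,
    volumes: list[float],
    frames_per_step: int,
    disturbance_sigma: float,
    settle_rate: float,
    seed: int,
) -> list[FillFrame]:
    """Per-frame perimeters of a fill run, without rendering images.

    After each addition of fluid the surface is disturbed: frame ``t`` of a
    step carries a perturbation of amplitude
    ``disturbance_sigma * settle_rate**t`` that decays geometrically toward
    the model response.  Below the valid-film volume, each frame is an
    independent uniform draw (dry-well scatter — the readings carry no
    information).  Deterministic given ``seed``.
    """
    if any(b < a for a, b in zip(volumes, volumes[1:])):
        raise ValueError("volumes must be non-decreasing")
    if not 0.0 < settle_rate < 1.0:
        raise ValueError("settle_rate must be in (0, 1)")
    if frames_per_step < 1:
        raise ValueError("frames_per_step must be >= 1")
    if disturbance_sigma < 0:
        raise ValueError("disturbance_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    scatter_lo = 0.4 * model.p0
    scatter_hi = _response(model, model.v_C) + model.tilt_bias
    out: list[FillFrame] = []
    for step, v in enumerate(volumes):
        target = volume_to_perimeter(model, v)
        for t in range(frames_per_step):
            if target is None:
                p = rng.uniform(scatter_lo, scatter_hi)
            else:
                p = target + disturbance_sigma * settle_rate**t * rng.standard_normal()
                p = max(p, 1.0)
            out.append(
                FillFrame(step=step, frame=t, volume=v, true_perimeter=target, frame_perimeter=p)
            )
    return out


def simulate_fill_sequence(
    model: WellResponseModel,
    volumes: list[float],
    frames_per_step: int = 12,
    disturbance_sigma: float = 12.0,
    settle_rate: float = 0.5,
    seed: int = 0,
    scene: SceneSpec | None = None,
) -> list[FillFrame]:
    """Simulate a fill run and render each frame.

    ``scene`` provides the imaging conditions (size, levels, noise,
    occlusion, axis ratio); its ``true_perimeter`` and ``seed`` are
    overridden per frame.  The model's ``opacity`` raises the background
    level, emulating a cloudy fluid.  Deterministic given ``seed``.
    """
    if scene is None:
        scene = SceneSpec(true_perimeter=model.p0)
    if model.opacity > 0:
        scene = cloudy_scene(scene, model.opacity)
    frames = simulate_perimeter_sequence(
        model, volumes, frames_per_step, disturbance_sigma, settle_rate, seed
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    out: list[FillFrame] = []
    for f in frames:
        frame_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(scene, true_perimeter=f.frame_perimeter, seed=frame_seed)
        out.append(replace(f, image=render_spot(spec)))
    return out
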