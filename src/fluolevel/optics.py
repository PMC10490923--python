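"""Refraction model of apparent light-source distance through a fluid layer.

A camera at the bottom of a transparent well looks up through a layer of
fluid at an overhead light source (an LED).  Because the fluid's refractive
index differs from the surrounding medium, rays from the source bend at the
two fluid interfaces and the source appears displaced along the optical
axis.  For a layer with parallel surfaces the displacement is linear in the
fluid depth, which is what makes the apparent size of the source a usable
level signal.

Geometry (distances along the optical axis, measurement plane at the
bottom):

    source ──(h0, outer medium)── fluid top
              ──(L, fluid)── fluid bottom
              ──(h1, outer medium)── measurement plane

A ray leaving the source at angle ``theta1`` from the vertical refracts to
``theta2`` at the fluid top (Snell's law) and back to ``theta1`` at the
fluid bottom, since the two interfaces are parallel.  Back-projecting the
exit ray to the optical axis gives the apparent source distance

    I = h0 + h1 + L * tan(theta2) / tan(theta1)

which equals the true distance ``h = h0 + L + h1`` when ``L = 0`` or when
the indices match, and is first-degree in ``L`` otherwise.  When a fixed
well fills (source and camera fixed, fluid displacing the outer medium:
``h`` constant, ``h0 = h - h1 - L``), this is

    I = h - L * (1 - C2 / C1),   C1 = tan(theta1), C2 = tan(theta2),

strictly decreasing in ``L`` for a fluid denser than the outer medium: the
source appears closer, hence larger, as the well fills.

Every closed-form result here is cross-checked against
:func:`trace_ray_oracle`, an explicit segment-by-segment 2-D ray
construction that knows nothing about the formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalStack",
    "TransferConstants",
    "RayTraceResult",
    "TotalInternalReflection",
    "snell_refract",
    "transfer_constants",
    "apparent_distance",
    "trace_ray_oracle",
    "apparent_perimeter",
    "fill_stack",
    "DEFAULT_THETA1",
]

#: Default incidence angle (radians).  The source emits in all directions,
#: so any ray that intersects the fluid surface may be chosen; a small
#: angle matches a distant, small source seen near the optical axis.
DEFAULT_THETA1 = math.radians(5.0)


class TotalInternalReflection(ValueError):
    """Raised when a ray cannot refract into the less dense medium."""


@dataclass(frozen=True)
class OpticalStack:
    """Axial geometry and refractive indices of the sensing column.

    Parameters
    ----------
    n_outer:
        Refractive index of the medium above and below the fluid
        (typically air, 1.0).  Must be >= 1.
    n_fluid:
        Refractive index of the fluid (water: 1.333).  Must be >= 1.
    h0:
        Source to fluid-surface distance, mm (> 0).
    h1:
        Fluid-bottom to measurement-plane distance, mm (>= 0).
    L:
        Fluid depth, mm (>= 0).
    """

    n_outer: float
    n_fluid: float
    h0: float
    h1: float
    L: float

    def __post_init__(self) -> None:
        if self.n_outer < 1.0 or self.n_fluid < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.h0 <= 0:
            raise ValueError("h0 must be positive")
        if self.h1 < 0 or self.L < 0:
            raise ValueError("h1 and L must be non-negative")

    @property
    def h(self) -> float:
        """Total source-to-measurement-plane distance, mm."""
        return self.h0 + self.L + self.h1


def fill_stack(
    h: float,
    h1: float,
    L: float,
    n_outer: float = 1.0,
    n_fluid: float = 1.333,
) -> OpticalStack:
    """Stack for a fixed well at fill depth ``L``.

    Source and measurement plane are fixed (total distance ``h``); the
    fluid displaces the outer medium, so ``h0 = h - h1 - L``.  This is the
    parameterization under which the apparent distance decreases as the
    well fills.
    """
    h0 = h - h1 - L
    if h0 <= 0:
        raise ValueError("fluid depth exceeds available column height")
    return OpticalStack(n_outer=n_outer, n_fluid=n_fluid, h0=h0, h1=h1, L=L)


@dataclass(frozen=True)
class TransferConstants:
    """Constants of the depth -> apparent-distance transfer function."""

    C0: float  # mm, h - h1
    C1: float  # tan(theta1)
    C2: float  # tan(theta2)
    theta1: float  # radians
    theta2: float  # radians, from Snell's law


@dataclass(frozen=True)
class RayTraceResult:
    """Outcome of the explicit two-interface ray trace."""

    exit_angle: float  # radians; equals theta1 for parallel interfaces
    lateral_offset_at_plane: float  # mm
    apparent_distance: float  # mm, back-projected source distance


def snell_refract(theta_in: float, n_in: float, n_out: float) -> float:
    """Refract a ray at a planar interface: n_in sin(theta_in) = n_out sin(theta_out).

    Angles are measured from the interface normal, in radians.

    Raises
    ------
    TotalInternalReflection
        If ``n_in * sin(theta_in) / n_out > 1`` (only possible when
        ``n_in > n_out``).
    """
    if not 0.0 <= theta_in < math.pi / 2:
        raise ValueError("theta_in must be in [0, pi/2)")
    if n_in < 1.0 or n_out < 1.0:
        raise ValueError("refractive indices must be >= 1")
    s = n_in * math.sin(theta_in) / n_out
    if s > 1.0:
        raise TotalInternalReflection(
            f"sin(theta_out) = {s:.6f} > 1 for theta_in = {theta_in:.6f} rad"
        )
    return math.asin(s)


def transfer_constants(stack: OpticalStack, theta1: float = DEFAULT_THETA1) -> TransferConstants:
    """Constants C0 = h - h1, C1 = tan(theta1), C2 = tan(theta2) for a stack.

    ``theta1`` must lie in (0, pi/2): the source emits in all directions,
    so any angle whose ray meets the fluid surface may be chosen, and the
    ratio C2/C1 is what enters the transfer function.
    """
    if not 0.0 < theta1 < math.pi / 2:
        raise ValueError("theta1 must be in (0, pi/2)")
    theta2 = snell_refract(theta1, stack.n_outer, stack.n_fluid)
    return TransferConstants(
        C0=stack.h - stack.h1,
        C1=math.tan(theta1),
        C2=math.tan(theta2),
        theta1=theta1,
        theta2=theta2,
    )


def apparent_distance(stack: OpticalStack, theta1: float = DEFAULT_THETA1) -> float:
    """Apparent source distance I (mm) seen from the measurement plane.

    ``I = h0 + h1 + L * C2 / C1`` — first-degree in the fluid depth.  At
    ``L = 0`` (or matched indices) this is the true geometric distance
    ``h``.  For a fixed well filling up (``h`` constant), substitute
    ``h0 = h - h1 - L`` to see ``I = h - L * (1 - C2/C1)``: the source
    appears closer as the level rises when ``n_fluid > n_outer``, and the
    relationship inverts when the fluid is less dense than the
    surroundings.
    """
    c = transfer_constants(stack, theta1)
    return stack.h0 + stack.h1 + stack.L * c.C2 / c.C1


def trace_ray_oracle(stack: OpticalStack, theta1: float = DEFAULT_THETA1) -> RayTraceResult:
    """Brute-force validation oracle: explicit 2-D ray through the column.

    Constructs the ray segment by segment — outer medium, fluid, outer
    medium — accumulating the lateral offset at each interface crossing,
    then back-projects the exit ray to the optical axis.  Shares no algebra
    with :func:`apparent_distance` beyond Snell's law itself.
    """
    if not 0.0 < theta1 < math.pi / 2:
        raise ValueError("theta1 must be in (0, pi/2)")
    # Segment 1: source -> fluid top, angle theta1 in the outer medium.
    x = stack.h0 * math.tan(theta1)
    # Segment 2: through the fluid at the refracted angle.
    theta2 = snell_refract(theta1, stack.n_outer, stack.n_fluid)
    x += stack.L * math.tan(theta2)
    # Segment 3: back into the outer medium; parallel interfaces return
    # the ray to its original inclination (theta3 = theta1).
    theta3 = snell_refract(theta2, stack.n_fluid, stack.n_outer)
    x += stack.h1 * math.tan(theta3)
    # Back-project the exit ray from the plane to the optical axis.
    apparent = x / math.tan(theta3)
    return RayTraceResult(
        exit_angle=theta3,
        lateral_offset_at_plane=x,
        apparent_distance=apparent,
    )


def apparent_perimeter(I: float, source_diameter: float, pixel_scale: float) -> float:
    """Perimeter (px) of the source image under a pinhole-projection model.

    ``perimeter = pi * source_diameter * pixel_scale / I``: the image of a
    disc of physical diameter ``source_diameter`` (mm) at apparent distance
    ``I`` (mm), with ``pixel_scale`` in px·mm (pixels per unit angular
    size, calibrated by imaging a ruled slide at known distances).  Strictly
    decreasing in ``I``: a closer-appearing source looks bigger.
    """
    if I <= 0 or source_diameter <= 0 or pixel_scale <= 0:
        raise ValueError("I, source_diameter and pixel_scale must be positive")
    return math.pi * source_diameter * pixel_scale / I


def apparent_distance_sweep(
    h: float,
    h1: float,
    depths: "np.ndarray | list[float]",
    n_outer: float = 1.0,
    n_fluid: float = 1.333,
    theta1: float = DEFAULT_THETA1,
) -> np.ndarray:
    """Apparent distance over a fill sweep of a fixed well (h constant)."""
    return np.array(
        [
            apparent_distance(fill_stack(h, h1, float(L), n_outer, n_fluid), theta1)
            for L in depths
        ]
    )
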