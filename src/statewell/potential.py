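"""Nonstationary double-well potential and its parameterizations.

The behavioral observable (rescaled sensing-rate, unitless) is modeled as a
diffusion in a quartic energy landscape

    U(x, t) = a(t) (x - 1/2) + b(t) (x - 1/2)^2 + c(t) (x - 1/2)^4

whose symmetric part is specified by two shape parameters: the well depth
``h`` relative to the unstable point (negative when the wells lie below the
barrier) and the separation ``d`` between the unstable point and either
stable point.  For the symmetric well (``a = 0``) the canonical polynomial
coefficients follow exactly from the shape:

    b = 2 h / d^2,    c = -h / d^4

which places the minima at 1/2 +/- d with U(1/2 +/- d) - U(1/2) = h.  A slow
latent variable s(t) tilts and stretches the landscape through an affine map
(:class:`LatentMap`), modulating the switching rates between the two wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PotentialShape",
    "CanonicalCoefficients",
    "LatentMap",
    "FixedPoint",
    "shape_to_canonical",
    "canonical_to_shape",
    "latent_to_shape",
    "potential_value",
    "potential_gradient",
    "potential_curvature",
    "fixed_points",
    "unstable_point",
    "boltzmann_density",
]

#: Tolerance on the cubic discriminant when classifying the fixed-point
#: structure near a saddle-node bifurcation.
DISCRIMINANT_TOL = 1e-10


@dataclass(frozen=True)
class PotentialShape:
    """Tilt/depth/separation parameterization of the double well.

    Parameters
    ----------
    h : float
        Depth of the wells relative to the unstable point (unitless);
        negative values put the wells below the barrier.
    d : float
        Separation between the unstable point and either stable point
        (unitless, in rescaled-signal units). Must be positive.
    a : float
        Tilt coefficient (unitless). ``a = 0`` gives a symmetric well.
    """

    h: float
    d: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"separation d must be positive, got {self.d}")


@dataclass(frozen=True)
class CanonicalCoefficients:
    """Polynomial coefficients (a, b, c) of the quartic landscape."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class LatentMap:
    """Affine map from the latent variable s(t) to tilt a(t) and separation d(t).

    ``a(s)`` and ``d(s)`` interpolate linearly between their values at the
    observed latent extrema: ``a(s_min) = a1``, ``a(s_max) = a2`` and
    likewise ``d1``/``d2``.  Latent values outside ``[s_min, s_max]`` are
    clipped to the endpoints (the extrema are by construction the extrema of
    the latent trajectory, so out-of-range queries only arise from
    user-supplied inputs).
    """

    s_min: float
    s_max: float
    a1: float
    a2: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not self.s_max > self.s_min:
            raise ValueError(
                f"degenerate latent map: s_max ({self.s_max}) must exceed "
                f"s_min ({self.s_min})"
            )

    def tilt(self, s):
        """Tilt a(s), affine in s, clipped at the endpoints."""
        s = np.clip(s, self.s_min, self.s_max)
        frac = (s - self.s_min) / (self.s_max - self.s_min)
        return self.a1 + (self.a2 - self.a1) * frac

    def separation(self, s):
        """Separation d(s), affine in s, clipped at the endpoints."""
        s = np.clip(s, self.s_min, self.s_max)
        frac = (s - self.s_min) / (self.s_max - self.s_min)
        return self.d1 + (self.d2 - self.d1) * frac


@dataclass(frozen=True)
class FixedPoint:
    """A stationary point of the landscape with its stability label."""

    x: float
    stable: bool


def shape_to_canonical(shape: PotentialShape) -> CanonicalCoefficients:
    """Convert shape parameters (h, d, a) to canonical coefficients (a, b, c).

    Exact relations: b = 2h/d^2 and c = -h/d^4.
    """
    if not shape.d > 0:
        raise ValueError(f"separation d must be positive, got {shape.d}")
    d2 = shape.d * shape.d
    return CanonicalCoefficients(
        a=shape.a, b=2.0 * shape.h / d2, c=-shape.h / (d2 * d2)
    )


def canonical_to_shape(coeffs: CanonicalCoefficients) -> PotentialShape:
    """Invert :func:`shape_to_canonical` (requires b < 0 < c, a true double well)."""
    if not (coeffs.c > 0 and coeffs.b < 0):
        raise ValueError(
            "coefficients do not describe a symmetric double well "
            f"(need b < 0 < c, got b={coeffs.b}, c={coeffs.c})"
        )
    d = math.sqrt(-coeffs.b / (2.0 * coeffs.c))
    h = coeffs.b * d * d / 2.0
    return PotentialShape(h=h, d=d, a=coeffs.a)


def latent_to_shape(s: float, lmap: LatentMap, h: float) -> PotentialShape:
    """Shape of the landscape at latent value ``s`` (depth h is not modulated)."""
    return PotentialShape(h=h, d=float(lmap.separation(s)), a=float(lmap.tilt(s)))


def potential_value(x, coeffs: CanonicalCoefficients):
    """U(x) = a(x-1/2) + b(x-1/2)^2 + c(x-1/2)^4."""
    y = np.asarray(x, dtype=float) - 0.5
    out = coeffs.a * y + coeffs.b * y**2 + coeffs.c * y**4
    return out if out.ndim else float(out)


def potential_gradient(x, coeffs: CanonicalCoefficients):
    """U'(x) = a + 2b(x-1/2) + 4c(x-1/2)^3."""
    y = np.asarray(x, dtype=float) - 0.5
    out = coeffs.a + 2.0 * coeffs.b * y + 4.0 * coeffs.c * y**3
    return out if out.ndim else float(out)


def potential_curvature(x, coeffs: CanonicalCoefficients):
    """U''(x) = 2b + 12c(x-1/2)^2."""
    y = np.asarray(x, dtype=float) - 0.5
    out = 2.0 * coeffs.b + 12.0 * coeffs.c * y**2
    return out if out.ndim else float(out)


def _real_cubic_roots(p: float, q: float) -> list[float]:
    """Real roots of the depressed cubic y^3 + p y + q = 0 (closed form).

    The discriminant sign is resolved with an absolute tolerance so the root
    count is deterministic across platforms at a saddle-node, where two roots
    collide.
    """
    disc = -4.0 * p**3 - 27.0 * q**2
    if disc > DISCRIMINANT_TOL:
        # three distinct real roots: trigonometric method (requires p < 0)
        m = 2.0 * math.sqrt(-p / 3.0)
        arg = 3.0 * q / (p * m)
        arg = min(1.0, max(-1.0, arg))
        theta = math.acos(arg) / 3.0
        return sorted(m * math.cos(theta - 2.0 * math.pi * k / 3.0) for k in range(3))
    if disc < -DISCRIMINANT_TOL:
        # one real root: Cardano
        s = math.sqrt(q**2 / 4.0 + p**3 / 27.0)
        u = -q / 2.0 + s
        v = -q / 2.0 - s
        return [math.copysign(abs(u) ** (1.0 / 3.0), u)
                + math.copysign(abs(v) ** (1.0 / 3.0), v)]
    # degenerate (saddle-node): a repeated root plus a simple one
    if abs(p) <= DISCRIMINANT_TOL and abs(q) <= DISCRIMINANT_TOL:
        return [0.0]
    double = -3.0 * q / (2.0 * p)
    simple = 3.0 * q / p
    return sorted({double, simple})


def fixed_points(coeffs: CanonicalCoefficients) -> list[FixedPoint]:
    """Stationary points of U, sorted ascending, labeled by stability.

    Solves the cubic U'(x) = 0 in closed form.  Depending on the tilt the
    landscape has one or three stationary points; the structure changes
    through saddle-node bifurcations as the tilt is swept.
    """
    a, b, c = coeffs.a, coeffs.b, coeffs.c
    if c == 0.0:
        if b == 0.0:
            return []  # pure tilt or flat: no stationary point
        y = -a / (2.0 * b)
        return [FixedPoint(x=y + 0.5, stable=b > 0)]
    # 4c y^3 + 2b y + a = 0  ->  y^3 + p y + q = 0
    p = b / (2.0 * c)
    q = a / (4.0 * c)
    roots = _real_cubic_roots(p, q)
    out = []
    for y in roots:
        curv = 2.0 * b + 12.0 * c * y * y
        out.append(FixedPoint(x=y + 0.5, stable=curv > 0))
    return out


def unstable_point(coeffs: CanonicalCoefficients) -> float | None:
    """Location of the barrier (unstable stationary point), or None if monostable."""
    unstable = [fp.x for fp in fixed_points(coeffs) if not fp.stable]
    if not unstable:
        return None
    return unstable[0]


def boltzmann_density(x, coeffs: CanonicalCoefficients, D: float):
    """Stationary density exp(-U/D)/Z of the frozen landscape, normalized on ``x``.

    ``x`` must be a dense, increasing grid covering the support; the
    normalization uses trapezoidal quadrature on that grid.
    """
    x = np.asarray(x, dtype=float)
    u = potential_value(x, coeffs)
    w = np.exp(-(u - u.min()) / D)
    z = np.trapezoid(w, x)
    return w / z
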