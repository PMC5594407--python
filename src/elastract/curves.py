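"""Discrete planar curves and their derivative operators.

A fiber tract is modelled as an absolutely continuous curve
``beta : [0, 1] -> D`` with ``D = [0, 1]^2``, sampled at T uniformly spaced
parameter values ``t_i = i/(T-1)``.  All derivative quantities (velocity,
acceleration, unit tangent, curvature) are computed with second-order
finite-difference stencils: central differences at interior samples and
one-sided three-point stencils at the two endpoints.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Curve",
    "DegenerateCurveError",
    "param_derivative",
    "param_second_derivative",
    "curve_derivatives",
    "resample_uniform",
]


class DegenerateCurveError(ValueError):
    """Raised when a curve has too few points or a vanishing velocity."""


def param_derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """d/dt of per-sample values on a uniform parameter grid.

    Second-order central differences inside, second-order one-sided
    stencils at the boundary (``np.gradient`` with ``edge_order=2``).
    Works on any array whose first axis is the parameter axis.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise DegenerateCurveError("need at least 3 samples to differentiate")
    return np.gradient(values, dt, axis=0, edge_order=2)


def param_second_derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """d^2/dt^2 with the standard three-point second difference.

    Interior: (f[i+1] - 2 f[i] + f[i-1]) / dt^2.  Endpoints use the
    second-order one-sided four-point stencil when T >= 4, otherwise the
    adjacent interior value is copied.
    """
    f = np.asarray(values, dtype=float)
    T = f.shape[0]
    if T < 3:
        raise DegenerateCurveError("need at least 3 samples to differentiate")
    out = np.empty_like(f)
    out[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / dt**2
    if T >= 4:
        out[0] = (2.0 * f[0] - 5.0 * f[1] + 4.0 * f[2] - f[3]) / dt**2
        out[-1] = (2.0 * f[-1] - 5.0 * f[-2] + 4.0 * f[-3] - f[-4]) / dt**2
    else:
        out[0] = out[1]
        out[-1] = out[-2]
    return out


class Curve:
    """An ordered planar polyline on the unit square.

    Parameters
    ----------
    points : (T, 2) array_like
        Sample coordinates in domain units.  T >= 3, all points inside
        [0, 1]^2 (within a small tolerance), consecutive points distinct.
    """

    #: tolerance for the inside-the-domain check
    _DOMAIN_TOL = 1e-9

    def __init__(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"curve points must be (T, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise DegenerateCurveError(
                f"a curve needs at least 3 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("curve contains non-finite coordinates")
        if pts.min() < -self._DOMAIN_TOL or pts.max() > 1.0 + self._DOMAIN_TOL:
            raise ValueError("curve leaves the unit-square domain [0, 1]^2")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise DegenerateCurveError("consecutive curve points coincide")
        self.points = np.clip(pts, 0.0, 1.0)
        self.points.setflags(write=False)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.points.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        a, b = self.points[0], self.points[-1]
        return (
            f"Curve(T={len(self)}, "
            f"({a[0]:.3f},{a[1]:.3f})->({b[0]:.3f},{b[1]:.3f}))"
        )

    @property
    def dt(self) -> float:
        return 1.0 / (len(self) - 1)

    @property
    def t(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, len(self))

    def length(self) -> float:
        """Polyline (chordal) length."""
        seg = np.diff(self.points, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def reversed(self) -> "Curve":
        return Curve(self.points[::-1])


def curve_derivatives(curve: Curve):
    """Velocity, acceleration, unit tangents and speeds of a discrete curve.

    Returns
    -------
    velocity : (T, 2) ndarray
        Finite-difference estimate of the curve velocity (d beta / dt).
    acceleration : (T, 2) ndarray
        Second-difference estimate of the curve acceleration.
    tangent : (T, 2) ndarray
        Unit tangents n(t) = velocity / speed.
    speed : (T,) ndarray
        Velocity magnitudes, all strictly positive.

    Raises
    ------
    DegenerateCurveError
        If any finite-difference velocity vanishes.
    """
    vel = param_derivative(curve.points, curve.dt)
    acc = param_second_derivative(curve.points, curve.dt)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if np.any(speed <= 0.0):
        raise DegenerateCurveError("zero-length velocity on the discrete curve")
    tangent = vel / speed[:, None]
    return vel, acc, tangent, speed


def curvature_and_normal(curve: Curve):
    """Signed curvature and the curvature-signed unit normal.

    kappa = (xdot * yddot - ydot * xddot) / speed^3; the normal is the
    tangent rotated by +90 degrees and carries no extra sign (so
    kappa * normal is the rotation-equivariant curvature vector).
    """
    vel, acc, tangent, speed = curve_derivatives(curve)
    cross = vel[:, 0] * acc[:, 1] - vel[:, 1] * acc[:, 0]
    kappa = cross / speed**3
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    return kappa, normal


def resample_uniform(points: np.ndarray, T: int) -> np.ndarray:
    """Resample a polyline to ``T`` points uniformly spaced in arc length.

    Endpoints are preserved exactly.  Accepts a Curve or a raw array and
    returns a raw (T, 2) array.
    """
    pts = points.points if isinstance(points, Curve) else np.asarray(points, float)
    seg = np.diff(pts, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    if s[-1] <= 0:
        raise DegenerateCurveError("cannot resample a zero-length polyline")
    s /= s[-1]
    # guard against repeated knots from coincident points
    s = np.maximum.accumulate(s + np.arange(len(s)) * 1e-15)
    target = np.linspace(0.0, 1.0, T)
    out = np.column_stack(
        [np.interp(target, s, pts[:, 0]), np.interp(target, s, pts[:, 1])]
    )
    out[0], out[-1] = pts[0], pts[-1]
    return out
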