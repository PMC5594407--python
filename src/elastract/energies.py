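"""Energy terms of the posterior and their analytic curve-space gradients.

The total energy of a candidate fiber beta is a weighted sum of

* a data term: for tensor fields the scale-invariant alignment integral
  ``E_data = Int_0^1 n(t)^T M(beta(t))^{-1} n(t) dt`` with n the unit
  tangent; for ODF fields ``E_data = Int_0^1 -f_{beta(t)}(n(t)) dt``;
* a smoothness (length) penalty ``E_smooth = Int_0^1 |beta_dot| dt``;
* a shape-prior term (see :mod:`elastract.shape`).

Gradients are L2 gradient densities along the curve, derived from the first
variation ``grad E = dg/dbeta - d/dt (dg/dbeta_dot)``.  The time derivative
is taken with the *same* finite-difference stencil used for the curve
velocity, which makes the returned field the exact adjoint of the discrete
trapezoid energy at interior samples (up to the bilinear gradient caches of
the field).  Expanding the d/dt term analytically recovers the familiar
closed forms: the inverse-tensor expression with its n_dot, beta_ddot and
grad_x M^{-1} terms for the tensor case, the curvature flow ``kappa n`` for
the length term, and the projected first/second circular derivatives of f
for the ODF case.

Conventions: the data-term gradients are densities with respect to the
uniform parameter measure dt; the smoothness gradient is the classical
curvature flow (density with respect to arc length), with magnitude kappa
and direction *away* from the center of the osculating circle — the descent
step then moves the curve toward the chord and shrinks its length.
Endpoint entries are reported but are meant to be masked by the tracker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import Curve, curve_derivatives, param_derivative
from .fields import ODFField, TensorField

__all__ = [
    "EnergyReport",
    "e_data_tensor",
    "grad_e_data_tensor",
    "e_smooth",
    "grad_e_smooth",
    "e_data_odf",
    "grad_e_data_odf",
    "data_energy",
    "data_gradient",
]


@dataclass
class EnergyReport:
    """An energy value together with its per-point gradient field."""

    value: float
    gradient: np.ndarray  # (T, 2)

    def __post_init__(self):
        if not np.all(np.isfinite(self.gradient)):
            raise ValueError("non-finite energy gradient")


def _trapz(values: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(values, dx=dt))


# ---------------------------------------------------------------------------
# tensor data term
# ---------------------------------------------------------------------------

def e_data_tensor(field: TensorField, curve: Curve, speed_weighted: bool = False) -> float:
    """Alignment energy of a curve with the inverse tensor field.

    Trapezoidal quadrature of ``n^T M^{-1} n`` over t.  The integrand
    depends on the tangent *direction* only, so the value is invariant to
    constant rescaling of traversal speed.  With ``speed_weighted=True`` the
    measure becomes ``|beta_dot| dt``, which buys full reparameterization
    invariance at the price of length dependence (optional variant).
    """
    _, _, tangent, speed = curve_derivatives(curve)
    Minv = field.inverse_many(curve.points)
    g = np.einsum("ni,nij,nj->n", tangent, Minv, tangent)
    if speed_weighted:
        g = g * speed
    return _trapz(g, curve.dt)


def grad_e_data_tensor(field: TensorField, curve: Curve) -> np.ndarray:
    """L2 gradient density of :func:`e_data_tensor` (default measure).

    Pointwise ``dg/dbeta - D[dg/dbeta_dot]`` with
    ``dg/dbeta_dot = (2/|beta_dot|) (M^{-1} n - (n^T M^{-1} n) n)`` and
    ``(dg/dbeta)_k = n^T (d_k M^{-1}) n`` from the cached gradient field.
    """
    _, _, tangent, speed = curve_derivatives(curve)
    pts = curve.points
    Minv = field.inverse_many(pts)
    A = field.gradient_many(pts, "M_inverse")  # (T, 2, 2, 2)

    Mn = np.einsum("nij,nj->ni", Minv, tangent)
    nMn = np.einsum("ni,ni->n", tangent, Mn)
    p = (2.0 / speed)[:, None] * (Mn - nMn[:, None] * tangent)
    spatial = np.einsum("ni,nijk,nj->nk", tangent, A, tangent)
    return spatial - param_derivative(p, curve.dt)


# ---------------------------------------------------------------------------
# smoothness / length term
# ---------------------------------------------------------------------------

def e_smooth(curve: Curve) -> float:
    """Curve length ``Int |beta_dot| dt`` by trapezoidal quadrature."""
    _, _, _, speed = curve_derivatives(curve)
    return _trapz(speed, curve.dt)


def grad_e_smooth(curve: Curve) -> np.ndarray:
    """Curvature-flow gradient of the length penalty.

    Equals ``-dT/ds`` (T the unit tangent, s arc length): magnitude is the
    curvature kappa, direction away from the curvature center, so that a
    descent step is the curve-shortening flow.
    """
    _, _, tangent, speed = curve_derivatives(curve)
    return -param_derivative(tangent, curve.dt) / speed[:, None]


# ---------------------------------------------------------------------------
# ODF data term
# ---------------------------------------------------------------------------

def e_data_odf(field: ODFField, curve: Curve) -> float:
    """HARDI data energy: minus the ODF mass along the tangent direction."""
    _, _, tangent, _ = curve_derivatives(curve)
    theta = np.arctan2(tangent[:, 1], tangent[:, 0])
    f = field.evaluate_many(curve.points, theta)
    return _trapz(-f, curve.dt)


def grad_e_data_odf(field: ODFField, curve: Curve) -> np.ndarray:
    """L2 gradient density of :func:`e_data_odf`.

    Uses the analytic circular derivative of the Fourier representation for
    the tangent-rotation term and the coefficient-gradient cache for the
    spatial term.  ``dg/dbeta_dot = -(f'(theta)/|beta_dot|) n_perp`` where
    ``n_perp`` is the 90-degree rotated unit tangent.
    """
    _, _, tangent, speed = curve_derivatives(curve)
    pts = curve.points
    theta = np.arctan2(tangent[:, 1], tangent[:, 0])
    f1 = field.evaluate_many(pts, theta, deriv=1)
    n_perp = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    p = -(f1 / speed)[:, None] * n_perp
    spatial = -field.spatial_gradient_many(pts, theta)
    return spatial - param_derivative(p, curve.dt)


# ---------------------------------------------------------------------------
# dispatch helpers used by the tracker
# ---------------------------------------------------------------------------

def data_energy(field, curve: Curve) -> float:
    if isinstance(field, TensorField):
        return e_data_tensor(field, curve)
    if isinstance(field, ODFField):
        return e_data_odf(field, curve)
    raise TypeError(f"unsupported field type {type(field).__name__}")


def data_gradient(field, curve: Curve) -> np.ndarray:
    if isinstance(field, TensorField):
        return grad_e_data_tensor(field, curve)
    if isinstance(field, ODFField):
        return grad_e_data_odf(field, curve)
    raise TypeError(f"unsupported field type {type(field).__name__}")
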