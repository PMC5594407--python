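"""Gridded diffusion-data fields on the unit square.

Two field types drive the data term of the tracker:

* :class:`TensorField` — a grid of 2x2 symmetric positive-definite (SPD)
  diffusion tensors, with cached inverse tensors and cached central-difference
  spatial gradients of both the tensor field and its inverse.
* :class:`ODFField` — a grid of antipodally symmetric orientation
  distribution functions on the unit circle, stored as truncated even-order
  Fourier series so that directional derivatives are analytic.

Grid convention: the domain is D = [0, 1]^2, the grid is node-centered with
node (i, j) located at ((i + 1/2)/G1, (j + 1/2)/G2).  Interpolation is
entrywise bilinear; queries outside the node lattice but inside D are clamped
to the boundary nodes, queries outside D raise :class:`OutOfDomainError`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["OutOfDomainError", "TensorField", "ODFField"]

_DOMAIN_TOL = 1e-9


class OutOfDomainError(ValueError):
    """A query point lies outside the unit-square domain."""


# ---------------------------------------------------------------------------
# bilinear machinery shared by both field types
# ---------------------------------------------------------------------------

def _check_in_domain(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] != 2:
        raise ValueError("query points must have shape (..., 2)")
    if x.min() < -_DOMAIN_TOL or x.max() > 1.0 + _DOMAIN_TOL:
        bad = x[(x < -_DOMAIN_TOL).any(axis=-1) | (x > 1 + _DOMAIN_TOL).any(axis=-1)]
        raise OutOfDomainError(f"point(s) outside [0,1]^2, e.g. {bad[0]}")
    return np.clip(x, 0.0, 1.0)


def _bilinear_weights(x: np.ndarray, G1: int, G2: int):
    """Node indices and weights for clamped bilinear interpolation."""
    u = x[:, 0] * G1 - 0.5
    v = x[:, 1] * G2 - 0.5
    u = np.clip(u, 0.0, G1 - 1.0)
    v = np.clip(v, 0.0, G2 - 1.0)
    i0 = np.minimum(np.floor(u).astype(int), G1 - 2) if G1 > 1 else np.zeros(len(u), int)
    j0 = np.minimum(np.floor(v).astype(int), G2 - 2) if G2 > 1 else np.zeros(len(v), int)
    fu = u - i0
    fv = v - j0
    return i0, j0, fu, fv


def _bilinear_gather(arr: np.ndarray, i0, j0, fu, fv) -> np.ndarray:
    """Interpolate ``arr[(G1, G2) + extra]`` at fractional node coordinates."""
    G1, G2 = arr.shape[:2]
    i1 = np.minimum(i0 + 1, G1 - 1)
    j1 = np.minimum(j0 + 1, G2 - 1)
    extra = (1,) * (arr.ndim - 2)
    wu = fu.reshape((-1,) + extra)
    wv = fv.reshape((-1,) + extra)
    return (
        arr[i0, j0] * (1 - wu) * (1 - wv)
        + arr[i1, j0] * wu * (1 - wv)
        + arr[i0, j1] * (1 - wu) * wv
        + arr[i1, j1] * wu * wv
    )


def _grid_gradient(arr: np.ndarray, G1: int, G2: int) -> np.ndarray:
    """Central-difference spatial gradient, stacked on a trailing axis.

    Units are array units per domain unit (grid spacing 1/G along each axis).
    """
    d1 = np.gradient(arr, 1.0 / G1, axis=0, edge_order=2 if G1 > 2 else 1)
    d2 = np.gradient(arr, 1.0 / G2, axis=1, edge_order=2 if G2 > 2 else 1)
    return np.stack([d1, d2], axis=-1)


# ---------------------------------------------------------------------------
# symmetric 2x2 eigen machinery (vectorized, closed form)
# ---------------------------------------------------------------------------

def sym_eigvals(mats: np.ndarray):
    """Eigenvalues (larger, smaller) of symmetric 2x2 matrices."""
    a = mats[..., 0, 0]
    b = mats[..., 0, 1]
    d = mats[..., 1, 1]
    half = 0.5 * (a + d)
    disc = np.sqrt((0.5 * (a - d)) ** 2 + b**2)
    return half + disc, half - disc


def sym_floor_eigvals(mats: np.ndarray, floor: float) -> np.ndarray:
    """Raise eigenvalues of symmetric 2x2 matrices to at least ``floor``."""
    mats = mats.copy()
    lam1, lam2 = sym_eigvals(mats)
    need = lam2 < floor
    if not np.any(need):
        return mats
    idx = np.nonzero(need)
    sub = mats[idx]
    a, b, d = sub[:, 0, 0], sub[:, 0, 1], sub[:, 1, 1]
    l1 = np.maximum(lam1[idx], floor)
    l2 = np.full_like(l1, floor)
    # leading eigenvector, guarded against the isotropic case
    vx = np.where(np.abs(b) > 1e-300, b, np.where(a >= d, 1.0, 0.0))
    vy = np.where(np.abs(b) > 1e-300, l1 - a, np.where(a >= d, 0.0, 1.0))
    nrm = np.hypot(vx, vy)
    nrm[nrm == 0] = 1.0
    vx, vy = vx / nrm, vy / nrm
    fixed = np.empty_like(sub)
    fixed[:, 0, 0] = l1 * vx**2 + l2 * vy**2
    fixed[:, 0, 1] = fixed[:, 1, 0] = (l1 - l2) * vx * vy
    fixed[:, 1, 1] = l1 * vy**2 + l2 * vx**2
    mats[idx] = fixed
    return mats


def _inv2(mats: np.ndarray) -> np.ndarray:
    a = mats[..., 0, 0]
    b = mats[..., 0, 1]
    d = mats[..., 1, 1]
    det = a * d - b * b
    out = np.empty_like(mats)
    out[..., 0, 0] = d / det
    out[..., 0, 1] = out[..., 1, 0] = -b / det
    out[..., 1, 1] = a / det
    return out


# ---------------------------------------------------------------------------
# TensorField
# ---------------------------------------------------------------------------

class TensorField:
    """A node-centered grid of 2x2 SPD diffusion tensors over [0, 1]^2.

    Parameters
    ----------
    tensors : (G1, G2, 2, 2) array_like
        Per-node tensors.  Must be symmetric to machine tolerance and
        positive definite.
    eig_floor : float, optional
        Lower bound applied to eigenvalues everywhere (construction and
        interpolation).  Default: 1e-4 times the largest eigenvalue in the
        field.

    Attributes
    ----------
    M : (G1, G2, 2, 2) ndarray — floored, exactly symmetric node tensors.
    M_inv : (G1, G2, 2, 2) ndarray — cached per-node inverses.
    grad_M, grad_M_inv : (G1, G2, 2, 2, 2) ndarray
        Cached central-difference spatial gradients; the trailing axis is the
        spatial direction, i.e. ``grad_M[..., k]`` estimates dM/dx_k.
    """

    def __init__(self, tensors, eig_floor: float | None = None):
        M = np.asarray(tensors, dtype=float)
        if M.ndim != 4 or M.shape[2:] != (2, 2):
            raise ValueError(f"tensors must be (G1, G2, 2, 2), got {M.shape}")
        asym = np.abs(M[..., 0, 1] - M[..., 1, 0])
        scale = max(np.abs(M).max(), 1.0)
        if asym.max() > 1e-8 * scale:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(f"tensor at node ({i}, {j}) is not symmetric")
        M = 0.5 * (M + np.swapaxes(M, 2, 3))
        lam1, lam2 = sym_eigvals(M)
        if lam2.min() <= 0.0:
            i, j = np.unravel_index(np.argmin(lam2), lam2.shape)
            raise ValueError(
                f"tensor at node ({i}, {j}) is not positive definite "
                f"(min eigenvalue {lam2[i, j]:.3e})"
            )
        if eig_floor is None:
            eig_floor = 1e-4 * lam1.max()
        self.eig_floor = float(eig_floor)
        self.M = sym_floor_eigvals(M, self.eig_floor)
        self.G1, self.G2 = M.shape[:2]
        self.M_inv = _inv2(self.M)
        self.grad_M = _grid_gradient(self.M, self.G1, self.G2)
        self.grad_M_inv = _grid_gradient(self.M_inv, self.G1, self.G2)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_function(cls, fn, grid=(20, 20), eig_floor=None) -> "TensorField":
        """Sample ``fn(x) -> 2x2 SPD`` at the node centers of ``grid``."""
        G1, G2 = grid
        xs, ys = cls.node_axes(G1, G2)
        M = np.empty((G1, G2, 2, 2))
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                M[i, j] = fn(np.array([x, y]))
        return cls(M, eig_floor=eig_floor)

    @staticmethod
    def node_axes(G1: int, G2: int):
        return (np.arange(G1) + 0.5) / G1, (np.arange(G2) + 0.5) / G2

    @property
    def grid(self):
        return (self.G1, self.G2)

    # -- queries -----------------------------------------------------------
    def _weights(self, x):
        x = _check_in_domain(x)
        return (x,) + _bilinear_weights(x, self.G1, self.G2)

    def interpolate_many(self, x) -> np.ndarray:
        """Bilinear tensors at points ``x`` (N, 2) -> (N, 2, 2), floored."""
        _, i0, j0, fu, fv = self._weights(x)
        out = _bilinear_gather(self.M, i0, j0, fu, fv)
        return sym_floor_eigvals(out, self.eig_floor)

    def interpolate(self, x) -> np.ndarray:
        return self.interpolate_many(np.asarray(x, float)[None])[0]

    def inverse_many(self, x) -> np.ndarray:
        """Bilinear interpolation of the cached inverse field."""
        _, i0, j0, fu, fv = self._weights(x)
        out = _bilinear_gather(self.M_inv, i0, j0, fu, fv)
        return sym_floor_eigvals(out, 0.0)  # convex combo of SPD: no-op floor

    def gradient_many(self, x, which: str = "M_inverse") -> np.ndarray:
        """Interpolated spatial gradient tensors, (N, 2, 2, 2).

        ``which`` selects the differentiated field: ``"M"`` or
        ``"M_inverse"``.  The trailing axis indexes the spatial direction.
        """
        if which not in ("M", "M_inverse"):
            raise ValueError("which must be 'M' or 'M_inverse'")
        arr = self.grad_M if which == "M" else self.grad_M_inv
        _, i0, j0, fu, fv = self._weights(x)
        return _bilinear_gather(arr, i0, j0, fu, fv)

    def gradient_at(self, x, which: str = "M_inverse") -> np.ndarray:
        return self.gradient_many(np.asarray(x, float)[None], which)[0]

    def principal_direction_many(self, x) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue of interpolated M."""
        M = self.interpolate_many(x)
        lam1, _ = sym_eigvals(M)
        b = M[:, 0, 1]
        a = M[:, 0, 0]
        d = M[:, 1, 1]
        vx = np.where(np.abs(b) > 1e-14, b, np.where(a >= d, 1.0, 0.0))
        vy = np.where(np.abs(b) > 1e-14, lam1 - a, np.where(a >= d, 0.0, 1.0))
        nrm = np.hypot(vx, vy)
        return np.column_stack([vx / nrm, vy / nrm])


# ---------------------------------------------------------------------------
# ODFField
# ---------------------------------------------------------------------------

def fourier_orders(n_coeffs: int) -> np.ndarray:
    """Harmonic order of each coefficient: [0, 2, 2, 4, 4, ...]."""
    if n_coeffs % 2 != 1:
        raise ValueError("ODF coefficient count must be odd (a0 + (a,b) pairs)")
    k = np.arange((n_coeffs - 1) // 2) + 1
    return np.concatenate([[0], np.repeat(2 * k, 2)])


def fourier_basis(theta: np.ndarray, n_coeffs: int, deriv: int = 0) -> np.ndarray:
    """Even-order Fourier basis [1, cos2t, sin2t, cos4t, ...] or a theta
    derivative of it, evaluated at ``theta``; shape (len(theta), n_coeffs)."""
    theta = np.atleast_1d(np.asarray(theta, float))
    orders = fourier_orders(n_coeffs)
    out = np.empty((theta.shape[0], n_coeffs))
    out[:, 0] = 1.0 if deriv == 0 else 0.0
    K = (n_coeffs - 1) // 2
    for kk in range(1, K + 1):
        m = 2 * kk
        c, s = np.cos(m * theta), np.sin(m * theta)
        if deriv == 0:
            ca, cb = c, s
        elif deriv == 1:
            ca, cb = -m * s, m * c
        elif deriv == 2:
            ca, cb = -(m**2) * c, -(m**2) * s
        else:
            raise ValueError("deriv must be 0, 1 or 2")
        out[:, 2 * kk - 1] = ca
        out[:, 2 * kk] = cb
    del orders
    return out


def project_to_fourier(f_samples: np.ndarray, thetas: np.ndarray, n_coeffs: int):
    """Least-squares projection of circle samples onto the even basis.

    With ``thetas`` uniform on [0, 2pi) this is the discrete Fourier
    projection (the basis is orthogonal under the uniform measure).
    """
    B = fourier_basis(thetas, n_coeffs)
    # uniform grid: <b_i, b_j> = N * diag(1, 1/2, ..., 1/2)
    N = len(thetas)
    coeffs = B.T @ f_samples / N
    coeffs[..., 1:] *= 2.0
    return coeffs


class ODFField:
    """Gridded antipodally symmetric direction densities on the circle.

    Each node stores coefficients of the truncated even Fourier series

        f(theta) = a0 + sum_k [ a_{2k} cos(2k theta) + b_{2k} sin(2k theta) ]

    up to order ``L`` (``n_coeffs = 1 + L``).  Storing only even harmonics
    enforces f(theta) = f(theta + pi) exactly.  At construction the density
    is clipped at zero (projected back onto the basis) and renormalized so
    that each node integrates to one over the circle.
    """

    _N_THETA = 256  # circle samples used for the clip-and-reproject step

    def __init__(self, coeffs, clip: bool = True):
        c = np.array(coeffs, dtype=float)
        if c.ndim != 3:
            raise ValueError(f"coeffs must be (G1, G2, C), got {c.shape}")
        fourier_orders(c.shape[2])  # validates C
        self.G1, self.G2, self.n_coeffs = c.shape
        if clip:
            thetas = np.linspace(0.0, 2 * np.pi, self._N_THETA, endpoint=False)
            B = fourier_basis(thetas, self.n_coeffs)
            flat = c.reshape(-1, self.n_coeffs)
            f = flat @ B.T
            if f.min() < -1e-12:
                f = np.clip(f, 0.0, None)
                flat = project_to_fourier(f.T, thetas, self.n_coeffs).T
            c = flat.reshape(c.shape)
        a0 = c[..., 0]
        if np.any(a0 <= 0):
            raise ValueError("ODF with non-positive mean density")
        c = c / (2.0 * np.pi * a0[..., None])  # integral over circle -> 1
        self.coeffs = c
        self.grad_coeffs = _grid_gradient(c, self.G1, self.G2)

    @property
    def grid(self):
        return (self.G1, self.G2)

    def _coeffs_at(self, x) -> np.ndarray:
        x = _check_in_domain(x)
        i0, j0, fu, fv = _bilinear_weights(x, self.G1, self.G2)
        return _bilinear_gather(self.coeffs, i0, j0, fu, fv)

    def evaluate_many(self, x, theta, deriv: int = 0) -> np.ndarray:
        """f (or d^deriv f / d theta^deriv) at points ``x``, angles ``theta``."""
        c = self._coeffs_at(x)
        B = fourier_basis(theta, self.n_coeffs, deriv=deriv)
        return np.einsum("nc,nc->n", c, B)

    def evaluate(self, x, direction) -> float:
        """Density at one point for a unit direction vector."""
        d = np.asarray(direction, float)
        if abs(np.hypot(d[0], d[1]) - 1.0) > 1e-6:
            raise ValueError("direction must be a unit vector")
        theta = np.arctan2(d[1], d[0])
        return float(self.evaluate_many(np.asarray(x, float)[None], [theta])[0])

    def spatial_gradient_many(self, x, theta) -> np.ndarray:
        """grad_x f(x, theta) via the coefficient-gradient cache, (N, 2)."""
        x = _check_in_domain(x)
        i0, j0, fu, fv = _bilinear_weights(x, self.G1, self.G2)
        gc = _bilinear_gather(self.grad_coeffs, i0, j0, fu, fv)  # (N, C, 2)
        B = fourier_basis(theta, self.n_coeffs)
        return np.einsum("nck,nc->nk", gc, B)
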