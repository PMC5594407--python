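"""Shared fixtures: synthetic fields, curves, a fitted prior, FD oracles."""

from __future__ import annotations

import numpy as np
import pytest

from elastract.curves import Curve
from elastract.fields import ODFField, TensorField, _inv2
from elastract.phantoms import make_scene, make_training_shapes, scene_to_tensor_field
from elastract.shape import ShapePrior


# ---------------------------------------------------------------------------
# field factories
# ---------------------------------------------------------------------------

def bilinear_inverse_field(seed: int = 0, grid: int = 40) -> TensorField:
    """Random SPD field whose *inverse* entries lie in span{1, x, y, xy}.

    Bilinear interpolation and central differencing are exact on this
    class, so the analytic data-term gradient matches finite differences
    of the discrete energy to machine precision — the right fixture for
    the tight gradient-agreement checks.
    """
    r = np.random.default_rng(seed)
    G = grid
    xs = (np.arange(G) + 0.5) / G
    X, Y = np.meshgrid(xs, xs, indexing="ij")

    def entry(base, amp):
        c = r.uniform(-amp, amp, 3)
        return base + c[0] * X + c[1] * Y + c[2] * X * Y

    a = entry(r.uniform(1.5, 2.5), 0.6)
    d = entry(r.uniform(1.5, 2.5), 0.6)
    b = entry(0.0, 0.4)
    Minv = np.empty((G, G, 2, 2))
    Minv[..., 0, 0] = a
    Minv[..., 0, 1] = Minv[..., 1, 0] = b
    Minv[..., 1, 1] = d
    return TensorField(_inv2(Minv))


def trig_tensor_field(seed: int = 0, grid: int = 80) -> TensorField:
    """Generic smooth (trigonometric) SPD field sampled on a fine grid."""
    r = np.random.default_rng(seed)
    a = r.uniform(-1, 1, 4)
    b = r.uniform(-1, 1, 4)

    def fn(x):
        th = 0.5 * (a[0] * np.sin(2 * np.pi * x[0] * 0.7)
                    + a[1] * np.cos(2 * np.pi * x[1] * 0.6) + a[2] * x[0] + a[3])
        l1 = 1.0 + 0.4 * np.sin(np.pi * (b[0] * x[0] + b[1] * x[1]))
        l2 = 0.4 + 0.2 * np.cos(np.pi * (b[2] * x[0] + b[3] * x[1]))
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s], [s, c]])
        return R @ np.diag([l1, l2]) @ R.T

    return TensorField.from_function(fn, (grid, grid))


def smooth_odf_field(seed: int = 0, grid: int = 60, n_coeffs: int = 9) -> ODFField:
    """Smoothly varying single-ish-lobe ODF field."""
    r = np.random.default_rng(seed)
    G = grid
    xs = (np.arange(G) + 0.5) / G
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    th0 = r.uniform(0, np.pi)
    ang = th0 + 0.6 * np.sin(np.pi * X) + 0.4 * np.cos(0.8 * np.pi * Y)
    amp = 0.5 + 0.3 * np.sin(0.6 * np.pi * (X + Y))
    co = np.zeros((G, G, n_coeffs))
    co[..., 0] = 1.0
    co[..., 1] = amp * np.cos(2 * ang)
    co[..., 2] = amp * np.sin(2 * ang)
    co[..., 3] = 0.2 * amp * np.cos(4 * ang)
    co[..., 4] = 0.2 * amp * np.sin(4 * ang)
    return ODFField(co)


def smooth_curve(seed: int = 0, T: int = 60) -> Curve:
    """Random smooth open curve crossing the domain left to right."""
    r = np.random.default_rng(seed)
    t = np.linspace(0, 1, T)
    x = 0.15 + 0.7 * t
    y = (0.5 + 0.15 * np.sin(np.pi * t * r.uniform(0.8, 1.5))
         + 0.05 * np.sin(2 * np.pi * t + r.uniform(0, 6)))
    return Curve(np.column_stack([x, y]))


def arc_points(bow: float, T: int = 80, a=(0.1, 0.35), b=(0.9, 0.35),
               modes=None) -> np.ndarray:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    chord = b - a
    n = np.array([-chord[1], chord[0]])
    n /= np.hypot(*n)
    t = np.linspace(0, 1, T)
    off = bow * np.sin(np.pi * t)
    if modes is not None:
        for k, amp in enumerate(modes, start=2):
            off = off + amp * np.sin(k * np.pi * t)
    return a + t[:, None] * chord + off[:, None] * n


# ---------------------------------------------------------------------------
# finite-difference oracles
# ---------------------------------------------------------------------------

def fd_curve_gradient(energy_fn, curve: Curve, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a curve energy w.r.t. every point."""
    pts = curve.points.copy()
    g = np.zeros_like(pts)
    for i in range(pts.shape[0]):
        for k in range(2):
            p1 = pts.copy()
            p1[i, k] += h
            p2 = pts.copy()
            p2[i, k] -= h
            g[i, k] = (energy_fn(Curve(p1)) - energy_fn(Curve(p2))) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# session-scoped expensive artifacts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def crossing_scene():
    return make_scene("crossing", seed=1)


@pytest.fixture(scope="session")
def crossing_field(crossing_scene):
    return scene_to_tensor_field(crossing_scene)


@pytest.fixture(scope="session")
def fitted_prior():
    """Shape prior fitted on the standard 30-arc training ensemble."""
    shapes = make_training_shapes(make_scene("arc_bundle", seed=10_001), T=100)
    return ShapePrior(n_points=100).fit(shapes)


@pytest.fixture(scope="session")
def small_prior():
    """Cheaper prior at T=60 for gradient-heavy tests."""
    shapes = make_training_shapes(make_scene("arc_bundle", seed=10_001), T=60)
    return ShapePrior(n_points=60).fit(shapes)
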