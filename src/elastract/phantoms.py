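"""Synthetic ground-truth scenes and their tensor / ODF fields.

The simulation protocol follows the standard 2D phantom recipe: ground
truth fibers drawn on [0, 1]^2 are rasterized onto a coarse grid (default
20 x 20); each cell's tensor is assembled from the mean outer product of
the unit tangents of the truth segments crossing it; a 2D Gaussian
smoothing is applied before use.  Crossing cells therefore receive nearly
isotropic tensors (or multi-lobe ODFs), which is exactly what defeats
local streamlining and motivates the global tracker.

Scene kinds
-----------
``crossing``     two bundles intersecting near the center (main experiment);
``kissing``      two bundles approaching without intersecting;
``noisy_patch``  one bundle plus a box of randomized tensors;
``arc_bundle``   an ensemble of perturbed arcs sharing endpoint regions —
                 the training data for the shape prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ive

from .curves import Curve, resample_uniform
from .fields import ODFField, TensorField, sym_floor_eigvals

__all__ = ["Scene", "make_scene", "scene_to_tensor_field", "scene_to_odf_field",
           "make_training_shapes"]

SCENE_KINDS = ("crossing", "kissing", "noisy_patch", "arc_bundle")


@dataclass
class Scene:
    """Named ground-truth fiber bundles plus the generating parameters."""

    kind: str
    bundles: dict[str, list[np.ndarray]]
    params: dict
    seed: int
    rois: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)

    @property
    def truth_fibers(self) -> list[np.ndarray]:
        """All fibers of the primary bundle (the tracking target)."""
        key = "primary" if "primary" in self.bundles else next(iter(self.bundles))
        return self.bundles[key]

    def all_fibers(self) -> list[np.ndarray]:
        return [f for fibers in self.bundles.values() for f in fibers]


def _arc(a, b, bow: float, T: int = 200, modes=None) -> np.ndarray:
    """Chord from a to b plus a transverse sine bow (plus optional modes)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    chord = b - a
    n = np.array([-chord[1], chord[0]])
    n /= np.hypot(*n)
    t = np.linspace(0.0, 1.0, T)
    off = bow * np.sin(np.pi * t)
    if modes is not None:
        for k, amp in enumerate(modes, start=2):
            off = off + amp * np.sin(k * np.pi * t)
    return a + t[:, None] * chord + off[:, None] * n


def _jittered_arcs(rng, n, a, b, bow, bow_jitter, endpoint_jitter, wiggle, T):
    fibers = []
    for _ in range(n):
        ai = np.asarray(a) + rng.normal(0.0, endpoint_jitter, 2)
        bi = np.asarray(b) + rng.normal(0.0, endpoint_jitter, 2)
        bowi = bow + rng.normal(0.0, bow_jitter)
        modes = rng.normal(0.0, wiggle, 2)
        fibers.append(np.clip(_arc(ai, bi, bowi, T=T, modes=modes), 0.0, 1.0))
    return fibers


_CROSSING_DEFAULTS = dict(
    n_primary=5, a=(0.1, 0.35), b=(0.9, 0.35), bow=0.12,
    primary_spacing=0.002, crossing_spacing=0.05, crossing_angle=60.0,
    crossing_extent=(0.0, 0.20), decoy_end=(0.9, 0.60), n_crossing=3,
    roi_radius=0.08, T=200,
)


def make_scene(kind: str, params: dict | None = None, seed: int = 0) -> Scene:
    """Deterministic ground-truth scene of the requested kind."""
    if kind not in SCENE_KINDS:
        raise ValueError(f"unknown scene kind {kind!r}; choose from {SCENE_KINDS}")
    rng = np.random.default_rng(seed)
    p = dict(params or {})

    if kind == "arc_bundle":
        defaults = dict(n_fibers=30, a=(0.1, 0.35), b=(0.9, 0.35), bow=0.12,
                        bow_jitter=0.03, endpoint_jitter=0.008, wiggle=0.005, T=200)
        defaults.update(p)
        p = defaults
        fibers = _jittered_arcs(rng, p["n_fibers"], p["a"], p["b"], p["bow"],
                                p["bow_jitter"], p["endpoint_jitter"],
                                p["wiggle"], p["T"])
        bundles = {"primary": fibers}
        rois = _endpoint_rois(fibers, 0.08)

    elif kind == "crossing":
        defaults = dict(_CROSSING_DEFAULTS)
        defaults.update(p)
        p = defaults
        primary = []
        offsets = (np.arange(p["n_primary"]) - (p["n_primary"] - 1) / 2)
        for k in offsets:
            shift = np.array([0.0, k * p["primary_spacing"]])
            primary.append(
                _arc(np.asarray(p["a"]) + shift, np.asarray(p["b"]) + shift,
                     p["bow"] + 0.3 * k * p["primary_spacing"], T=p["T"])
            )
        # the crossing bundle rises steeply through the primary bundle near
        # its apex, then bends into a roughly horizontal "decoy" course: a
        # deterministic tracker that follows local principal directions is
        # carried through the junction onto the decoy and never returns
        apex = np.array([0.5, p["a"][1] + p["bow"]])
        ang = np.deg2rad(p["crossing_angle"])
        direction = np.array([np.cos(ang), np.sin(ang)])
        ext = p["crossing_extent"]
        ext = ext if isinstance(ext, (tuple, list)) else (ext, ext)
        decoy_end = np.asarray(p["decoy_end"], float)
        perp = np.array([-direction[1], direction[0]])
        crossing = []
        t_b = np.linspace(0.0, 1.0, p["T"])[:, None]
        for k in (np.arange(p["n_crossing"]) - (p["n_crossing"] - 1) / 2):
            shift = k * p["crossing_spacing"] * perp
            P0 = apex - ext[0] * direction + shift
            P1 = apex + ext[1] * direction + shift
            P2 = decoy_end + shift
            bez = ((1 - t_b) ** 2 * P0 + 2 * t_b * (1 - t_b) * P1 + t_b**2 * P2)
            crossing.append(np.clip(bez, 0.02, 0.98))
        bundles = {"primary": primary, "crossing": crossing}
        rois = _endpoint_rois(primary, p["roi_radius"])

    elif kind == "kissing":
        defaults = dict(gap=0.03, T=200)
        defaults.update(p)
        p = defaults
        # bundles bow toward the horizontal midline and stop gap/2 short of
        # it, approaching within a grid cell without touching
        reach = 0.2 - p["gap"] / 2
        lower = [_arc((0.1, 0.3), (0.9, 0.3), reach - 0.004 * abs(k), T=p["T"])
                 for k in range(-1, 2)]
        upper = [_arc((0.1, 0.7), (0.9, 0.7), -(reach - 0.004 * abs(k)), T=p["T"])
                 for k in range(-1, 2)]
        bundles = {"primary": lower, "kissing": upper}
        rois = _endpoint_rois(lower, 0.08)

    else:  # noisy_patch
        defaults = dict(n_fibers=3, a=(0.1, 0.5), b=(0.9, 0.5), bow=0.0,
                        spacing=0.03, box=(0.4, 0.6, 0.4, 0.6),
                        magnitude=1.0, T=200)
        defaults.update(p)
        p = defaults
        fibers = []
        for k in (np.arange(p["n_fibers"]) - (p["n_fibers"] - 1) / 2):
            shift = np.array([0.0, k * p["spacing"]])
            fibers.append(_arc(np.asarray(p["a"]) + shift,
                               np.asarray(p["b"]) + shift, p["bow"], T=p["T"]))
        bundles = {"primary": fibers}
        rois = _endpoint_rois(fibers, 0.08)

    return Scene(kind=kind, bundles=bundles, params=p, seed=seed, rois=rois)


def _endpoint_rois(fibers, radius):
    starts = np.array([f[0] for f in fibers])
    ends = np.array([f[-1] for f in fibers])
    return {
        "A": (starts.mean(axis=0), radius),
        "B": (ends.mean(axis=0), radius),
    }


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _cell_tangent_stats(scene: Scene, grid):
    """Per-cell sum of tangent outer products and per-cell tangent angles."""
    G1, G2 = grid
    outer = np.zeros((G1, G2, 2, 2))
    count = np.zeros((G1, G2))
    angles: dict[tuple[int, int], list[tuple[float, float]]] = {}
    step = 0.25 / max(G1, G2)
    for fiber in scene.all_fibers():
        n_fine = max(int(np.ceil(_polyline_length(fiber) / step)), 8)
        pts = resample_uniform(fiber, n_fine + 1)
        seg = np.diff(pts, axis=0)
        mids = 0.5 * (pts[1:] + pts[:-1])
        lens = np.hypot(seg[:, 0], seg[:, 1])
        u = seg / lens[:, None]
        i = np.clip((mids[:, 0] * G1).astype(int), 0, G1 - 1)
        j = np.clip((mids[:, 1] * G2).astype(int), 0, G2 - 1)
        np.add.at(outer, (i, j), np.einsum("nk,nl->nkl", u, u))
        np.add.at(count, (i, j), 1.0)
        phi = np.arctan2(u[:, 1], u[:, 0])
        for ii, jj, ph in zip(i, j, phi):
            angles.setdefault((int(ii), int(jj)), []).append((float(ph), 1.0))
    return outer, count, angles


def _polyline_length(pts):
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def scene_to_tensor_field(scene: Scene, grid=(20, 20), a_long: float = 1.0,
                          a_perp: float = 0.1, iso_baseline: float = 0.2,
                          smooth_sigma: float = 0.75, noise: float = 0.0) -> TensorField:
    """Rasterize a scene into a smoothed SPD tensor field.

    Occupied cells get ``a_long * mean(u u^T) + a_perp * I`` from the unit
    tangents u of the truth segments in the cell; untouched cells get
    ``iso_baseline * I``; a ``noisy_patch`` box is replaced by random SPD
    tensors; every matrix entry is then Gaussian-smoothed (sigma in cells)
    and eigenvalues re-floored.
    """
    G1, G2 = grid
    outer, count, _ = _cell_tangent_stats(scene, grid)
    M = np.zeros((G1, G2, 2, 2))
    M[..., 0, 0] = iso_baseline
    M[..., 1, 1] = iso_baseline
    occ = count > 0
    mean_outer = np.zeros_like(outer)
    mean_outer[occ] = outer[occ] / count[occ][..., None, None]
    M[occ] = a_long * mean_outer[occ] + a_perp * np.eye(2)

    rng = np.random.default_rng(scene.seed + 77003)
    if scene.kind == "noisy_patch":
        x0, x1, y0, y1 = scene.params["box"]
        xs, ys = TensorField.node_axes(G1, G2)
        in_box = (xs[:, None] >= x0) & (xs[:, None] <= x1) & \
                 (ys[None, :] >= y0) & (ys[None, :] <= y1)
        idx = np.nonzero(in_box)
        mag = scene.params.get("magnitude", 1.0)
        for i, j in zip(*idx):
            th = rng.uniform(0.0, np.pi)
            lam = rng.uniform(0.1, 1.0, 2) * mag
            c, s = np.cos(th), np.sin(th)
            R = np.array([[c, -s], [s, c]])
            M[i, j] = R @ np.diag(lam) @ R.T
    if noise > 0:
        eta = rng.normal(0.0, noise, (G1, G2, 2, 2))
        eta = 0.5 * (eta + np.swapaxes(eta, 2, 3))
        M = M + eta

    for k in range(2):
        for l in range(2):
            M[..., k, l] = gaussian_filter(M[..., k, l], smooth_sigma, mode="nearest")
    M = 0.5 * (M + np.swapaxes(M, 2, 3))
    M = sym_floor_eigvals(M, 1e-3 * a_long)
    return TensorField(M)


def _von_mises_lobe_coeffs(phi: float, kappa: float, n_coeffs: int) -> np.ndarray:
    """Even-Fourier coefficients of the antipodal von Mises density
    f(theta) = exp(kappa cos(2(theta - phi))) / (2 pi I0(kappa))."""
    K = (n_coeffs - 1) // 2
    k = np.arange(1, K + 1)
    ratio = ive(k, kappa) / ive(0, kappa)  # I_k/I_0, overflow-safe
    c = np.empty(n_coeffs)
    c[0] = 1.0 / (2.0 * np.pi)
    c[1::2] = ratio * np.cos(2 * k * phi) / np.pi
    c[2::2] = ratio * np.sin(2 * k * phi) / np.pi
    return c


def scene_to_odf_field(scene: Scene, grid=(20, 20), sharpness: float = 6.0,
                       smooth_sigma: float = 0.75, order: int = 8) -> ODFField:
    """Rasterize a scene into a smoothed ODF field.

    Each occupied cell receives a mixture of antipodally symmetric von
    Mises lobes (in the doubled angle) centered on the tangent angles of
    the truth segments crossing it; crossing cells naturally become
    multi-lobed.  Empty cells are uniform.  Coefficients are Gaussian
    smoothed, then clipped/renormalized by the ODFField constructor.
    """
    G1, G2 = grid
    n_coeffs = 1 + order
    _, count, angles = _cell_tangent_stats(scene, grid)
    coeffs = np.zeros((G1, G2, n_coeffs))
    coeffs[..., 0] = 1.0 / (2.0 * np.pi)
    for (i, j), lst in angles.items():
        acc = np.zeros(n_coeffs)
        wsum = 0.0
        for phi, w in lst:
            acc += w * _von_mises_lobe_coeffs(phi, sharpness, n_coeffs)
            wsum += w
        coeffs[i, j] = acc / wsum
    for c in range(n_coeffs):
        coeffs[..., c] = gaussian_filter(coeffs[..., c], smooth_sigma, mode="nearest")
    return ODFField(coeffs)


def make_training_shapes(scene: Scene, T: int = 100) -> list[Curve]:
    """Training curves for the shape prior from an ``arc_bundle`` scene."""
    if scene.kind != "arc_bundle":
        raise ValueError("training shapes require an 'arc_bundle' scene")
    return [Curve(resample_uniform(f, T)) for f in scene.bundles["primary"]]
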