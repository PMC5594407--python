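"""Deterministic FACT-style streamline tracking (the comparison baseline).

Fibers are grown bidirectionally from a seed by fixed-step Euler
integration along the principal eigenvector of the interpolated tensor,
with sign continuity enforced by the running direction.  Tracking stops at
the domain boundary, when the turning angle between consecutive steps
exceeds a threshold, when local anisotropy falls below a floor, or at the
step cap.  Deliberately simple (no Runge-Kutta, no interpolated stopping):
the baseline is meant to exhibit the classical failure modes at crossings
and noise, not to fix them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import Curve
from .fields import OutOfDomainError, TensorField, sym_eigvals

__all__ = ["StreamlineConfig", "StreamlineError", "anisotropy_index", "fact_track"]


class StreamlineError(RuntimeError):
    """A streamline could not be started or produced a degenerate track."""


@dataclass
class StreamlineConfig:
    """FACT parameters.

    step : integration step in domain units (default 1/4 of a 20-grid cell).
    max_steps : per-direction step cap.
    angle_threshold : max turning angle between consecutive steps, degrees.
    anisotropy_floor : stop when the planar anisotropy index drops below.
    """

    step: float = 0.0125
    max_steps: int = 400
    angle_threshold: float = 45.0
    anisotropy_floor: float = 0.15

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not (0.0 < self.angle_threshold <= 90.0):
            raise ValueError("angle threshold must lie in (0, 90] degrees")


def anisotropy_index(tensor: np.ndarray) -> float:
    """Planar anisotropy (l1 - l2)/sqrt(l1^2 + l2^2) in [0, 1)."""
    t = np.asarray(tensor, float)
    lam1, lam2 = sym_eigvals(t)
    if lam2 <= 0:
        raise ValueError("anisotropy index requires an SPD tensor")
    return float((lam1 - lam2) / np.hypot(lam1, lam2))


def _march(field: TensorField, start: np.ndarray, direction: np.ndarray,
           cfg: StreamlineConfig) -> list[np.ndarray]:
    cos_thresh = np.cos(np.deg2rad(cfg.angle_threshold))
    pts = []
    x = start.copy()
    d = direction.copy()
    for _ in range(cfg.max_steps):
        x_new = x + cfg.step * d
        if x_new.min() < 0.0 or x_new.max() > 1.0:
            break
        M = field.interpolate(x_new)
        if anisotropy_index(M) < cfg.anisotropy_floor:
            break
        d_new = field.principal_direction_many(x_new[None])[0]
        if d_new @ d < 0:
            d_new = -d_new
        if d_new @ d < cos_thresh:
            break
        x, d = x_new, d_new
        pts.append(x.copy())
    return pts


def fact_track(field: TensorField, seed, cfg: StreamlineConfig | None = None) -> Curve:
    """Bidirectional FACT streamline through ``seed``.

    Returns the concatenated polyline as a Curve.  Raises
    :class:`StreamlineError` if the seed sits in a sub-threshold region or
    the resulting track is degenerate (< 3 points).
    """
    cfg = cfg or StreamlineConfig()
    seed = np.asarray(seed, float)
    if seed.min() < 0.0 or seed.max() > 1.0:
        raise OutOfDomainError(f"seed {seed} outside [0,1]^2")
    M0 = field.interpolate(seed)
    if anisotropy_index(M0) < cfg.anisotropy_floor:
        raise StreamlineError("seed lies in a region below the anisotropy floor")
    d0 = field.principal_direction_many(seed[None])[0]
    fwd = _march(field, seed, d0, cfg)
    bwd = _march(field, seed, -d0, cfg)
    pts = bwd[::-1] + [seed] + fwd
    if len(pts) < 3:
        raise StreamlineError("streamline terminated immediately around the seed")
    return Curve(np.array(pts))
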