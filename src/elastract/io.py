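"""Readers and writers for fields, fiber sets and shape models.

Formats
-------
Tensor / ODF fields
    A NIfTI volume of shape (G1, G2, 1, C) holding the per-node channels
    (``Mxx, Mxy, Myy`` for tensor fields; the even Fourier coefficients
    ``a0, a2, b2, ...`` for ODF fields), plus a JSON sidecar ``<stem>.json``
    recording the channel layout and the domain convention.
Fibers
    Delimited text (CSV) with header ``fiber_id,point_index,x,y``;
    coordinates in domain units, full double precision.
Shape models
    A single JSON document: scalar metadata in the header, arrays stored as
    base64-encoded little-endian float64 blocks (text-safe, lossless).
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import Curve
from .fields import ODFField, TensorField
from .shape import ShapeModel

__all__ = [
    "write_tensor_field", "write_odf_field", "read_field",
    "write_fibers", "read_fibers",
    "write_shape_model", "read_shape_model",
]

_FORMAT_VERSION = 1


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def _write_volume(path, channels: np.ndarray, meta: dict) -> None:
    vol = channels[:, :, None, :]  # (G1, G2, 1, C)
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))
    meta = dict(meta, version=_FORMAT_VERSION, domain="[0,1]^2",
                grid_convention="node-centered: node (i,j) at ((i+.5)/G1,(j+.5)/G2)")
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def write_tensor_field(path, field: TensorField) -> None:
    """Write a tensor field as a 3-channel NIfTI volume + JSON sidecar."""
    ch = np.stack(
        [field.M[..., 0, 0], field.M[..., 0, 1], field.M[..., 1, 1]], axis=-1
    )
    _write_volume(path, ch, {"kind": "tensor2", "channels": ["Mxx", "Mxy", "Myy"],
                             "eig_floor": field.eig_floor})


def write_odf_field(path, field: ODFField) -> None:
    """Write an ODF field as an n-channel NIfTI volume + JSON sidecar."""
    K = (field.n_coeffs - 1) // 2
    names = ["a0"] + [f"{ab}{2 * k}" for k in range(1, K + 1) for ab in ("a", "b")]
    _write_volume(path, field.coeffs, {"kind": "odf_fourier", "channels": names})


def read_field(path):
    """Read a tensor or ODF field written by this module.

    The sidecar's ``kind`` decides the returned type; invariants (symmetry,
    positive definiteness, normalization) are re-validated on load and a
    violation raises ``ValueError`` naming the offending node.
    """
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim != 4 or vol.shape[2] != 1:
        raise ValueError(f"expected a (G1, G2, 1, C) volume, got {vol.shape}")
    ch = vol[:, :, 0, :]
    kind = meta.get("kind")
    if kind == "tensor2":
        if ch.shape[-1] != 3:
            raise ValueError("tensor2 field requires 3 channels (Mxx, Mxy, Myy)")
        M = np.empty(ch.shape[:2] + (2, 2))
        M[..., 0, 0] = ch[..., 0]
        M[..., 0, 1] = M[..., 1, 0] = ch[..., 1]
        M[..., 1, 1] = ch[..., 2]
        return TensorField(M, eig_floor=meta.get("eig_floor"))
    if kind == "odf_fourier":
        return ODFField(ch)
    raise ValueError(f"unknown field kind {kind!r} in {sidecar}")


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------

def write_fibers(path, fibers) -> None:
    """Write a list of curves to the delimited fiber format."""
    rows = []
    for fid, fib in enumerate(fibers):
        pts = fib.points if isinstance(fib, Curve) else np.asarray(fib, float)
        for idx, (x, y) in enumerate(pts):
            rows.append((fid, idx, x, y))
    df = pd.DataFrame(rows, columns=["fiber_id", "point_index", "x", "y"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_fibers(path) -> list[Curve]:
    """Read a fiber file back into a list of curves, order preserved."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["fiber_id", "point_index", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"fiber file {path} lacks column(s) {missing}")
    out = []
    for fid, grp in df.groupby("fiber_id", sort=True):
        grp = grp.sort_values("point_index")
        try:
            out.append(Curve(grp[["x", "y"]].to_numpy()))
        except ValueError as exc:
            raise ValueError(f"fiber {fid} in {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# shape models
# ---------------------------------------------------------------------------

def _encode(arr: np.ndarray) -> dict:
    a = np.ascontiguousarray(arr, dtype="<f8")
    return {"shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _decode(block: dict) -> np.ndarray:
    raw = base64.b64decode(block["data"])
    return np.frombuffer(raw, dtype="<f8").reshape(block["shape"]).copy()


def write_shape_model(path, model: ShapeModel, seed=None) -> None:
    """Serialize a fitted shape model (JSON header + base64 arrays)."""
    doc = {
        "format": "elastract-shape-model",
        "version": _FORMAT_VERSION,
        "T": model.T,
        "m": model.m,
        "delta": model.delta,
        "seed": seed,
        "meta": {k: v for k, v in model.meta.items()
                 if isinstance(v, (int, float, str, bool, type(None)))},
        "mean": _encode(model.mean),
        "components": _encode(model.components),
        "singular_values": _encode(model.singular_values),
    }
    Path(path).write_text(json.dumps(doc))


def read_shape_model(path) -> ShapeModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "elastract-shape-model":
        raise ValueError(f"{path} is not a shape-model file")
    model = ShapeModel(
        mean=_decode(doc["mean"]),
        components=_decode(doc["components"]),
        singular_values=_decode(doc["singular_values"]),
        delta=float(doc["delta"]),
        meta=dict(doc.get("meta") or {}),
    )
    model.validate()
    return model
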