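"""Anatomical reference frame: Henle's spine, zygoma line, rigid registration.

The thickness map is transferred to the patient with a ruler, so it carries
two landmarks the surgeon can palpate: the Henle's spine (HS, a bony
prominence at the posterosuperior margin of the ear canal) and the
posteriorly prolonged line of the zygoma (ZL).  On the rendered map the HS
shows as concentric isodistance rings and the ZL as a line; port positions
are reported in a 2D (posterior, cranial) chart with the HS at the origin
and the ZL direction as the x-axis.

Two points on a line do not fix the "cranial" axis in 3D, so the frame
carries a third reference point above the ZL; cranial is the component of
(point - HS) orthogonal to the ZL direction, signed positive toward that
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError

__all__ = [
    "LandmarkFrame",
    "RigidTransform",
    "build_frame_overlays",
    "hs_zl_coordinates",
    "measure_port_position",
    "rigid_landmark_register",
    "read_landmarks",
    "write_landmarks",
    "write_position_records",
]


@dataclass
class LandmarkFrame:
    """HS point + ZL line (+ cranial reference) in world mm.

    ``zl_a -> zl_b`` is oriented posteriorly, so the posterior coordinate
    grows from ``zl_a`` toward ``zl_b``.  ``sphere_interval`` is the spacing
    of the HS isodistance rings (5 mm default; display only).
    """

    hs: np.ndarray
    zl_a: np.ndarray
    zl_b: np.ndarray
    cranial_ref: np.ndarray
    sphere_interval: float = 5.0
    side: str = "right"

    def __post_init__(self) -> None:
        for name in ("hs", "zl_a", "zl_b", "cranial_ref"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.isfinite(v).all():
                raise ValidationError(f"landmark {name} must be a finite 3-vector")
            setattr(self, name, v)
        if np.allclose(self.zl_a, self.zl_b):
            raise ValidationError("zl_a and zl_b must differ (they define the zygoma line)")
        if self.sphere_interval <= 0:
            raise ValidationError("sphere_interval must be > 0")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")

    @property
    def zl_direction(self) -> np.ndarray:
        u = self.zl_b - self.zl_a
        return u / np.linalg.norm(u)

    @property
    def cranial_direction(self) -> np.ndarray:
        u = self.zl_direction
        c = (self.cranial_ref - self.hs) - np.dot(self.cranial_ref - self.hs, u) * u
        n = np.linalg.norm(c)
        if n < 1e-9:
            raise ValidationError("degenerate frame: cranial reference lies on the ZL axis")
        return c / n


@dataclass
class RigidTransform:
    """Proper rigid motion (rotation + translation, no scale, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (determinant +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def build_frame_overlays(
    frame: LandmarkFrame,
    mesh: trimesh.Trimesh,
    ring_half_width: float = 0.3,
    line_half_width: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-vertex overlay channels for the rendered map.

    ``hs_ring`` flags vertices within ``ring_half_width`` mm of an HS
    isodistance sphere (multiples of ``sphere_interval``); ``zl_line`` flags
    vertices within ``line_half_width`` mm of the infinite prolonged zygoma
    line.  Both are uint8 {0, 1} channels attachable to the mesh export.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    d_hs = np.linalg.norm(v - frame.hs, axis=1)
    r = np.mod(d_hs, frame.sphere_interval)
    hs_ring = ((r < ring_half_width) | (frame.sphere_interval - r < ring_half_width))

    u = frame.zl_direction
    w = v - frame.zl_a
    d_line = np.linalg.norm(w - np.outer(w @ u, u), axis=1)
    zl_line = d_line < line_half_width
    return {"hs_ring": hs_ring.astype(np.uint8), "zl_line": zl_line.astype(np.uint8)}


def hs_zl_coordinates(point: np.ndarray, frame: LandmarkFrame) -> tuple[float, float]:
    """(posterior, cranial) chart coordinates of a world point, in mm.

    The HS maps to (0, 0); the x-axis is the ZL direction (posterior
    positive), the y-axis the in-plane cranial direction.  Because both axes
    are defined intrinsically per side, left and right cases chart into the
    same quadrant convention and Fig-style plots superpose without an
    explicit mirror.
    """
    p = np.asarray(point, dtype=float)
    if p.shape != (3,) or not np.isfinite(p).all():
        raise ValidationError("point must be a finite 3-vector")
    w = p - frame.hs
    posterior = float(w @ frame.zl_direction)
    cranial = float(w @ frame.cranial_direction)
    return posterior, cranial


def measure_port_position(port_center: np.ndarray, frame: LandmarkFrame) -> dict:
    """Record the implanted port center in the (posterior, cranial) chart."""
    posterior, cranial = hs_zl_coordinates(port_center, frame)
    return {"posterior_mm": posterior, "cranial_mm": cranial, "side": frame.side}


def rigid_landmark_register(source: np.ndarray, target: np.ndarray):
    """Least-squares rigid alignment of matched landmark sets (Kabsch).

    Returns ``(transform, residuals)`` where ``residuals`` are per-landmark
    fiducial registration errors in mm.  The determinant is corrected so the
    result is always a proper rotation, never a reflection.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValidationError("source and target must be matched (n, 3) arrays")
    if len(src) < 3:
        raise ValidationError("at least 3 landmark pairs required")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    src_c, tgt_c = src - cs, tgt - ct
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise ValidationError("landmarks are collinear; rotation is not determined")
    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    transform = RigidTransform(rotation=R, translation=t)
    residuals = np.linalg.norm(transform.apply(src) - tgt, axis=1)
    return transform, residuals


def write_position_records(records: list[dict], path: str | Path) -> Path:
    """Write port-position chart records as CSV (id, posterior_mm, cranial_mm)."""
    path = Path(path)
    lines = ["experiment,posterior_mm,cranial_mm,side"]
    for rec in records:
        lines.append(f"{rec.get('experiment', '')},{rec['posterior_mm']:.3f},"
                     f"{rec['cranial_mm']:.3f},{rec.get('side', '')}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_landmarks(frame: LandmarkFrame, path: str | Path) -> Path:
    """Write the frame as a JSON sidecar ({name: [x, y, z] mm})."""
    path = Path(path)
    payload = {
        "hs": frame.hs.tolist(),
        "zl_a": frame.zl_a.tolist(),
        "zl_b": frame.zl_b.tolist(),
        "cranial_ref": frame.cranial_ref.tolist(),
        "sphere_interval": frame.sphere_interval,
        "side": frame.side,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_landmarks(path: str | Path) -> LandmarkFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark sidecar not found: {path}")
    raw = json.loads(path.read_text())
    try:
        return LandmarkFrame(
            hs=raw["hs"], zl_a=raw["zl_a"], zl_b=raw["zl_b"],
            cranial_ref=raw["cranial_ref"],
            sphere_interval=raw.get("sphere_interval", 5.0),
            side=raw.get("side", "right"),
        )
    except KeyError as exc:
        raise ValidationError(f"landmark sidecar {path} missing key {exc}") from exc
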