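"""Implant-site safety evaluation against the thickness field.

The port needs a drilled cavity of roughly 10 mm x 5 mm, at most 6 mm deep,
with the deepest drilling confined to bone thicker than 6 mm; elsewhere only
the 3-4 mm bedding is removed.  A candidate site passes when

1. thickness at the deepest-drilling point is *strictly* greater than the
   maximum depth (evaluated on raw thickness, never on band labels),
2. thickness covers the required depth everywhere under the footprint
   (margin >= 0), and
3. the contact patch is flat enough for a stable fixation (RMS deviation
   from its best-fit plane below a tolerance).

The footprint is laid on the tangent plane of the surface at the site —
valid because the footprint (~10 mm) is small against skull curvature —
and each sample is snapped to the nearest external vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .surface import SurfacePartition
from .thickness import ThicknessField

__all__ = ["PortFootprint", "SiteEvaluation", "evaluate_site", "scan_candidate_sites"]


@dataclass
class PortFootprint:
    """Geometry and drilling-depth profile of the port cavity.

    ``max_depth_mm`` applies at ``deepest_point_mm`` (an in-footprint offset,
    default the center); everywhere else only ``bedding_depth_mm`` is
    drilled.  ``flatness_tol_mm`` bounds the RMS plane deviation of the
    contact patch; there is no clinically established value, so it is a
    plain parameter.
    """

    length_mm: float = 10.0
    width_mm: float = 5.0
    max_depth_mm: float = 6.0
    bedding_depth_mm: float = 3.5
    deepest_point_mm: tuple[float, float] = (0.0, 0.0)
    flatness_tol_mm: float = 1.0
    sample_step_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValidationError("footprint length and width must be > 0")
        if self.bedding_depth_mm > self.max_depth_mm:
            raise ValidationError("depth profile must not exceed the overall max depth")
        dx, dy = self.deepest_point_mm
        if abs(dx) > self.length_mm / 2 or abs(dy) > self.width_mm / 2:
            raise ValidationError("deepest point must lie inside the footprint")
        if self.sample_step_mm <= 0 or self.flatness_tol_mm < 0:
            raise ValidationError("sample step must be > 0 and flatness tolerance >= 0")

    def sample_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """(offsets, required_depths): in-plane sample grid plus the deepest
        point, with the drilling depth required at each sample."""
        xs = np.arange(-self.length_mm / 2, self.length_mm / 2 + 1e-9, self.sample_step_mm)
        ys = np.arange(-self.width_mm / 2, self.width_mm / 2 + 1e-9, self.sample_step_mm)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        offsets = np.column_stack([gx.ravel(), gy.ravel()])
        offsets = np.vstack([offsets, np.asarray(self.deepest_point_mm)])
        depths = np.full(len(offsets), self.bedding_depth_mm)
        depths[-1] = self.max_depth_mm
        return offsets, depths


@dataclass
class SiteEvaluation:
    """Verdict and per-criterion detail for one candidate site."""

    center: np.ndarray
    orientation_deg: float
    verdict: str  # "pass" | "exposure-risk" | "off-surface"
    thickness_at_deepest_mm: float = float("nan")
    min_margin_mm: float = float("nan")
    flatness_rms_mm: float = float("nan")
    criteria: dict = field(default_factory=dict)
    vertex_index: int = -1

    def as_record(self) -> dict:
        def clean(x):
            return None if isinstance(x, float) and np.isnan(x) else x
        return {k: clean(v) for k, v in self._record().items()}

    def _record(self) -> dict:
        return {
            "x": float(self.center[0]), "y": float(self.center[1]), "z": float(self.center[2]),
            "orientation_deg": self.orientation_deg, "verdict": self.verdict,
            "thickness_at_deepest_mm": self.thickness_at_deepest_mm,
            "min_margin_mm": self.min_margin_mm, "flatness_rms_mm": self.flatness_rms_mm,
            **{f"crit_{k}": v for k, v in self.criteria.items()},
        }


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(n, e1)


def evaluate_site(
    partition: SurfacePartition,
    fld: ThicknessField,
    center: np.ndarray,
    orientation_deg: float = 0.0,
    footprint: PortFootprint | None = None,
    off_mesh_mm: float = 2.0,
    tree: cKDTree | None = None,
) -> SiteEvaluation:
    """Evaluate one candidate port position on the external surface."""
    footprint = footprint or PortFootprint()
    ext = partition.external
    if len(fld.values) != len(ext.vertices):
        raise ValidationError("thickness field does not match the partition")
    center = np.asarray(center, dtype=float)
    tree = tree or cKDTree(ext.vertices)

    d0, i0 = tree.query(center)
    if d0 > off_mesh_mm:
        return SiteEvaluation(center=center, orientation_deg=orientation_deg,
                              verdict="off-surface", vertex_index=int(i0))
    anchor = np.asarray(ext.vertices[i0])
    # average the normal over the footprint-scale neighborhood: single-vertex
    # normals carry voxelization staircase noise of up to ~45 degrees
    nbr = tree.query_ball_point(anchor, max(footprint.length_mm, footprint.width_mm) / 2)
    normal = np.asarray(ext.vertex_normals[nbr]).mean(axis=0)
    if np.linalg.norm(normal) < 1e-9:
        normal = np.asarray(ext.vertex_normals[i0])
    e1, e2 = _tangent_basis(normal)
    th = np.deg2rad(orientation_deg)
    u = np.cos(th) * e1 + np.sin(th) * e2
    v = -np.sin(th) * e1 + np.cos(th) * e2

    offsets, depths = footprint.sample_offsets()
    samples = anchor + offsets[:, :1] * u + offsets[:, 1:] * v
    d, idx = tree.query(samples)
    if (d > off_mesh_mm).any():
        return SiteEvaluation(center=center, orientation_deg=orientation_deg,
                              verdict="off-surface", vertex_index=int(i0))

    thickness = fld.values[idx]
    t_deepest = float(thickness[-1])
    margins = thickness - depths
    min_margin = float(margins.min())

    patch = ext.vertices[idx]
    centered = patch - patch.mean(axis=0)
    # flatness: RMS distance of snapped contact points to their best-fit plane
    *_, vt = np.linalg.svd(centered, full_matrices=False)
    flatness = float(np.sqrt(np.mean((centered @ vt[-1]) ** 2)))

    criteria = {
        "deepest_covered": t_deepest > footprint.max_depth_mm,
        "margin_nonnegative": min_margin >= 0.0,
        "flat_enough": flatness <= footprint.flatness_tol_mm,
    }
    verdict = "pass" if all(criteria.values()) else "exposure-risk"
    return SiteEvaluation(center=center, orientation_deg=orientation_deg, verdict=verdict,
                          thickness_at_deepest_mm=t_deepest, min_margin_mm=min_margin,
                          flatness_rms_mm=flatness, criteria=criteria, vertex_index=int(i0))


def scan_candidate_sites(
    partition: SurfacePartition,
    fld: ThicknessField,
    footprint: PortFootprint | None = None,
    frame=None,
    keep_out_center: np.ndarray | None = None,
    keep_out_radius_mm: float = 0.0,
    stride: int = 25,
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> list[SiteEvaluation]:
    """Grid-scan the external surface for passing sites, best first.

    Every ``stride``-th external vertex is evaluated at each orientation;
    passing sites are ranked by (min margin desc, flatness asc, vertex
    index asc) — deterministic for identical inputs.  An empty list is a
    meaningful outcome: nowhere is the bone thick enough, which is the
    patient-exclusion signal.  ``keep_out_center``/``radius`` excludes a
    region (e.g. around the auricle); ``frame`` is carried for reporting
    chart coordinates of the candidates.
    """
    footprint = footprint or PortFootprint()
    ext = partition.external
    tree = cKDTree(ext.vertices)
    passing: list[SiteEvaluation] = []
    for vi in range(0, len(ext.vertices), max(1, stride)):
        center = np.asarray(ext.vertices[vi])
        if keep_out_center is not None and keep_out_radius_mm > 0:
            if np.linalg.norm(center - np.asarray(keep_out_center)) <= keep_out_radius_mm:
                continue
        best = None
        for ori in orientations_deg:
            ev = evaluate_site(partition, fld, center, ori, footprint, tree=tree)
            ev.vertex_index = vi
            if ev.verdict == "pass" and (best is None or ev.min_margin_mm > best.min_margin_mm):
                best = ev
        if best is not None:
            passing.append(best)
    passing.sort(key=lambda e: (-e.min_margin_mm, e.flatness_rms_mm, e.vertex_index))
    return passing
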