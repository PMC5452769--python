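"""Synthetic label-mask phantoms with known ground truth.

Every stage of the pipeline is validated without any scan data using three
phantoms that emulate the anatomy the map is built for:

* ``shell`` — a spherical cortical shell of exactly known thickness;
* ``slab`` — a region-of-interest crop (open at the crop faces) with a
  designated skin-side face, optionally tilted to separate closest-point
  thickness from ray thickness;
* ``temporal`` — a curved plate of smoothly varying thickness (3-9 mm by
  default) with sealed air cells that must be absorbed into bone, an open
  cavity reaching interior air (middle-ear analogue) that must stay
  outside, and an inner-surface groove (sigmoid-sinus analogue).

Ground truth for the temporal phantom is computed by a voxel Euclidean
distance transform to the interior air — deliberately a different algorithm
from the mesh pipeline, so agreement between the two is evidence rather
than tautology.  The default 0.4 mm spacing matches the clinical CBCT
protocol, so voxelization tolerances transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .frame import LandmarkFrame
from .segmentation import SegmentationPolicy, fill_enclosed_cavities
from .volume import LabelMask, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_shell_phantom",
    "make_slab_phantom",
    "make_temporal_phantom",
]


@dataclass
class PhantomSpec:
    """Parameters of the temporal-like phantom."""

    kind: str = "temporal"
    spacing: float = 0.4
    seed: int = 0
    lateral_mm: float = 40.0
    curvature_radius_mm: float = 120.0
    thickness_range_mm: tuple[float, float] = (3.0, 9.0)
    n_air_cells: int = 10
    air_cell_radius_mm: tuple[float, float] = (0.5, 1.2)
    groove_radius_mm: float = 2.0
    middle_ear_radius_mm: float = 3.5

    def __post_init__(self) -> None:
        tmin, tmax = self.thickness_range_mm
        if self.spacing <= 0 or tmin <= 0 or tmax <= tmin or self.lateral_mm <= 0:
            raise ValidationError("phantom lengths must be positive and tmax > tmin")
        if tmin - self.groove_radius_mm < 2 * self.spacing:
            raise ValidationError(
                "groove would perforate the shell (tmin - groove radius < 2 voxels)"
            )


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom.

    ``thickness_at(points)`` answers the true wall thickness (mm) at any
    external-surface query point; for analytic phantoms it is a constant,
    for the temporal phantom it interpolates a distance-transform grid.
    """

    frame: LandmarkFrame
    exterior_faces: tuple[str, ...]
    constant_thickness_mm: float | None = None
    truth_fn: Callable[[np.ndarray], np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def thickness_at(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.constant_thickness_mm is not None:
            return np.full(len(points), self.constant_thickness_mm)
        return self.truth_fn(points)


def _grid(extent_mm: np.ndarray, spacing: float):
    """Voxel-center coordinate grid covering +/- extent per axis."""
    ns = (np.ceil(2 * extent_mm / spacing)).astype(int) + 1
    origin = -(ns - 1) / 2.0 * spacing
    axes = [origin[a] + spacing * np.arange(ns[a]) for a in range(3)]
    return np.meshgrid(*axes, indexing="ij"), tuple(origin)


def make_shell_phantom(outer_r: float = 40.0, inner_r: float = 34.0,
                       spacing: float = 0.4) -> tuple[LabelMask, PhantomTruth]:
    """Voxelized spherical shell: true thickness is exactly ``outer_r - inner_r``."""
    if not 0 < inner_r < outer_r or spacing <= 0:
        raise ValidationError("need 0 < inner_r < outer_r and spacing > 0")
    (x, y, z), origin = _grid(np.full(3, outer_r + 2 * spacing), spacing)
    r = np.sqrt(x * x + y * y + z * z)
    mask_data = ((r >= inner_r) & (r <= outer_r)).astype(np.uint8)
    prov = {"phantom": "shell", "outer_r": outer_r, "inner_r": inner_r}
    if outer_r - inner_r < 2 * spacing:
        prov["thin_shell"] = True  # below the sampling limit: < 2 voxels thick
    mask = LabelMask(data=mask_data, spacing=(spacing,) * 3, origin=origin, provenance=prov)
    hs = np.array([outer_r, 0.0, 0.0])
    frame = LandmarkFrame(hs=hs, zl_a=hs, zl_b=hs + [0.0, 15.0, 0.0],
                          cranial_ref=[0.0, 0.0, outer_r])
    truth = PhantomTruth(frame=frame, exterior_faces=("-x", "+x", "-y", "+y", "-z", "+z"),
                         constant_thickness_mm=outer_r - inner_r, metadata=dict(prov))
    return mask, truth


def make_slab_phantom(thickness: float = 8.0, lateral: float = 40.0, spacing: float = 0.4,
                      tilt_deg: float = 0.0) -> tuple[LabelMask, PhantomTruth]:
    """ROI-cropped slab, open at the crop faces, skin side designated "+z".

    With a tilt, the perpendicular (closest-point) thickness is still the
    nominal value — not thickness / cos(tilt) as a vertical ray would give.
    """
    if thickness <= 0 or lateral <= 0 or spacing <= 0:
        raise ValidationError("slab thickness, lateral size and spacing must be > 0")
    th = np.deg2rad(tilt_deg)
    zspan = thickness / np.cos(th) + lateral * abs(np.tan(th)) / 2 + 6 * spacing
    nxy = int(np.ceil(lateral / spacing)) + 1
    nz = int(np.ceil(2 * zspan / spacing)) + 1
    origin = (-(nxy - 1) / 2 * spacing, -(nxy - 1) / 2 * spacing, -(nz - 1) / 2 * spacing)
    ax = origin[0] + spacing * np.arange(nxy)
    az = origin[2] + spacing * np.arange(nz)
    x, _, z = np.meshgrid(ax, ax, az, indexing="ij")
    d = z * np.cos(th) - x * np.sin(th)  # signed distance along the slab normal
    mask_data = ((d >= -thickness / 2) & (d <= thickness / 2)).astype(np.uint8)
    prov = {"phantom": "slab", "thickness": thickness, "tilt_deg": tilt_deg}
    mask = LabelMask(data=mask_data, spacing=(spacing,) * 3, origin=origin, provenance=prov)

    n = np.array([-np.sin(th), 0.0, np.cos(th)])
    in_plane_x = np.array([np.cos(th), 0.0, np.sin(th)])
    hs = n * thickness / 2  # on the top (skin-side) surface
    frame = LandmarkFrame(hs=hs, zl_a=hs, zl_b=hs + 15 * in_plane_x,
                          cranial_ref=hs + [0.0, 10.0, 0.0])
    truth = PhantomTruth(frame=frame, exterior_faces=("+z",),
                         constant_thickness_mm=thickness, metadata=dict(prov))
    return mask, truth


def make_temporal_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[LabelMask, PhantomTruth, LandmarkFrame]:
    """Curved temporal-bone-like plate with air cells, open cavity and groove.

    Returns ``(mask, truth, frame)``; the frame doubles as the landmark
    sidecar content.  Deterministic for a fixed ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h = spec.spacing
    L = spec.lateral_mm
    tmin, tmax = spec.thickness_range_mm
    rc = spec.curvature_radius_mm

    ztop = tmax + 3.0
    zbot = -(spec.middle_ear_radius_mm * 2 + 3.0)
    nxy = int(np.ceil(L / h)) + 1
    nz = int(np.ceil((ztop + 4 * h - zbot) / h)) + 1
    origin = (-(nxy - 1) / 2 * h, -(nxy - 1) / 2 * h, zbot)
    ax = origin[0] + h * np.arange(nxy)
    az = origin[2] + h * np.arange(nz)
    x, y, z = np.meshgrid(ax, ax, az, indexing="ij")

    # outer surface: gentle spherical dome; thickness: smooth random field
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    k1, k2 = rng.uniform(1.2, 1.8, size=2) * (2 * np.pi / L)
    smooth = 0.5 + 0.5 * np.sin(k1 * x + p1) * np.cos(k2 * y + p2)
    z_out = ztop - tmax - (x * x + y * y) / (2 * rc) + tmax * 0.35
    t_field = tmin + (tmax - tmin) * smooth
    z_in = z_out - t_field
    mask_data = (z <= z_out) & (z >= z_in)

    # sealed air cells in the mid-wall (must later be absorbed into bone)
    rmin, rmax_cell = spec.air_cell_radius_mm
    placed = 0
    guard = 0
    cell_centers: list[tuple[float, float]] = []
    min_sep = 2 * rmax_cell + 3 * h  # sealed cells must stay disjoint
    while placed < spec.n_air_cells and guard < 50 * spec.n_air_cells:
        guard += 1
        cx, cy = rng.uniform(-L / 2 + 4, L / 2 - 4, size=2)
        if abs(cx) < spec.groove_radius_mm + 2:  # keep clear of the groove at x=0
            continue
        if any(np.hypot(cx - px, cy - py) < min_sep for px, py in cell_centers):
            continue
        i = int(round((cx - origin[0]) / h))
        j = int(round((cy - origin[1]) / h))
        t_loc = t_field[i, j, 0]
        r_cell = min(rng.uniform(rmin, rmax_cell), 0.3 * t_loc)
        if r_cell < 1.5 * h:
            continue
        cz = z_out[i, j, 0] - 0.5 * t_loc
        bubble = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r_cell ** 2
        mask_data &= ~bubble
        cell_centers.append((cx, cy))
        placed += 1

    # middle-ear analogue: pocket bulging into the wall, open to interior air
    me_x, me_y = L / 4, -L / 4
    i = int(round((me_x - origin[0]) / h))
    j = int(round((me_y - origin[1]) / h))
    me_z = z_in[i, j, 0] - 0.3 * spec.middle_ear_radius_mm
    pocket = (x - me_x) ** 2 + (y - me_y) ** 2 + (z - me_z) ** 2 <= spec.middle_ear_radius_mm ** 2
    mask_data &= ~pocket

    # sigmoid-sinus analogue: groove carved into the inner surface along y at x=0
    groove = (x ** 2 + (z - z_in) ** 2) <= spec.groove_radius_mm ** 2
    mask_data &= ~groove

    prov = {"phantom": "temporal", "seed": spec.seed, "spacing": h,
            "thickness_range_mm": list(spec.thickness_range_mm),
            "n_air_cells": placed}
    mask = LabelMask(data=mask_data.astype(np.uint8), spacing=(h,) * 3,
                     origin=origin, provenance=prov)

    hs_x = -L / 2 + 6.0
    i = int(round((hs_x - origin[0]) / h))
    j = int(round((0.0 - origin[1]) / h))
    hs = np.array([hs_x, 0.0, z_out[i, j, 0]])
    frame = LandmarkFrame(hs=hs, zl_a=hs, zl_b=hs + [15.0, 0.0, 0.0],
                          cranial_ref=[0.0, 0.0, ztop + 5.0])

    truth = PhantomTruth(frame=frame, exterior_faces=("+z",),
                         truth_fn=_edt_truth(mask), metadata=dict(prov))
    return mask, truth, frame


def _edt_truth(mask: LabelMask) -> Callable[[np.ndarray], np.ndarray]:
    """Distance-transform thickness oracle, independent of the mesh pipeline.

    Sealed air cells are absorbed (they are "inside"); interior air is every
    background component not reachable from the "+z" (skin) face.  The
    returned function linearly interpolates, at world query points, the
    Euclidean distance to interior air minus half a voxel (the isosurface
    sits halfway between bone and air voxel centers).
    """
    filled = fill_enclosed_cavities(mask, SegmentationPolicy(fill_diameter_mm=5.0))
    bg = ~filled.data.astype(bool)
    labels, _ = ndimage.label(bg, structure=np.ones((3, 3, 3), bool))
    skin_side = set(np.unique(labels[:, :, -1])) - {0}
    interior_air = bg & ~np.isin(labels, list(skin_side))
    edt = ndimage.distance_transform_edt(~interior_air, sampling=filled.spacing)
    half_voxel = 0.5 * min(filled.spacing)

    def thickness_at(points: np.ndarray) -> np.ndarray:
        idx = filled.world_to_index(np.atleast_2d(points))
        vals = ndimage.map_coordinates(edt, idx.T, order=1, mode="nearest")
        return np.maximum(vals - half_voxel, 0.0)

    return thickness_at


def as_intensity_volume(mask: LabelMask, bone_value: float = 1200.0,
                        air_value: float = -400.0) -> Volume:
    """Render a label phantom as a CBCT-like two-level intensity volume."""
    data = np.where(mask.data > 0, bone_value, air_value).astype(np.float32)
    return Volume(data=data, spacing=mask.spacing, origin=mask.origin,
                  orientation=mask.orientation)
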