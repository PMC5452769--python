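"""Isosurface extraction and the external / internal surface split.

The thickness map needs two sheets: the *external* surface (outer skull,
"surface A") and the *internal* surface facing dura, sigmoid sinus and
facial nerve ("surface B").  Extraction is a marching-cubes isosurface at
level 0.5 of the binary mask; the split classifies each mesh component by
which air region its outward normals point into — the exterior air touching
the user-designated "outside" faces of the (cropped) volume, or enclosed /
cranial-side air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import ProcessingError, ValidationError
from .segmentation import _STRUCT_BG
from .volume import LabelMask

__all__ = ["SurfacePartition", "extract_surface", "partition_surfaces", "ALL_FACES"]

#: face designators: axis letter with sign, e.g. "+z" is the high-z volume face
ALL_FACES = ("-x", "+x", "-y", "+y", "-z", "+z")

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class SurfacePartition:
    """External (skull) and internal (dura-facing) triangle meshes.

    ``unclassified`` holds components the reachability classifier could not
    assign with enough of a majority; they are kept out of the thickness
    computation rather than corrupting it.
    """

    external: trimesh.Trimesh
    internal: trimesh.Trimesh
    unclassified: trimesh.Trimesh | None = None

    def __post_init__(self) -> None:
        if self.external is None or len(self.external.vertices) == 0:
            raise ProcessingError("partition produced an empty external surface")


def _as_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _clean(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices (1e-6 mm) and drop degenerate triangles."""
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    return mesh


def _face_components(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Connected components as arrays of face indices (edge adjacency)."""
    return trimesh.graph.connected_components(
        mesh.face_adjacency, min_len=0, nodes=np.arange(len(mesh.faces))
    )


def extract_surface(mask: LabelMask, min_triangles: int = 10) -> trimesh.Trimesh:
    """Marching-cubes isosurface of the binary mask, in world mm.

    The mesh is watertight wherever the foreground does not touch the volume
    boundary; components with fewer than ``min_triangles`` faces (speckle)
    are removed.  Face winding is oriented so normals point from bone into
    air, checked against the mask.
    """
    if not mask.data.any():
        raise ValidationError("cannot extract a surface from an empty mask")
    verts, faces, _, _ = measure.marching_cubes(
        mask.data.astype(np.float32), level=0.5, spacing=mask.spacing
    )
    verts = verts + np.asarray(mask.origin)
    mesh = _clean(_as_mesh(verts, faces))

    comps = _face_components(mesh)
    keep = np.concatenate([c for c in comps if len(c) >= min_triangles]) if comps else []
    if len(keep) == 0:
        raise ProcessingError("all surface components below the triangle-count floor")
    mesh.update_faces(np.sort(keep))
    mesh.remove_unreferenced_vertices()

    # rebuild on fresh buffers (trimesh caches go stale after update_faces),
    # then orient normals bone -> air by probing the mask half a voxel out
    mesh = _as_mesh(mesh.vertices.copy(), mesh.faces.copy())
    h = 0.5 * min(mask.spacing)
    probe = mesh.triangles_center + mesh.face_normals * h
    inside = _sample_mask(mask, probe)
    if np.mean(inside) > 0.5:
        mesh = _as_mesh(mesh.vertices.copy(), np.ascontiguousarray(mesh.faces[:, ::-1]))
    return mesh


def _sample_mask(mask: LabelMask, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel mask values at world points; points off-grid count as 0."""
    idx = np.rint(mask.world_to_index(points)).astype(int)
    shape = np.array(mask.shape)
    ok = (idx >= 0).all(axis=1) & (idx < shape).all(axis=1)
    vals = np.zeros(len(points), dtype=np.uint8)
    sel = idx[ok]
    vals[ok] = mask.data[sel[:, 0], sel[:, 1], sel[:, 2]]
    return vals


def _background_regions(mask: LabelMask, exterior_faces: tuple[str, ...]):
    """Label background (26-conn); return labels + the set reachable from
    the designated exterior faces."""
    labels, _ = ndimage.label(~mask.data.astype(bool), structure=_STRUCT_BG)
    exterior: set[int] = set()
    for face in exterior_faces:
        sign, axis = face[0], face[1]
        if sign not in "+-" or axis not in _AXIS:
            raise ValidationError(f"bad face designator {face!r}; use e.g. '+z'")
        sl = [slice(None)] * 3
        sl[_AXIS[axis]] = -1 if sign == "+" else 0
        exterior.update(np.unique(labels[tuple(sl)]))
    exterior.discard(0)
    return labels, exterior


def partition_surfaces(
    mesh: trimesh.Trimesh,
    mask: LabelMask,
    exterior_faces: tuple[str, ...] = ALL_FACES,
    majority: float = 0.8,
) -> SurfacePartition:
    """Split a surface into external / internal sheets by air reachability.

    For each connected component, points half a voxel along the outward
    normals are sampled in the background label image.  Components whose
    samples fall predominantly (>= ``majority``) in the exterior air — the
    background reachable from ``exterior_faces`` — become external; those
    facing enclosed or non-designated air become internal; mixed components
    are returned as unclassified.

    ``exterior_faces`` exists because real temporal-bone masks are crops:
    the cranial-cavity background also touches the crop boundary, and only
    the user knows which faces look at skin.  The default treats every face
    as exterior, which is right for closed phantoms.
    """
    comps = _face_components(mesh)
    if len(comps) == 1 and mesh.is_watertight and len(mesh.faces) == len(comps[0]):
        raise ProcessingError(
            "cannot partition: single closed component (solid object with no cavity)"
        )

    labels, exterior = _background_regions(mask, exterior_faces)
    h = 0.5 * min(mask.spacing)
    shape = np.array(mask.shape)

    centers = mesh.triangles_center
    normals = mesh.face_normals

    ext_faces: list[np.ndarray] = []
    int_faces: list[np.ndarray] = []
    unc_faces: list[np.ndarray] = []
    designated = set(exterior_faces)
    for comp in comps:
        probe = centers[comp] + normals[comp] * h
        idx = np.rint(mask.world_to_index(probe)).astype(int)
        in_grid = (idx >= 0).all(axis=1) & (idx < shape).all(axis=1)
        # probes leaving the grid vote by the face they exit through
        votes_ext = votes_int = 0
        for out in idx[~in_grid]:
            ax = int(np.argmax(np.maximum(-out, out - shape + 1)))
            face = ("+" if out[ax] >= shape[ax] else "-") + "xyz"[ax]
            if face in designated:
                votes_ext += 1
            else:
                votes_int += 1
        sel = idx[in_grid]
        lab = labels[sel[:, 0], sel[:, 1], sel[:, 2]]
        bg = lab > 0
        is_ext = np.isin(lab, list(exterior)) & bg
        votes_ext += int(np.count_nonzero(is_ext))
        votes_int += int(np.count_nonzero(bg & ~is_ext))
        total = votes_ext + votes_int
        if total == 0:
            unc_faces.append(comp)
        elif votes_ext / total >= majority:
            ext_faces.append(comp)
        elif votes_int / total >= majority:
            int_faces.append(comp)
        else:
            unc_faces.append(comp)

    def submesh(groups: list[np.ndarray]) -> trimesh.Trimesh | None:
        if not groups:
            return None
        sub = mesh.submesh([np.concatenate(groups)], append=True)
        sub.remove_unreferenced_vertices()
        return sub

    external = submesh(ext_faces)
    internal = submesh(int_faces)
    if external is None:
        raise ProcessingError("no component classified as external")
    if internal is None:
        raise ProcessingError("no component classified as internal")
    return SurfacePartition(external=external, internal=internal, unclassified=submesh(unc_faces))
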