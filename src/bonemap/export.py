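"""Colored thickness-mesh export: binary PLY, legacy VTK PolyData, CSV audit.

The PLY path goes through trimesh (custom per-vertex channels are written
as extra vertex properties and recovered from the raw PLY element on read).
Legacy-ASCII VTK PolyData is written by a small in-package writer since no
installed library emits that format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError
from .frame import LandmarkFrame, build_frame_overlays
from .surface import SurfacePartition
from .thickness import BandSpec, ThicknessField, classify_bands

__all__ = ["export_thickness_mesh", "read_thickness_mesh", "export_partition"]

_CHANNEL_DTYPES = {"thickness_mm": np.float32, "band": np.uint8,
                   "hs_ring": np.uint8, "zl_line": np.uint8, "site": np.uint8}


def _build_channels(partition, fld, bands, frame, extra_channels):
    ext = partition.external
    if len(fld.values) != len(ext.vertices):
        raise ValidationError("thickness field length does not match the external surface")
    band, colors = classify_bands(fld, bands)
    channels: dict[str, np.ndarray] = {
        "thickness_mm": fld.values.astype(np.float32),
        "band": band,
    }
    if frame is not None:
        channels.update(build_frame_overlays(frame, ext))
    for name, vals in (extra_channels or {}).items():
        vals = np.asarray(vals)
        if len(vals) != len(ext.vertices):
            raise ValidationError(f"channel {name!r} length mismatch")
        channels[name] = vals.astype(_CHANNEL_DTYPES.get(name, vals.dtype))
    return channels, colors


def export_thickness_mesh(
    partition: SurfacePartition,
    fld: ThicknessField,
    bands: BandSpec | None = None,
    frame: LandmarkFrame | None = None,
    path: str | Path = "thickness.ply",
    extra_channels: dict | None = None,
) -> Path:
    """Write the external surface with thickness, band, color and overlay
    channels.  Format chosen by suffix: .ply (binary), .vtk (legacy ASCII
    PolyData), .csv (audit dump)."""
    bands = bands or BandSpec()
    path = Path(path)
    channels, colors = _build_channels(partition, fld, bands, frame, extra_channels)
    ext = partition.external
    suffix = path.suffix.lower()
    try:
        if suffix == ".ply":
            _write_ply(ext, channels, colors, path)
        elif suffix == ".vtk":
            _write_vtk(ext, channels, colors, path)
        elif suffix == ".csv":
            _write_csv(ext, channels, path)
        else:
            raise ValidationError(f"unsupported export format {suffix!r}")
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc
    return path


def _write_ply(mesh: trimesh.Trimesh, channels, colors, path: Path) -> None:
    out = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    out.visual.vertex_colors = np.column_stack(
        [colors, np.full(len(colors), 255, np.uint8)])
    for name, vals in channels.items():
        out.vertex_attributes[name] = vals
    data = trimesh.exchange.ply.export_ply(out, encoding="binary", include_attributes=True)
    path.write_bytes(data)


def _write_vtk(mesh: trimesh.Trimesh, channels, colors, path: Path) -> None:
    v, f = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    lines = ["# vtk DataFile Version 3.0", "bonemap thickness surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(v)} float"]
    lines += [" ".join(f"{x:.6f}" for x in p) for p in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in f]
    lines.append(f"POINT_DATA {len(v)}")
    for name, vals in channels.items():
        vtk_type = "float" if np.issubdtype(vals.dtype, np.floating) else "int"
        lines.append(f"SCALARS {name} {vtk_type} 1")
        lines.append("LOOKUP_TABLE default")
        fmt = "{:.6f}" if vtk_type == "float" else "{:d}"
        lines += [fmt.format(x) for x in vals.tolist()]
    lines.append("COLOR_SCALARS rgb 3")
    lines += [" ".join(f"{c / 255:.4f}" for c in row) for row in colors]
    path.write_text("\n".join(lines) + "\n")


def _write_csv(mesh: trimesh.Trimesh, channels, path: Path) -> None:
    names = list(channels)
    header = "vertex,x,y,z," + ",".join(names)
    rows = [header]
    v = np.asarray(mesh.vertices)
    cols = [channels[n] for n in names]
    for i in range(len(v)):
        vals = ",".join(f"{c[i]:.6f}" if np.issubdtype(c.dtype, np.floating)
                        else str(int(c[i])) for c in cols)
        rows.append(f"{i},{v[i, 0]:.6f},{v[i, 1]:.6f},{v[i, 2]:.6f},{vals}")
    path.write_text("\n".join(rows) + "\n")


def export_partition(partition: SurfacePartition, path: str | Path) -> Path:
    """Write the whole partitioned surface with a ``surface_class`` channel
    (0 = external, 1 = internal, 2 = unclassified) as binary PLY."""
    path = Path(path)
    parts = [(partition.external, 0), (partition.internal, 1)]
    if partition.unclassified is not None:
        parts.append((partition.unclassified, 2))
    meshes, labels = [], []
    for m, lab in parts:
        meshes.append(m)
        labels.append(np.full(len(m.vertices), lab, np.uint8))
    combined = trimesh.util.concatenate(meshes)
    out = trimesh.Trimesh(vertices=combined.vertices, faces=combined.faces, process=False)
    out.vertex_attributes["surface_class"] = np.concatenate(labels)
    path.write_bytes(trimesh.exchange.ply.export_ply(out, encoding="binary",
                                                     include_attributes=True))
    return path


def read_thickness_mesh(path: str | Path):
    """Read back an exported .ply or .vtk surface.

    Returns ``(mesh, channels)`` with the per-vertex channels as a dict of
    arrays (thickness preserved to float32)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.suffix.lower() == ".ply":
        mesh = trimesh.load(str(path), process=False)
        raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
        channels = {}
        if raw is not None:
            for name in raw.dtype.names:
                if name not in ("x", "y", "z", "red", "green", "blue", "alpha",
                                "nx", "ny", "nz"):
                    channels[name] = np.asarray(raw[name])
        return mesh, channels
    if path.suffix.lower() == ".vtk":
        return _read_vtk(path)
    raise ValidationError(f"unsupported mesh format {path.suffix!r}")


def _read_vtk(path: Path):
    tokens = path.read_text().splitlines()
    i, npts, verts, faces, channels = 0, 0, None, None, {}
    while i < len(tokens):
        line = tokens[i].split()
        if not line:
            i += 1
            continue
        key = line[0].upper()
        if key == "POINTS":
            npts = int(line[1])
            verts = np.array([tokens[i + 1 + j].split() for j in range(npts)], dtype=float)
            i += npts + 1
        elif key == "POLYGONS":
            nf = int(line[1])
            faces = np.array([tokens[i + 1 + j].split()[1:] for j in range(nf)], dtype=int)
            i += nf + 1
        elif key == "SCALARS":
            name, vtype = line[1], line[2]
            dtype = np.float32 if vtype == "float" else np.int64
            vals = np.array(tokens[i + 2:i + 2 + npts], dtype=dtype)
            channels[name] = vals
            i += npts + 2
        elif key == "COLOR_SCALARS":
            i += npts + 1
        else:
            i += 1
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return mesh, channels
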