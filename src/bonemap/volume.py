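"""Scalar volumes with world geometry, and NIfTI / MetaImage / DICOM I/O.

Conventions used by the whole package (stated once, here):

* ``data[i, j, k]`` indexes the ``(x, y, z)`` axes, 0-based, with ``i``
  (the x axis) varying fastest in memory order of the on-disk formats.
* World coordinates are voxel-*center* coordinates in millimetres:
  ``world(i, j, k) = origin + (i, j, k) * spacing``.
* Spacing must be present and strictly positive on every axis; a header
  without spacing is an error, never a silent 1 mm default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import ValidationError

__all__ = ["Volume", "LabelMask", "read_volume", "write_volume", "read_dicom_series"]


@dataclass
class Volume:
    """A 3D scalar grid (image intensities or labels) with world geometry.

    Parameters
    ----------
    data:
        3D array indexed ``[i, j, k]`` for the ``(x, y, z)`` axes.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    orientation:
        Free-form axis-orientation tag carried through I/O (the direction
        cosine matrix flattened, for ITK-read images).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "identity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"non-3D data: got {self.data.ndim} dimensions")
        if any(s < 2 for s in self.data.shape):
            raise ValidationError(f"volume needs >= 2 voxels per axis, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        return np.asarray(ijk, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - np.array(self.origin)) / np.array(self.spacing)

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LabelMask(Volume):
    """A binary Volume: 1 = "inside" (bone), 0 = "outside".

    ``provenance`` records how the mask was produced (threshold, fill
    parameters, warnings) so every downstream artifact can log it.
    """

    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"label mask must be binary, found values {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @classmethod
    def from_volume(cls, vol: Volume, data: np.ndarray, provenance: dict | None = None) -> "LabelMask":
        return cls(data=data, spacing=vol.spacing, origin=vol.origin,
                   orientation=vol.orientation, provenance=provenance or {})


def _from_sitk(img: sitk.Image) -> Volume:
    if img.GetDimension() != 3:
        raise ValidationError(f"non-3D data: image has dimension {img.GetDimension()}")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"missing or non-positive spacing in header: {spacing}")
    # sitk arrays come back [z, y, x]; transpose into our [x, y, z] order
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(
        data=data,
        spacing=spacing,
        origin=img.GetOrigin(),
        orientation=",".join(f"{d:g}" for d in img.GetDirection()),
    )


def read_volume(path: str | Path, format_hint: str | None = None) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing and origin are taken from the header; a missing or zero spacing
    raises instead of defaulting to 1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        if format_hint:
            reader = sitk.ImageFileReader()
            reader.SetImageIO(format_hint)
            reader.SetFileName(str(path))
            img = reader.Execute()
        else:
            img = sitk.ReadImage(str(path))
    except (RuntimeError, OSError) as exc:
        raise ValidationError(f"unreadable volume {path}: {exc}") from exc
    return _from_sitk(img)


def read_dicom_series(directory: str | Path) -> Volume:
    """Read a DICOM series from a directory (optional input path)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"no such directory: {directory}")
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(directory))
    if not names:
        raise ValidationError(f"no DICOM series found in {directory}")
    reader.SetFileNames(names)
    return _from_sitk(reader.Execute())


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI or MetaImage, chosen by the file suffix."""
    path = Path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))
    return path


def like(vol: Volume, data: np.ndarray) -> Volume:
    """A new Volume sharing geometry with ``vol``."""
    return replace(vol, data=data)
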