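"""Density-threshold bone segmentation and boundary-aware cavity filling.

CBCT intensity tracks tissue density, so bone is labelled by a global
threshold.  The temporal bone then needs a topological correction: mastoid
air cells are enclosed low-density pockets that count as "inside" for
thickness purposes, while open cavities (middle ear, and the cranial side of
a cropped region of interest) must remain "outside".  ``fill_enclosed_cavities``
implements that policy reproducibly: a background component is absorbed into
bone only if it is fully enclosed, small enough, and not explicitly protected
by an exclusion seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume import LabelMask, Volume

__all__ = ["SegmentationPolicy", "segment_bone", "fill_enclosed_cavities"]

# Complementary connectivity pair: 6-connected foreground, 26-connected
# background, the standard choice avoiding topological paradoxes.
_STRUCT_BG = np.ones((3, 3, 3), dtype=bool)
_STRUCT_FG = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationPolicy:
    """Reproducible replacement for interactive slice-by-slice labelling.

    Parameters
    ----------
    threshold:
        Bone intensity threshold; voxels with intensity >= threshold are bone.
    fill_diameter_mm:
        Enclosed background components whose sphere-equivalent diameter is at
        most this value are absorbed into bone (mastoid air cells).  The 5 mm
        default separates typical air cells from the much larger middle-ear
        and cranial cavities.
    exclusion_seeds_mm:
        World points (mm) marking cavities that must stay "outside" no matter
        their size, e.g. a seed dropped in the middle ear.
    """

    threshold: float = 0.5
    fill_diameter_mm: float = 5.0
    exclusion_seeds_mm: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        if self.fill_diameter_mm < 0:
            raise ValidationError("fill diameter must be >= 0")


def segment_bone(volume: Volume, policy: SegmentationPolicy) -> LabelMask:
    """Threshold intensities into a binary bone mask (no morphology yet)."""
    data = np.asarray(volume.data)
    if not np.isfinite(data).all():
        raise ValidationError("volume intensities must be finite")
    mask = (data >= policy.threshold).astype(np.uint8)
    prov = {"threshold": policy.threshold}
    if not mask.any():
        prov["empty_warning"] = True
    return LabelMask.from_volume(volume, mask, prov)


def _equivalent_diameter_mm(voxel_count: int, voxel_volume: float) -> float:
    """Diameter of the sphere with the same volume as ``voxel_count`` voxels."""
    return float((6.0 * voxel_count * voxel_volume / np.pi) ** (1.0 / 3.0))


def fill_enclosed_cavities(mask: LabelMask, policy: SegmentationPolicy) -> LabelMask:
    """Absorb small enclosed background cavities into the bone label.

    A background connected component (26-connectivity) is relabelled 1 iff it

    * does not touch the volume boundary (fully enclosed),
    * has sphere-equivalent diameter <= ``policy.fill_diameter_mm``, and
    * contains none of ``policy.exclusion_seeds_mm``.
    """
    data = mask.data.astype(bool)
    bg = ~data
    labels, nlab = ndimage.label(bg, structure=_STRUCT_BG)

    seed_labels: set[int] = set()
    for seed in policy.exclusion_seeds_mm:
        idx = np.rint(mask.world_to_index(seed)).astype(int)
        if (idx < 0).any() or (idx >= np.array(mask.shape)).any():
            raise ValidationError(f"exclusion seed {tuple(seed)} outside volume bounds")
        lab = labels[tuple(idx)]
        if lab > 0:
            seed_labels.add(int(lab))

    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)

    counts = np.bincount(labels.ravel(), minlength=nlab + 1)
    filled = data.copy()
    n_filled = 0
    for lab in range(1, nlab + 1):
        if lab in boundary_labels or lab in seed_labels:
            continue
        if _equivalent_diameter_mm(counts[lab], mask.voxel_volume) <= policy.fill_diameter_mm:
            filled[labels == lab] = True
            n_filled += 1

    prov = dict(mask.provenance)
    prov.update({"fill_diameter_mm": policy.fill_diameter_mm, "cavities_filled": n_filled})
    return LabelMask.from_volume(mask, filled.astype(np.uint8), prov)
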