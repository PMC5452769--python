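"""Threshold segmentation and boundary-aware cavity filling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bonemap as bm
from bonemap.errors import ValidationError
from bonemap.phantoms import as_intensity_volume


def _uniform(value, shape=(5, 5, 5)):
    return bm.Volume(data=np.full(shape, float(value)), spacing=(1, 1, 1))


def test_uniform_volume_above_threshold_saturates():
    mask = bm.segment_bone(_uniform(101.0), bm.SegmentationPolicy(threshold=100.0))
    assert mask.data.all()
    assert "empty_warning" not in mask.provenance


def test_uniform_volume_below_threshold_is_empty_with_warning():
    mask = bm.segment_bone(_uniform(99.0), bm.SegmentationPolicy(threshold=100.0))
    assert not mask.data.any()
    assert mask.provenance.get("empty_warning") is True


def test_shell_intensities_segment_to_exact_voxel_classification():
    """Thresholding a two-level shell recovers the generator's analytic mask."""
    shell_mask, _ = bm.make_shell_phantom(10.0, 7.0, spacing=0.8)
    intens = as_intensity_volume(shell_mask, bone_value=1200.0, air_value=-400.0)
    seg = bm.segment_bone(intens, bm.SegmentationPolicy(threshold=300.0))
    assert np.array_equal(seg.data, shell_mask.data)


def test_nonfinite_intensities_rejected():
    vol = _uniform(1.0)
    vol.data[2, 2, 2] = np.nan
    with pytest.raises(ValidationError):
        bm.segment_bone(vol, bm.SegmentationPolicy(threshold=0.5))


def _block_with_bubble(tunnel=False):
    data = np.ones((20, 20, 20), np.uint8)
    data[9:11, 9:11, 9:11] = 0          # ~2 mm bubble at 1 mm spacing
    if tunnel:
        data[10, 10, 11:] = 0           # connect bubble to the +z boundary
    return bm.LabelMask(data=data, spacing=(1, 1, 1))


def test_enclosed_bubble_absorbed_into_bone():
    policy = bm.SegmentationPolicy(fill_diameter_mm=5.0)
    filled = bm.fill_enclosed_cavities(_block_with_bubble(), policy)
    assert filled.data.all()
    assert filled.provenance["cavities_filled"] == 1


def test_bubble_with_tunnel_to_boundary_stays_open():
    policy = bm.SegmentationPolicy(fill_diameter_mm=5.0)
    filled = bm.fill_enclosed_cavities(_block_with_bubble(tunnel=True), policy)
    assert filled.data[10, 10, 10] == 0


def test_seeded_and_oversized_cavities_retained():
    """Ten small sealed bubbles are filled; a seeded 8 mm cavity is not."""
    rng = np.random.default_rng(3)
    data = np.ones((40, 40, 40), np.uint8)
    centers = []
    while len(centers) < 10:
        c = rng.integers(4, 36, size=3)
        if centers and (np.abs(np.array(centers) - c).max(axis=1) < 6).any():
            continue
        if np.linalg.norm(c - 20) < 9:  # keep clear of the big cavity
            continue
        centers.append(c)
        data[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2] = 0  # 3 mm
    x, y, z = np.mgrid[:40, :40, :40]
    data[(x - 20) ** 2 + (y - 20) ** 2 + (z - 20) ** 2 <= 16] = 0  # 8 mm cavity
    mask = bm.LabelMask(data=data, spacing=(1, 1, 1))
    policy = bm.SegmentationPolicy(fill_diameter_mm=5.0,
                                   exclusion_seeds_mm=((20.0, 20.0, 20.0),))
    filled = bm.fill_enclosed_cavities(mask, policy)
    assert filled.provenance["cavities_filled"] == 10
    assert filled.data[20, 20, 20] == 0


def test_exclusion_seed_outside_bounds_rejected():
    with pytest.raises(ValidationError, match="outside volume bounds"):
        bm.fill_enclosed_cavities(
            _block_with_bubble(),
            bm.SegmentationPolicy(exclusion_seeds_mm=((99.0, 0.0, 0.0),)))


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_filling_is_idempotent_and_monotone(seed):
    rng = np.random.default_rng(seed)
    data = (rng.random((12, 12, 12)) < 0.7).astype(np.uint8)
    mask = bm.LabelMask(data=data, spacing=(1, 1, 1))
    policy = bm.SegmentationPolicy(fill_diameter_mm=4.0)
    once = bm.fill_enclosed_cavities(mask, policy)
    twice = bm.fill_enclosed_cavities(once, policy)
    assert np.array_equal(once.data, twice.data)
    assert (once.data >= mask.data).all()


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_segmentation_is_threshold_monotone(seed):
    rng = np.random.default_rng(seed)
    vol = bm.Volume(data=rng.random((8, 8, 8)) * 100, spacing=(1, 1, 1))
    lo = bm.segment_bone(vol, bm.SegmentationPolicy(threshold=30.0))
    hi = bm.segment_bone(vol, bm.SegmentationPolicy(threshold=60.0))
    assert (hi.data <= lo.data).all()
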