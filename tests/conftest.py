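"""Shared fixtures: coarse phantoms run once per session.

Unit tests use 0.5-0.8 mm voxels and small radii so the whole suite stays
fast; tolerances scale with the voxel size.  The acceptance tests rebuild
the clinically sized 0.4 mm phantoms themselves.
"""

import numpy as np
import pytest

import bonemap as bm


@pytest.fixture(scope="session")
def coarse_shell():
    """20/15 mm spherical shell at 0.8 mm spacing, full pipeline."""
    mask, truth = bm.make_shell_phantom(outer_r=20.0, inner_r=15.0, spacing=0.8)
    mesh = bm.extract_surface(mask)
    part = bm.partition_surfaces(mesh, mask)
    fld = bm.compute_thickness(part)
    return {"mask": mask, "truth": truth, "mesh": mesh, "part": part, "fld": fld}


def _slab_bundle(thickness, tilt=0.0, spacing=0.5):
    mask, truth = bm.make_slab_phantom(thickness, lateral=30.0, spacing=spacing,
                                       tilt_deg=tilt)
    mesh = bm.extract_surface(mask)
    part = bm.partition_surfaces(mesh, mask, exterior_faces=truth.exterior_faces)
    fld = bm.compute_thickness(part)
    return {"mask": mask, "truth": truth, "mesh": mesh, "part": part, "fld": fld}


@pytest.fixture(scope="session")
def slab8():
    return _slab_bundle(8.0)


@pytest.fixture(scope="session")
def slab4():
    return _slab_bundle(4.0)


@pytest.fixture(scope="session")
def temporal_bundle():
    """Temporal-like phantom (seed 0, 0.5 mm) through the whole pipeline."""
    spec = bm.PhantomSpec(seed=0, spacing=0.5)
    mask, truth, frame = bm.make_temporal_phantom(spec)
    policy = bm.SegmentationPolicy(threshold=300.0)
    intens = bm.phantoms.as_intensity_volume(mask)
    seg = bm.fill_enclosed_cavities(bm.segment_bone(intens, policy), policy)
    mesh = bm.extract_surface(seg)
    part = bm.partition_surfaces(mesh, seg, exterior_faces=truth.exterior_faces)
    fld = bm.compute_thickness(part)
    return {"spec": spec, "mask": mask, "truth": truth, "frame": frame,
            "seg": seg, "mesh": mesh, "part": part, "fld": fld}


@pytest.fixture(scope="session")
def records():
    return bm.load_table1()


def random_mesh_pair(rng, n_points=40, n_tri=30, scale=10.0):
    """Random query points plus a random triangle soup for oracle checks."""
    points = rng.normal(size=(n_points, 3)) * scale
    tri = rng.normal(size=(n_tri, 3, 3)) * scale
    # reject (rebuild) degenerate triangles so the brute-force oracle is defined
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    while (areas < 1e-6).any():
        bad = areas < 1e-6
        tri[bad] = rng.normal(size=(bad.sum(), 3, 3)) * scale
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return points, tri
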