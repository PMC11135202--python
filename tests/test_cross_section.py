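"""Plane geometry: frames, resampling, connectivity, Feret diameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortatrace import (
    LostLumenError,
    PhantomSpec,
    connected_region,
    generate_phantom,
    make_frame,
    max_diameter,
    min_diameter,
    region_centroid,
    sample_plane,
)
from aortatrace.cross_section import region_area

from conftest import random_blob

ORIGIN = np.zeros(3)


def rasterized_disc(radius_mm: float, pitch: float) -> np.ndarray:
    m = int(np.ceil(radius_mm / pitch)) + 2
    c = (np.arange(2 * m + 1) - m) * pitch
    x, y = np.meshgrid(c, c, indexing="ij")
    return (x**2 + y**2 <= radius_mm**2).astype(np.uint8)


def rasterized_ellipse(a: float, b: float, pitch: float) -> np.ndarray:
    m = int(np.ceil(max(a, b) / pitch)) + 2
    c = (np.arange(2 * m + 1) - m) * pitch
    x, y = np.meshgrid(c, c, indexing="ij")
    return ((x / a) ** 2 + (y / b) ** 2 <= 1.0).astype(np.uint8)


def brute_force_max(region: np.ndarray, pitch: float) -> float:
    pts = np.argwhere(region).astype(float) * pitch
    if len(pts) < 2:
        return 0.0
    d = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def rotation_scan_min(region: np.ndarray, pitch: float, step_deg=0.5) -> float:
    pts = np.argwhere(region).astype(float) * pitch
    if len(pts) < 2:
        return 0.0
    best = np.inf
    for ang in np.arange(0.0, 180.0, step_deg):
        n = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
        proj = pts @ n
        best = min(best, proj.max() - proj.min())
    return float(best)


class TestMakeFrame:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3).filter(
        lambda v: np.linalg.norm(v) > 1e-3))
    def test_orthonormal_right_handed(self, normal):
        f = make_frame(ORIGIN, normal)
        for v in (f.u_axis, f.v_axis, f.normal):
            assert abs(np.linalg.norm(v) - 1.0) < 1e-9
        assert abs(f.u_axis @ f.v_axis) < 1e-9
        assert abs(f.u_axis @ f.normal) < 1e-9
        assert np.allclose(np.cross(f.u_axis, f.v_axis), f.normal, atol=1e-9)

    def test_deterministic_and_scale_invariant(self):
        a = make_frame(ORIGIN, [0.0, 0.0, 1.0])
        b = make_frame(ORIGIN, [0.0, 0.0, 1.0])
        c = make_frame(ORIGIN, [0.0, 0.0, 2.0])
        assert np.array_equal(a.u_axis, b.u_axis)
        assert np.allclose(a.u_axis, c.u_axis) and np.allclose(a.v_axis, c.v_axis)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            make_frame(ORIGIN, [0.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def cylinder():
    return generate_phantom(
        PhantomSpec(shape="straight_cylinder", radius=10, length=60)
    )


class TestSamplePlane:
    def test_axial_disc_area(self, cylinder):
        mask, _ = cylinder
        f = make_frame([0, 0, 30.0], [0, 0, 1.0])
        grid = sample_plane(mask, f, 20.0, 0.5)
        area = grid.sum() * 0.25
        assert abs(area - 100 * np.pi) / (100 * np.pi) < 0.02

    def test_tilted_plane_oblique_ellipse_area(self, cylinder):
        mask, _ = cylinder
        t = np.deg2rad(20.0)
        f = make_frame([0, 0, 30.0], [np.sin(t), 0, np.cos(t)])
        grid = sample_plane(mask, f, 20.0, 0.5)
        expected = 100 * np.pi / np.cos(t)
        assert abs(grid.sum() * 0.25 - expected) / expected < 0.03

    def test_plane_outside_mask_is_empty(self, cylinder):
        mask, _ = cylinder
        f = make_frame([0, 0, 500.0], [0, 0, 1.0])
        assert sample_plane(mask, f, 20.0, 0.5).sum() == 0


class TestConnectedRegion:
    def test_two_discs_keep_seeded_one(self):
        grid = np.zeros((40, 40), dtype=np.uint8)
        grid[5:15, 5:15] = 1
        grid[25:35, 25:35] = 1
        out = connected_region(grid, (10, 10))
        assert out[5:15, 5:15].all() and not out[25:35, 25:35].any()

    def test_single_component_identity(self):
        grid = rasterized_disc(5.0, 1.0)
        m = grid.shape[0] // 2
        assert np.array_equal(connected_region(grid, (m, m)), grid)

    def test_seed_snaps_within_five_pixels(self):
        grid = np.zeros((20, 20), dtype=np.uint8)
        grid[10:15, 10:15] = 1
        out = connected_region(grid, (7, 10))  # 3 px off the block
        assert out.sum() == 25

    def test_lost_lumen(self):
        with pytest.raises(LostLumenError):
            connected_region(np.zeros((20, 20), dtype=np.uint8), (10, 10))


class TestFeretDiameters:
    def test_single_pixel_is_zero(self):
        grid = np.zeros((5, 5), dtype=np.uint8)
        grid[2, 2] = 1
        assert max_diameter(grid, 1.0) == 0.0
        assert min_diameter(grid, 1.0) == 0.0

    def test_disc_max_diameter(self):
        grid = rasterized_disc(10.0, 0.25)
        assert abs(max_diameter(grid, 0.25) - 20.0) <= 0.5  # 2 * pitch

    def test_disc_min_equals_max(self):
        grid = rasterized_disc(10.0, 0.25)
        assert max_diameter(grid, 0.25) - min_diameter(grid, 0.25) <= 0.5

    def test_ellipse_min_diameter(self):
        grid = rasterized_ellipse(15.0, 10.0, 0.25)
        assert abs(min_diameter(grid, 0.25) - 20.0) <= 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_agreement_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        blob = random_blob(rng)
        assert max_diameter(blob, 1.0) == pytest.approx(
            brute_force_max(blob, 1.0), abs=1e-9
        )
        mn = min_diameter(blob, 1.0)
        oracle = rotation_scan_min(blob, 1.0)
        assert abs(mn - oracle) <= 0.01 * max(oracle, 1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_circle_lower_bound(self, seed):
        rng = np.random.default_rng(100 + seed)
        blob = random_blob(rng)
        area = region_area(blob, 1.0)
        assert max_diameter(blob, 1.0) >= 2 * np.sqrt(area / np.pi) - 2.0


class TestRegionCentroid:
    def test_centered_disc(self):
        grid = rasterized_disc(8.0, 0.5)
        f = make_frame([1.0, 2.0, 3.0], [0, 0, 1.0])
        assert np.linalg.norm(region_centroid(grid, f, 0.5) - [1, 2, 3]) <= 0.5

    def test_two_pixel_midpoint(self):
        grid = np.zeros((5, 5), dtype=np.uint8)
        grid[2, 1] = grid[2, 3] = 1
        f = make_frame(ORIGIN, [0, 0, 1.0])
        assert np.allclose(region_centroid(grid, f, 1.0), ORIGIN, atol=1e-9)

    def test_offset_disc_maps_through_frame(self):
        pitch, du, dv = 0.5, 3.0, -2.0
        grid = np.zeros((61, 61), dtype=np.uint8)
        c = (np.arange(61) - 30) * pitch
        x, y = np.meshgrid(c, c, indexing="ij")
        grid[((x - du) ** 2 + (y - dv) ** 2) <= 36.0] = 1
        f = make_frame(ORIGIN, [1.0, 1.0, 0.2])
        expected = ORIGIN + du * f.u_axis + dv * f.v_axis
        assert np.linalg.norm(region_centroid(grid, f, pitch) - expected) <= pitch

    def test_empty_region_rejected(self):
        f = make_frame(ORIGIN, [0, 0, 1.0])
        with pytest.raises(ValueError):
            region_centroid(np.zeros((5, 5), dtype=np.uint8), f, 1.0)


def test_rotation_invariance_of_section_diameters(cylinder):
    """Rotating the volume 90 degrees about a grid axis must not change the
    measured section diameter beyond discretization."""
    mask, _ = cylinder
    from aortatrace import AortaMask

    rot = AortaMask(np.rot90(mask.voxels, axes=(1, 2)).copy(), mask.affine,
                    mask.axis_labels)
    f1 = make_frame([0, 0, 30.0], [0, 0, 1.0])
    g1 = connected_region(sample_plane(mask, f1, 20.0, 0.5), (40, 40))
    # the cylinder axis is now along the volume's y axis; pick the matching plane
    n2 = np.array([0.0, 1.0, 0.0])
    origin2 = rot.voxel_to_world(
        np.array(np.array(rot.voxels.shape) / 2.0)
    )
    g2 = connected_region(sample_plane(rot, make_frame(origin2, n2), 20.0, 0.5),
                          (40, 40))
    assert abs(max_diameter(g1, 0.5) - max_diameter(g2, 0.5)) < 1.0
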