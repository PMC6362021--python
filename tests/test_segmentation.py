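"""Segmentation protocol: thresholding, cleaning, pruning, planes, labels."""

import numpy as np
import pytest
from scipy import ndimage

from vwerp.core import EXTERIOR, INLET, INTERIOR, OUTLET, WALL, VoxelGrid
from vwerp.phantom import TubeGeometry, poiseuille_field
from vwerp.segmentation import (
    SegmentationConfig,
    clean_mask,
    extract_centerline,
    initial_mask,
    label_domain,
    make_plane,
    prune_erroneous_voxels,
    select_vessel,
)

STRUCT6 = ndimage.generate_binary_structure(3, 1)


@pytest.fixture(scope="module")
def tube_field(fluid):
    geom = TubeGeometry(radius=6e-3, length=30e-3)
    grid = VoxelGrid((18, 18, 34), (1e-3,) * 3)
    field, _ = poiseuille_field(geom, 0.4, grid, frames=4, fluid=fluid)
    return geom, grid, field


@pytest.fixture(scope="module")
def tube_mask(tube_field):
    geom, grid, field = tube_field
    s, r = geom.frame_coords(grid)
    return (r < geom.radius) & (s >= 0) & (s <= geom.length)


class TestInitialMask:
    def test_threshold_matches_analytic_disc(self, tube_field):
        """At threshold 0.25*VENC with VENC = v_peak, the mask is the
        set r < R*sqrt(0.75); its voxel count matches the analytic
        cylinder within 5%."""
        geom, grid, field = tube_field
        venc = 0.4
        mask = initial_mask(field, venc, SegmentationConfig(threshold_fraction=0.25))
        R_eff = geom.radius * np.sqrt(0.75)
        n_slices = int(geom.length / grid.spacing[2]) + 1
        expected = np.pi * R_eff**2 / (grid.spacing[0] * grid.spacing[1]) * n_slices
        assert mask.sum() == pytest.approx(expected, rel=0.05)

    def test_zero_field_empty_mask(self, tube_field):
        _, grid, field = tube_field
        from vwerp.core import VelocityField4D

        zero = VelocityField4D(grid, field.dt, np.zeros_like(field.values))
        with pytest.warns(UserWarning, match="empty mask"):
            mask = initial_mask(zero, 1.0)
        assert not mask.any()

    def test_degenerate_threshold_keeps_all_moving_voxels(self, tube_field,
                                                          tube_mask):
        geom, grid, field = tube_field
        cfg = SegmentationConfig(threshold_fraction=1e-9)
        mask = initial_mask(field, 0.4, cfg)
        assert mask.sum() >= tube_mask.sum() * 0.99


class TestCleanMask:
    def test_small_islands_removed_tube_kept(self, tube_mask):
        m = tube_mask.copy()
        m[0, 0, 0:4] = True  # 4-voxel island
        m[0, 5, 0:3] = True
        m[17, 17, 5:9] = True
        out = clean_mask(m)
        np.testing.assert_array_equal(out, tube_mask)

    def test_boundary_of_island_rule(self):
        m = np.zeros((30, 10, 10), dtype=bool)
        m[0:10, 0, 0] = True  # 10-voxel line: removed (<= 10)
        m[15:26, 0, 0] = True  # 11-voxel line: retained
        out = clean_mask(m)
        assert not out[0:10, 0, 0].any()
        assert out[15:26, 0, 0].all()

    def test_internal_cavity_filled(self, tube_mask):
        m = tube_mask.copy()
        m[9, 9, 15:17] = False  # 2-voxel cavity inside the lumen
        out = clean_mask(m)
        assert out[9, 9, 15:17].all()

    def test_idempotent(self, tube_mask):
        m = tube_mask.copy()
        m[0, 0, 0:3] = True
        once = clean_mask(m)
        np.testing.assert_array_equal(clean_mask(once), once)


class TestSelectVessel:
    def test_two_tubes_seed_picks_one(self):
        m = np.zeros((20, 8, 8), dtype=bool)
        m[2:6, 2:6, :] = True
        m[12:16, 2:6, :] = True
        out = select_vessel(m, (3, 3, 4))
        assert out[2:6, 2:6, :].all() and not out[12:16].any()

    def test_single_component_identity(self, tube_mask):
        seed = tuple(np.argwhere(tube_mask)[0])
        np.testing.assert_array_equal(select_vessel(tube_mask, seed), tube_mask)

    def test_single_voxel_component(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        out = select_vessel(m, (2, 2, 2))
        assert out.sum() == 1

    def test_seed_outside_rejected(self, tube_mask):
        with pytest.raises(ValueError, match="outside"):
            select_vessel(tube_mask, (0, 0, 0))


class TestPruning:
    def test_clean_phantom_untouched(self, tube_field, tube_mask):
        _, _, field = tube_field
        out = prune_erroneous_voxels(field, tube_mask)
        np.testing.assert_array_equal(out, tube_mask)

    def test_direction_flipped_border_voxel_removed(self, tube_field, tube_mask):
        """A border voxel whose flow points 180 degrees against its
        neighbourhood fails the 120-degree direction filter."""
        _, _, field = tube_field
        border = tube_mask & ~ndimage.binary_erosion(tube_mask, structure=STRUCT6)
        bad = tuple(np.argwhere(border)[7])
        vals = field.values.copy()
        vals[(slice(None),) + bad + (slice(None),)] *= -1.0
        from vwerp.core import VelocityField4D

        flipped = VelocityField4D(field.grid, field.dt, vals)
        out = prune_erroneous_voxels(flipped, tube_mask)
        assert not out[bad]
        removed = tube_mask & ~out
        assert removed.sum() == 1

    def test_temporal_outlier_border_voxel_removed(self, tube_field, tube_mask):
        """A border voxel with a 100x temporal derivative lies far beyond
        two standard deviations of the derivative distribution."""
        _, _, field = tube_field
        border = tube_mask & ~ndimage.binary_erosion(tube_mask, structure=STRUCT6)
        bad = tuple(np.argwhere(border)[11])
        vals = field.values.copy()
        base = vals[(slice(None),) + bad + (slice(None),)]
        wobble = 100.0 * np.abs(base).max() * (-1.0) ** np.arange(vals.shape[0])
        vals[(slice(None),) + bad + (2,)] = wobble
        from vwerp.core import VelocityField4D

        noisy = VelocityField4D(field.grid, field.dt, vals)
        out = prune_erroneous_voxels(noisy, tube_mask)
        assert not out[bad]

    def test_tiny_mask_skipped_with_warning(self, tube_field):
        _, grid, field = tube_field
        m = np.zeros(grid.shape, dtype=bool)
        m[8, 8, 10:14] = True
        with pytest.warns(UserWarning, match="too small"):
            out = prune_erroneous_voxels(field, m)
        np.testing.assert_array_equal(out, m)


class TestCenterline:
    def test_straight_tube_on_axis(self, tube_mask):
        cl = extract_centerline(tube_mask)
        # geometric axis: x = y = 8.5 in voxel units -> within 1 voxel
        assert np.abs(cl[:, 0] - 8.5).max() <= 1.0
        assert np.abs(cl[:, 1] - 8.5).max() <= 1.0
        assert len(np.unique(cl[:, 2])) >= 25

    def test_bent_tube_arc_length(self):
        """90-degree bend: path length within 10% of the analytic arc."""
        n = 40
        m = np.zeros((n, 12, n), dtype=bool)
        Rb, rt = 24.0, 4.0  # bend radius, tube radius (voxels)
        ii, jj, kk = np.mgrid[0:n, 0:12, 0:n]
        rr = np.sqrt((ii - 0) ** 2 + (kk - 0) ** 2)
        d = np.sqrt((rr - Rb) ** 2 + (jj - 6) ** 2)
        m[(d < rt) & (ii >= 0) & (kk >= 0)] = True
        cl = extract_centerline(m)
        steps = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        arc = np.pi / 2 * Rb
        assert steps.sum() == pytest.approx(arc, rel=0.10)

    def test_single_voxel_line_is_itself(self):
        m = np.zeros((3, 3, 12), dtype=bool)
        m[1, 1, 1:11] = True
        cl = extract_centerline(m)
        assert (cl[:, :2] == 1).all()
        assert len(cl) == 10

    def test_loop_rejected(self):
        # a solid torus has a handle: centreline ambiguous
        n = 32
        ii, jj, kk = np.mgrid[0:n, 0:12, 0:n]
        rr = np.sqrt((ii - 16) ** 2 + (kk - 16) ** 2)
        d = np.sqrt((rr - 10) ** 2 + (jj - 6) ** 2)
        m = d < 3
        with pytest.raises(ValueError, match="loop|ambiguous"):
            extract_centerline(m)


class TestMakePlane:
    def test_end_plane_normals_and_area(self, tube_field, tube_mask):
        geom, grid, _ = tube_field
        cl = extract_centerline(tube_mask)
        ks = np.unique(np.nonzero(tube_mask)[2])
        seed_lo = (8, 8, int(ks[0]))
        seed_hi = (8, 8, int(ks[-1]))
        p_in = make_plane(tube_mask, cl, seed_lo, "inlet")
        p_out = make_plane(tube_mask, cl, seed_hi, "outlet")
        np.testing.assert_allclose(p_in.normal, [0, 0, -1], atol=1e-9)
        np.testing.assert_allclose(p_out.normal, [0, 0, 1], atol=1e-9)
        disc = np.pi * geom.radius**2 / (grid.spacing[0] * grid.spacing[1])
        assert p_in.n_voxels == pytest.approx(disc, rel=0.10)

    def test_mid_vessel_plane_perpendicular(self, tube_mask):
        cl = extract_centerline(tube_mask)
        p = make_plane(tube_mask, cl, (8, 14, 17), "outlet")
        assert abs(p.normal[2]) == pytest.approx(1.0)
        assert len(np.unique(p.voxels[:, 2])) == 1

    def test_far_seed_rejected(self, tube_mask):
        cl = extract_centerline(tube_mask)
        with pytest.raises(ValueError, match="3 voxels"):
            make_plane(tube_mask, cl, (0, 0, 0), "inlet")


class TestLabelDomain:
    def test_partition_and_wall_adjacency(self, tube_field, tube_mask):
        _, grid, _ = tube_field
        cl = extract_centerline(tube_mask)
        ks = np.unique(np.nonzero(tube_mask)[2])
        p_in = make_plane(tube_mask, cl, (8, 8, int(ks[0])), "inlet")
        p_out = make_plane(tube_mask, cl, (8, 8, int(ks[-1])), "outlet")
        labels = label_domain(tube_mask, p_in, p_out, grid)
        lab = labels.labels
        assert set(np.unique(lab)) == {EXTERIOR, INTERIOR, INLET, OUTLET, WALL}
        interior = lab == INTERIOR
        near_int = ndimage.binary_dilation(interior, structure=STRUCT6)
        assert not ((lab == WALL) & ~near_int).any()
        # wall voxels also touch non-interior territory
        near_ext = ndimage.binary_dilation(
            (lab == EXTERIOR) | (lab == WALL), structure=STRUCT6
        )
        assert ((lab == WALL) & near_ext).sum() == (lab == WALL).sum()

    def test_mid_planes_confine_interior(self, tube_field, tube_mask):
        """Planes at L/4 and 3L/4 leave only the middle half interior;
        its voxel count matches the analytic sub-cylinder within 10%."""
        geom, grid, _ = tube_field
        cl = extract_centerline(tube_mask)
        ks = np.unique(np.nonzero(tube_mask)[2])
        k1 = int(ks[0] + len(ks) // 4)
        k2 = int(ks[0] + 3 * len(ks) // 4)
        p_in = make_plane(tube_mask, cl, (8, 14, k1), "inlet")
        p_out = make_plane(tube_mask, cl, (8, 14, k2), "outlet")
        labels = label_domain(tube_mask, p_in, p_out, grid)
        lab = labels.labels
        kz = np.nonzero(lab == INTERIOR)[2]
        assert kz.min() == k1 + 1 and kz.max() == k2 - 1
        expected = np.pi * geom.radius**2 * (k2 - k1 - 1) * grid.spacing[2] / grid.dV
        assert (lab == INTERIOR).sum() == pytest.approx(expected, rel=0.10)
        # mask voxels beyond the planes are relabelled exterior
        beyond = tube_mask.copy()
        beyond[:, :, k1:] = False
        assert (lab[beyond] == EXTERIOR).all()

    def test_coincident_planes_rejected(self, tube_field, tube_mask):
        _, grid, _ = tube_field
        cl = extract_centerline(tube_mask)
        p = make_plane(tube_mask, cl, (8, 14, 17), "inlet")
        q = make_plane(tube_mask, cl, (8, 14, 17), "outlet")
        with pytest.raises(ValueError, match="overlap|degenerate"):
            label_domain(tube_mask, p, q, grid)


@pytest.fixture(scope="module")
def stenotic(fluid):
    geom = TubeGeometry(radius=6e-3, length=40e-3, stenosis=(0.5, 0.5, 4e-3))
    grid = VoxelGrid((18, 18, 44), (1e-3,) * 3)
    field, _ = poiseuille_field(geom, 0.3, grid, frames=2, fluid=fluid)
    s, r = geom.frame_coords(grid)
    mask = (r < geom.local_radius(s)) & (s >= 0) & (s <= geom.length)
    return geom, grid, field, mask


class TestStenoticPhantom:
    """The quasi-1D stenotic tube exercises plane selection where the
    cross-section varies (no pressure claim is attached to it)."""

    def test_throat_narrower_and_faster(self, stenotic):
        geom, grid, field, mask = stenotic
        k_throat = grid.shape[2] // 2
        k_ref = 5
        area_throat = mask[:, :, k_throat].sum()
        area_ref = mask[:, :, k_ref].sum()
        assert area_throat < 0.5 * area_ref
        v = field.values[0, ..., 2]
        assert v[:, :, k_throat].max() > 2.5 * v[:, :, k_ref].max()

    def test_centerline_passes_throat_on_axis(self, stenotic):
        _, grid, _, mask = stenotic
        cl = extract_centerline(mask)
        k_throat = grid.shape[2] // 2
        at = cl[cl[:, 2] == k_throat]
        assert len(at) >= 1
        assert np.abs(at[:, :2] - 8.5).max() <= 1.0

    def test_plane_area_shrinks_at_throat(self, stenotic):
        geom, grid, _, mask = stenotic
        cl = extract_centerline(mask)
        p_mid = make_plane(mask, cl, (8, 11, grid.shape[2] // 2), "outlet")
        p_ref = make_plane(mask, cl, (8, 14, 6), "inlet")
        assert p_mid.n_voxels < 0.5 * p_ref.n_voxels


def test_stokes_reference_filter_keeps_consistent_flow(tube_field, tube_mask):
    """Filter (iii): a forward Poiseuille flow is everywhere within the
    angular limit of the solved reference Stokes flow, so nothing is
    pruned when the inlet/outlet planes are supplied."""
    _, grid, field = tube_field
    cl = extract_centerline(tube_mask)
    ks = np.unique(np.nonzero(tube_mask)[2])
    p_in = make_plane(tube_mask, cl, (8, 8, int(ks[0])), "inlet")
    p_out = make_plane(tube_mask, cl, (8, 8, int(ks[-1])), "outlet")
    out = prune_erroneous_voxels(field, tube_mask, None, p_in, p_out)
    np.testing.assert_array_equal(out, tube_mask)
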