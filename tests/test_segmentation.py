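"""Calibration, thresholding, morphology, surfaces, alignment, deviation."""

import numpy as np
import pytest

from tmjfem.core import ImageVolume, Mask, RigidTransform, TriSurface
from tmjfem.geometry import closest_point_on_surface
from tmjfem.segmentation import (align_surface, calibrate, dice,
                                 extract_surface, morph_clean,
                                 resolve_priority, smooth_surface,
                                 surface_deviation, threshold_mask)


def vol_from(data, spacing=1.0):
    return ImageVolume(np.asarray(data, dtype=float), spacing=spacing,
                       origin=np.zeros(3))


class TestCalibrate:
    def test_reference_points_map_exactly(self):
        raw = vol_from(np.array([[[1524.0, 524.0, 1024.0]]]))
        hu = calibrate(raw, mean_water=1524.0, mean_air=524.0)
        assert hu.data[0, 0, 0] == 0.0
        assert hu.data[0, 0, 1] == -1000.0
        assert hu.data[0, 0, 2] == -500.0  # midpoint by linearity

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 3000, (4, 4, 4))
        w, a = 1500.0, 500.0
        direct = calibrate(vol_from(data), w, a)
        scaled = calibrate(vol_from(2.5 * data + 7.0), 2.5 * w + 7.0, 2.5 * a + 7.0)
        assert np.allclose(direct.data, scaled.data, atol=1e-9)

    def test_equal_references_rejected(self):
        with pytest.raises(ValueError):
            calibrate(vol_from(np.zeros((2, 2, 2))), 100.0, 100.0)


class TestThreshold:
    def test_uniform_volume_range_excluding_value_is_empty(self):
        v = vol_from(np.full((3, 3, 3), 50.0))
        with pytest.warns(UserWarning, match="empty"):
            m = threshold_mask(v, lo=100.0, hi=200.0)
        assert m.count() == 0

    def test_adaptive_split_lies_strictly_between_two_values(self):
        data = np.full((4, 4, 4), 10.0)
        data[2:] = 90.0
        v = vol_from(data)
        m = threshold_mask(v, method="adaptive", hi=None, name="hi-side")
        # exhaustive check: any split in (10, 90) selects exactly the 90s
        assert m.count() == 32
        assert np.array_equal(m.data, data >= 90.0)


class TestMorphClean:
    def test_speck_removed_sphere_intact(self):
        g = np.mgrid[-8:9, -8:9, -8:9]
        sphere = (g ** 2).sum(0) <= 25
        m = sphere.copy()
        m[0, 0, 0] = True
        out = morph_clean(Mask(m), min_island=5)
        assert not out.data[0, 0, 0]
        assert np.array_equal(out.data, sphere)

    def test_enclosed_cavity_filled(self):
        g = np.mgrid[-8:9, -8:9, -8:9]
        r2 = (g ** 2).sum(0)
        hollow = (r2 <= 36) & (r2 > 9)
        out = morph_clean(Mask(hollow), min_island=0)
        assert np.array_equal(out.data, r2 <= 36)

    def test_idempotent_on_its_own_output(self):
        rng = np.random.default_rng(3)
        m = Mask(rng.random((15, 15, 15)) > 0.7)
        once = morph_clean(m, min_island=4, closing_radius=1)
        twice = morph_clean(once, min_island=4, closing_radius=1)
        assert np.array_equal(once.data, twice.data)

    def test_never_drops_a_component_larger_than_min_island(self):
        g = np.mgrid[-6:7, -6:7, -6:7]
        sphere = (g ** 2).sum(0) <= 16
        out = morph_clean(Mask(sphere), min_island=sphere.sum() - 1)
        assert out.data.sum() >= sphere.sum()


class TestResolvePriority:
    def test_disjoint_masks_union_order_irrelevant(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2] = True
        b[2:] = True
        la = resolve_priority([Mask(a, "a"), Mask(b, "b")])
        lb = resolve_priority([Mask(b, "b"), Mask(a, "a")])
        assert (la.data > 0).sum() == 64
        assert np.array_equal(la.data > 0, lb.data > 0)

    def test_full_overlap_takes_higher_priority(self):
        a = np.ones((3, 3, 3), bool)
        b = np.ones((3, 3, 3), bool)
        lab = resolve_priority([Mask(a, "first"), Mask(b, "second")])
        assert np.all(lab.data == 1)

    def test_random_overlaps_match_first_hit_oracle(self):
        rng = np.random.default_rng(1)
        masks = [Mask(rng.random((6, 6, 6)) > 0.5, f"m{i}") for i in range(4)]
        lab = resolve_priority(masks)
        for idx in np.ndindex(6, 6, 6):
            expected = 0
            for i, m in enumerate(masks):
                if m.data[idx]:
                    expected = i + 1
                    break
            assert lab.data[idx] == expected


class TestExtractSurface:
    def test_single_voxel_encloses_one_voxel_volume(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        s = extract_surface(Mask(m, spacing=0.3))
        assert s.n_faces == 12
        assert s.enclosed_volume() == pytest.approx(0.3 ** 3, rel=0.2)

    def test_border_touching_slab_has_only_open_faces(self):
        m = np.zeros((6, 7, 8), bool)
        m[:3] = True
        s = extract_surface(Mask(m, spacing=1.0))
        assert s.area() == pytest.approx(7 * 8, rel=1e-12)

    def test_ball_volume_within_5_percent_of_analytic(self):
        g = np.mgrid[-12:13, -12:13, -12:13]
        ball = (g ** 2).sum(0) <= 100
        s = extract_surface(Mask(ball, spacing=1.0))
        assert s.enclosed_volume() == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(Mask(np.zeros((3, 3, 3), bool)))


class TestSmoothSurface:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        m = Mask(rng.random((8, 8, 8)) > 0.5)
        out = smooth_surface(m, 0.0)
        assert np.array_equal(out.data, m.data)

    def test_slab_interior_unchanged(self):
        m = np.zeros((20, 20, 20), bool)
        m[4:16, 4:16, 4:16] = True
        out = smooth_surface(Mask(m), 1.5)
        interior = np.zeros_like(m)
        interior[7:13, 7:13, 7:13] = True
        assert np.all(out.data[interior])
        assert not np.any(out.data & ~m & ~_dilate(m, 3))

    def test_thin_rod_vanishes_under_smoothing(self):
        # motivates skipping smoothing for screw-scale structures
        m = np.zeros((20, 20, 20), bool)
        m[10, 10, 2:18] = True
        out = smooth_surface(Mask(m), 1.5)
        assert out.count() == 0


def _dilate(m, it):
    from scipy import ndimage
    return ndimage.binary_dilation(m, iterations=it)


def _sphere_surface(radius, subdiv=3, center=(0, 0, 0)):
    import trimesh
    s = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    s.apply_translation(center)
    return TriSurface(np.asarray(s.vertices), np.asarray(s.faces))


class TestAlignSurface:
    def test_already_aligned_identity(self):
        s = _sphere_surface(5.0)
        tf = align_surface(s, s, refine=True)
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(tf.translation).max() < 1e-6

    def test_recovers_known_translation(self):
        s = _sphere_surface(5.0)
        t = np.array([0.4, -0.3, 0.25])
        target = TriSurface(s.vertices + t, s.faces)
        tf = align_surface(s, target, refine=True)
        assert np.linalg.norm(tf.translation - t) < 0.05
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-3

    def test_refine_off_returns_init_verbatim(self):
        s = _sphere_surface(3.0)
        init = RigidTransform.from_translation([1.0, 2.0, 3.0])
        out = align_surface(s, s, init=init, refine=False)
        assert out is init

    def test_refinement_does_not_increase_mean_distance(self):
        s = _sphere_surface(5.0)
        target = TriSurface(s.vertices + [0.3, 0.0, 0.0], s.faces)
        init = RigidTransform.identity()
        d0, _, _ = closest_point_on_surface(init.apply(s.vertices), target)
        tf = align_surface(s, target, init=init, refine=True)
        d1, _, _ = closest_point_on_surface(tf.apply(s.vertices), target)
        assert d1.mean() <= d0.mean() + 1e-12


class TestSurfaceDeviation:
    def test_identical_surfaces_have_zero_deviation(self):
        s = _sphere_surface(4.0)
        dev = surface_deviation(s, s)
        assert dev.max < 1e-12

    def test_plane_translated_along_normal(self):
        verts = np.array([[x, y, 0.0] for x in range(5) for y in range(5)])
        faces = []
        for i in range(4):
            for j in range(4):
                a = 5 * i + j
                faces += [[a, a + 5, a + 1], [a + 1, a + 5, a + 6]]
        plane = TriSurface(verts, faces)
        moved = TriSurface(verts + [0.0, 0.0, 0.5], faces)
        dev = surface_deviation(moved, plane)
        assert np.allclose(dev.distances, 0.5, atol=1e-9)

    def test_concentric_spheres_deviation_close_to_radius_gap(self):
        inner = _sphere_surface(10.0, subdiv=4)
        outer = _sphere_surface(10.5, subdiv=4)
        dev = surface_deviation(outer, inner)
        # chord-height error of the inner tessellation bounds the deficit
        tri = inner.triangles()
        edge = np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1).max()
        chord_height = edge ** 2 / (8 * 10.0)
        assert dev.distances.max() <= 0.5 + 1e-9
        assert dev.distances.min() >= 0.5 - chord_height - 1e-9

    def test_invariant_under_common_rigid_motion(self):
        a = _sphere_surface(5.0)
        b = _sphere_surface(5.4)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        tf = RigidTransform(R, [1.0, -2.0, 0.5])
        d0 = surface_deviation(a, b).distances
        d1 = surface_deviation(a.transformed(tf), b.transformed(tf)).distances
        assert np.abs(d0 - d1).max() < 1e-9

    def test_empty_target_rejected(self):
        s = _sphere_surface(2.0)
        with pytest.raises(ValueError):
            surface_deviation(s, TriSurface(np.zeros((0, 3)), np.zeros((0, 3))))


class TestDice:
    def test_identical_masks(self):
        m = Mask(np.ones((3, 3, 3), bool))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0] = True
        b[1] = True
        assert dice(Mask(a), Mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2] = True
        b[1:3] = True
        assert dice(Mask(a), Mask(b)) == 0.5

    def test_both_empty_defined_as_one(self):
        e = Mask(np.zeros((2, 2, 2), bool))
        assert dice(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(Mask(np.ones((2, 2, 2), bool)), Mask(np.ones((3, 3, 3), bool)))
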