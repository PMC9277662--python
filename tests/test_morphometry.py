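"""Morphometry: calibration, segmentation, ROIs, BVTV/BMD/BSA, damage
quantification and surface geometry against analytic and counting oracles."""
import numpy as np
import pytest
from skimage.morphology import ball

from sbmech import morphometry as morph
from sbmech.synthetic import generate_volume
from sbmech.synthetic.volume import VoxelVolume


def make_volume(data, voxel_um=60.0):
    return VoxelVolume(data=np.asarray(data, np.float32), voxel_size_um=voxel_um)


class TestCalibration:
    def test_two_point_line_by_hand(self):
        data = np.zeros((4, 8, 8), np.float32)
        m1 = np.zeros_like(data, bool); m1[:, :, :3] = True
        m2 = np.zeros_like(data, bool); m2[:, :, 5:] = True
        data[m1] = 2500.0
        data[m2] = 7500.0
        cal = morph.calibrate_density(make_volume(data), (m1, m2), (250.0, 750.0))
        assert cal.slope == pytest.approx(0.1, rel=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.density(5000.0) == pytest.approx(500.0, rel=1e-12)
        # exact at both phantom points, affine at probe grayscales
        for gs, d in ((2500, 250), (7500, 750), (0, 0)):
            assert cal.density(gs) == pytest.approx(d, abs=1e-9)

    def test_identity_calibration(self):
        data = np.zeros((4, 8, 8), np.float32)
        m1 = np.zeros_like(data, bool); m1[:, :2] = True
        m2 = np.zeros_like(data, bool); m2[:, 6:] = True
        data[m1], data[m2] = 250.0, 750.0
        cal = morph.calibrate_density(make_volume(data), (m1, m2), (250.0, 750.0))
        assert cal.slope == pytest.approx(1.0) and cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_calibration_rejected(self):
        data = np.full((4, 8, 8), 100.0, np.float32)
        m = np.ones_like(data, bool)
        with pytest.raises(ValueError, match="degenerate|identical"):
            morph.calibrate_density(make_volume(data), (m, m), (250.0, 750.0))

    def test_synthetic_volume_bmd_within_1pct(self):
        vol, truth = generate_volume(shape=(80, 72, 72), voxel_size=60.0,
                                     target_bvtv=0.85, tissue_bmd=900.0, seed=5)
        cal = morph.calibrate_density(
            vol, (truth.phantoms[0].mask, truth.phantoms[1].mask),
            (truth.phantoms[0].density, truth.phantoms[1].density))
        lower = morph.default_lower_threshold(vol, truth.specimen_footprint)
        mask = morph.smooth_and_segment(vol, lower) & truth.specimen_footprint[None]
        roi = np.zeros(vol.data.shape, bool)
        roi[truth.interface_z:] = truth.specimen_footprint
        _, bmd = morph.compute_bvtv_bmd(vol, mask, roi, cal)
        assert bmd == pytest.approx(truth.mean_tissue_bmd, rel=0.01)


class TestSegmentation:
    def test_binary_volume_mask_recovers_high_set(self):
        data = np.zeros((24, 24, 24), np.float32)
        data[:, :, 12:] = 400.0
        mask = morph.smooth_and_segment(make_volume(data), lower_threshold=200.0)
        # away from the boundary, smoothing changes nothing
        assert mask[:, :, 16:].all()
        assert not mask[:, :, :8].any()

    def test_raising_lower_threshold_never_grows_mask(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.uniform(0, 500, (20, 20, 20)))
        prev = None
        for lower in (100.0, 200.0, 300.0, 400.0):
            m = morph.smooth_and_segment(vol, lower)
            if prev is not None:
                assert not (m & ~prev).any()  # monotone shrinkage
            prev = m

    def test_synthetic_volume_bvtv_within_002(self):
        vol, truth = generate_volume(shape=(80, 72, 72), voxel_size=60.0,
                                     target_bvtv=0.82, seed=6)
        lower = morph.default_lower_threshold(vol, truth.specimen_footprint)
        mask = morph.smooth_and_segment(vol, lower) & truth.specimen_footprint[None]
        roi = np.zeros(vol.data.shape, bool)
        roi[truth.interface_z:] = truth.specimen_footprint
        bvtv, _ = morph.compute_bvtv_bmd(vol, mask, roi)
        assert bvtv == pytest.approx(truth.bvtv, abs=0.02)

    def test_threshold_validation(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            morph.smooth_and_segment(vol, 500.0, 400.0)
        with pytest.raises(ValueError):
            morph.smooth_and_segment(vol, 10.0, 1000.0)  # outside gs range


class TestInterface:
    def test_flat_slab(self):
        mask = np.zeros((50, 16, 16), bool)
        mask[30:] = True
        m, ref = morph.detect_interface(mask, voxel_size_mm=0.004)
        assert ref == pytest.approx(30 * 0.004, rel=1e-12)
        assert np.allclose(m, 30 * 0.004)

    def test_sinusoidal_surface_median(self):
        ny = nx = 32
        yy, xx = np.mgrid[0:ny, 0:nx]
        height = (20 + 6 * np.sin(2 * np.pi * xx / nx)).astype(int)
        mask = np.zeros((40, ny, nx), bool)
        for y in range(ny):
            for x in range(nx):
                mask[height[y, x]:, y, x] = True
        _, ref = morph.detect_interface(mask, voxel_size_mm=0.01)
        assert ref == pytest.approx(np.median(height) * 0.01, abs=0.01)

    def test_tilted_plane_recovered_within_1vox_rms(self):
        ny = nx = 32
        yy, xx = np.mgrid[0:ny, 0:nx]
        height = (10 + 0.5 * xx).astype(int)
        mask = np.zeros((40, ny, nx), bool)
        for y in range(ny):
            for x in range(nx):
                mask[height[y, x]:, y, x] = True
        m, _ = morph.detect_interface(mask, voxel_size_mm=1.0)
        rms = np.sqrt(np.nanmean((m - height) ** 2))
        assert rms <= 1.0

    def test_empty_footprint_columns_rejected(self):
        mask = np.zeros((10, 8, 8), bool)
        mask[5:, :4] = True
        fp = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="columns"):
            morph.detect_interface(mask, 0.01, footprint=fp)


class TestRois:
    def test_unit_conversion_superficial_slab(self):
        # 2.0 mm at 4 um voxels = 500 layers, starting 125 past the interface
        fp = np.ones((8, 8), bool)
        rois = morph.build_rois((800, 8, 8), interface_reference_mm=0.4,
                                specs=[morph.RoiSpec("superficial", 0.5, 2.0, 0.0)],
                                voxel_size_mm=0.004, footprint=fp)
        zs = np.where(rois["superficial"].any(axis=(1, 2)))[0]
        assert zs.size == 500
        assert zs[0] == 100 + 125  # interface layers + 0.5 mm offset

    def test_superficial_and_deep_disjoint_contiguous(self):
        fp = np.ones((10, 10), bool)
        rois = morph.build_rois((200, 10, 10), 0.0,
                                [morph.RoiSpec("superficial", 0.5, 2.0, 0.0),
                                 morph.RoiSpec("deep", 2.5, 2.0, 0.0)],
                                voxel_size_mm=0.05, footprint=fp)
        sup, deep = rois["superficial"], rois["deep"]
        assert not (sup & deep).any()
        zs = np.where(sup.any(axis=(1, 2)))[0]
        zd = np.where(deep.any(axis=(1, 2)))[0]
        assert zd[0] == zs[-1] + 1  # contiguous half-open intervals

    def test_edge_erosion_matches_distance_transform(self):
        from scipy.ndimage import distance_transform_edt
        yy, xx = np.mgrid[0:40, 0:40]
        fp = (yy - 20) ** 2 + (xx - 20) ** 2 <= 18**2
        rois = morph.build_rois((10, 40, 40), 0.0,
                                [morph.RoiSpec("total", 0.0, 0.0, 1.0)],
                                voxel_size_mm=0.1, footprint=fp)
        expected = distance_transform_edt(fp) * 0.1 >= 1.0
        assert np.array_equal(rois["total"][5], expected)

    def test_slab_past_volume_rejected(self):
        fp = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="mm"):
            morph.build_rois((30, 8, 8), 0.0,
                             [morph.RoiSpec("deep", 2.5, 2.0, 0.0)],
                             voxel_size_mm=0.05, footprint=fp)


class TestBvTvBmd:
    def test_all_bone_roi(self):
        vol = make_volume(np.full((10, 10, 10), 400.0))
        mask = np.ones((10, 10, 10), bool)
        bvtv, _ = morph.compute_bvtv_bmd(vol, mask, mask)
        assert bvtv == 1.0

    def test_350_of_1000_voxels(self):
        rng = np.random.default_rng(1)
        mask = np.zeros(1000, bool)
        mask[rng.choice(1000, 350, replace=False)] = True
        mask = mask.reshape(10, 10, 10)
        vol = make_volume(np.where(mask, 400.0, 0.0))
        roi = np.ones((10, 10, 10), bool)
        bvtv, _ = morph.compute_bvtv_bmd(vol, mask, roi)
        assert bvtv == pytest.approx(0.35, abs=1e-12)
        assert bvtv == mask.sum() / 1000  # brute-force recount

    def test_empty_roi_rejected(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            morph.compute_bvtv_bmd(vol, np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))


class TestBsa:
    def test_cube_within_3pct(self):
        vox = 0.008
        n = int(round(1.0 / vox))
        cube = np.zeros((n + 20,) * 3, bool)
        cube[10:10 + n, 10:10 + n, 10:10 + n] = True
        a = morph.compute_bsa(cube, np.ones_like(cube), vox)
        assert a == pytest.approx(6.0, rel=0.03)

    def test_sphere_within_3pct(self):
        vox = 0.008
        r_mm = 0.2
        sp = np.pad(ball(int(round(r_mm / vox))), 10).astype(bool)
        a = morph.compute_bsa(sp, np.ones_like(sp), vox)
        assert a == pytest.approx(4 * np.pi * r_mm**2, rel=0.03)

    def test_empty_mask_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            a = morph.compute_bsa(np.zeros((8, 8, 8), bool), np.ones((8, 8, 8), bool), 0.01)
        assert a == 0.0

    def test_voxel_face_counting_overestimates_sphere(self):
        vox = 0.008
        sp = np.pad(ball(25), 5).astype(bool)
        mesh = morph.compute_bsa(sp, np.ones_like(sp), vox)
        faces = morph.compute_bsa(sp, np.ones_like(sp), vox, method="voxel")
        assert faces > 1.3 * mesh  # ~1.5x for curved surfaces


class TestDamage:
    def test_eq1_eq2_arithmetic(self):
        # damaged 2 mm^3 of 100 mm^3 bone -> DBVF 0.02; /50 mm^2 -> 4e-4 mm^-2
        vox = 0.1  # 1000 voxels per mm^3 -> use counts directly
        n_bone, n_dam = 100_000, 2_000
        mask = np.zeros((50, 50, 50), bool)
        mask.flat[:n_bone] = True
        data = np.zeros((50, 50, 50), np.float32)
        data[mask] = 400.0
        dam_idx = np.flatnonzero(mask)[:n_dam]
        data.flat[dam_idx] = 650.0
        dbv, dbvf, adj = morph.quantify_damage(
            make_volume(data, 100.0), mask, np.ones_like(mask), vox, bsa=50.0)
        assert dbv == pytest.approx(2.0, rel=1e-9)
        assert dbvf == pytest.approx(0.02, rel=1e-12)
        assert adj == pytest.approx(0.0004, rel=1e-12)

    def test_no_label_zero_everywhere(self):
        mask = np.ones((8, 8, 8), bool)
        vol = make_volume(np.full((8, 8, 8), 400.0))
        dbv, dbvf, adj = morph.quantify_damage(vol, mask, mask, 0.05, bsa=10.0)
        assert dbv == dbvf == adj == 0.0

    def test_raising_threshold_never_increases_dbvf(self):
        rng = np.random.default_rng(3)
        vol = make_volume(rng.uniform(300, 800, (16, 16, 16)))
        mask = np.ones((16, 16, 16), bool)
        prev = 1.1
        for thr in (450.0, 550.0, 650.0, 750.0):
            _, dbvf, _ = morph.quantify_damage(vol, mask, mask, 0.05, label_threshold=thr, bsa=1.0)
            assert dbvf <= prev
            prev = dbvf

    def test_synthetic_surface_labels_recovered(self):
        vol, truth = generate_volume(shape=(80, 72, 72), voxel_size=60.0,
                                     target_bvtv=0.8, damage_fraction=0.03, seed=9)
        _, dbvf, _ = morph.quantify_damage(vol, truth.bone_mask, truth.damage_zone,
                                           vol.voxel_size_mm, bsa=None)
        assert dbvf == pytest.approx(0.03, abs=0.005)

    def test_bad_bsa_rejected(self):
        mask = np.ones((8, 8, 8), bool)
        vol = make_volume(np.full((8, 8, 8), 650.0))
        with pytest.raises(ValueError, match="BSA"):
            morph.quantify_damage(vol, mask, mask, 0.05, bsa=0.0)


class TestSurfaceGeometry:
    def _maps(self, ny=40, nx=40, depth=2.0, cart=0.5):
        fp = np.ones((ny, nx), bool)
        iface = np.full((ny, nx), depth)
        cartm = np.full((ny, nx), depth - cart)
        return iface, cartm, fp

    def test_flat_interface_90deg_zero_evenness(self):
        iface, cart, fp = self._maps()
        sm = morph.surface_geometry(iface, cart, fp, pixel_size_mm=0.1)
        assert sm.surface_angle_a == pytest.approx(90.0, abs=1e-9)
        assert sm.surface_angle_b == pytest.approx(90.0, abs=1e-9)
        assert sm.evenness_area_a == pytest.approx(0.0, abs=1e-9)
        assert sm.cartilage_thickness_a == pytest.approx(0.5, rel=1e-9)

    def test_circular_arc_evenness_matches_segment_area(self):
        # convex bump: depth dips by a circular arc of known sagitta
        ny = nx = 81
        px = 0.05
        fp = np.ones((ny, nx), bool)
        x = (np.arange(nx) - 40) * px
        r, half_chord = 10.0, 2.0
        sag = r - np.sqrt(r**2 - half_chord**2)
        bump = np.sqrt(np.clip(r**2 - x**2, 0, None)) - np.sqrt(r**2 - half_chord**2)
        bump = np.clip(bump, 0, None)  # nonzero only within the chord
        iface = 3.0 - bump[None, :].repeat(ny, axis=0)  # shallower = convex
        sm = morph.surface_geometry(iface, None, fp, pixel_size_mm=px)
        theta = np.arcsin(half_chord / r)
        segment = r**2 * theta - half_chord * (r - sag)
        assert sm.evenness_area_a == pytest.approx(segment, rel=0.02)
        assert sm.evenness_area_a > 0  # convex positive by convention

    def test_tilted_interface_angle(self):
        ny = nx = 20
        fp = np.ones((ny, nx), bool)
        px = 0.1
        x = np.arange(nx) * px
        iface = 1.0 + 0.2 * x[None, :].repeat(ny, axis=0)
        sm = morph.surface_geometry(iface, None, fp, pixel_size_mm=px)
        assert sm.surface_angle_a == pytest.approx(90.0 - np.degrees(np.arctan(0.2)), abs=0.2)

    def test_line_outside_footprint_rejected(self):
        iface, cart, fp = self._maps()
        fp[:] = False
        with pytest.raises(ValueError, match="footprint"):
            morph.surface_geometry(iface, cart, fp, pixel_size_mm=0.1)
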