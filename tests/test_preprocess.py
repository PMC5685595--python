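"""Stitching, post detection, registration, interface fit, segmentation."""

import numpy as np
import pytest
from skimage.transform import SimilarityTransform, warp

from sprouttrack.phantoms import (
    BranchSpec,
    PhantomSpec,
    default_post_positions,
    generate_vessel_mask,
    jitter_transform,
    render_microscopy,
    split_tiles,
)
from sprouttrack.preprocess import (
    GelRegion,
    decompose_about_center,
    detect_posts,
    fit_cell_gel_interface,
    register_to_reference,
    segment_vessels,
    stitch_tiles,
)


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec(
        image_size=(300, 400), monolayer_height=40,
        sprouts=[BranchSpec(points=[(180, 260), (170, 120), (160, 60)], radius=6)],
        seed=3,
    )
    mask, gt = generate_vessel_mask(spec)
    img = render_microscopy(mask, default_post_positions(spec.image_size), seed=1)
    return spec, mask, img


class TestStitching:
    def test_single_tile_unchanged(self):
        img = np.random.default_rng(0).uniform(0, 255, (60, 80))
        res = stitch_tiles([img])
        assert np.array_equal(res.mosaic, img)

    def test_two_tiles_offset_recovery(self, phantom):
        _, mask, _ = phantom
        big = render_microscopy(np.tile(mask, (1, 3)), default_post_positions((300, 1200)), seed=2)
        ts = split_tiles(big, 0.3, n_tiles=2)
        res = stitch_tiles(ts.tiles)
        rec_dx = res.offsets[1][0] - res.offsets[0][0]
        assert abs(rec_dx - (ts.offsets[1] - ts.offsets[0])) <= 1.0

    def test_three_tiles_mosaic_dimensions(self, phantom):
        _, mask, _ = phantom
        big = render_microscopy(np.tile(mask, (1, 3)), default_post_positions((300, 1200)), seed=2)
        ts = split_tiles(big, 0.3, n_tiles=3)
        res = stitch_tiles(ts.tiles)
        assert abs(res.mosaic.shape[1] - big.shape[1]) <= 2
        assert abs(res.mosaic.shape[0] - big.shape[0]) <= 2

    def test_restitched_overlap_intensity_error(self, phantom):
        _, mask, _ = phantom
        big = render_microscopy(np.tile(mask, (1, 3)), default_post_positions((300, 1200)), seed=2)
        ts = split_tiles(big, 0.3, n_tiles=3)
        res = stitch_tiles(ts.tiles)
        h = min(res.mosaic.shape[0], big.shape[0])
        w = min(res.mosaic.shape[1], big.shape[1])
        err = np.abs(res.mosaic[:h, :w] - big[:h, :w])
        assert np.mean(err) < 2.0

    def test_featureless_tiles_fail_with_diagnostic(self):
        flat = np.full((80, 80), 100.0)
        with pytest.raises(ValueError):
            stitch_tiles([flat, flat])


class TestPosts:
    def test_detected_at_known_positions(self, phantom):
        spec, _, img = phantom
        pm = detect_posts(img)
        ys = sorted(default_post_positions(spec.image_size))
        det_left = sorted(c[1] for c in pm.centroids if c[0] < 200)
        assert len(det_left) == 3
        assert np.allclose(det_left, ys, atol=3)
        # each post bounded by at least 2 detected edge lines
        assert len(pm.edge_lines) >= 2 * len(pm.centroids) / 2

    def test_rho_close_to_post_edge(self, phantom):
        spec, _, img = phantom
        pm = detect_posts(img)
        # some near-vertical line should sit near the left post face x=14
        vertical = [rho for rho, th in pm.edge_lines if abs(th) < 0.2 or abs(th - np.pi) < 0.2]
        assert any(abs(abs(r) - 14) <= 3 or abs(abs(r) - 30) <= 3 for r in vertical)

    def test_rotation_shifts_theta(self, phantom):
        spec, mask, _ = phantom
        # posts near mid-height so a 5 degree rotation keeps them in frame
        img = render_microscopy(mask, [120, 150, 180], seed=1)
        rot = warp(img, jitter_transform(0, 0, 5.0, 1.0, img.shape).inverse,
                   order=1, preserve_range=True, cval=100)
        pm0 = detect_posts(img)
        pm1 = detect_posts(rot)
        # the vertical post faces (theta ~ 0) tilt by the rotation angle
        v0 = np.mean([t for _, t in pm0.edge_lines if t < 0.3 or t > np.pi - 0.3])
        v1 = np.mean([min(t, np.pi - t) for _, t in pm1.edge_lines if t < 0.3 or t > np.pi - 0.3])
        assert abs((v1 - v0) - np.deg2rad(5)) <= np.deg2rad(1.5)

    def test_postfree_image_rejected(self):
        img = np.random.default_rng(0).normal(100, 10, (120, 160))
        with pytest.raises(ValueError):
            detect_posts(img)


class TestRegistration:
    def test_identity(self, phantom):
        _, _, img = phantom
        tf, aligned = register_to_reference(img, img)
        dx, dy, dth, sc = decompose_about_center(tf, img.shape)
        assert abs(dx) < 0.2 and abs(dy) < 0.2 and abs(dth) < 0.05 and abs(sc - 1) < 1e-3

    @pytest.mark.parametrize("jit", [(7, -3, 2.0, 1.0), (-5, 4, -1.2, 1.01)])
    def test_recovers_injected_jitter(self, phantom, jit):
        _, _, img = phantom
        dx, dy, dth, sc = jit
        jt = jitter_transform(dx, dy, dth, sc, img.shape)
        jimg = warp(img, jt.inverse, order=1, preserve_range=True, cval=0)
        tf, _ = register_to_reference(jimg, img)
        comp = tf.params @ jt.params      # should be ~identity
        center = np.array([img.shape[1] / 2, img.shape[0] / 2, 1.0])
        resid = comp @ center - center
        ang = np.degrees(np.arctan2(comp[1, 0], comp[0, 0]))
        assert np.abs(resid[:2]).max() <= 0.5
        assert abs(ang) <= 0.2

    def test_skeletons_overlay_after_registration(self, phantom):
        from sprouttrack.pipeline import register_and_segment
        from sprouttrack.skeletonize import SkelConfig, afmm_skeletonize

        _, _, img = phantom
        jt = jitter_transform(4, -5, 1.0, 1.0, img.shape)
        jimg = warp(img, jt.inverse, order=1, preserve_range=True, cval=0)
        masks = register_and_segment([img, jimg], erosion_radius=1)
        s0, _ = afmm_skeletonize(masks[0], SkelConfig(u_threshold=15))
        s1, _ = afmm_skeletonize(masks[1], SkelConfig(u_threshold=15))
        from scipy.spatial.distance import cdist

        d = cdist(np.argwhere(s0), np.argwhere(s1)).min(axis=1)
        assert np.median(d) <= 2.0


class TestInterface:
    def test_flat_interface(self, phantom):
        spec, _, img = phantom
        gel = fit_cell_gel_interface(img, monolayer_band=80)
        a, b, c = gel.parabola
        assert abs(a) < 1e-4
        assert abs(c - 260) <= 3

    def test_parabolic_interface_recovery(self):
        spec = PhantomSpec(image_size=(400, 400), monolayer_height=60,
                           interface_coeffs=(0.0005, -0.2, 360.0), sprouts=[])
        mask = np.zeros(spec.image_size, dtype=bool)
        from sprouttrack.phantoms import _monolayer_mask

        img = render_microscopy(_monolayer_mask(spec), seed=0)
        gel = fit_cell_gel_interface(img, monolayer_band=100)
        xs = np.arange(0, 400, 16)
        true_y = 0.0005 * xs**2 - 0.2 * xs + 360.0
        assert np.abs(gel.interface_y(xs) - true_y).max() <= 4.0

    def test_exact_points_exact_recovery(self):
        xs = np.arange(0, 200, dtype=float)
        ys = 0.002 * xs**2 - 0.3 * xs + 150.0
        coef = np.polyfit(xs, ys, 2)
        assert np.allclose(coef, [0.002, -0.3, 150.0], atol=1e-9)

    def test_fallback_on_empty_band(self):
        img = np.full((200, 150), 100.0)
        with pytest.warns(UserWarning):
            gel = fit_cell_gel_interface(img, monolayer_band=50)
        assert gel.parabola[0] == 0.0 and gel.parabola[2] == 150.0


class TestSegmentation:
    def test_noise_free_round_trip(self, phantom):
        spec, mask, _ = phantom
        img0 = render_microscopy(mask, default_post_positions(spec.image_size), seed=1, noise_sigma=0)
        pm = detect_posts(img0)
        gel = fit_cell_gel_interface(img0, monolayer_band=80, posts=pm)
        seg = segment_vessels(img0, gel, min_object_area=50, closing_radius=2,
                              erosion_radius=0, interface_margin=0)
        gelmask = gel.mask(img0.shape)
        truth = mask & gelmask
        mismatch = (seg ^ truth).sum()
        assert mismatch / truth.sum() < 0.06

    def test_speckles_removed(self, phantom):
        spec, mask, _ = phantom
        noisy = mask.copy()
        rng = np.random.default_rng(0)
        for _ in range(20):
            r, c = rng.integers(20, 200), rng.integers(20, 380)
            noisy[r:r + 3, c:c + 3] = True
        img = render_microscopy(noisy, default_post_positions(spec.image_size), seed=1, noise_sigma=0)
        gel = fit_cell_gel_interface(img, monolayer_band=80, posts=detect_posts(img))
        seg = segment_vessels(img, gel, min_object_area=50, erosion_radius=1)
        from scipy import ndimage

        lab, n = ndimage.label(seg, structure=np.ones((3, 3), dtype=int))
        assert n <= 2  # the vessel (possibly split at a post shadow), no speckles

    def test_empty_gel_yields_empty_mask(self):
        img = np.random.default_rng(0).normal(100, 1.0, (100, 100))
        gel = GelRegion(parabola=(0.0, 0.0, 80.0))
        with pytest.warns(UserWarning):
            seg = segment_vessels(img, gel)
        assert not seg.any()

    def test_idempotent_on_clean_binary(self, phantom):
        spec, mask, _ = phantom
        binary = np.where(mask, 200.0, 40.0)
        gel = GelRegion(parabola=(0.0, 0.0, 260.0))
        seg = segment_vessels(binary, gel, erosion_radius=0, closing_radius=0,
                              min_object_area=0, interface_margin=0)
        truth = mask & gel.mask(binary.shape)
        assert np.array_equal(seg, truth)
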