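"""Z-projection, warping, overlays and dihedral orientation enumeration."""

import numpy as np
import pytest

from cryoclem.geometry import Transform2D, compose_transforms, identity_transform, similarity_from_params
from cryoclem.projection import (
    ImagePlane,
    TomogramStack,
    compose_overlay,
    enumerate_orientations,
    match_orientation,
    warp_image,
    zproject,
)


def plane(pixels, px=1.0, frame="em", channel="EM"):
    return ImagePlane(pixels=np.asarray(pixels, dtype=float), pixel_size_nm=px, frame_id=frame, channel=channel)


class TestZProject:
    def test_single_slice_unchanged(self, rng):
        sl = rng.normal(size=(12, 17))
        out = zproject(TomogramStack(voxels=sl[None], voxel_size_nm=2.0), "min")
        assert np.array_equal(out.pixels, sl)
        assert out.pixel_size_nm == 2.0

    def test_constant_stack(self):
        stack = TomogramStack(voxels=np.full((4, 5, 6), 3.25), voxel_size_nm=1.0)
        for m in ("min", "mean", "max"):
            assert np.all(zproject(stack, m).pixels == 3.25)

    def test_min_projection_reveals_dark_spheres(self, rng):
        vol = np.full((7, 40, 40), 100.0)
        minima = {}
        for z in range(7):
            x, y = rng.integers(5, 35, 2)
            vol[z, y, x] = z  # darkest voxel of its column
            minima[(int(y), int(x))] = z
        proj = zproject(TomogramStack(voxels=vol, voxel_size_nm=1.0), "min").pixels
        for (y, x), v in minima.items():
            assert proj[y, x] == v

    def test_projection_order(self, rng):
        stack = TomogramStack(voxels=rng.normal(size=(5, 8, 9)), voxel_size_nm=1.0)
        lo = zproject(stack, "min").pixels
        mid = zproject(stack, "mean").pixels
        hi = zproject(stack, "max").pixels
        assert np.all(lo <= mid) and np.all(mid <= hi)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            zproject(TomogramStack(voxels=np.zeros((1, 4, 4)), voxel_size_nm=1.0), "median")


class TestWarp:
    def test_identity_is_pixel_identical(self, rng):
        src = plane(rng.normal(size=(20, 30)))
        out = warp_image(src, identity_transform("affine"), (20, 30))
        assert np.allclose(out.pixels, src.pixels, atol=1e-12)

    def test_integer_translation_matches_slicing(self, rng):
        img = rng.normal(size=(32, 32))
        t = Transform2D("translation", np.eye(2), [3, 5])  # +3 x (cols), +5 y (rows)
        out = warp_image(plane(img), t, (32, 32)).pixels
        assert np.allclose(out[5:, 3:], img[:-5, :-3], atol=1e-9)

    def test_warp_roundtrip_on_smooth_image(self, rng):
        ys, xs = np.mgrid[0:64, 0:64].astype(float)
        img = np.sin(xs / 9.0) + np.cos(ys / 7.0)  # band-limited
        t = similarity_from_params(12, 1.1, [3.2, -1.4])
        fwd = warp_image(plane(img), t, (64, 64))
        back = warp_image(fwd, t.inverse(), (64, 64))
        valid = back.metadata["valid_mask"] & fwd.metadata["valid_mask"]
        interior = np.zeros_like(valid)
        interior[10:-10, 10:-10] = True
        sel = valid & interior
        rng_dyn = img.max() - img.min()
        assert np.abs(back.pixels - img)[sel].max() <= 0.02 * rng_dyn

    def test_warp_commutes_with_composition(self, rng):
        ys, xs = np.mgrid[0:48, 0:48].astype(float)
        img = np.sin(xs / 8.0) * np.cos(ys / 6.0)
        a = similarity_from_params(8, 1.05, [1.0, 2.0])
        b = similarity_from_params(-5, 0.95, [-2.0, 0.5])
        two_step = warp_image(warp_image(plane(img), a, (48, 48)), b, (48, 48))
        one_step = warp_image(plane(img), compose_transforms(b, a), (48, 48))
        valid = two_step.metadata["valid_mask"] & one_step.metadata["valid_mask"]
        interior = np.zeros_like(valid)
        interior[8:-8, 8:-8] = True
        diff = np.abs(two_step.pixels - one_step.pixels)[valid & interior]
        assert diff.max() <= 0.05 * (img.max() - img.min())

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            Transform2D("affine", [[1, 0], [1, 0]], [0, 0])


class TestOverlay:
    def test_no_channels_gives_grayscale_base(self, rng):
        base = plane(rng.uniform(0, 100, (16, 16)))
        rgb = compose_overlay(base, [])
        norm = (base.pixels - base.pixels.min()) / np.ptp(base.pixels)
        for c in range(3):
            assert np.allclose(rgb[:, :, c], norm)

    def test_single_green_channel_adds_normalized_fm(self, rng):
        base = plane(np.zeros((16, 16)))
        fm = plane(rng.uniform(0, 50, (16, 16)), frame="fm", channel="psd95")
        rgb = compose_overlay(base, [(fm, identity_transform("affine"), "green")])
        norm = (fm.pixels - fm.pixels.min()) / np.ptp(fm.pixels)
        assert np.allclose(rgb[:, :, 1], np.clip(norm, 0, 1), atol=1e-9)
        assert np.allclose(rgb[:, :, 0], 0)

    def test_zero_intensity_channels_leave_base(self, rng):
        base = plane(rng.uniform(0, 100, (16, 16)))
        dark = plane(np.zeros((16, 16)), frame="fm")
        rgb0 = compose_overlay(base, [])
        rgb1 = compose_overlay(base, [(dark, identity_transform("affine"), "red")])
        assert np.allclose(rgb0, rgb1)

    def test_frame_mismatch_rejected(self, rng):
        base = plane(rng.uniform(0, 1, (8, 8)), frame="montage")
        fm = plane(rng.uniform(0, 1, (8, 8)), frame="fm")
        t = identity_transform("affine", source_frame="fm", target_frame="elsewhere")
        with pytest.raises(ValueError, match="frame"):
            compose_overlay(base, [(fm, t, "green")])

    def test_bead_overlay_peaks_on_dark_em_discs(self):
        from cryoclem.synthetic import SceneSpec, generate_scene, render_em, render_fm

        spec = SceneSpec(seed=21, noise_sigma=0.0, n_beads=9)
        man = generate_scene(spec)
        em = render_em(man, "montage")
        beads = render_fm(man, "beads")
        t = compose_transforms(man.fm_to_montage, man.channel_shift.inverse())
        rgb = compose_overlay(em, [(beads, t, "red")])
        red = rgb[:, :, 0] - rgb[:, :, 2]  # red excess over the gray base
        h = 70  # the warped FM spot is ~40 montage px wide; use its centroid
        for bx, by in man.beads_montage:
            y0, x0 = int(by) - h, int(bx) - h
            window = np.clip(red[y0 : y0 + 2 * h + 1, x0 : x0 + 2 * h + 1], 0, None)
            ys, xs = np.mgrid[0 : window.shape[0], 0 : window.shape[1]]
            cy = (window * ys).sum() / window.sum() + y0
            cx = (window * xs).sum() / window.sum() + x0
            assert abs(cx - bx) <= 1.0 and abs(cy - by) <= 1.0


class TestOrientations:
    def asym(self, rng):
        return plane(rng.normal(size=(12, 18)), frame="lm", channel="bf")

    def test_eight_variants_distinct_for_asymmetric_image(self, rng):
        variants = enumerate_orientations(self.asym(rng))
        assert len(variants) == 8
        arrays = [v.pixels for v, _ in variants]
        for i in range(8):
            for j in range(i + 1, 8):
                assert arrays[i].shape != arrays[j].shape or not np.allclose(arrays[i], arrays[j])

    def test_tagged_transform_reproduces_original(self, rng):
        lm = self.asym(rng)
        for variant, t in enumerate_orientations(lm):
            restored = warp_image(variant, t, lm.pixels.shape)
            assert np.allclose(restored.pixels, lm.pixels, atol=1e-9)

    def test_constant_image_variants_identical_with_distinct_tags(self):
        lm = plane(np.full((10, 10), 4.0), frame="lm")
        variants = enumerate_orientations(lm)
        tags = {v.metadata["orientation"] for v, _ in variants}
        assert len(tags) == 8
        for v, _ in variants:
            assert np.all(v.pixels == 4.0)

    def test_match_orientation_recovers_applied_rotation(self, rng):
        lm = plane(rng.normal(size=(24, 24)), frame="lm")
        variants = enumerate_orientations(lm)
        for true_idx in (0, 3, 5):
            em_ref = variants[true_idx][0]  # the EM view shows this orientation
            best, scores = match_orientation(lm, em_ref)
            assert best == true_idx
            assert scores[best] == pytest.approx(1.0, abs=1e-9)
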