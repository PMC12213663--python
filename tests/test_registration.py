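"""Control-point fitting, error metrics, matching and the correlation chain."""

import numpy as np
import pytest

from cryoclem.geometry import Correspondence, Point2D, PointSet, Transform2D, identity_transform, similarity_from_params
from cryoclem.registration import (
    DegenerateGeometryError,
    build_chain,
    estimate_channel_shift,
    estimate_transform,
    estimate_transform_robust,
    match_correspondences,
)


def corrs_from(src, dst, w=None):
    w = w if w is not None else np.ones(len(src))
    return [Correspondence(Point2D(*s), Point2D(*d), wi) for s, d, wi in zip(src, dst, w)]


class TestEstimateTransform:
    def test_identity_correspondences(self, rng):
        pts = rng.uniform(0, 50, (8, 2))
        res = estimate_transform(corrs_from(pts, pts), "similarity")
        assert res.fre_rms_px == pytest.approx(0, abs=1e-12)
        assert np.allclose(res.transform.matrix, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("model", ["translation", "rigid", "similarity", "affine"])
    def test_exact_recovery_all_models(self, model, rng):
        if model == "affine":
            truth = Transform2D("affine", [[1.1, 0.3], [-0.2, 0.9]], [4, -2])
        elif model == "translation":
            truth = Transform2D("translation", np.eye(2), [3.5, -1.25])
        else:
            truth = Transform2D(model, similarity_from_params(30, 1.2 if model == "similarity" else 1.0).matrix, [10, -4])
        src = rng.uniform(-40, 40, (10, 2))
        res = estimate_transform(corrs_from(src, truth.apply(src)), model)
        assert np.abs(res.transform.matrix - truth.matrix).max() < 1e-9
        assert np.abs(res.transform.offset - truth.offset).max() < 1e-9
        assert res.fre_rms_px < 1e-9

    def test_reflected_similarity_recovered(self, rng):
        truth = similarity_from_params(-70, 2.5, [1, 2], reflect=True)
        src = rng.uniform(-30, 30, (6, 2))
        res = estimate_transform(corrs_from(src, truth.apply(src)), "similarity")
        assert res.transform.is_reflecting
        assert res.fre_rms_px < 1e-9

    def test_fre_equals_rms_of_residual_norms(self, rng):
        src = rng.uniform(0, 50, (9, 2))
        dst = src + rng.normal(0, 1, (9, 2))
        res = estimate_transform(corrs_from(src, dst), "similarity")
        rms = np.sqrt(np.mean(np.sum(res.residuals_px**2, axis=1)))
        assert res.fre_rms_px == pytest.approx(rms, abs=1e-9)

    def test_collinear_points_affine_raises(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            estimate_transform(corrs_from(src, src + 1), "affine")

    def test_too_few_points_names_minimum(self):
        with pytest.raises(ValueError, match="3"):
            estimate_transform(corrs_from([[0, 0], [1, 0]], [[0, 0], [1, 0]]), "affine")

    def test_weighted_fit_downweights_outlier(self, rng):
        truth = similarity_from_params(15, 1.1, [2, 3])
        src = rng.uniform(0, 50, (10, 2))
        dst = truth.apply(src)
        dst[0] += 40.0
        w = np.ones(10)
        w[0] = 0.0
        res = estimate_transform(corrs_from(src, dst, w), "similarity")
        assert np.abs(res.transform.matrix - truth.matrix).max() < 1e-9

    def test_fre_invariant_under_rigid_target_change(self, rng):
        src = rng.uniform(0, 50, (8, 2))
        dst = src + rng.normal(0, 0.8, (8, 2))
        fre0 = estimate_transform(corrs_from(src, dst), "similarity").fre_rms_px
        rig = similarity_from_params(57, 1.0, [12, -9])
        fre1 = estimate_transform(corrs_from(src, rig.apply(dst)), "similarity").fre_rms_px
        assert fre1 == pytest.approx(fre0, abs=1e-9)

    def test_mean_loo_tre_exceeds_fre_on_noisy_data(self, rng):
        # prediction error at a held-out point is pessimistic relative to FRE
        n_rep, n = 300, 6
        diffs = []
        for _ in range(n_rep):
            truth = similarity_from_params(rng.uniform(-90, 90), rng.uniform(0.5, 2), rng.uniform(-5, 5, 2))
            src = rng.uniform(-30, 30, (n, 2))
            dst = truth.apply(src) + rng.normal(0, 0.5, (n, 2))
            res = estimate_transform(corrs_from(src, dst), "similarity")
            diffs.append(res.mean_loo_tre_px - res.fre_rms_px)
        assert np.mean(diffs) > 0

    def test_fre_grows_linearly_with_noise(self, rng):
        n = 8
        slope_expected = np.sqrt(2 * (1 - 2.0 / n))
        sigmas = np.array([0.1, 0.5, 1.0, 2.0])
        means = []
        for sigma in sigmas:
            fres = []
            for _ in range(400):
                truth = similarity_from_params(rng.uniform(-90, 90), 1.0, [0, 0])
                src = rng.uniform(-30, 30, (n, 2))
                dst = truth.apply(src) + rng.normal(0, sigma, (n, 2))
                fres.append(estimate_transform(corrs_from(src, dst), "similarity", compute_loo=False).fre_rms_px)
            means.append(np.mean(fres))
        slope = np.polyfit(sigmas, means, 1)[0]
        assert abs(slope - slope_expected) / slope_expected < 0.1


class TestChannelShift:
    def test_identical_channels_give_identity(self, rng):
        pts = rng.uniform(0, 256, (10, 2))
        ref = PointSet(points=pts, frame_id="green")
        mov = PointSet(points=pts.copy(), frame_id="red")
        res = estimate_channel_shift(ref, mov)
        assert res.fre_rms_px == pytest.approx(0, abs=1e-9)
        assert np.allclose(res.transform.matrix, np.eye(2), atol=1e-12)

    def test_shift_with_scale_recovered_across_field(self, rng):
        # chromatic shift: (1.7, -2.3) px offset plus 1% magnification difference
        truth = Transform2D("affine", 1.01 * np.eye(2), [1.7, -2.3])
        beads = rng.uniform(10, 500, (20, 2))
        mov = truth.inverse().apply(beads)  # moving channel sees shrunk/shifted positions
        res = estimate_channel_shift(
            PointSet(points=beads, frame_id="green"), PointSet(points=mov, frame_id="red")
        )
        probe = rng.uniform(10, 500, (100, 2))
        err = np.linalg.norm(res.transform.apply(truth.inverse().apply(probe)) - probe, axis=1)
        assert err.max() < 0.02

    def test_mismatched_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="equal counts"):
            estimate_channel_shift(
                PointSet(points=rng.uniform(0, 9, (5, 2)), frame_id="a"),
                PointSet(points=rng.uniform(0, 9, (4, 2)), frame_id="b"),
            )

    def test_collinear_beads_affine_degenerate(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0) * 2])
        with pytest.raises(DegenerateGeometryError):
            estimate_channel_shift(
                PointSet(points=pts, frame_id="a"), PointSet(points=pts + 1, frame_id="b")
            )


class TestMatching:
    def test_identical_sets_identity_initial(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        corrs = match_correspondences(list(pts), list(pts), identity_transform(), 1.0)
        assert len(corrs) == 10
        for c in corrs:
            assert c.source == c.target

    def test_true_pairs_found_among_spurious(self, rng):
        # 12 true markers + 4 spurious per side under an unknown similarity
        truth = similarity_from_params(24, 6.5, [300, -40])
        true_src = rng.uniform(10, 90, (12, 2))
        spur_src = rng.uniform(10, 90, (4, 2))
        true_dst = truth.apply(true_src)
        spur_dst = rng.uniform(*sorted(true_dst.ravel()[[0, -1]]), (4, 2))
        src = np.vstack([true_src, spur_src])
        dst = np.vstack([true_dst, spur_dst])
        corrs = match_correspondences(list(src), list(dst), None, 3.0)
        found = {(c.source.x, c.source.y, c.target.x, c.target.y) for c in corrs}
        expected = {(s[0], s[1], d[0], d[1]) for s, d in zip(true_src, true_dst)}
        assert expected <= found
        assert len(found) <= 13  # at most one coincidental extra

    def test_unequal_set_sizes_bound_matching(self, rng):
        truth = similarity_from_params(-8, 2.0, [5, 5])
        src = rng.uniform(0, 80, (8, 2))
        dst = truth.apply(np.vstack([src, rng.uniform(0, 80, (7, 2))]))
        corrs = match_correspondences(list(src), list(dst), None, 2.0)
        assert len(corrs) <= 8

    def test_reflected_alignment_found(self, rng):
        truth = similarity_from_params(40, 3.0, [50, 80], reflect=True)
        src = rng.uniform(0, 60, (9, 2))
        corrs = match_correspondences(list(src), list(truth.apply(src)), None, 2.0)
        assert len(corrs) == 9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            match_correspondences([], [(0, 0)], None, 1.0)

    def test_no_alignment_raises(self, rng):
        src = rng.uniform(0, 10, (5, 2))
        dst = rng.uniform(1000, 1010, (5, 2))
        with pytest.raises(ValueError):
            match_correspondences(list(src), list(dst), identity_transform(), 0.5)


class TestRobust:
    def test_all_inliers_matches_plain_fit(self, rng):
        truth = similarity_from_params(12, 0.8, [3, 3])
        src = rng.uniform(0, 60, (10, 2))
        corrs = corrs_from(src, truth.apply(src))
        plain = estimate_transform(corrs, "similarity")
        robust = estimate_transform_robust(corrs, "similarity", inlier_threshold_px=2.0, seed=5)
        assert np.abs(plain.transform.matrix - robust.transform.matrix).max() < 1e-9
        assert robust.inlier_mask.all()

    def test_gross_outliers_rejected(self, rng):
        truth = similarity_from_params(-33, 1.4, [7, -2])
        src = rng.uniform(0, 80, (12, 2))
        dst = truth.apply(src)
        dst[[2, 5, 9]] += 50.0
        corrs = corrs_from(src, dst)
        robust = estimate_transform_robust(corrs, "similarity", inlier_threshold_px=2.0, seed=7)
        ref = estimate_transform([c for i, c in enumerate(corrs) if i not in (2, 5, 9)], "similarity")
        assert np.abs(robust.transform.matrix - ref.transform.matrix).max() < 1e-6
        assert sorted(np.nonzero(~robust.inlier_mask)[0]) == [2, 5, 9]

    def test_reproducible_for_fixed_seed(self, rng):
        src = rng.uniform(0, 80, (10, 2))
        dst = src + rng.normal(0, 1.0, (10, 2))
        corrs = corrs_from(src, dst)
        a = estimate_transform_robust(corrs, "similarity", inlier_threshold_px=2.0, seed=11)
        b = estimate_transform_robust(corrs, "similarity", inlier_threshold_px=2.0, seed=11)
        assert np.array_equal(a.inlier_mask, b.inlier_mask)
        assert np.allclose(a.transform.matrix, b.transform.matrix)

    def test_consensus_impossible_raises(self):
        src = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        dst = src.copy()
        dst[[0, 1, 2]] += [[50, 3], [-40, 60], [33, -71]]
        with pytest.raises(ValueError, match="consensus"):
            estimate_transform_robust(corrs_from(src, dst), "similarity", inlier_threshold_px=1.0, seed=3)


class TestChain:
    def make_result(self, t, rng, n=6):
        src = rng.uniform(0, 50, (n, 2))
        return estimate_transform(corrs_from(src, t.apply(src)), "similarity",
                                  source_frame=t.source_frame, target_frame=t.target_frame)

    def test_identity_stages_compose_to_identity(self, rng):
        coarse = self.make_result(identity_transform("similarity", source_frame="fm", target_frame="montage"), rng)
        fine = self.make_result(identity_transform("similarity", source_frame="montage", target_frame="tomo"), rng)
        chain = build_chain(identity_transform("affine"), coarse, fine)
        assert np.allclose(chain.fm_to_tomogram.matrix, np.eye(2), atol=1e-9)
        assert np.allclose(chain.fm_to_tomogram.offset, 0, atol=1e-9)

    def test_composition_matches_pointwise(self, rng):
        t1 = similarity_from_params(10, 40, [800, 700], source_frame="fm", target_frame="montage")
        t2 = similarity_from_params(-5, 7.36, [-4000, -3500], source_frame="montage", target_frame="tomo")
        chain = build_chain(identity_transform("affine"), self.make_result(t1, rng), self.make_result(t2, rng))
        probes = rng.uniform(0, 200, (20, 2))
        direct = t2.apply(t1.apply(probes))
        assert np.abs(chain.fm_to_tomogram.apply(probes) - direct).max() < 1e-6

    def test_frame_mismatch_raises(self, rng):
        coarse = self.make_result(identity_transform("similarity", source_frame="fm", target_frame="montage"), rng)
        fine = self.make_result(identity_transform("similarity", source_frame="other", target_frame="tomo"), rng)
        with pytest.raises(ValueError, match="chainable"):
            build_chain(identity_transform("affine"), coarse, fine)

    def test_predicted_error_propagates_fine_scale(self, rng):
        t1 = similarity_from_params(0, 1.0, [0, 0], source_frame="fm", target_frame="montage")
        t2 = similarity_from_params(0, 10.0, [0, 0], source_frame="montage", target_frame="tomo")
        src = rng.uniform(0, 50, (8, 2))
        coarse = estimate_transform(
            corrs_from(src, t1.apply(src) + rng.normal(0, 0.5, (8, 2))), "similarity",
            source_frame="fm", target_frame="montage",
        )
        fine = self.make_result(t2, rng, n=8)
        chain = build_chain(identity_transform("affine"), coarse, fine)
        # coarse TRE enters the prediction magnified by the fine-stage scale
        assert chain.predicted_error_px >= 10.0 * coarse.mean_loo_tre_px * 0.999
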