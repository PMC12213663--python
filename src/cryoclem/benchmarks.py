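"""Reproducible benchmark routines exercising the whole pipeline.

Each function generates its own synthetic inputs from an explicit seed, runs
the relevant operations, and returns a dict of measured quantities.  They
back both the acceptance test suite and the standalone acceptance script, so
the numbers reported in either place come from one code path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .detection import DetectionParams, detect_fiducials
from .geometry import Correspondence, Point2D, Transform2D, identity_transform, similarity_from_params
from .morphometry import (
    MembraneTrace,
    classify_vesicle_state,
    evaluate_synapse_criteria,
    measure_cleft_width,
)
from .projection import TomogramStack, zproject
from .registration import estimate_channel_shift, estimate_transform, estimate_transform_robust, match_correspondences, build_chain
from .synthetic import SceneSpec, generate_scene, generate_synapse_phantom, render_em, render_fm

__all__ = [
    "exact_recovery",
    "similarity_oracle_agreement",
    "fre_noise_law",
    "detection_performance",
    "robust_outlier_rejection",
    "end_to_end_noiseless",
    "end_to_end_statistical",
    "projection_oracle",
    "morphometry_analytics",
    "criteria_report_checks",
]


def _random_transform(rng: np.random.Generator, model: str) -> Transform2D:
    th = rng.uniform(-180, 180)
    t = rng.uniform(-50, 50, 2)
    if model == "translation":
        return Transform2D("translation", np.eye(2), t)
    if model == "rigid":
        return Transform2D("rigid", similarity_from_params(th, 1.0).matrix, t)
    if model == "similarity":
        s = rng.uniform(0.3, 3.0)
        refl = bool(rng.integers(0, 2))
        tt = similarity_from_params(th, s, t, reflect=refl)
        return tt
    # affine: well-conditioned random linear part
    while True:
        m = rng.uniform(-2, 2, (2, 2))
        sv = np.linalg.svd(m, compute_uv=False)
        if sv[-1] > 0.2:
            return Transform2D("affine", m, t)


def exact_recovery(seed: int, n_instances: int = 1000) -> dict:
    """Noiseless correspondences from a known transform, for every model.

    Returns the maximum parameter error (matrix and offset entries, relative
    to the truth's scale) and the maximum FRE across all instances.
    """
    rng = np.random.default_rng([seed, 1])
    max_param = 0.0
    max_fre = 0.0
    models = ("translation", "rigid", "similarity", "affine")
    for i in range(n_instances):
        model = models[i % 4]
        truth = _random_transform(rng, model)
        n = int(rng.integers(max(4, 3 + 1), 16))
        src = rng.uniform(-100, 100, (n, 2))
        dst = truth.apply(src)
        corrs = [Correspondence(Point2D(*s), Point2D(*d)) for s, d in zip(src, dst)]
        fit = estimate_transform(corrs, model, compute_loo=False)
        scale = max(1.0, np.abs(truth.matrix).max(), np.abs(truth.offset).max())
        err = max(
            np.abs(fit.transform.matrix - truth.matrix).max(),
            np.abs(fit.transform.offset - truth.offset).max(),
        ) / scale
        max_param = max(max_param, err)
        max_fre = max(max_fre, fit.fre_rms_px)
    return {"max_param_error": max_param, "max_fre_px": max_fre, "n": n_instances}


def _similarity_fre_iterative(src: np.ndarray, dst: np.ndarray) -> float:
    """Independent oracle: similarity fit by generic nonlinear least squares
    over (angle, log-scale, tx, ty), both orientations tried."""

    def residual(p, refl):
        th, ls, tx, ty = p
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        if refl:
            r = r @ np.diag([-1.0, 1.0])
        mapped = src @ (np.exp(ls) * r).T + np.array([tx, ty])
        return (mapped - dst).ravel()

    best = np.inf
    for refl in (False, True):
        sol = least_squares(residual, x0=[0.0, 0.0, 0.0, 0.0], args=(refl,), method="lm", xtol=1e-15, ftol=1e-15)
        fre = np.sqrt(np.mean(np.sum(sol.fun.reshape(-1, 2) ** 2, axis=1)))
        best = min(best, fre)
    return float(best)


def similarity_oracle_agreement(seed: int, n_instances: int = 1000) -> dict:
    """Closed-form similarity fit vs an iterative least-squares oracle.

    Noisy correspondences (so the optimum is non-trivial); returns the
    maximum |FRE_closed_form - FRE_iterative| over the instances.
    """
    rng = np.random.default_rng([seed, 2])
    max_diff = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 12))
        truth = _random_transform(rng, "similarity")
        src = rng.uniform(-50, 50, (n, 2))
        dst = truth.apply(src) + rng.normal(0, 1.0, (n, 2))
        corrs = [Correspondence(Point2D(*s), Point2D(*d)) for s, d in zip(src, dst)]
        fit = estimate_transform(corrs, "similarity", compute_loo=False)
        oracle = _similarity_fre_iterative(src, dst)
        max_diff = max(max_diff, abs(fit.fre_rms_px - oracle))
    return {"max_fre_diff_px": max_diff, "n": n_instances}


def fre_noise_law(seed: int, n_reps: int = 2000, n_points: int = 6, sigmas=(0.25, 0.5, 1.0)) -> dict:
    """Mean FRE_RMS of a similarity fit vs the analytic residual-dof law.

    With N correspondences, target-side iid Gaussian noise sigma and a
    4-parameter similarity fit, E[FRE_RMS] ~= sigma * sqrt(2 (1 - 2/N)).
    Returns the relative deviation per sigma and the worst case.
    """
    rng = np.random.default_rng([seed, 3])
    expected_factor = np.sqrt(2.0 * (1.0 - 2.0 / n_points))
    deviations = {}
    for sigma in sigmas:
        fres = np.empty(n_reps)
        for r in range(n_reps):
            truth = _random_transform(rng, "similarity")
            src = rng.uniform(-40, 40, (n_points, 2))
            dst = truth.apply(src) + rng.normal(0, sigma, (n_points, 2))
            corrs = [Correspondence(Point2D(*s), Point2D(*d)) for s, d in zip(src, dst)]
            fres[r] = estimate_transform(corrs, "similarity", compute_loo=False).fre_rms_px
        deviations[sigma] = abs(fres.mean() - sigma * expected_factor) / (sigma * expected_factor)
    return {
        "relative_deviation_per_sigma": deviations,
        "max_relative_deviation": max(deviations.values()),
        "n": n_reps,
    }


def detection_performance(seed: int, n_scenes: int = 500) -> dict:
    """Recall, localization RMS and false-positive rate at SNR 10.

    Each scene is a rendered fluorescence bead channel (12 beads, relative
    noise 0.1 at the peak, separations >= 2 apparent diameters).  A detection
    within 1 px of a truth position counts as that marker; anything else is a
    false positive.
    """
    n_true = 0
    n_found = 0
    n_false = 0
    n_pixels = 0
    sq_errs: list[float] = []
    for i in range(n_scenes):
        spec = SceneSpec(seed=int(seed * 1_000_003 + i) % (2**31), noise_sigma=0.1, n_beads=12)
        man = generate_scene(spec)
        plane = render_fm(man, "beads")
        n_pixels += plane.pixels.size
        params = DetectionParams(
            expected_diameter_nm=spec.bead_fm_diameter_nm, pixel_size_nm=spec.fm_pixel_nm
        )
        dets = detect_fiducials(plane.pixels, params)
        truth = man.beads_fm_beads
        n_true += len(truth)
        if not dets:
            continue
        centers = np.array([[d.center.x, d.center.y] for d in dets])
        dist, idx = cKDTree(truth).query(centers)
        matched = dist < 1.0
        n_false += int((~matched).sum())
        hit = set(idx[matched])
        n_found += len(hit)
        sq_errs.extend(dist[matched] ** 2)
    return {
        "recall": n_found / n_true,
        "localization_rms_px": float(np.sqrt(np.mean(sq_errs))) if sq_errs else float("nan"),
        "false_positives_per_million_px": 1e6 * n_false / n_pixels,
        "n": n_scenes,
    }


def robust_outlier_rejection(seed: int, n_trials: int = 500) -> dict:
    """RANSAC consensus vs the known-inlier fit with <= 30% gross outliers.

    Inliers follow the truth transform exactly; outliers are displaced ~50 px.
    Returns the maximum parameter difference between the robust fit and the
    fit on the true inliers only.
    """
    rng = np.random.default_rng([seed, 4])
    max_diff = 0.0
    for trial in range(n_trials):
        n = int(rng.integers(10, 16))
        n_out = int(rng.integers(1, int(0.3 * n) + 1))
        truth = _random_transform(rng, "similarity")
        src = rng.uniform(-60, 60, (n, 2))
        dst = truth.apply(src)
        out_idx = rng.choice(n, n_out, replace=False)
        for j in out_idx:
            ang = rng.uniform(0, 2 * np.pi)
            dst[j] += 50.0 * np.array([np.cos(ang), np.sin(ang)])
        corrs = [Correspondence(Point2D(*s), Point2D(*d)) for s, d in zip(src, dst)]
        robust = estimate_transform_robust(
            corrs, "similarity", inlier_threshold_px=2.0, seed=int(rng.integers(2**31)),
        )
        inlier_corrs = [c for j, c in enumerate(corrs) if j not in out_idx]
        ref = estimate_transform(inlier_corrs, "similarity", compute_loo=False)
        diff = max(
            np.abs(robust.transform.matrix - ref.transform.matrix).max(),
            np.abs(robust.transform.offset - ref.transform.offset).max(),
        )
        max_diff = max(max_diff, diff)
    return {"max_param_diff": max_diff, "n": n_trials}


def _run_rendered_pipeline(spec: SceneSpec) -> tuple[float, dict]:
    """detect -> match -> coarse -> fine -> chain on a fully rendered scene.

    Returns the worst probe-point error (tomogram px) and stage diagnostics.
    """
    man = generate_scene(spec)
    shift = estimate_channel_shift(
        man.point_set("calibration_ref"), man.point_set("calibration_moving")
    )  # fm_beads -> fm

    fm = render_fm(man, "beads")
    dets_fm = detect_fiducials(
        fm.pixels,
        DetectionParams(expected_diameter_nm=spec.bead_fm_diameter_nm, pixel_size_nm=spec.fm_pixel_nm),
    )
    fm_pts = [tuple(shift.transform.apply(np.array([d.center.x, d.center.y]))) for d in dets_fm]

    em = render_em(man, "montage")
    dets_mb = detect_fiducials(
        em.pixels,
        DetectionParams(expected_diameter_nm=spec.bead_diameter_nm, pixel_size_nm=spec.montage_pixel_nm, polarity="dark"),
    )
    coarse = estimate_transform(
        match_correspondences(fm_pts, dets_mb, None, 10.0),
        "similarity", source_frame="fm", target_frame="montage",
    )

    dets_mg = detect_fiducials(
        em.pixels,
        DetectionParams(
            expected_diameter_nm=spec.gold50_diameter_nm, pixel_size_nm=spec.montage_pixel_nm,
            polarity="dark", threshold=0.5,
        ),
    )
    tp = render_em(man, "tomo_projection")
    dets_tg = detect_fiducials(
        tp.pixels,
        DetectionParams(expected_diameter_nm=spec.gold50_diameter_nm, pixel_size_nm=spec.tomo_pixel_nm, polarity="dark"),
    )
    fine = estimate_transform(
        match_correspondences(dets_mg, dets_tg, None, 15.0),
        "similarity", source_frame="montage", target_frame="tomo_projection",
    )

    chain = build_chain(identity_transform("affine", source_frame="fm", target_frame="fm"), coarse, fine)
    mapped = chain.fm_to_tomogram.apply(man.puncta_fm)
    err = float(np.linalg.norm(np.atleast_2d(mapped) - man.puncta_tomo, axis=1).max())
    diag = {
        "coarse_n": coarse.n_points,
        "coarse_fre_px": coarse.fre_rms_px,
        "fine_n": fine.n_points,
        "fine_fre_px": fine.fre_rms_px,
    }
    return err, diag


def end_to_end_noiseless(seed: int) -> dict:
    """Full rendered pipeline on a noiseless scene: probe error in tomo px."""
    err, diag = _run_rendered_pipeline(SceneSpec(seed=seed, noise_sigma=0.0))
    return {"probe_error_tomo_px": err, "n": 1, **diag}


def end_to_end_statistical(seed: int, n_scenes: int = 500, sigma_px: float = 0.5) -> dict:
    """Statistical closure with picking noise at each registration stage.

    Each stage's correspondences are perturbed by iid Gaussian noise of
    ``sigma_px`` pixels in that stage's registration (target) frame — montage
    pixels for the coarse bead stage, tomogram-projection pixels for the fine
    gold stage — modeling the marker-picking error in the frame where each
    transform is fitted.  Reports the fraction of scenes whose probe-point
    error stays within 50 nm (the fine marker's size) and the 95th-percentile
    error in nm.
    """
    errors_nm = np.empty(n_scenes)
    for i in range(n_scenes):
        s = int(seed * 2_000_003 + i) % (2**31)
        spec = SceneSpec(seed=s)
        man = generate_scene(spec)
        rng = np.random.default_rng([s, 99])

        beads_mont = man.beads_montage + rng.normal(0, sigma_px, man.beads_montage.shape)
        corrs_c = [
            Correspondence(Point2D(*a), Point2D(*b))
            for a, b in zip(man.beads_fm, beads_mont)
        ]
        coarse = estimate_transform(corrs_c, "similarity", source_frame="fm", target_frame="montage")

        gold_tomo = man.gold50_tomo + rng.normal(0, sigma_px, man.gold50_tomo.shape)
        corrs_f = [
            Correspondence(Point2D(*a), Point2D(*b))
            for a, b in zip(man.gold50_montage, gold_tomo)
        ]
        fine = estimate_transform(corrs_f, "similarity", source_frame="montage", target_frame="tomo_projection")

        chain = build_chain(identity_transform("affine", source_frame="fm", target_frame="fm"), coarse, fine)
        mapped = np.atleast_2d(chain.fm_to_tomogram.apply(man.puncta_fm))
        err_px = np.linalg.norm(mapped - man.puncta_tomo, axis=1).max()
        errors_nm[i] = err_px * spec.tomo_pixel_nm
    within = float(np.mean(errors_nm <= 50.0))
    return {
        "fraction_within_50nm": within,
        "p95_error_nm": float(np.percentile(errors_nm, 95)),
        "median_error_nm": float(np.median(errors_nm)),
        "n": n_scenes,
    }


def projection_oracle(seed: int, n_stacks: int = 20) -> dict:
    """min/mean/max z-projections vs a naive per-pixel Python loop."""
    rng = np.random.default_rng([seed, 5])
    max_diff = 0.0
    for _ in range(n_stacks):
        nz, ny, nx = rng.integers(2, 9), rng.integers(4, 17), rng.integers(4, 17)
        vol = rng.normal(0, 1, (nz, ny, nx))
        stack = TomogramStack(voxels=vol, voxel_size_nm=1.0)
        for method, red in (("min", min), ("mean", lambda v: sum(v) / len(v)), ("max", max)):
            proj = zproject(stack, method).pixels
            for y in range(ny):
                for x in range(nx):
                    ref = red([float(vol[z, y, x]) for z in range(nz)])
                    max_diff = max(max_diff, abs(proj[y, x] - ref))
    return {"max_abs_diff": max_diff, "n": n_stacks}


def morphometry_analytics(seed: int, n_phantoms: int = 200) -> dict:
    """Cleft-width phantoms and vesicle-state classification vs truth.

    Parallel lines 20 nm apart (width exactly 20, cv 0); concentric arcs
    (analytic width = radius difference); generator phantoms with a known
    state mix, classified and compared label-by-label.
    """
    # parallel-line phantom
    x = np.arange(0.0, 400.0, 2.0)
    pre = MembraneTrace(np.column_stack([x, np.zeros_like(x)]), 1.0, "presynaptic")
    post = MembraneTrace(np.column_stack([x, np.full_like(x, 20.0)]), 1.0, "postsynaptic")
    prof_par = measure_cleft_width(pre, post, step_nm=2.0)

    # concentric arcs, radii 200 / 220 nm (analytic width 20 nm)
    th_pre = np.linspace(0.2, np.pi - 0.2, 20001)
    th_post = np.linspace(0.1, np.pi - 0.1, 22001)
    arc_pre = MembraneTrace(
        200.0 * np.column_stack([np.cos(th_pre), np.sin(th_pre)]), 1.0, "presynaptic"
    )
    arc_post = MembraneTrace(
        220.0 * np.column_stack([np.cos(th_post), np.sin(th_post)]), 1.0, "postsynaptic"
    )
    prof_arc = measure_cleft_width(arc_pre, arc_post, step_nm=2.0)
    arc_err = float(np.abs(prof_arc.widths_nm - 20.0).max())

    # state-mix classification agreement
    n_total = 0
    n_agree = 0
    mean_errs = []
    sd_errs = []
    for i in range(n_phantoms):
        s = int(seed * 3_000_017 + i) % (2**31)
        mix = {"docked_or_primed": 2, "tethered_candidate": 3, "fusing": 1, "fully_fused": 1}
        ann, truth = generate_synapse_phantom(
            s, width_nm=20.0, width_jitter_sd=2.0, n_vesicles=20, state_mix=mix
        )
        pre_m = ann.membrane("presynaptic")
        for v, lab in zip(ann.vesicles, truth["labels"]):
            n_total += 1
            n_agree += classify_vesicle_state(v, pre_m, pixel_size_nm=ann.pixel_size_nm) == lab
        prof = measure_cleft_width(pre_m, ann.membrane("postsynaptic"), step_nm=2.0)
        mean_errs.append(abs(prof.mean_nm - 20.0))
        sd_errs.append(abs(prof.sd_nm - 2.0) / 2.0)
    return {
        "parallel_mean_nm": prof_par.mean_nm,
        "parallel_cv": prof_par.cv,
        "arc_max_width_error_nm": arc_err,
        "state_agreement": n_agree / n_total,
        "jitter_phantom_max_mean_error_nm": float(np.max(mean_errs)),
        "jitter_phantom_max_sd_rel_error": float(np.max(sd_errs)),
        "n": n_phantoms,
    }


def criteria_report_checks(seed: int) -> dict:
    """The canonical phantom passes all three criteria; degenerate ones fail."""
    ann, _ = generate_synapse_phantom(
        seed, width_nm=20.0, width_jitter_sd=1.0, n_vesicles=30,
        state_mix={"tethered_candidate": 3},
    )
    pre, post = ann.membrane("presynaptic"), ann.membrane("postsynaptic")
    profile = measure_cleft_width(pre, post, step_nm=2.0)
    canonical = evaluate_synapse_criteria(ann, profile)

    # degenerate: single membrane, no vesicles
    from .morphometry import SynapseAnnotation

    lone = SynapseAnnotation(membranes=[pre], vesicles=[], pixel_size_nm=ann.pixel_size_nm)
    single = evaluate_synapse_criteria(lone, None)

    # degenerate: 40 nm cleft
    ann40, _ = generate_synapse_phantom(
        seed + 1, width_nm=40.0, width_jitter_sd=1.0, n_vesicles=30,
        state_mix={"tethered_candidate": 3},
    )
    prof40 = measure_cleft_width(
        ann40.membrane("presynaptic"), ann40.membrane("postsynaptic"), step_nm=2.0
    )
    wide = evaluate_synapse_criteria(ann40, prof40)

    return {
        "canonical_all_pass": canonical.all_pass,
        "single_membrane_c1": single.c1_opposed_membranes,
        "wide_cleft_c3": wide.c3_uniform_cleft,
        "wide_cleft_c1": wide.c1_opposed_membranes,
        "wide_cleft_c2": wide.c2_attached_vesicle,
        "n": 1,
    }
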