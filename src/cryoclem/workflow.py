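"""End-to-end correlation workflow: detect -> channel shift -> coarse -> fine -> chain.

Mirrors the three-step procedure of a cryo-CLEM session: fluorescence
imaging, EM acquisition at the positions of interest, and multi-scale
correlation of the two.  The workflow is configured by a single
:class:`RunConfig` (YAML/JSON file or dict; CLI flags override), runs each
stage with stage-scoped logging, and writes a machine-readable report that —
together with the config hash and seed it embeds — suffices to reproduce the
run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .detection import DetectionParams, detect_fiducials
from .geometry import PointSet, Transform2D, identity_transform
from .io import read_image, read_points, write_image
from .projection import ImagePlane, TomogramStack, compose_overlay, zproject
from .registration import (
    RegistrationResult,
    build_chain,
    estimate_channel_shift,
    estimate_transform,
    estimate_transform_robust,
    match_correspondences,
)

__all__ = ["RunConfig", "StageError", "run_workflow"]

logger = logging.getLogger("cryoclem")


class StageError(RuntimeError):
    """A workflow stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


@dataclass
class StageDetection:
    """Detector settings for one image; ``enabled=False`` forces picked CSVs."""

    enabled: bool = True
    expected_diameter_nm: float = 400.0
    polarity: str = "bright"
    threshold: float = 0.3


@dataclass
class RunConfig:
    """All inputs, parameters and outputs of one correlation run.

    Point CSVs, when given, take precedence over the detector for that
    stage (the manual-picking path); image paths are then optional.
    """

    seed: int = 0
    out_dir: str = "correlation_out"
    verbosity: str = "info"

    # images
    fm_signal_image: str | None = None
    fm_bead_image: str | None = None
    montage_image: str | None = None
    tomo_projection_image: str | None = None
    tomogram_volume: str | None = None  # projected if no projection image given
    projection_method: str = "min"

    # pixel sizes (nm/px) for detection, overriding file metadata when set
    fm_pixel_nm: float | None = None
    montage_pixel_nm: float | None = None
    tomo_pixel_nm: float | None = None

    # channel shift
    calibration_ref_points: str | None = None
    calibration_moving_points: str | None = None
    channel_shift_model: str = "affine"

    # coarse stage (200 nm beads, FM -> montage)
    coarse_fm_points: str | None = None
    coarse_em_points: str | None = None
    coarse_model: str = "similarity"
    coarse_detect_fm: StageDetection = field(default_factory=lambda: StageDetection(expected_diameter_nm=400.0))
    coarse_detect_em: StageDetection = field(
        default_factory=lambda: StageDetection(expected_diameter_nm=200.0, polarity="dark")
    )
    coarse_max_dist_px: float = 10.0

    # fine stage (50 nm gold, montage -> tomogram projection)
    fine_em_points: str | None = None
    fine_tomo_points: str | None = None
    fine_model: str = "similarity"
    # threshold 0.5: suppresses the edge responses of the much larger beads,
    # which score below ~0.4 of a true gold particle at the gold scale
    fine_detect_em: StageDetection = field(
        default_factory=lambda: StageDetection(expected_diameter_nm=50.0, polarity="dark", threshold=0.5)
    )
    fine_detect_tomo: StageDetection = field(
        default_factory=lambda: StageDetection(expected_diameter_nm=50.0, polarity="dark")
    )
    fine_max_dist_px: float = 15.0

    # robust estimation
    robust: bool = False
    robust_inlier_threshold_px: float = 3.0

    # probe points (signal-channel FM coordinates) to map into the tomogram
    probe_points: str | None = None
    probe_detect: StageDetection = field(default_factory=lambda: StageDetection(expected_diameter_nm=400.0))

    # overlay
    write_overlays: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in (
            "coarse_detect_fm", "coarse_detect_em", "fine_detect_em",
            "fine_detect_tomo", "probe_detect",
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = StageDetection(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(verbosity: str) -> None:
    level = {"quiet": logging.WARNING, "info": logging.INFO, "verbose": logging.DEBUG}.get(
        verbosity, logging.INFO
    )
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)


def _load_plane(path, pixel_nm, stage: str, frame_id: str) -> ImagePlane:
    try:
        obj = read_image(path, pixel_size_nm=pixel_nm, frame_id=frame_id)
    except Exception as exc:
        raise StageError(stage, f"cannot load image {path}: {exc}", "check the path and format")
    if not isinstance(obj, ImagePlane):
        raise StageError(stage, f"{path} is a volume, expected a 2D image")
    return obj


def _stage_points(
    csv_path, image_path, det: StageDetection, pixel_nm, stage: str, frame_id: str
) -> tuple[list, ImagePlane | None]:
    """Points for one side of a stage: picked CSV wins, else run the detector."""
    if csv_path:
        ps = read_points(csv_path)
        return list(ps.points), None
    if not det.enabled or image_path is None:
        raise StageError(
            stage,
            f"no picked points and no usable image for the {frame_id} side",
            "provide a points CSV or enable detection with an image",
        )
    plane = _load_plane(image_path, pixel_nm, stage, frame_id)
    params = DetectionParams(
        expected_diameter_nm=det.expected_diameter_nm,
        pixel_size_nm=plane.pixel_size_nm,
        polarity=det.polarity,
        threshold=det.threshold,
    )
    dets = detect_fiducials(plane.pixels, params)
    logger.info("[%s] detected %d markers in %s", stage, len(dets), frame_id)
    return dets, plane


def _fit_stage(
    source, target, model: str, max_dist: float, cfg: RunConfig, stage: str,
    source_frame: str, target_frame: str,
) -> RegistrationResult:
    try:
        corrs = match_correspondences(source, target, None, max_dist)
        logger.info("[%s] matched %d correspondences", stage, len(corrs))
        if cfg.robust:
            return estimate_transform_robust(
                corrs, model,
                inlier_threshold_px=cfg.robust_inlier_threshold_px,
                seed=cfg.seed, source_frame=source_frame, target_frame=target_frame,
            )
        return estimate_transform(corrs, model, source_frame=source_frame, target_frame=target_frame)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc), "check marker picks/detection parameters")


def run_workflow(config: RunConfig | dict) -> dict:
    """Execute the full correlation workflow and write its report.

    Returns the report dict (also written to ``<out_dir>/report.json``):
    all fitted transforms with FRE/TRE, the composed FM -> tomogram mapping,
    mapped probe points, the config hash and seed, and package versions.
    Any stage failure raises :class:`StageError` naming the stage.
    """
    cfg = RunConfig.from_dict(config) if isinstance(config, dict) else config
    _setup_logging(cfg.verbosity)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "stages": {},
    }

    # -- channel shift ----------------------------------------------------
    stage = "channel-shift"
    if cfg.calibration_ref_points and cfg.calibration_moving_points:
        try:
            ref = read_points(cfg.calibration_ref_points)
            mov = read_points(cfg.calibration_moving_points)
            shift_res = estimate_channel_shift(ref, mov, cfg.channel_shift_model)
        except Exception as exc:
            raise StageError(stage, str(exc), "check the calibration bead CSVs")
        fm_shift = shift_res.transform  # moving (bead channel) -> reference (signal)
        report["stages"][stage] = shift_res.to_dict()
        logger.info("[%s] FRE %.4f px over %d beads", stage, shift_res.fre_rms_px, shift_res.n_points)
    else:
        fm_shift = identity_transform("affine", source_frame="fm_beads", target_frame="fm")
        report["stages"][stage] = {"note": "no calibration points given; identity shift assumed"}
        logger.info("[%s] skipped (identity)", stage)

    # -- coarse stage ------------------------------------------------------
    stage = "coarse"
    fm_side, _ = _stage_points(
        cfg.coarse_fm_points, cfg.fm_bead_image, cfg.coarse_detect_fm, cfg.fm_pixel_nm, stage, "fm_beads"
    )
    em_side, montage_plane = _stage_points(
        cfg.coarse_em_points, cfg.montage_image, cfg.coarse_detect_em, cfg.montage_pixel_nm, stage, "montage"
    )
    # bead-channel coordinates -> signal-channel frame before fitting
    from .detection import FiducialDetection

    def _xy(items):
        return [it.center if isinstance(it, FiducialDetection) else it for it in items]

    fm_pts = [tuple(fm_shift.apply(np.asarray(p, dtype=float))) for p in _xy(fm_side)]
    coarse = _fit_stage(fm_pts, _xy(em_side), cfg.coarse_model, cfg.coarse_max_dist_px, cfg, stage, "fm", "montage")
    report["stages"][stage] = coarse.to_dict()
    logger.info("[%s] FRE %.3f px, n=%d", stage, coarse.fre_rms_px, coarse.n_points)

    # -- fine stage --------------------------------------------------------
    stage = "fine"
    tomo_proj_path = cfg.tomo_projection_image
    tomo_plane = None
    if tomo_proj_path is None and cfg.tomogram_volume and (
        cfg.fine_tomo_points is None or cfg.write_overlays
    ):
        try:
            vol = read_image(cfg.tomogram_volume, pixel_size_nm=cfg.tomo_pixel_nm)
        except Exception as exc:
            raise StageError(stage, f"cannot load tomogram {cfg.tomogram_volume}: {exc}")
        if isinstance(vol, TomogramStack):
            tomo_plane = zproject(vol, cfg.projection_method)
            proj_path = out / "tomo_projection.mrc"
            write_image(tomo_plane, proj_path)
            tomo_proj_path = str(proj_path)
            logger.info("[%s] z-projected tomogram (%s) -> %s", stage, cfg.projection_method, proj_path)
        else:
            tomo_proj_path = cfg.tomogram_volume

    em_side2, montage_plane2 = _stage_points(
        cfg.fine_em_points, cfg.montage_image, cfg.fine_detect_em, cfg.montage_pixel_nm, stage, "montage"
    )
    tomo_side, tomo_plane2 = _stage_points(
        cfg.fine_tomo_points, tomo_proj_path, cfg.fine_detect_tomo, cfg.tomo_pixel_nm, stage, "tomo_projection"
    )
    tomo_plane = tomo_plane or tomo_plane2
    fine = _fit_stage(
        _xy(em_side2), _xy(tomo_side), cfg.fine_model, cfg.fine_max_dist_px, cfg, stage,
        "montage", "tomo_projection",
    )
    report["stages"][stage] = fine.to_dict()
    logger.info("[%s] FRE %.3f px, n=%d", stage, fine.fre_rms_px, fine.n_points)

    # -- chain -------------------------------------------------------------
    stage = "chain"
    try:
        # build_chain expects the signal->bead-channel direction for bookkeeping;
        # we fitted the coarse stage in the signal frame, so the chain's shift is identity
        chain = build_chain(identity_transform("affine", source_frame="fm", target_frame="fm"), coarse, fine)
    except Exception as exc:
        raise StageError(stage, str(exc), "stage frames are inconsistent")
    report["fm_to_tomogram"] = chain.fm_to_tomogram.to_dict()
    report["channel_shift_moving_to_fm"] = fm_shift.to_dict()
    report["predicted_error_tomo_px"] = chain.predicted_error_px
    logger.info("[%s] composed FM->tomogram; predicted error %s px", stage, chain.predicted_error_px)

    # -- probe points ------------------------------------------------------
    stage = "probe"
    probe_fm: list = []
    if cfg.probe_points:
        probe_fm = [tuple(p) for p in read_points(cfg.probe_points).points]
    elif cfg.fm_signal_image and cfg.probe_detect.enabled:
        dets, _ = _stage_points(None, cfg.fm_signal_image, cfg.probe_detect, cfg.fm_pixel_nm, stage, "fm")
        probe_fm = [tuple(d.center) for d in dets]
    if probe_fm:
        mapped = chain.fm_to_tomogram.apply(np.asarray(probe_fm, dtype=float))
        report["probe_points_fm"] = [list(p) for p in probe_fm]
        report["probe_points_tomo"] = np.atleast_2d(mapped).tolist()
        logger.info("[%s] mapped %d probe points into the tomogram frame", stage, len(probe_fm))

    # -- overlay -----------------------------------------------------------
    stage = "overlay"
    if cfg.write_overlays and cfg.fm_signal_image and montage_plane is not None:
        try:
            import imageio.v3 as iio

            signal_plane = _load_plane(cfg.fm_signal_image, cfg.fm_pixel_nm, stage, "fm")
            t_sig = coarse.transform
            channels = [(signal_plane, t_sig, "green")]
            if cfg.fm_bead_image:
                bead_plane = _load_plane(cfg.fm_bead_image, cfg.fm_pixel_nm, stage, "fm_beads")
                channels.append((bead_plane, t_sig.compose(fm_shift), "red"))
            rgb = compose_overlay(montage_plane, channels)
            iio.imwrite(out / "overlay_montage.png", (rgb * 255).astype(np.uint8))
            if tomo_plane is not None:
                rgb_t = compose_overlay(
                    tomo_plane, [(signal_plane, chain.fm_to_tomogram, "green")]
                )
                iio.imwrite(out / "overlay_tomogram.png", (rgb_t * 255).astype(np.uint8))
            logger.info("[%s] wrote overlay images", stage)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc), "check images and transforms")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("report written to %s", out / "report.json")
    return report
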