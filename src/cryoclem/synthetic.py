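"""Ground-truth scene generator for the multi-scale correlation hierarchy.

Emulates the imaging chain of a cryo-CLEM experiment on neurons grown on an
EM grid: a two-channel cryo-fluorescence view (signal puncta + 200 nm dark
red beads), a middle-magnification EM montage of the same area, and a
high-magnification tomogram with its z-projection.  Three marker classes tie
the frames together — 200 nm beads (FM + montage), 50 nm gold (montage +
tomogram) and 10 nm gold (tomogram only, for tilt alignment) — with known
similarity transforms between frames and a known inter-channel chromatic
shift, so every registration, detection and morphometry operation can be
tested against exact truth.

Default conditions follow the emulated experiment: 8-15 beads, 6-15 gold
particles, tomogram pixel 0.5432 nm, FM pixel 160 nm (100x objective on a
16 um camera pixel; an assumption, the FM pixel size of such rigs is not
standardized), PSF FWHM 400 nm for a 0.8 NA air objective.  All randomness
flows from the single scene seed through named substreams; no global state.

The 3D tomogram stack is rendered at a binned voxel size (default 4x the
projection pixel, ~2.2 nm/voxel) so a 50 nm gold sphere fits in a modest
volume; the 2D projection frame used for fine correlation is rendered at the
full pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .geometry import PointSet, Transform2D, similarity_from_params
from .morphometry import MembraneTrace, SynapseAnnotation, Vesicle
from .projection import ImagePlane, TomogramStack

__all__ = [
    "SceneSpec",
    "SceneManifest",
    "generate_scene",
    "render_fm",
    "render_em",
    "render_tomogram",
    "generate_synapse_phantom",
]

# substream labels: every rng is default_rng([seed, _STREAM[name]])
_STREAM = {
    "placement": 0,
    "transforms": 1,
    "amplitudes": 2,
    "render_psd95": 3,
    "render_beads": 4,
    "render_montage": 5,
    "render_tomo_projection": 6,
    "render_tomogram": 7,
}

BEAD_RANGE = (8, 15)
GOLD50_RANGE = (6, 15)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``n_beads``/``n_gold50`` default to None, meaning they are drawn
    uniformly from the emulated experiment's ranges (8-15 beads, 6-15 gold);
    explicit values are validated against those ranges unless
    ``enforce_ranges`` is off (useful for stress tests).
    ``noise_sigma`` is the total relative noise at a bright marker peak
    (0 disables noise and background texture); the default 0.1 corresponds
    to SNR 10.
    """

    seed: int
    fm_pixel_nm: float = 160.0
    montage_pixel_nm: float = 4.0
    tomo_pixel_nm: float = 0.5432
    fm_shape: tuple[int, int] = (256, 256)
    montage_shape: tuple[int, int] = (1536, 1536)
    tomo_shape: tuple[int, int] = (1536, 1536)
    tomo_stack_bin: int = 4
    tomo_stack_slices: int = 32
    n_beads: int | None = None
    n_gold50: int | None = None
    n_gold10: int = 15
    n_puncta: int = 1
    bead_diameter_nm: float = 200.0
    gold50_diameter_nm: float = 50.0
    gold10_diameter_nm: float = 10.0
    psf_fwhm_nm: float = 400.0
    noise_sigma: float = 0.1
    fm_amplitude: float = 1000.0
    fm_background: float = 100.0
    em_background: float = 1000.0
    em_marker_depth: float = 600.0
    max_rotation_coarse_deg: float = 15.0
    max_rotation_fine_deg: float = 8.0
    channel_shift_max_px: float = 3.0
    channel_shift_scale_jitter: float = 0.01
    enforce_ranges: bool = True

    def __post_init__(self) -> None:
        for name in ("fm_pixel_nm", "montage_pixel_nm", "tomo_pixel_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.enforce_ranges:
            if self.n_beads is not None and not BEAD_RANGE[0] <= self.n_beads <= BEAD_RANGE[1]:
                raise ValueError(f"n_beads must lie in {BEAD_RANGE} (got {self.n_beads})")
            if self.n_gold50 is not None and not GOLD50_RANGE[0] <= self.n_gold50 <= GOLD50_RANGE[1]:
                raise ValueError(f"n_gold50 must lie in {GOLD50_RANGE} (got {self.n_gold50})")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    @property
    def psf_sigma_fm_px(self) -> float:
        return self.psf_fwhm_nm / 2.355 / self.fm_pixel_nm

    @property
    def bead_fm_diameter_nm(self) -> float:
        """Apparent bead size in FM: diffraction-limited spots cannot be
        smaller than the PSF."""
        return max(self.bead_diameter_nm, self.psf_fwhm_nm)


@dataclass
class SceneManifest:
    """Exact truth record of a generated scene (the oracle for every test).

    Marker positions are stored per frame; positions in linked frames are
    consistent with the true transforms to machine precision.
    """

    spec: SceneSpec
    # transforms (truth)
    channel_shift: Transform2D = None  # "fm" (signal) -> "fm_beads" frame
    fm_to_montage: Transform2D = None  # "fm" -> "montage"
    montage_to_tomo: Transform2D = None  # "montage" -> "tomo_projection"
    # marker truth, (N, 2) arrays of (x, y)
    beads_fm: np.ndarray = None
    beads_fm_beads: np.ndarray = None
    beads_montage: np.ndarray = None
    gold50_tomo: np.ndarray = None
    gold50_montage: np.ndarray = None
    gold10_tomo: np.ndarray = None
    puncta_fm: np.ndarray = None
    puncta_tomo: np.ndarray = None
    # channel-shift calibration field (multicolor beads spanning the FM frame)
    calibration_ref: np.ndarray = None
    calibration_moving: np.ndarray = None
    # per-marker render attributes (fixed at generation time for determinism)
    bead_amplitudes: np.ndarray = None
    punctum_amplitudes: np.ndarray = None
    bead_depths: np.ndarray = None
    gold50_depths: np.ndarray = None
    gold10_depths: np.ndarray = None
    gold50_z: np.ndarray = None  # z (slice units of the binned stack)
    gold10_z: np.ndarray = None
    omitted: dict = field(default_factory=dict)

    # -- convenience ------------------------------------------------------
    def point_set(self, which: str) -> PointSet:
        table = {
            "beads_fm": ("fm", self.spec.fm_pixel_nm, self.beads_fm),
            "beads_fm_beads": ("fm_beads", self.spec.fm_pixel_nm, self.beads_fm_beads),
            "beads_montage": ("montage", self.spec.montage_pixel_nm, self.beads_montage),
            "gold50_montage": ("montage", self.spec.montage_pixel_nm, self.gold50_montage),
            "gold50_tomo": ("tomo_projection", self.spec.tomo_pixel_nm, self.gold50_tomo),
            "gold10_tomo": ("tomo_projection", self.spec.tomo_pixel_nm, self.gold10_tomo),
            "puncta_fm": ("fm", self.spec.fm_pixel_nm, self.puncta_fm),
            "puncta_tomo": ("tomo_projection", self.spec.tomo_pixel_nm, self.puncta_tomo),
            "calibration_ref": ("fm", self.spec.fm_pixel_nm, self.calibration_ref),
            "calibration_moving": ("fm_beads", self.spec.fm_pixel_nm, self.calibration_moving),
        }
        frame, px, pts = table[which]
        return PointSet(points=pts, frame_id=frame, pixel_size_nm=px)

    @property
    def fm_to_tomo(self) -> Transform2D:
        return self.montage_to_tomo.compose(self.fm_to_montage)


def _place_markers(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    min_dist,
    existing: np.ndarray | None = None,
    existing_min_dist: float = 0.0,
    exclusion=None,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform dart-throwing with minimum-separation rejection.

    ``bounds`` is (x0, x1, y0, y1); ``min_dist`` the minimum center distance
    among the new markers; ``exclusion`` an optional predicate rejecting
    candidate positions outright.
    """
    x0, x1, y0, y1 = bounds
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} markers with min separation {min_dist:.1f} px "
                f"in [{x0:.0f},{x1:.0f}]x[{y0:.0f},{y1:.0f}] after {max_tries} tries; "
                "lower the count or the separation"
            )
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if exclusion is not None and exclusion(cand):
            continue
        if placed and np.min(np.linalg.norm(np.asarray(placed) - cand, axis=1)) < min_dist:
            continue
        if (
            existing is not None
            and len(existing)
            and np.min(np.linalg.norm(existing - cand, axis=1)) < existing_min_dist
        ):
            continue
        placed.append(cand)
    return np.asarray(placed).reshape(n, 2)


def generate_scene(spec: SceneSpec) -> SceneManifest:
    """Draw marker positions and truth transforms for one scene.

    Deterministic for a fixed seed.  Beads live in the FM and montage
    frames, 50 nm gold in the montage and tomogram-projection frames, 10 nm
    gold in the tomogram only.  Beads are kept out of the (tiny) tomogram
    footprint — the operator targets tilt series away from the opaque
    microspheres.
    """
    rng_t = spec.rng("transforms")
    man = SceneManifest(spec=spec)

    # --- truth transforms ------------------------------------------------
    lin = np.eye(2) + rng_t.uniform(
        -spec.channel_shift_scale_jitter, spec.channel_shift_scale_jitter, (2, 2)
    )
    shift = rng_t.uniform(-spec.channel_shift_max_px, spec.channel_shift_max_px, 2)
    man.channel_shift = Transform2D("affine", lin, shift, source_frame="fm", target_frame="fm_beads")

    s1 = spec.fm_pixel_nm / spec.montage_pixel_nm
    th1 = rng_t.uniform(-spec.max_rotation_coarse_deg, spec.max_rotation_coarse_deg)
    fm_c = np.array([spec.fm_shape[1] / 2.0, spec.fm_shape[0] / 2.0]) + rng_t.uniform(-5, 5, 2)
    mont_c = np.array([spec.montage_shape[1] / 2.0, spec.montage_shape[0] / 2.0])
    t1 = similarity_from_params(th1, s1, source_frame="fm", target_frame="montage")
    t1.offset = mont_c - t1.matrix @ fm_c
    man.fm_to_montage = t1

    s2 = spec.montage_pixel_nm / spec.tomo_pixel_nm
    th2 = rng_t.uniform(-spec.max_rotation_fine_deg, spec.max_rotation_fine_deg)
    mont_anchor = mont_c + rng_t.uniform(-40, 40, 2)
    tomo_c = np.array([spec.tomo_shape[1] / 2.0, spec.tomo_shape[0] / 2.0])
    t2 = similarity_from_params(th2, s2, source_frame="montage", target_frame="tomo_projection")
    t2.offset = tomo_c - t2.matrix @ mont_anchor
    man.montage_to_tomo = t2

    # --- counts ----------------------------------------------------------
    rng_p = spec.rng("placement")
    n_beads = spec.n_beads if spec.n_beads is not None else int(rng_p.integers(*BEAD_RANGE, endpoint=True))
    n_gold50 = spec.n_gold50 if spec.n_gold50 is not None else int(rng_p.integers(*GOLD50_RANGE, endpoint=True))

    # --- 50 nm gold: sampled in the tomogram-projection frame ------------
    gold50_d_tomo = spec.gold50_diameter_nm / spec.tomo_pixel_nm
    margin = gold50_d_tomo  # keep full disc + refinement window inside
    man.gold50_tomo = _place_markers(
        rng_p,
        n_gold50,
        (margin, spec.tomo_shape[1] - 1 - margin, margin, spec.tomo_shape[0] - 1 - margin),
        min_dist=2.0 * gold50_d_tomo,
    )
    tomo_to_mont = man.montage_to_tomo.inverse()
    man.gold50_montage = tomo_to_mont.apply(man.gold50_tomo)

    # --- 10 nm gold: tomogram frame only ---------------------------------
    gold10_d_tomo = spec.gold10_diameter_nm / spec.tomo_pixel_nm
    man.gold10_tomo = _place_markers(
        rng_p,
        spec.n_gold10,
        (30, spec.tomo_shape[1] - 31, 30, spec.tomo_shape[0] - 31),
        min_dist=2.0 * gold10_d_tomo,
        existing=man.gold50_tomo,
        existing_min_dist=0.75 * (gold50_d_tomo + gold10_d_tomo),
    )

    # --- beads: sampled in the montage frame, kept off the tomo footprint -
    bead_d_mont = spec.bead_diameter_nm / spec.montage_pixel_nm
    bead_sep_mont = 2.0 * spec.bead_fm_diameter_nm / spec.montage_pixel_nm  # FM resolvability
    bead_margin = 1.5 * bead_d_mont
    pad = spec.bead_diameter_nm / spec.tomo_pixel_nm  # bead radius buffer, tomo px

    def in_tomo_field(p_mont: np.ndarray) -> bool:
        q = man.montage_to_tomo.apply(p_mont)
        return bool(
            -pad <= q[0] <= spec.tomo_shape[1] - 1 + pad
            and -pad <= q[1] <= spec.tomo_shape[0] - 1 + pad
        )

    man.beads_montage = _place_markers(
        rng_p,
        n_beads,
        (
            bead_margin,
            spec.montage_shape[1] - 1 - bead_margin,
            bead_margin,
            spec.montage_shape[0] - 1 - bead_margin,
        ),
        min_dist=max(bead_sep_mont, 1.5 * bead_d_mont),
        existing=man.gold50_montage,
        existing_min_dist=0.75 * (bead_d_mont + spec.gold50_diameter_nm / spec.montage_pixel_nm),
        exclusion=in_tomo_field,
    )
    mont_to_fm = man.fm_to_montage.inverse()
    man.beads_fm = mont_to_fm.apply(man.beads_montage)
    man.beads_fm_beads = man.channel_shift.apply(man.beads_fm)

    # --- signal puncta: inside the tomogram footprint ---------------------
    t_margin = 0.2 * min(spec.tomo_shape)
    man.puncta_tomo = _place_markers(
        rng_p,
        spec.n_puncta,
        (t_margin, spec.tomo_shape[1] - 1 - t_margin, t_margin, spec.tomo_shape[0] - 1 - t_margin),
        min_dist=2.0 * spec.psf_fwhm_nm / spec.tomo_pixel_nm,
        existing=man.gold50_tomo,
        existing_min_dist=gold50_d_tomo,
    )
    man.puncta_fm = mont_to_fm.apply(tomo_to_mont.apply(man.puncta_tomo))

    # --- channel-shift calibration bead field -----------------------------
    n_cal = 20
    m = 8
    cal = _place_markers(
        rng_p,
        n_cal,
        (m, spec.fm_shape[1] - 1 - m, m, spec.fm_shape[0] - 1 - m),
        min_dist=2.0 * spec.bead_fm_diameter_nm / spec.fm_pixel_nm,
    )
    man.calibration_ref = cal
    man.calibration_moving = man.channel_shift.apply(cal)

    # --- render attributes -------------------------------------------------
    rng_a = spec.rng("amplitudes")
    man.bead_amplitudes = spec.fm_amplitude * rng_a.uniform(0.8, 1.2, n_beads)
    man.punctum_amplitudes = spec.fm_amplitude * rng_a.uniform(0.8, 1.2, spec.n_puncta)
    man.bead_depths = spec.em_marker_depth * rng_a.uniform(0.8, 1.2, n_beads)
    man.gold50_depths = spec.em_marker_depth * rng_a.uniform(0.8, 1.2, n_gold50)
    man.gold10_depths = 0.6 * spec.em_marker_depth * rng_a.uniform(0.8, 1.2, spec.n_gold10)

    # z positions in the binned stack
    r_vox = spec.gold50_diameter_nm / 2.0 / (spec.tomo_stack_bin * spec.tomo_pixel_nm)
    zlo, zhi = r_vox + 1, spec.tomo_stack_slices - 1 - r_vox - 1
    man.gold50_z = rng_a.uniform(zlo, zhi, n_gold50)
    man.gold10_z = rng_a.uniform(2, spec.tomo_stack_slices - 3, spec.n_gold10)
    return man


# -- rendering primitives --------------------------------------------------

def _phi(edges: np.ndarray, c: float, sigma: float) -> np.ndarray:
    return 0.5 * (1.0 + erf((edges - c) / (np.sqrt(2.0) * sigma)))


def _add_gaussian_spot(img: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    """Pixel-integrated 2D Gaussian of peak amplitude ``amp`` added in place."""
    h, w = img.shape
    half = int(np.ceil(6 * sigma)) + 1
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    fx = _phi(xs + 0.5, cx, sigma) - _phi(xs - 0.5, cx, sigma)
    fy = _phi(ys + 0.5, cy, sigma) - _phi(ys - 0.5, cy, sigma)
    img[y0:y1, x0:x1] += amp * 2.0 * np.pi * sigma**2 * np.outer(fy, fx)


def _subtract_disc(img: np.ndarray, cx: float, cy: float, radius: float, depth: float, edge: float) -> None:
    """Soft-edged dark disc (erf profile) subtracted in place."""
    h, w = img.shape
    half = int(np.ceil(radius + 5 * edge)) + 1
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    r = np.sqrt(xs[None, :] ** 2 + ys[:, None] ** 2)
    img[y0:y1, x0:x1] -= depth * 0.5 * (1.0 - erf((r - radius) / (np.sqrt(2.0) * edge)))


def _apply_fm_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise calibrated so that the total
    noise at a nominal-amplitude peak equals noise_sigma * fm_amplitude."""
    if spec.noise_sigma == 0:
        return img
    peak = spec.fm_amplitude + spec.fm_background
    var_read = max((spec.noise_sigma * spec.fm_amplitude) ** 2 - peak, 0.0)
    noisy = rng.poisson(np.clip(img, 0, None)).astype(float)
    if var_read > 0:
        noisy += rng.normal(0.0, np.sqrt(var_read), img.shape)
    return noisy


def render_fm(manifest: SceneManifest, channel: str = "psd95") -> ImagePlane:
    """Render one fluorescence channel of the scene.

    ``"psd95"`` shows the signal puncta in the reference ("fm") frame;
    ``"beads"`` shows the 200 nm beads in the chromatically shifted
    ("fm_beads") frame.  Spots are pixel-integrated Gaussians of PSF-limited
    size; noise follows the scene's ``noise_sigma`` (none when 0).
    """
    spec = manifest.spec
    if channel == "psd95":
        positions, amps, frame = manifest.puncta_fm, manifest.punctum_amplitudes, "fm"
        rng = spec.rng("render_psd95")
    elif channel == "beads":
        positions, amps, frame = manifest.beads_fm_beads, manifest.bead_amplitudes, "fm_beads"
        rng = spec.rng("render_beads")
    else:
        raise ValueError("channel must be 'psd95' or 'beads'")

    img = np.full(spec.fm_shape, spec.fm_background, dtype=float)
    sigma = max(spec.bead_fm_diameter_nm if channel == "beads" else spec.psf_fwhm_nm, spec.psf_fwhm_nm)
    sigma = sigma / 2.355 / spec.fm_pixel_nm
    for (x, y), a in zip(positions, amps):
        _add_gaussian_spot(img, x, y, sigma, a)
    img = _apply_fm_noise(img, spec, rng)
    return ImagePlane(
        pixels=img, pixel_size_nm=spec.fm_pixel_nm, frame_id=frame, channel=channel,
        metadata={"seed": spec.seed},
    )


def _em_frame_markers(manifest: SceneManifest, frame: str):
    """(positions, diameters_nm, depths) of every marker class in an EM frame."""
    spec = manifest.spec
    if frame == "montage":
        return [
            ("bead", manifest.beads_montage, spec.bead_diameter_nm, manifest.bead_depths),
            ("gold50", manifest.gold50_montage, spec.gold50_diameter_nm, manifest.gold50_depths),
        ], spec.montage_pixel_nm, spec.montage_shape
    if frame == "tomo_projection":
        return [
            ("gold50", manifest.gold50_tomo, spec.gold50_diameter_nm, manifest.gold50_depths),
            ("gold10", manifest.gold10_tomo, spec.gold10_diameter_nm, manifest.gold10_depths),
        ], spec.tomo_pixel_nm, spec.tomo_shape
    raise ValueError("frame must be 'montage' or 'tomo_projection'")


def render_em(manifest: SceneManifest, frame: str = "montage") -> ImagePlane:
    """Render an EM frame: dark soft-edged discs on a textured background.

    Markers whose diameter falls below 1 px at the frame's pixel size are
    silently omitted and recorded in ``manifest.omitted[frame]`` — the same
    way 10 nm gold is invisible at montage magnification.
    """
    spec = manifest.spec
    classes, px_nm, shape = _em_frame_markers(manifest, frame)
    rng = spec.rng(f"render_{frame}")
    img = np.full(shape, spec.em_background, dtype=float)
    if spec.noise_sigma > 0:
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 2.0)
        tex *= spec.noise_sigma * spec.em_marker_depth / max(tex.std(), 1e-12)
        img += tex
    omitted = []
    for name, positions, diam_nm, depths in classes:
        diam_px = diam_nm / px_nm
        if diam_px < 1.0:
            omitted.append(name)
            continue
        radius = diam_px / 2.0
        edge = max(0.8, radius / 20.0)
        for (x, y), d in zip(positions, depths):
            _subtract_disc(img, x, y, radius, d, edge)
    manifest.omitted[frame] = omitted
    return ImagePlane(
        pixels=img, pixel_size_nm=px_nm, frame_id=frame, channel="EM",
        metadata={"seed": spec.seed, "omitted": omitted},
    )


def render_tomogram(manifest: SceneManifest) -> TomogramStack:
    """Render the binned 3D tomogram volume containing the gold as spheres.

    Voxel size is ``tomo_stack_bin * tomo_pixel_nm`` (cubic); gold particles
    sit at their manifest (x, y) positions divided by the bin factor, at
    their manifest z.  A min z-projection of the result reveals every gold
    particle of the manifest in one image.
    """
    spec = manifest.spec
    bin_ = spec.tomo_stack_bin
    voxel = bin_ * spec.tomo_pixel_nm
    nz = spec.tomo_stack_slices
    ny = spec.tomo_shape[0] // bin_
    nx = spec.tomo_shape[1] // bin_
    rng = spec.rng("render_tomogram")
    vol = np.full((nz, ny, nx), spec.em_background, dtype=float)
    if spec.noise_sigma > 0:
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (nz, ny, nx)), 1.5)
        tex *= spec.noise_sigma * spec.em_marker_depth / max(tex.std(), 1e-12)
        vol += tex
    for positions, zs, diam_nm, depths in (
        (manifest.gold50_tomo, manifest.gold50_z, spec.gold50_diameter_nm, manifest.gold50_depths),
        (manifest.gold10_tomo, manifest.gold10_z, spec.gold10_diameter_nm, manifest.gold10_depths),
    ):
        r_vox = diam_nm / 2.0 / voxel
        if 2 * r_vox < 1.0:
            continue
        for (x, y), z, d in zip(positions, zs, depths):
            zi0 = max(0, int(np.floor(z - r_vox)))
            zi1 = min(nz, int(np.ceil(z + r_vox)) + 1)
            for zi in range(zi0, zi1):
                dz = zi - z
                if abs(dz) >= r_vox:
                    continue
                r_slice = np.sqrt(r_vox**2 - dz**2)
                if r_slice < 0.3:
                    continue
                _subtract_disc(vol[zi], x / bin_, y / bin_, r_slice, d, 0.8)
    return TomogramStack(voxels=vol, voxel_size_nm=voxel)


def write_scene(
    manifest: SceneManifest,
    outdir,
    *,
    write_volume: bool = False,
) -> dict:
    """Write a generated scene to disk in standard formats.

    Produces TIFF fluorescence channels, MRC EM images (montage and tomogram
    z-projection frame, optionally the 3D volume), truth point CSVs per
    frame, and JSON truth transforms + manifest summary.  Returns a dict of
    written paths.
    """
    import json

    from . import io as clem_io

    outdir = Path(outdir)
    (outdir / "points").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    paths: dict[str, str] = {}

    for channel, name in (("psd95", "fm_psd95.tif"), ("beads", "fm_beads.tif")):
        p = outdir / name
        clem_io.write_image(render_fm(manifest, channel), p)
        paths[name] = str(p)
    for frame, name in (("montage", "montage.mrc"), ("tomo_projection", "tomo_projection.mrc")):
        p = outdir / name
        clem_io.write_image(render_em(manifest, frame), p)
        paths[name] = str(p)
    if write_volume:
        p = outdir / "tomogram.mrc"
        clem_io.write_image(render_tomogram(manifest), p)
        paths["tomogram.mrc"] = str(p)

    for which in (
        "beads_fm", "beads_fm_beads", "beads_montage", "gold50_montage",
        "gold50_tomo", "gold10_tomo", "puncta_fm", "puncta_tomo",
        "calibration_ref", "calibration_moving",
    ):
        p = outdir / "points" / f"{which}.csv"
        clem_io.write_points(manifest.point_set(which), p)
        paths[f"points/{which}.csv"] = str(p)

    transforms = {
        "channel_shift": manifest.channel_shift.to_dict(),
        "fm_to_montage": manifest.fm_to_montage.to_dict(),
        "montage_to_tomo": manifest.montage_to_tomo.to_dict(),
        "fm_to_tomo": manifest.fm_to_tomo.to_dict(),
    }
    p = outdir / "truth" / "transforms.json"
    with open(p, "w") as fh:
        json.dump(transforms, fh, indent=2)
    paths["truth/transforms.json"] = str(p)

    summary = {
        "seed": manifest.spec.seed,
        "n_beads": len(manifest.beads_fm),
        "n_gold50": len(manifest.gold50_tomo),
        "n_gold10": len(manifest.gold10_tomo),
        "n_puncta": len(manifest.puncta_fm),
        "pixel_sizes_nm": {
            "fm": manifest.spec.fm_pixel_nm,
            "montage": manifest.spec.montage_pixel_nm,
            "tomo_projection": manifest.spec.tomo_pixel_nm,
        },
        "noise_sigma": manifest.spec.noise_sigma,
    }
    p = outdir / "truth" / "manifest.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["truth/manifest.json"] = str(p)
    return paths


# -- morphometry phantom ----------------------------------------------------

_MIX_STATES = ("docked_or_primed", "tethered_candidate", "free", "fusing", "fully_fused")
_GAP_RANGES = {
    "docked_or_primed": (0.0, 1.5),
    "tethered_candidate": (4.0, 9.0),
    "free": (30.0, 120.0),
}


def generate_synapse_phantom(
    seed: int,
    width_nm: float = 20.0,
    width_jitter_sd: float = 1.0,
    n_vesicles: int = 30,
    state_mix: dict | None = None,
    *,
    pixel_size_nm: float = 1.0,
    length_nm: float = 1200.0,
    n_connectors: int = 0,
    curve_amplitude_nm: float = 25.0,
) -> tuple[SynapseAnnotation, dict]:
    """Synthetic synapse annotation with exact ground truth.

    Two roughly parallel membrane polylines are built ``width_nm`` apart
    (plus a smooth zero-mean jitter of standard deviation
    ``width_jitter_sd``); vesicles are placed on the presynaptic side at
    membrane gaps drawn to realize ``state_mix`` (a dict mapping state names
    to counts; remaining vesicles are free).  Returns the annotation and a
    truth dict with per-vesicle state labels, the realized width profile and
    connector degrees.

    Raises :class:`ValueError` for an infeasible mix (more vesicles requested
    than fit along the membrane, or mix counts exceeding ``n_vesicles``).
    """
    if width_nm <= 0:
        raise ValueError("width_nm must be > 0")
    rng = np.random.default_rng([int(seed), 101])
    state_mix = dict(state_mix or {})
    for k in state_mix:
        if k not in _MIX_STATES:
            raise ValueError(f"unknown state {k!r} in state_mix")
    n_special = sum(state_mix.values())
    if n_special > n_vesicles:
        raise ValueError(f"state_mix requests {n_special} vesicles but n_vesicles={n_vesicles}")

    # presynaptic membrane: gently curved, densely sampled (1 nm)
    s = np.arange(0.0, length_nm + 0.5, 1.0)
    y = curve_amplitude_nm * np.sin(2 * np.pi * s / length_nm * 1.3 + rng.uniform(0, 2 * np.pi))
    pre_nm = np.column_stack([s, y])
    d = np.gradient(pre_nm, axis=0)
    tang = d / np.linalg.norm(d, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])  # points to the cleft side

    # smooth zero-mean width jitter
    if width_jitter_sd > 0:
        jit = np.zeros_like(s)
        for k in range(1, 5):
            jit += rng.normal(0, 1) * np.sin(2 * np.pi * k * s / length_nm + rng.uniform(0, 2 * np.pi))
        jit -= jit.mean()
        jit *= width_jitter_sd / max(jit.std(), 1e-12)
    else:
        jit = np.zeros_like(s)
    widths = width_nm + jit
    if np.any(widths <= 0):
        raise ValueError("width jitter drives the cleft width non-positive")
    post_nm = pre_nm + normal * widths[:, None]

    membranes = [
        MembraneTrace(pre_nm / pixel_size_nm, pixel_size_nm, "presynaptic"),
        MembraneTrace(post_nm / pixel_size_nm, pixel_size_nm, "postsynaptic"),
    ]

    # vesicles on the presynaptic (anti-cleft) side at controlled gaps:
    # membrane-proximal states occupy the first row of slots along the
    # membrane; free vesicles may also fill a second, deeper row
    slot_pitch = 60.0
    slots = np.arange(40.0, length_nm - 40.0, slot_pitch)
    n_special = sum(state_mix.values())
    if n_special > len(slots) or n_vesicles > 2 * len(slots):
        raise ValueError(
            f"cannot place {n_vesicles} vesicles ({n_special} membrane-proximal) "
            f"along a {length_nm:.0f} nm membrane"
        )
    special_labels: list[str] = []
    for st in _MIX_STATES:
        if st != "free":
            special_labels.extend([st] * state_mix.get(st, 0))
    n_free = n_vesicles - len(special_labels)

    slot_order = rng.permutation(len(slots))
    assignments: list[tuple[str, float, float]] = []  # (state, arc position, row offset)
    for st, si in zip(special_labels, slot_order):
        assignments.append((st, slots[si], 0.0))
    free_slots = list(slot_order[len(special_labels):]) + list(range(len(slots)))
    for k in range(n_free):
        if k < len(slot_order) - len(special_labels):
            assignments.append(("free", slots[free_slots[k]], 0.0))
        else:  # second row, deeper into the terminal
            assignments.append(("free", slots[k % len(slots)], 190.0))

    vesicles: list[Vesicle] = []
    truth_labels: list[str] = []
    for st, slot, row_off in assignments:
        i = int(round(slot))
        radius = float(np.clip(rng.normal(20.0, 2.5), 14.0, 26.0))
        flag = None
        if st == "fusing":
            gap = -0.3 * radius
            flag = "fusing"
        elif st == "fully_fused":
            gap = -0.4 * radius
            flag = "fully_fused"
        else:
            gap = float(rng.uniform(*_GAP_RANGES[st])) + row_off
        center_nm = pre_nm[i] - normal[i] * (radius + gap)
        vesicles.append(
            Vesicle(center=tuple(center_nm / pixel_size_nm), radius_nm=radius, state_flag=flag)
        )
        truth_labels.append(st)

    # connectors between consecutive placed free vesicles
    connectors = []
    degrees = np.zeros(len(vesicles), dtype=int)
    free_idx = [i for i, st in enumerate(truth_labels) if st == "free"]
    for c in range(min(n_connectors, max(0, len(free_idx) - 1))):
        i, j = free_idx[c], free_idx[c + 1]
        a = np.asarray(vesicles[i].center, dtype=float)
        b = np.asarray(vesicles[j].center, dtype=float)
        u = (b - a) / np.linalg.norm(b - a)
        pa = a + u * (vesicles[i].radius_nm / pixel_size_nm)
        pb = b - u * (vesicles[j].radius_nm / pixel_size_nm)
        connectors.append((tuple(pa), tuple(pb)))
        degrees[i] += 1
        degrees[j] += 1

    ann = SynapseAnnotation(
        membranes=membranes, vesicles=vesicles, connectors=connectors, pixel_size_nm=pixel_size_nm
    )
    truth = {
        "labels": truth_labels,
        "width_nm": width_nm,
        "width_jitter_sd": width_jitter_sd,
        "width_profile_nm": widths,
        "connector_degrees": degrees.tolist(),
    }
    return ann, truth
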