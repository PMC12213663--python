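"""Fiducial marker detection and sub-pixel localization.

Detects the three marker classes of the multi-scale correlation hierarchy:
200 nm fluorescent microspheres (bright, diffraction-limited spots in the
fluorescence channels; dark discs in the EM montage), 50 nm colloidal gold
(dark discs in the montage and the tomogram z-projection) and 10 nm gold
(tomogram only).

The detector is a scale-normalized Laplacian-of-Gaussian blob response tuned
to the expected marker diameter, followed by local-maximum extraction with a
minimum-separation constraint and an iterative Gaussian-weighted centroid for
sub-pixel refinement.  Dark markers are handled by negating the response, not
the input.  Manually picked coordinate lists remain a first-class input via
:mod:`cryoclem.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .geometry import Point2D

__all__ = [
    "FiducialDetection",
    "DetectionParams",
    "detect_fiducials",
    "refine_subpixel",
]


@dataclass
class FiducialDetection:
    """One detected marker: sub-pixel center, size estimate, polarity, strength."""

    center: Point2D
    radius_px: float
    polarity: str  # "bright" | "dark"
    score: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")


@dataclass
class DetectionParams:
    """Detector configuration.

    ``expected_diameter_nm`` is the marker's physical diameter — for
    diffraction-limited fluorescent beads use the apparent size
    ``max(bead diameter, PSF FWHM)``.  ``threshold`` is a relative cutoff on
    the blob response, as a fraction of the strongest response in the image;
    ``noise_floor_k`` additionally rejects responses below k robust standard
    deviations (MAD) of the response map, keeping pure-noise maxima out of
    sparse scenes.
    """

    expected_diameter_nm: float
    pixel_size_nm: float
    polarity: Literal["bright", "dark"] = "bright"
    threshold: float = 0.3
    min_separation_factor: float = 1.0
    noise_floor_k: float = 6.0

    def __post_init__(self) -> None:
        if self.expected_diameter_nm <= 0:
            raise ValueError("expected_diameter_nm must be > 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        if self.min_separation_factor <= 0:
            raise ValueError("min_separation_factor must be > 0")
        if self.noise_floor_k < 0:
            raise ValueError("noise_floor_k must be >= 0")

    @property
    def expected_diameter_px(self) -> float:
        return self.expected_diameter_nm / self.pixel_size_nm


def _blob_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized negative LoG: positive peaks at bright blobs of scale sigma."""
    return -(sigma**2) * ndimage.gaussian_laplace(image, sigma, mode="reflect")


def detect_fiducials(image: np.ndarray, params: DetectionParams) -> list[FiducialDetection]:
    """Detect markers of a given expected size in a 2D intensity image.

    Returns detections sorted by descending score; no two detections lie
    closer than ``min_separation_factor`` times the expected diameter.  Ties
    in score are resolved toward the smaller (row, column) position so the
    output is deterministic.

    Raises
    ------
    ValueError
        If the image is smaller than 16x16, or the expected diameter falls
        outside [1 px, min(image dims)/4] at the given pixel size (below
        1 px the caller should move to a higher-magnification image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D intensity array")
    if min(img.shape) < 16:
        raise ValueError("image must be at least 16x16 pixels")
    diam_px = params.expected_diameter_px
    if diam_px < 1.0:
        raise ValueError(
            f"expected diameter {params.expected_diameter_nm} nm is {diam_px:.2f} px at "
            f"{params.pixel_size_nm} nm/px (< 1 px); use a higher-magnification image"
        )
    if diam_px > min(img.shape) / 4:
        raise ValueError(
            f"expected diameter {diam_px:.1f} px exceeds min(image dims)/4 = {min(img.shape) / 4:.1f} px"
        )

    scale = img.std()
    if scale == 0.0:  # constant image: nothing to detect
        return []
    work = img if params.polarity == "bright" else -img

    # LoG scale for a blob of radius r peaks at sigma = r / sqrt(2)
    sigma = diam_px / (2.0 * np.sqrt(2.0))
    resp = _blob_response(work, sigma)
    resp_max = resp.max()
    if resp_max <= 0:
        return []

    # cutoff: relative to the strongest response, but never below the robust
    # noise floor (MAD-based), so noise maxima cannot pass in sparse scenes
    sigma_hat = 1.4826 * np.median(np.abs(resp - np.median(resp)))
    cutoff = max(params.threshold * resp_max, params.noise_floor_k * sigma_hat)

    sep = params.min_separation_factor * diam_px
    # local maxima within the separation radius
    size = max(3, int(round(sep)) | 1)
    local_max = resp == ndimage.maximum_filter(resp, size=size, mode="reflect")
    cand = np.nonzero(local_max & (resp >= cutoff))
    if cand[0].size == 0:
        return []
    scores = resp[cand]
    rows, cols = cand
    # descending score; ties -> smaller (row, col)
    order = np.lexsort((cols, rows, -scores))
    rows, cols, scores = rows[order], cols[order], scores[order]

    # greedy minimum-separation enforcement (footprint above is square; make it Euclidean)
    kept_rc: list[tuple[int, int]] = []
    kept_scores: list[float] = []
    for r, c, s in zip(rows, cols, scores):
        if all((r - kr) ** 2 + (c - kc) ** 2 >= sep**2 for kr, kc in kept_rc):
            kept_rc.append((int(r), int(c)))
            kept_scores.append(float(s))

    radius = diam_px / 2.0
    detections: list[FiducialDetection] = []
    for (r, c), s in zip(kept_rc, kept_scores):
        window = _fitting_window(img.shape, (c, r), desired=int(2 * diam_px) | 1)
        if window >= 3:
            center = refine_subpixel(
                img, Point2D(float(c), float(r)), window,
                polarity=params.polarity, weight_sigma=max(1.2, 0.6 * radius),
            )
        else:
            center = Point2D(float(c), float(r))
        if not (0 <= center.x <= img.shape[1] - 1 and 0 <= center.y <= img.shape[0] - 1):
            center = Point2D(float(c), float(r))
        detections.append(FiducialDetection(center=center, radius_px=radius, polarity=params.polarity, score=s))
    return detections


def _fitting_window(shape: tuple[int, int], seed_xy: tuple[int, int], desired: int) -> int:
    """Largest odd window <= desired centered at seed that stays inside the image."""
    x, y = seed_xy
    half = min(desired // 2, x, y, shape[1] - 1 - x, shape[0] - 1 - y)
    return 2 * int(half) + 1


def refine_subpixel(
    image: np.ndarray,
    seed: Point2D,
    window_px: int,
    *,
    polarity: str = "bright",
    n_iter: int = 8,
    weight_sigma: float | None = None,
    with_contrast: bool = False,
):
    """Sub-pixel center via an iterative Gaussian-weighted centroid.

    A window of ``window_px`` (odd, >= 3) pixels around the seed is extracted;
    the local background (median of the window border) is subtracted after
    polarity normalization, and the centroid is re-weighted with a Gaussian
    centered on the running estimate (a mean-shift step) so that the result is
    unbiased for symmetric spots regardless of where they fall within a pixel.
    ``weight_sigma`` sets the weight's width in pixels (default: a quarter of
    the window); keep it near the spot radius so that neighboring structure
    inside a generous window cannot pull the centroid.

    Returns the refined :class:`Point2D`; with ``with_contrast=True`` returns
    ``(point, contrast)`` where contrast 0 flags a flat window (the window
    center is returned in that case).

    Raises
    ------
    ValueError
        If the window is even, < 3, or clipped by the image border.
    """
    img = np.asarray(image, dtype=float)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    half = window_px // 2
    cx, cy = int(round(seed.x)), int(round(seed.y))
    if cx - half < 0 or cy - half < 0 or cx + half > img.shape[1] - 1 or cy + half > img.shape[0] - 1:
        raise ValueError(
            f"window of {window_px} px at ({seed.x:.1f}, {seed.y:.1f}) is clipped by the image border"
        )
    win = img[cy - half : cy + half + 1, cx - half : cx + half + 1]
    win = win if polarity == "bright" else -win

    border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
    w = win - np.median(border)
    np.clip(w, 0.0, None, out=w)
    total = w.sum()
    if total <= 0:
        result = Point2D(float(cx), float(cy))
        return (result, 0.0) if with_contrast else result

    ys, xs = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1].astype(float)
    # plain centroid start, then Gaussian-reweighted (mean-shift) iterations
    ex, ey = float((w * xs).sum() / total), float((w * ys).sum() / total)
    sig_w = weight_sigma if weight_sigma is not None else max(1.0, half / 2.0)
    for _ in range(n_iter):
        g = np.exp(-((xs - ex) ** 2 + (ys - ey) ** 2) / (2.0 * sig_w**2))
        ww = w * g
        s = ww.sum()
        if s <= 0:
            break
        nx, ny = float((ww * xs).sum() / s), float((ww * ys).sum() / s)
        if abs(nx - ex) < 1e-9 and abs(ny - ey) < 1e-9:
            ex, ey = nx, ny
            break
        ex, ey = nx, ny
    result = Point2D(ex, ey)
    return (result, float(w.max())) if with_contrast else result
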