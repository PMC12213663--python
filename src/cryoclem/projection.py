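"""Tomogram z-projection, image warping, overlays and orientation matching.

These operations produce the images the registration transforms act on: the
z-projection that gathers all 50 nm gold of a tomogram into one plane, the
warped fluorescence channels, the color overlay of FM signal on the EM frame,
and the eight dihedral orientations used to match the grid's coordinate
letters between the light and electron microscopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Transform2D

__all__ = [
    "ImagePlane",
    "TomogramStack",
    "zproject",
    "warp_image",
    "compose_overlay",
    "enumerate_orientations",
    "match_orientation",
    "COLOR_MAP",
]

COLOR_MAP = {
    "green": (0.0, 1.0, 0.0),
    "red": (1.0, 0.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
    "cyan": (0.0, 1.0, 1.0),
}


@dataclass
class ImagePlane:
    """A single 2D intensity image with physical pixel size and frame label."""

    pixels: np.ndarray
    pixel_size_nm: float
    frame_id: str
    channel: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ImagePlane pixels must be 2D")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TomogramStack:
    """A reconstructed tomogram volume, axes (z, y, x), cubic voxels."""

    voxels: np.ndarray
    voxel_size_nm: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("TomogramStack needs a (z, y, x) volume with >= 1 slice")
        if not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be > 0")


_PROJECTORS = {"min": np.min, "mean": np.mean, "max": np.max}


def zproject(stack: TomogramStack, method: str = "min", *, frame_id: str = "tomo_projection") -> ImagePlane:
    """Per-pixel reduction of the volume along z.

    The default ``min`` keeps the darkest value per (y, x) column, which is
    what reveals every electron-dense gold particle of the tomogram in a
    single image regardless of its z position.
    """
    if method not in _PROJECTORS:
        raise ValueError(f"method must be one of {tuple(_PROJECTORS)}")
    proj = _PROJECTORS[method](stack.voxels, axis=0)
    return ImagePlane(
        pixels=proj,
        pixel_size_nm=stack.voxel_size_nm,
        frame_id=frame_id,
        channel="EM",
        metadata={"projection": method, "n_slices": int(stack.voxels.shape[0])},
    )


def warp_image(
    src: ImagePlane,
    t: Transform2D,
    target_shape: tuple[int, int],
    *,
    target_frame: str | None = None,
    target_pixel_size_nm: float | None = None,
    order: int = 1,
    fill_value: float = 0.0,
) -> ImagePlane:
    """Resample ``src`` into the target frame of transform ``t``.

    ``t`` maps source-frame (x, y) coordinates to target-frame coordinates;
    the output is computed by inverse mapping with bilinear interpolation
    (``order=1``).  Pixels that fall outside the source image receive
    ``fill_value``; a boolean validity mask is stored in
    ``metadata["valid_mask"]`` so later normalization can ignore them.
    """
    inv = t.inverse()  # target (x, y) -> source (x, y)
    # scipy's affine_transform works in (row, col); swap axes accordingly
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    mat_rc = swap @ inv.matrix @ swap
    off_rc = swap @ inv.offset
    warped = ndimage.affine_transform(
        np.asarray(src.pixels, dtype=float),
        mat_rc,
        offset=off_rc,
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=fill_value,
    )
    mask = ndimage.affine_transform(
        np.ones(src.pixels.shape, dtype=float),
        mat_rc,
        offset=off_rc,
        output_shape=tuple(target_shape),
        order=min(order, 1),
        mode="constant",
        cval=0.0,
    )
    valid = mask > 0.999
    return ImagePlane(
        pixels=warped,
        pixel_size_nm=target_pixel_size_nm or src.pixel_size_nm / max(t.scale, np.finfo(float).tiny),
        frame_id=target_frame or t.target_frame or src.frame_id,
        channel=src.channel,
        metadata={"valid_mask": valid, "fill_value": float(fill_value), "warped_from": src.frame_id},
    )


def _normalize(img: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalize over valid pixels; constant images map to zeros."""
    sel = img[valid] if valid is not None else img
    if sel.size == 0:
        return np.zeros_like(img)
    lo, hi = float(sel.min()), float(sel.max())
    if hi == lo:
        return np.zeros_like(img)
    out = (img - lo) / (hi - lo)
    np.clip(out, 0.0, 1.0, out=out)
    if valid is not None:
        out = np.where(valid, out, 0.0)
    return out


def compose_overlay(
    base_em: ImagePlane,
    fm_channels: list[tuple[ImagePlane, Transform2D, object]],
    *,
    alpha: float = 1.0,
) -> np.ndarray:
    """Render FM channels in color over the grayscale EM base.

    ``fm_channels`` is a list of ``(plane, transform, color)`` where the
    transform maps that channel's frame into the EM frame and ``color`` is an
    RGB triple in [0, 1] or a named color (``"green"``, ``"red"``, ...).
    Each channel is warped, min-max normalized over its valid footprint, and
    alpha-added.  Returns an (H, W, 3) float array in [0, 1]; with no FM
    channels this is just the grayscale EM.
    """
    base = _normalize(np.asarray(base_em.pixels, dtype=float))
    rgb = np.repeat(base[:, :, None], 3, axis=2)
    for plane, t, color in fm_channels:
        if (
            t.target_frame is not None
            and base_em.frame_id
            and t.target_frame != base_em.frame_id
        ):
            raise ValueError(
                f"channel {plane.channel!r} transform targets frame {t.target_frame!r}, "
                f"but the EM base is frame {base_em.frame_id!r}"
            )
        rgb_color = np.asarray(COLOR_MAP[color] if isinstance(color, str) else color, dtype=float)
        warped = warp_image(plane, t, base_em.shape, target_frame=base_em.frame_id)
        norm = _normalize(warped.pixels, warped.metadata["valid_mask"])
        rgb += alpha * norm[:, :, None] * rgb_color[None, None, :]
    np.clip(rgb, 0.0, 1.0, out=rgb)
    return rgb


def _dihedral_transform(k_rot: int, flip: bool, shape: tuple[int, int]) -> Transform2D:
    """Transform mapping variant (x, y) coordinates back onto the original image.

    The variant is produced by ``np.rot90(img, k)`` after an optional
    left-right flip of the original; the returned transform satisfies
    ``original = warp(variant, t)`` and ``p_variant = t^{-1}(p_original)``.
    """
    h, w = shape
    # original -> flipped coordinates
    mat = np.eye(2)
    off = np.zeros(2)
    if flip:
        mat = np.diag([-1.0, 1.0])
        off = np.array([w - 1.0, 0.0])
    # np.rot90 (CCW, k times) on the (possibly flipped) image; in (x, y) pixel
    # coordinates one CCW array rotation maps (x, y) -> (y, W-1-x) of the source,
    # i.e. variant[r', c'] = src[c', W-1-r']: p_var = (x', y') with x' = y, y' = W-1-x
    dims = (h, w) if not flip else (h, w)
    for _ in range(k_rot % 4):
        rot = np.array([[0.0, 1.0], [-1.0, 0.0]])
        roff = np.array([0.0, dims[1] - 1.0])
        mat = rot @ mat
        off = rot @ off + roff
        dims = (dims[1], dims[0])
    fwd = Transform2D("rigid", mat, off)  # original -> variant coords
    return fwd.inverse()


def enumerate_orientations(lm: ImagePlane) -> list[tuple[ImagePlane, Transform2D]]:
    """The 8 dihedral variants (4 rotations x optional flip) of an image.

    Each variant is returned with the rigid transform that maps its pixel
    coordinates back into the original image's frame, so the chosen
    orientation can be folded into the correlation chain.  Matching the
    orientation of the grid's coordinate letters between the LM and EM views
    amounts to picking one of these eight.
    """
    out = []
    base = np.asarray(lm.pixels)
    for flip in (False, True):
        img_f = base[:, ::-1] if flip else base
        for k in range(4):
            variant = np.ascontiguousarray(np.rot90(img_f, k))
            t = _dihedral_transform(k, flip, base.shape)
            tag = f"rot{90 * k}" + ("_flipped" if flip else "")
            plane = ImagePlane(
                pixels=variant,
                pixel_size_nm=lm.pixel_size_nm,
                frame_id=f"{lm.frame_id}:{tag}",
                channel=lm.channel,
                metadata={"orientation": tag, "k_rot": k, "flipped": flip},
            )
            t.source_frame = plane.frame_id
            t.target_frame = lm.frame_id
            out.append((plane, t))
    return out


def match_orientation(lm: ImagePlane, em_ref: ImagePlane) -> tuple[int, list[float]]:
    """Score the 8 orientations of ``lm`` against an EM reference by NCC.

    The EM reference is resampled to each variant's shape with spline
    interpolation and a normalized cross-correlation coefficient is computed;
    returns ``(best_index, scores)`` into :func:`enumerate_orientations`.
    Intended as assistance for the manual letter-matching step — the user
    keeps the final say.
    """
    variants = enumerate_orientations(lm)
    ref = np.asarray(em_ref.pixels, dtype=float)
    scores: list[float] = []
    for plane, _ in variants:
        img = np.asarray(plane.pixels, dtype=float)
        zoom = (img.shape[0] / ref.shape[0], img.shape[1] / ref.shape[1])
        ref_rs = ndimage.zoom(ref, zoom, order=1) if zoom != (1.0, 1.0) else ref
        ref_rs = ref_rs[: img.shape[0], : img.shape[1]]
        a = img[: ref_rs.shape[0], : ref_rs.shape[1]] - img.mean()
        b = ref_rs - ref_rs.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        scores.append(float((a * b).sum() / denom) if denom > 0 else 0.0)
    return int(np.argmax(scores)), scores
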