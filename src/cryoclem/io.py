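"""File formats: TIFF fluorescence images, MRC maps/volumes, point CSVs.

TIFF goes through :mod:`tifffile`; MRC (modes 0/1/2) through :mod:`gemmi`'s
CCP4/MRC map support, with the voxel size taken from the header (1 A = 0.1 nm)
and overridable by the caller.  Point lists are CSVs with a
``frame_id,x,y`` header; extra columns are preserved on round-trip, matching
the manual-picking workflow where coordinates come from an external viewer.
"""

from __future__ import annotations

import csv
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import tifffile

from .geometry import PointSet
from .projection import ImagePlane, TomogramStack

__all__ = [
    "CLEMIOError",
    "read_image",
    "write_image",
    "read_points",
    "write_points",
]


class CLEMIOError(IOError):
    """A file could not be read or written; the message names file and reason."""


_TIFF_EXT = {".tif", ".tiff"}
_MRC_EXT = {".mrc", ".mrcs", ".rec", ".map"}


def read_image(
    path,
    *,
    pixel_size_nm: float | None = None,
    frame_id: str | None = None,
    channel: str = "",
):
    """Read a TIFF (2D -> ImagePlane) or MRC (2D -> ImagePlane, 3D -> TomogramStack).

    MRC voxel size comes from the header (converted A -> nm); pass
    ``pixel_size_nm`` to override it, or to supply one for TIFFs without
    resolution metadata (default 1.0 with a metadata note).
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TIFF_EXT:
        try:
            data = tifffile.imread(path)
        except Exception as exc:
            raise CLEMIOError(f"cannot read TIFF {path}: {exc}") from exc
        if data.ndim != 2:
            raise CLEMIOError(f"cannot read TIFF {path}: expected a 2D image, got shape {data.shape}")
        px = pixel_size_nm
        if px is None:
            px = _tiff_pixel_size_nm(path)
        meta = {"path": str(path)}
        if px is None:
            px = 1.0
            meta["pixel_size_assumed"] = True
        return ImagePlane(
            pixels=np.asarray(data), pixel_size_nm=px,
            frame_id=frame_id or path.stem, channel=channel, metadata=meta,
        )
    if ext in _MRC_EXT:
        try:
            m = gemmi.read_ccp4_map(str(path))
        except Exception as exc:
            raise CLEMIOError(f"cannot read MRC {path}: {exc}") from exc
        grid = np.array(m.grid, copy=True)  # (x, y, z) fastest-first
        vol = grid.transpose(2, 1, 0)  # -> (z, y, x)
        voxel_a = m.grid.spacing[0]
        px = pixel_size_nm if pixel_size_nm is not None else (voxel_a * 0.1 if voxel_a > 0 else 1.0)
        if vol.shape[0] == 1:
            return ImagePlane(
                pixels=vol[0], pixel_size_nm=px,
                frame_id=frame_id or path.stem, channel=channel or "EM",
                metadata={"path": str(path)},
            )
        return TomogramStack(voxels=vol, voxel_size_nm=px)
    raise CLEMIOError(
        f"cannot read {path}: unsupported extension {ext!r} (expected TIFF or MRC)"
    )


def _tiff_pixel_size_nm(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None:
                return None
            num, den = res.value
            if num == 0:
                return None
            per_unit = num / den  # pixels per unit
            unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", None) or 0)
            if unit_nm is None:
                return None
            return unit_nm / per_unit
    except Exception:
        return None


def write_image(obj, path, *, dtype=None) -> None:
    """Write an ImagePlane (TIFF or MRC) or a TomogramStack (MRC).

    TIFF output embeds the pixel size as resolution metadata; MRC output is
    mode 2 (float32) with the voxel size in the header.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if isinstance(obj, ImagePlane) and ext in _TIFF_EXT:
        data = obj.pixels if dtype is None else np.asarray(obj.pixels).astype(dtype)
        px_cm = 1e7 / obj.pixel_size_nm  # pixels per centimeter
        tifffile.imwrite(path, data, resolution=(px_cm, px_cm), resolutionunit=3)
        return
    if ext in _MRC_EXT:
        if isinstance(obj, ImagePlane):
            vol = np.asarray(obj.pixels, dtype=np.float32)[None, :, :]
            voxel_nm = obj.pixel_size_nm
        elif isinstance(obj, TomogramStack):
            vol = np.asarray(obj.voxels, dtype=np.float32)
            voxel_nm = obj.voxel_size_nm
        else:
            raise CLEMIOError(f"cannot write {type(obj).__name__} to {path}")
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.transpose(2, 1, 0)))
        a = voxel_nm * 10.0  # nm -> Angstrom
        m.grid.unit_cell = gemmi.UnitCell(vol.shape[2] * a, vol.shape[1] * a, vol.shape[0] * a, 90, 90, 90)
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
        return
    raise CLEMIOError(f"cannot write {path}: unsupported extension {ext!r} for {type(obj).__name__}")


_REQUIRED_COLS = ("frame_id", "x", "y")


def read_points(path) -> PointSet:
    """Read a fiducial CSV (header ``frame_id,x,y``, extra columns kept).

    All rows must share one frame_id; x and y must be numeric.  Errors name
    the offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise CLEMIOError(f"cannot read points CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise CLEMIOError(f"points CSV {path} is missing required columns {missing}")
    if len(df.columns) != len(set(df.columns)):
        raise CLEMIOError(f"points CSV {path} has duplicated column names")

    if len(df) == 0:
        return PointSet(points=np.empty((0, 2)), frame_id=path.stem)

    # a duplicated header line shows up as a row whose cells repeat the header
    for i, row in df.iterrows():
        if str(row["x"]).strip() == "x" or str(row["y"]).strip() == "y":
            raise CLEMIOError(f"points CSV {path}: duplicated header at row {i + 2}")

    coords = np.empty((len(df), 2))
    for i, row in df.iterrows():
        try:
            coords[i] = (float(row["x"]), float(row["y"]))
        except (TypeError, ValueError):
            raise CLEMIOError(
                f"points CSV {path}: non-numeric coordinate at row {i + 2} "
                f"(x={row['x']!r}, y={row['y']!r})"
            ) from None
    frames = df["frame_id"].unique()
    if len(frames) > 1:
        raise CLEMIOError(
            f"points CSV {path} mixes frames {sorted(frames)}; one frame per file"
        )
    ps = PointSet(points=coords, frame_id=str(frames[0]))
    if "pixel_size_nm" in df.columns:
        try:
            ps.pixel_size_nm = float(df["pixel_size_nm"].iloc[0])
        except (TypeError, ValueError):
            pass
    return ps


def write_points(ps: PointSet, path, *, extra: dict | None = None) -> None:
    """Write a PointSet as a fiducial CSV; row order follows the point order."""
    path = Path(path)
    cols = ["frame_id", "x", "y"]
    rows = [
        {"frame_id": ps.frame_id, "x": repr(float(x)), "y": repr(float(y))}
        for x, y in ps.points
    ]
    if ps.pixel_size_nm is not None:
        cols.append("pixel_size_nm")
        for r in rows:
            r["pixel_size_nm"] = repr(float(ps.pixel_size_nm))
    for key, values in (extra or {}).items():
        cols.append(key)
        for r, v in zip(rows, values):
            r[key] = v
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        writer.writerows(rows)
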