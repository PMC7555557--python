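"""Image and ROI I/O: pixel-grid conventions for the whole pipeline.

Coordinate conventions
----------------------
Coordinates are 0-based ``(row, col)``.  Pixel ``(r, c)`` covers the
half-open square ``[r, r+1) x [c, c+1)`` and has center ``(r+0.5, c+0.5)``.
Rows are axial depth and columns lateral width, matching the screen
orientation of a clinical sonogram; the depth-to-width ratio downstream
relies on this.

Grayscale use of an RGB Doppler frame goes through ITU-R 601 luma.
"""

from __future__ import annotations

import glob as _glob
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as _MplPath
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import FormatError, ValidationError

__all__ = [
    "GrayImage",
    "RoiPolygon",
    "RoiMask",
    "DopplerFrame",
    "read_image",
    "rasterize_roi",
    "read_roi_json",
    "write_roi_json",
    "doppler_to_gray",
]

# ITU-R 601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """8-bit single-channel ultrasound image.

    ``axial_axis`` names the grid axis that corresponds to depth
    (0 = rows, the default for screen-oriented sonograms).
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0
    axial_axis: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("GrayImage requires a 2-D intensity grid")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("intensities must lie within [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RoiPolygon:
    """Ordered (row, col) boundary vertices of a manually drawn ROI.

    The polygon is closed implicitly (last vertex connects to the first)
    and must be simple after closure.
    """

    vertices: np.ndarray
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValidationError("a polygon needs at least 3 vertices")
        sh = _ShapelyPolygon(self.vertices)
        if not sh.is_simple:
            raise ValidationError("polygon is self-intersecting")

    @property
    def area(self) -> float:
        """Shoelace area of the closed polygon."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


@dataclass
class RoiMask:
    """Binary mask aligned to a GrayImage grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if self.area_px < 1:
            raise ValidationError("mask covers no pixels")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class DopplerFrame:
    """RGB color-Doppler frame with the on-screen velocity color-bar.

    ``colorbar_region`` is ``(r0, c0, r1, c1)`` (half-open, row/col) locating
    the rendered bar; ``vmax`` is the velocity (cm/s) at the top of the bar.
    """

    pixels: np.ndarray
    colorbar_region: tuple[int, int, int, int]
    vmax: float
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("DopplerFrame requires an RGB grid")
        self.pixels = self.pixels.astype(np.uint8)
        r0, c0, r1, c1 = self.colorbar_region
        h, w = self.pixels.shape[:2]
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValidationError("colorbar_region outside image bounds")
        if self.vmax <= 0:
            raise ValidationError("vmax must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def doppler_to_gray(frame: DopplerFrame) -> GrayImage:
    """ITU-R 601 luma conversion of an RGB Doppler frame."""
    luma = np.tensordot(frame.pixels.astype(float), _LUMA, axes=([2], [0]))
    return GrayImage(np.clip(np.round(luma), 0, 255), pixel_spacing=frame.pixel_spacing)


def _read_dicom(path: Path):
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pydicom raises a zoo of parse errors
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    spacing = 1.0
    if "PixelSpacing" in ds:
        spacing = float(ds.PixelSpacing[0])
    return arr, spacing


def read_image(
    path,
    format: str | None = None,
    colorbar_region: tuple[int, int, int, int] | None = None,
    vmax: float | None = None,
) -> GrayImage | DopplerFrame:
    """Read a PNG/TIFF/DICOM image as a GrayImage or DopplerFrame.

    Single-channel payloads become :class:`GrayImage` (rescaled to 8-bit if
    deeper); RGB payloads become :class:`DopplerFrame`, which requires
    ``colorbar_region`` and ``vmax``.  ``format`` is inferred from the file
    suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"{path}: no such file")
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"png": "png", "tif": "tiff", "tiff": "tiff", "dcm": "dicom"}.get(
            suffix, "png"
        )
    spacing = 1.0
    if format == "dicom":
        arr, spacing = _read_dicom(path)
    elif format in ("png", "tiff"):
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except (UnidentifiedImageError, OSError, SyntaxError) as exc:
            raise FormatError(f"{path}: not a readable {format} image") from exc
    else:
        raise ValidationError(f"unknown format {format!r}")

    if arr.ndim == 3 and arr.shape[2] >= 3:
        if colorbar_region is None or vmax is None:
            raise ValidationError(
                "RGB image read as DopplerFrame requires colorbar_region and vmax"
            )
        return DopplerFrame(
            arr[:, :, :3], colorbar_region=colorbar_region, vmax=vmax,
            pixel_spacing=spacing,
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: unsupported image layout {arr.shape}")
    if arr.dtype != np.uint8:  # normalize deeper intensity payloads to 8-bit
        lo, hi = float(arr.min()), float(arr.max())
        arr = np.zeros_like(arr, dtype=np.uint8) if hi == lo else np.round(
            255.0 * (arr.astype(float) - lo) / (hi - lo)
        ).astype(np.uint8)
    return GrayImage(arr, pixel_spacing=spacing)


def rasterize_roi(poly: RoiPolygon, shape: tuple[int, int]) -> RoiMask:
    """Rasterize a polygon: a pixel is included iff its center is inside.

    Uses the even-odd rule on pixel centers ``(r+0.5, c+0.5)``.  A polygon
    whose rasterization is empty (degenerate or fully outside the grid)
    raises :class:`ValidationError`.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    centers = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    path = _MplPath(np.vstack([poly.vertices, poly.vertices[:1]]), closed=True)
    inside = path.contains_points(centers).reshape(h, w)
    if not inside.any():
        raise ValidationError("polygon rasterizes to an empty mask")
    return RoiMask(inside)


def read_roi_json(path) -> list[RoiPolygon]:
    """Read ROI polygons for one mass.

    Schema: ``{"mass_id": ..., "image_id": ..., "rois": [[[r, c], ...], ...]}``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if "rois" not in payload:
        raise FormatError(f"{path}: missing 'rois' key")
    image_id = str(payload.get("image_id", ""))
    return [RoiPolygon(np.asarray(v, dtype=float), source_image_id=image_id)
            for v in payload["rois"]]


def write_roi_json(path, mass_id: str, image_id: str, polys: list[RoiPolygon]) -> None:
    payload = {
        "mass_id": mass_id,
        "image_id": image_id,
        "rois": [p.vertices.tolist() for p in polys],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def expand_globs(patterns) -> list[str]:
    """Expand CLI path globs, keeping literal paths that match nothing."""
    out: list[str] = []
    for pat in patterns:
        hits = sorted(_glob.glob(str(pat)))
        out.extend(hits if hits else [str(pat)])
    return out
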