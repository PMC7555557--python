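"""Grayscale (B-mode) morphology and intensity features per ROI.

Nine features characterize a lesion's shape and margin, mirroring the
visual criteria radiologists use on B-mode ultrasound:

- morphology: axis ratio (AR), depth-to-width ratio (DWR), radius
  variation (RV), tortuosity, ellipse-normalized skeleton (ENS);
- intensity: brightness difference (BD), margin sharpness (MS), angular
  variation of the interior (AVI) and of the margin (AVM).

All geometry is built on a moment-based equivalent ellipse (same second
central moments as the mask, rescaled to the mask area) and a polar
boundary profile r(theta) sampled from the mask centroid.  Intensity
features compare a thin band just inside the boundary with a band just
outside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import skeletonize

from .errors import ValidationError
from .image_io import GrayImage, RoiMask

__all__ = [
    "EllipseFit",
    "GsFeatures",
    "fit_ellipse",
    "ellipse_perimeter",
    "boundary_profile",
    "shape_features",
    "intensity_features",
    "extract_gs_features",
    "GS_FEATURE_NAMES",
]

GS_FEATURE_NAMES = ("AVI", "AVM", "BD", "MS", "AR", "DWR", "RV", "ENS", "tortuosity")


@dataclass
class EllipseFit:
    """Equivalent ellipse of a mask: same centroid and moment axes, area-matched."""

    center: tuple[float, float]
    a: float  # semi-major, px
    b: float  # semi-minor, px
    orientation: float  # radians of the major axis from the column (lateral) axis

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValidationError("ellipse requires a >= b > 0")

    @property
    def perimeter(self) -> float:
        return ellipse_perimeter(self.a, self.b)


@dataclass
class GsFeatures:
    AVI: float
    AVM: float
    BD: float
    MS: float
    AR: float
    DWR: float
    RV: float
    ENS: float
    tortuosity: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GS_FEATURE_NAMES}


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (relative error < 1e-4 for any a/b here)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def fit_ellipse(mask: RoiMask) -> EllipseFit:
    """Moment-based equivalent ellipse of a binary mask.

    Center is the pixel-centroid; axis directions and ratio come from the
    eigendecomposition of the second central moment matrix; both semi-axes
    are then rescaled together so the ellipse area equals the mask area.
    """
    rows, cols = np.nonzero(mask.mask)
    n = rows.size
    if n < 9:
        raise ValidationError("mask too small for an ellipse fit (area_px < 9)")
    r0, c0 = rows.mean(), cols.mean()
    dr, dc = rows - r0, cols - c0
    cov = np.array([[np.mean(dr * dr), np.mean(dr * dc)],
                    [np.mean(dr * dc), np.mean(dc * dc)]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-9:
        raise ValidationError("degenerate (collinear) mask")
    b, a = 2.0 * np.sqrt(evals)  # ellipse with identical normalized moments
    scale = math.sqrt(n / (math.pi * a * b))
    a, b = a * scale, b * scale
    major = evecs[:, 1]  # (d_row, d_col) of the major axis
    orientation = math.atan2(major[0], major[1])
    return EllipseFit(center=(float(r0), float(c0)), a=float(a), b=float(b),
                      orientation=float(orientation))


def boundary_profile(mask: RoiMask, n_angles: int = 360) -> np.ndarray:
    """Polar boundary profile r(theta) about the mask centroid.

    Rays leave the centroid at ``n_angles`` equally spaced angles (theta
    measured from the +column axis, increasing toward +rows); r(theta) is
    the distance to the farthest mask crossing along each ray, so
    non-star-shaped boundaries resolve to their outer crossing.
    """
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValidationError("empty mask")
    r0, c0 = rows.mean(), cols.mean()
    if not mask.mask[int(r0), int(c0)]:
        raise ValidationError("centroid lies outside the mask")
    h, w = mask.shape
    rmax = math.hypot(h, w)
    step = 0.125
    thetas = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    ts = np.arange(0.0, rmax, step)
    # boundary = 0.5-level set of the bilinearly interpolated mask indicator
    # (sub-pixel, consistent with marching-squares contours); r0/c0 are in
    # pixel-index space, which is also map_coordinates' frame
    iy = r0 + np.outer(np.sin(thetas), ts)
    ix = c0 + np.outer(np.cos(thetas), ts)
    field = ndimage.map_coordinates(mask.mask.astype(float), [iy, ix],
                                    order=1, mode="constant")
    inside = field >= 0.5
    # farthest inside sample per ray, then linear sub-step refinement of the
    # 0.5 crossing between that sample and the next
    idx_last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    rows_i = np.arange(len(thetas))
    f_last = field[rows_i, idx_last]
    idx_next = np.minimum(idx_last + 1, field.shape[1] - 1)
    f_next = field[rows_i, idx_next]
    drop = f_last - f_next
    frac = np.where(drop > 1e-12, (f_last - 0.5) / np.where(drop > 1e-12, drop, 1.0), 0.0)
    radii = np.where(inside.any(axis=1), ts[idx_last] + step * np.clip(frac, 0, 1), 0.0)
    return radii


def _skeleton_length(mask_arr: np.ndarray) -> float:
    """Length of the 1-px medial axis: unit steps orthogonal, sqrt(2) diagonal.

    Diagonal links that short-cut an existing orthogonal 2-step path are not
    double counted.
    """
    skel = skeletonize(mask_arr, method="lee")
    ys, xs = np.nonzero(skel)
    if ys.size == 0:
        return 0.0
    pts = set(zip(ys.tolist(), xs.tolist()))
    length = 0.0
    for y, x in pts:
        for dy, dx in ((0, 1), (1, 0)):  # each orthogonal edge once
            if (y + dy, x + dx) in pts:
                length += 1.0
        for dy, dx in ((1, 1), (1, -1)):  # each diagonal edge once
            if (y + dy, x + dx) in pts:
                # skip if the two endpoints share an orthogonal neighbor
                if (y, x + dx) in pts or (y + dy, x) in pts:
                    continue
                length += math.sqrt(2.0)
    return length if length > 0 else float(ys.size)


def _boundary_arclength(mask_arr: np.ndarray) -> float:
    # Crofton estimate: unbiased for smooth boundaries, unlike the staircase
    # length of a marching-squares contour
    return float(measure.perimeter_crofton(mask_arr, directions=4))


def shape_features(mask: RoiMask, axial_axis: int = 0,
                   n_angles: int = 360) -> dict[str, float]:
    """AR, DWR, RV, tortuosity, ENS of a binary ROI mask.

    AR = a/b of the equivalent ellipse; DWR = axial bounding-box extent over
    lateral extent; RV = std/mean of the boundary profile; tortuosity =
    boundary arclength over the equivalent-ellipse perimeter; ENS = medial
    skeleton length over the equivalent-ellipse perimeter.
    """
    fit = fit_ellipse(mask)
    rows, cols = np.nonzero(mask.mask)
    ext_rows = rows.max() - rows.min() + 1.0
    ext_cols = cols.max() - cols.min() + 1.0
    axial, lateral = (ext_rows, ext_cols) if axial_axis == 0 else (ext_cols, ext_rows)
    profile = boundary_profile(mask, n_angles=n_angles)
    rv = float(profile.std() / profile.mean())
    tort = _boundary_arclength(mask.mask) / fit.perimeter
    ens = _skeleton_length(mask.mask) / fit.perimeter
    return {
        "AR": fit.a / fit.b,
        "DWR": float(axial / lateral),
        "RV": rv,
        "tortuosity": float(tort),
        "ENS": float(ens),
    }


def _boundary_points_and_normals(mask: RoiMask, n_angles: int):
    """Boundary samples from the polar profile plus outward unit normals.

    The normal at each sample is perpendicular to the local boundary tangent
    (central difference of neighboring samples), oriented outward.
    """
    rows, cols = np.nonzero(mask.mask)
    r0, c0 = rows.mean() + 0.5, cols.mean() + 0.5
    profile = boundary_profile(mask, n_angles=n_angles)
    thetas = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    ys = r0 + profile * np.sin(thetas)
    xs = c0 + profile * np.cos(thetas)
    # tangent over a +-3-sample stencil: adjacent samples sit well under a
    # pixel apart, so a 1-sample stencil would be dominated by rasterization
    # jitter in the profile
    stencil = 3
    ty = np.roll(ys, -stencil) - np.roll(ys, stencil)
    tx = np.roll(xs, -stencil) - np.roll(xs, stencil)
    ny, nx = tx, -ty  # rotate tangent by -90 deg
    norm = np.hypot(ny, nx)
    norm[norm == 0] = 1.0
    ny, nx = ny / norm, nx / norm
    # orient outward: positive projection on the radial direction
    flip = (ny * (ys - r0) + nx * (xs - c0)) < 0
    ny[flip] *= -1
    nx[flip] *= -1
    return ys, xs, ny, nx, thetas


def intensity_features(image: GrayImage, mask: RoiMask, band_px: int = 5,
                       n_sectors: int = 36, n_angles: int = 360) -> dict[str, float]:
    """BD, MS, AVI, AVM from a grayscale image and its ROI mask.

    BD is the mean intensity of a ``band_px``-wide band just outside the
    boundary minus the mean of the band just inside.  MS is the mean
    absolute intensity difference between points ``band_px`` outside and
    ``band_px`` inside the boundary along the local normal.  AVI is the
    standard deviation over ``n_sectors`` equal angular sectors of the mean
    interior intensity; AVM is the standard deviation over the same sectors
    of the per-sector mean margin sharpness.
    """
    if image.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    rows, cols = np.nonzero(mask.mask)
    if (rows.min() < band_px or cols.min() < band_px
            or rows.max() >= image.shape[0] - band_px
            or cols.max() >= image.shape[1] - band_px):
        raise ValidationError("outer band would extend beyond the image")
    img = image.pixels.astype(float)

    dist_in = ndimage.distance_transform_edt(mask.mask)
    dist_out = ndimage.distance_transform_edt(~mask.mask)
    inner = mask.mask & (dist_in <= band_px)
    outer = (~mask.mask) & (dist_out <= band_px)
    bd = float(img[outer].mean() - img[inner].mean())

    ys, xs, ny, nx, thetas = _boundary_points_and_normals(mask, n_angles)
    out_pts = np.vstack([ys + band_px * ny, xs + band_px * nx]) - 0.5
    in_pts = np.vstack([ys - band_px * ny, xs - band_px * nx]) - 0.5
    i_out = ndimage.map_coordinates(img, out_pts, order=1, mode="nearest")
    i_in = ndimage.map_coordinates(img, in_pts, order=1, mode="nearest")
    ms_samples = np.abs(i_out - i_in)
    ms = float(ms_samples.mean())

    # sector index of an angle in [0, 2*pi)
    def sector_of(theta: np.ndarray) -> np.ndarray:
        return np.minimum(
            (np.mod(theta, 2.0 * math.pi) / (2.0 * math.pi) * n_sectors).astype(int),
            n_sectors - 1,
        )

    r0, c0 = rows.mean(), cols.mean()
    pix_theta = np.arctan2(rows - r0, cols - c0)
    pix_sector = sector_of(pix_theta)
    interior_vals = img[rows, cols]
    sector_means = [interior_vals[pix_sector == s].mean()
                    for s in range(n_sectors) if np.any(pix_sector == s)]
    avi = float(np.std(sector_means))

    ms_sector = sector_of(thetas)
    ms_means = [ms_samples[ms_sector == s].mean()
                for s in range(n_sectors) if np.any(ms_sector == s)]
    avm = float(np.std(ms_means))

    return {"BD": bd, "MS": ms, "AVI": avi, "AVM": avm}


def extract_gs_features(image: GrayImage, mask: RoiMask, band_px: int = 5,
                        n_sectors: int = 36, n_angles: int = 360) -> GsFeatures:
    """All nine grayscale features for one ROI."""
    shp = shape_features(mask, axial_axis=image.axial_axis, n_angles=n_angles)
    inten = intensity_features(image, mask, band_px=band_px,
                               n_sectors=n_sectors, n_angles=n_angles)
    return GsFeatures(**inten, **shp)
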