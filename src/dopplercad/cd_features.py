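"""Color-Doppler vascularity features: VFA and VI.

The on-screen Doppler color-bar is sampled into 100 equally spaced velocity
levels per flow direction, level ``l`` mapping to velocity index
``v(l) = l/100`` (fraction of the bar's maximum velocity ``vmax``).  A pixel
counts as Doppler signal when its RGB chromaticity distance from the gray
axis exceeds a threshold; each such pixel inherits the velocity index of its
nearest color-bar swatch.  From the per-pixel velocity-index map and an ROI:

- VFA (vascular fractional area) = percent of ROI pixels with color signal;
- VI (velocity index) = mean velocity index over those colored ROI pixels
  (0 when the ROI has no color signal).

Both flow directions (toward/away from the probe) map to the same
nonnegative index magnitude: the features measure vascularity, not flow
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import DopplerFrame, RoiMask

__all__ = [
    "ColorBar",
    "FlowMap",
    "CdFeatures",
    "extract_colorbar",
    "classify_flow",
    "vascularity",
    "CD_FEATURE_NAMES",
]

CD_FEATURE_NAMES = ("VI", "VFA")

N_LEVELS = 100


@dataclass
class ColorBar:
    """100-level velocity calibration sampled from a rendered color-bar.

    ``levels`` has shape (n_directions, 100, 3); row ``l-1`` holds the RGB
    swatch of level ``l`` (1..100).  Level ``l`` encodes the velocity
    fraction ``l/100`` of ``vmax``.
    """

    levels: np.ndarray
    vmax: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim == 2:
            self.levels = self.levels[None]
        if self.levels.shape[1:] != (N_LEVELS, 3):
            raise ValidationError("a ColorBar needs exactly 100 RGB levels per direction")
        if self.vmax <= 0:
            raise ValidationError("vmax must be positive")

    def velocity_index(self, level: int | np.ndarray) -> np.ndarray:
        """v(l) = l/100; strictly increasing, v(100) = 1."""
        return np.asarray(level, dtype=float) / N_LEVELS

    def velocity(self, level: int | np.ndarray) -> np.ndarray:
        """Physical velocity (cm/s) of a level."""
        return self.velocity_index(level) * self.vmax


@dataclass
class FlowMap:
    """Per-pixel Doppler classification aligned to a frame."""

    colored: np.ndarray
    vindex: np.ndarray

    def __post_init__(self) -> None:
        self.colored = np.asarray(self.colored, dtype=bool)
        self.vindex = np.asarray(self.vindex, dtype=float)
        if self.colored.shape != self.vindex.shape:
            raise ValidationError("colored and vindex shapes differ")
        if np.any((self.vindex > 0) & ~self.colored):
            raise ValidationError("vindex > 0 on a non-colored pixel")


@dataclass
class CdFeatures:
    VFA: float  # percent of ROI area
    VI: float  # mean velocity index (fraction of vmax)

    def __post_init__(self) -> None:
        if not (0.0 <= self.VFA <= 100.0):
            raise ValidationError("VFA out of [0, 100]")
        if self.VI < 0:
            raise ValidationError("VI must be nonnegative")
        if self.VFA == 0 and self.VI != 0:
            raise ValidationError("VI must be 0 when VFA is 0")

    def as_dict(self) -> dict[str, float]:
        return {"VI": self.VI, "VFA": self.VFA}


def extract_colorbar(frame: DopplerFrame, n_directions: int = 1) -> ColorBar:
    """Sample 100 equally spaced swatches per direction from the bar region.

    The bar's long axis carries velocity; for a vertical bar level 100
    (``vmax``) sits at the top of the region and level 1 near the bottom
    (mirrored for each additional direction block stacked below).  The
    region must offer at least 100 distinct sample positions per direction
    along its long axis.
    """
    r0, c0, r1, c1 = frame.colorbar_region
    region = frame.pixels[r0:r1, c0:c1].astype(float)
    if region.shape[0] < region.shape[1]:  # horizontal bar: rotate to vertical
        region = region.transpose(1, 0, 2)[::-1]
    length = region.shape[0]
    per_dir = length // n_directions
    if per_dir < N_LEVELS:
        raise ValidationError(
            f"colorbar region offers {per_dir} sample positions per direction; "
            f"{N_LEVELS} required"
        )
    ribbon = region.mean(axis=1)  # average across the bar's short axis
    directions = []
    for d in range(n_directions):
        block = ribbon[d * per_dir:(d + 1) * per_dir]
        # level l at fractional position (1 - l/100) from the block top
        pos = np.round((1.0 - np.arange(1, N_LEVELS + 1) / N_LEVELS)
                       * (per_dir - 1)).astype(int)
        directions.append(block[pos])
    return ColorBar(np.stack(directions), vmax=frame.vmax)


def chroma_distance(rgb: np.ndarray) -> np.ndarray:
    """Euclidean distance of RGB values from the gray axis r=g=b."""
    rgb = np.asarray(rgb, dtype=float)
    mean = rgb.mean(axis=-1, keepdims=True)
    return np.sqrt(((rgb - mean) ** 2).sum(axis=-1))


def classify_flow(frame: DopplerFrame, bar: ColorBar,
                  roi: RoiMask | None = None,
                  chroma_thresh: float = 20.0) -> FlowMap:
    """Classify Doppler-signal pixels and assign velocity indices.

    A pixel is colored iff its chromaticity distance from the gray axis
    exceeds ``chroma_thresh`` (8-bit RGB units).  Each colored pixel takes
    the velocity index of its nearest color-bar swatch (RGB Euclidean
    distance, ties resolved to the lower level).  The color-bar region
    itself is never classified as flow.  ``roi`` optionally restricts the
    classification to the ROI's pixels.
    """
    px = frame.pixels.astype(float)
    colored = chroma_distance(px) > chroma_thresh
    r0, c0, r1, c1 = frame.colorbar_region
    colored[r0:r1, c0:c1] = False
    if roi is not None:
        if roi.shape != frame.shape:
            raise ValidationError("frame and ROI shapes differ")
        colored &= roi.mask
    vindex = np.zeros(frame.shape, dtype=float)
    ys, xs = np.nonzero(colored)
    if ys.size:
        swatches = bar.levels.reshape(-1, 3)  # ascending level within direction
        vi_of_swatch = np.tile(np.arange(1, N_LEVELS + 1), bar.levels.shape[0]) / N_LEVELS
        d2 = ((px[ys, xs][:, None, :] - swatches[None]) ** 2).sum(axis=2)
        # argmin returns the first minimum: lower level wins ties
        vindex[ys, xs] = vi_of_swatch[np.argmin(d2, axis=1)]
    return FlowMap(colored=colored, vindex=vindex)


def vascularity(flow: FlowMap, roi: RoiMask,
                vi_denominator: str = "colored") -> CdFeatures:
    """VFA and VI of one ROI.

    ``vi_denominator="colored"`` (default) averages the velocity index over
    colored ROI pixels; ``"roi"`` averages over all ROI pixels, an
    alternative normalization some vascularity indices use.
    """
    if flow.colored.shape != roi.shape:
        raise ValidationError("flow map and ROI shapes differ")
    area = roi.area_px
    if area < 1:
        raise ValidationError("empty ROI")
    in_roi = roi.mask & flow.colored
    n_colored = int(in_roi.sum())
    vfa = 100.0 * n_colored / area
    if n_colored == 0:
        return CdFeatures(VFA=0.0, VI=0.0)
    total = float(flow.vindex[in_roi].sum())
    denom = n_colored if vi_denominator == "colored" else area
    return CdFeatures(VFA=vfa, VI=total / denom)
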