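"""Synthetic test bed: lesion images, Doppler overlays, tabular cohorts.

Three generators emulate the study conditions of a breast-ultrasound CAD
cohort so the full pipeline is testable without clinical images:

- :func:`make_lesion_image` draws a hypoechoic lesion on a speckled
  background.  The boundary is ``r(theta) = R * (1 + eps * cos(k*theta))``
  scaled anisotropically (axial vs lateral), with a Gaussian-blurred margin
  and multiplicative speckle; the analytic boundary doubles as the ROI
  polygon, and ground-truth RV, AR, DWR and BD are recorded.
- :func:`make_doppler_frame` paints vessel tracks over a grayscale image
  with exact color-bar swatches and renders a 100-level bar in the margin,
  recording ground-truth VFA/VI.
- :func:`simulate_cohort` draws tabular cohorts from class-conditional
  truncated Gaussians whose default means/SDs are the published feature
  distributions of the 95 benign / 64 malignant study cohort, with BI-RADS
  sampled from the study's category frequencies split so higher categories
  skew malignant.

Features are simulated independently per class (only marginals are
published); a correlation-matrix hook is provided for sensitivity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cd_features import N_LEVELS, ColorBar
from .cohort import NUMERIC_FEATURES, Cohort, cohort_from_frame
from .errors import ValidationError
from .image_io import DopplerFrame, GrayImage, RoiPolygon, rasterize_roi

__all__ = [
    "LesionSpec",
    "VesselSpec",
    "TabularSimSpec",
    "TABLE1_PARAMS",
    "BIRADS_CLASS_COUNTS",
    "make_lesion_image",
    "make_doppler_frame",
    "simulate_cohort",
    "default_bar_levels",
]

# Published class-conditional feature distributions:
# feature -> (benign mean, benign SD, malignant mean, malignant SD)
TABLE1_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "age": (46.2, 13.3, 57.1, 11.5),
    "AVI": (4.18, 1.66, 4.24, 1.84),
    "AVM": (3.35, 1.13, 3.60, 1.46),
    "BD": (17.2, 7.2, 11.0, 6.2),
    "MS": (82.8, 8.1, 74.0, 10.2),
    "AR": (1.74, 0.46, 1.60, 0.37),
    "DWR": (0.71, 0.19, 0.86, 0.27),
    "RV": (0.21, 0.07, 0.19, 0.07),
    "ENS": (0.14, 0.02, 0.15, 0.03),
    "tortuosity": (1.16, 0.07, 1.19, 0.12),
    "VI": (0.42, 0.58, 0.85, 0.64),
    "VFA": (0.82, 1.51, 2.59, 3.40),
}

# Physical bounds used to truncate the class-conditional Gaussians.
FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 95.0),
    "AVI": (0.0, math.inf),
    "AVM": (0.0, math.inf),
    "BD": (-math.inf, math.inf),
    "MS": (0.0, 255.0),
    "AR": (1.0, math.inf),
    "DWR": (0.05, math.inf),
    "RV": (0.0, math.inf),
    "ENS": (0.0, math.inf),
    "tortuosity": (1.0, math.inf),
    "VI": (0.0, math.inf),
    "VFA": (0.0, 100.0),
}

# Study BI-RADS category frequencies (0:12, 1:6, 2:9, 3:4, 4:66, 5:38 plus 24
# missing) split into per-class counts so higher categories skew malignant
# while the category-only classifier stays a weak baseline.
BIRADS_CLASS_COUNTS: dict[int, dict[str | int, int]] = {
    0: {0: 8, 1: 5, 2: 7, 3: 3, 4: 41, 5: 14, "missing": 17},   # benign, sum 95
    1: {0: 4, 1: 1, 2: 2, 3: 1, 4: 25, 5: 24, "missing": 7},    # malignant, sum 64
}


@dataclass
class VesselSpec:
    """A painted vessel track: polyline waypoints, half-width, velocity fraction."""

    path: list[tuple[float, float]]  # (row, col) waypoints
    width: float = 2.0
    velocity_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.velocity_fraction <= 1.0):
            raise ValidationError("velocity fraction must lie in (0, 1]")


@dataclass
class LesionSpec:
    """Parameters of one synthetic lesion."""

    radius: float = 40.0
    perturb_eps: float = 0.0
    perturb_k: int = 8
    axial_scale: float = 1.0
    lateral_scale: float = 1.0
    interior_mean: float = 50.0
    background_mean: float = 110.0
    margin_blur: float = 0.0  # Gaussian sigma, px
    speckle: float = 0.0  # multiplicative noise strength
    vessels: list[VesselSpec] = field(default_factory=list)
    label: int = 0

    def __post_init__(self) -> None:
        if self.radius < 10:
            raise ValidationError("lesion radius must be >= 10 px")
        if not (0.0 <= self.perturb_eps < 0.5):
            raise ValidationError("boundary perturbation eps must lie in [0, 0.5)")


def _polygon_second_moments(verts: np.ndarray):
    """Exact area, centroid and second central moments of a simple polygon."""
    r, c = verts[:, 0], verts[:, 1]
    r1, c1 = np.roll(r, -1), np.roll(c, -1)
    cross = c * r1 - c1 * r
    area = 0.5 * cross.sum()
    cr = ((r + r1) * cross).sum() / (6.0 * area)
    cc = ((c + c1) * cross).sum() / (6.0 * area)
    i_rr = ((r * r + r * r1 + r1 * r1) * cross).sum() / 12.0
    i_cc = ((c * c + c * c1 + c1 * c1) * cross).sum() / 12.0
    i_rc = ((2 * c * r + c * r1 + c1 * r + 2 * c1 * r1) * cross).sum() / 24.0
    a = abs(area)
    sgn = np.sign(area)
    m_rr = sgn * i_rr / a - cr * cr
    m_cc = sgn * i_cc / a - cc * cc
    m_rc = sgn * i_rc / a - cr * cc
    return a, (cr, cc), np.array([[m_rr, m_rc], [m_rc, m_cc]])


def make_lesion_image(spec: LesionSpec, seed: int = 0, canvas: int = 256):
    """Render a lesion image; returns (GrayImage, RoiPolygon, ground_truth).

    Ground truth holds RV (std/mean of boundary radii about the centroid),
    AR (from exact polygon second moments), DWR (polygon bounding-box axial
    over lateral extent) and BD (background minus interior contrast, before
    blur and speckle).
    """
    rng = np.random.default_rng(seed)
    center = (canvas / 2.0, canvas / 2.0)
    thetas = np.linspace(0.0, 2.0 * math.pi, 360, endpoint=False)
    r = spec.radius * (1.0 + spec.perturb_eps * np.cos(spec.perturb_k * thetas))
    rows = center[0] + spec.axial_scale * r * np.sin(thetas)
    cols = center[1] + spec.lateral_scale * r * np.cos(thetas)
    if rows.min() < 1 or cols.min() < 1 or rows.max() > canvas - 1 or cols.max() > canvas - 1:
        raise ValidationError("lesion exceeds the canvas")
    poly = RoiPolygon(np.column_stack([rows, cols]), source_image_id="phantom")

    mask = rasterize_roi(poly, (canvas, canvas)).mask
    img = np.where(mask, spec.interior_mean, spec.background_mean).astype(float)
    if spec.margin_blur > 0:
        img = ndimage.gaussian_filter(img, spec.margin_blur)
    if spec.speckle > 0:
        img = img * (1.0 + spec.speckle * rng.standard_normal(img.shape))
    image = GrayImage(np.clip(np.round(img), 0, 255))

    _, centroid, cov = _polygon_second_moments(poly.vertices)
    evals = np.linalg.eigvalsh(cov)
    radii = np.hypot(rows - centroid[0], cols - centroid[1])
    truth = {
        "RV": float(radii.std() / radii.mean()),
        "AR": float(math.sqrt(evals[1] / evals[0])),
        "DWR": float((rows.max() - rows.min()) / (cols.max() - cols.min())),
        "BD": float(spec.background_mean - spec.interior_mean),
    }
    return image, poly, truth


def default_bar_levels() -> np.ndarray:
    """Blue-to-red 100-level Doppler palette; every level is strongly chromatic."""
    lv = np.arange(1, N_LEVELS + 1) / N_LEVELS
    return np.column_stack([
        np.round(255 * lv), np.zeros(N_LEVELS), np.round(255 * (1 - lv)),
    ])


_BAR_HEIGHT = 200
_BAR_WIDTH = 8


def _render_colorbar(frame: np.ndarray, region, levels: np.ndarray) -> None:
    r0, c0, r1, c1 = region
    h = r1 - r0
    for y in range(h):
        lvl = int(np.clip(round(N_LEVELS * (1.0 - y / (h - 1))), 1, N_LEVELS))
        frame[r0 + y, c0:c1] = levels[lvl - 1]


def make_doppler_frame(image: GrayImage, spec: LesionSpec, vmax: float = 10.0,
                       bar_levels: np.ndarray | None = None, seed: int = 0):
    """Paint Doppler vessels over a grayscale image with a rendered color-bar.

    Each vessel's pixels get the exact swatch of level
    ``round(100 * velocity_fraction)``; a 100-swatch vertical bar is
    rendered in the right margin.  Returns (DopplerFrame, ground truth
    (VFA, VI) within the lesion ROI, painted mask).
    """
    levels = default_bar_levels() if bar_levels is None else np.asarray(bar_levels)
    h, w = image.shape
    frame = np.repeat(image.pixels[:, :, None], 3, axis=2).astype(float)
    region = (0, w - _BAR_WIDTH, min(_BAR_HEIGHT, h), w)
    if region[2] < N_LEVELS:
        raise ValidationError("image too short to render a 100-level color-bar")
    painted = np.zeros((h, w), dtype=bool)
    vfrac = np.zeros((h, w), dtype=float)
    rr, cc = np.mgrid[0:h, 0:w]
    for vessel in spec.vessels:
        pts = np.asarray(vessel.path, dtype=float)
        if (pts < 0).any() or (pts[:, 0] >= h).any() or (pts[:, 1] >= w).any():
            raise ValidationError("vessel path outside the canvas")
        level = int(np.clip(round(N_LEVELS * vessel.velocity_fraction), 1, N_LEVELS))
        hit = np.zeros((h, w), dtype=bool)
        for p, q in zip(pts[:-1], pts[1:]):
            d = _dist_to_segment(rr, cc, p, q)
            hit |= d <= vessel.width
        frame[hit] = levels[level - 1]
        painted |= hit
        vfrac[hit] = level / N_LEVELS
    _render_colorbar(frame, region, levels)
    dframe = DopplerFrame(np.clip(np.round(frame), 0, 255).astype(np.uint8),
                          colorbar_region=region, vmax=vmax)

    # ground truth inside the lesion ROI
    thetas = np.linspace(0.0, 2.0 * math.pi, 360, endpoint=False)
    r = spec.radius * (1.0 + spec.perturb_eps * np.cos(spec.perturb_k * thetas))
    rows = h / 2.0 + spec.axial_scale * r * np.sin(thetas)
    cols = w / 2.0 + spec.lateral_scale * r * np.cos(thetas)
    roi_mask = rasterize_roi(RoiPolygon(np.column_stack([rows, cols])), (h, w)).mask
    in_roi = painted & roi_mask
    n_col = int(in_roi.sum())
    vfa = 100.0 * n_col / int(roi_mask.sum())
    vi = float(vfrac[in_roi].mean()) if n_col else 0.0
    return dframe, {"VFA": vfa, "VI": vi}, painted


def _dist_to_segment(rr, cc, p, q) -> np.ndarray:
    pr, pc = p
    qr, qc = q
    dr, dc = qr - pr, qc - pc
    denom = dr * dr + dc * dc
    if denom == 0:
        return np.hypot(rr - pr, cc - pc)
    t = np.clip(((rr - pr) * dr + (cc - pc) * dc) / denom, 0.0, 1.0)
    return np.hypot(rr - (pr + t * dr), cc - (pc + t * dc))


@dataclass
class TabularSimSpec:
    """Class-conditional simulation parameters for a tabular cohort."""

    params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TABLE1_PARAMS))
    n_benign: int = 95
    n_malignant: int = 64
    n_missing_age: int = 3
    seed: int = 0
    correlation: np.ndarray | None = None  # optional feature correlation hook

    def __post_init__(self) -> None:
        if self.n_benign <= 0 or self.n_malignant <= 0:
            raise ValidationError("class sizes must be positive")
        for feat, (m0, s0, m1, s1) in self.params.items():
            if s0 <= 0 or s1 <= 0:
                raise ValidationError(f"{feat}: SDs must be positive")


def truncated_mean(feature: str, mean: float, sd: float) -> float:
    """Analytic mean of a feature's bound-truncated Gaussian."""
    lo, hi = FEATURE_BOUNDS.get(feature, (-math.inf, math.inf))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def _sample_feature(rng, feature, mean, sd, size, z=None):
    lo, hi = FEATURE_BOUNDS.get(feature, (-math.inf, math.inf))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    if z is None:
        return dist.rvs(size=size, random_state=rng)
    return dist.ppf(stats.norm.cdf(z))


def simulate_cohort(spec: TabularSimSpec) -> Cohort:
    """Draw a tabular cohort with the published class-conditional structure.

    Each numeric feature is an independent truncated Gaussian per class
    (Gaussian-copula correlated when ``spec.correlation`` is given);
    BI-RADS is categorical from the per-class frequency split, with missing
    a first-class value; a few ages are masked missing to mirror the
    clinical records.
    """
    rng = np.random.default_rng(spec.seed)
    feats = [f for f in NUMERIC_FEATURES if f in spec.params]
    frames = []
    for label, n in ((0, spec.n_benign), (1, spec.n_malignant)):
        block: dict[str, np.ndarray] = {}
        zmat = None
        if spec.correlation is not None:
            corr = np.asarray(spec.correlation)
            zmat = rng.multivariate_normal(np.zeros(len(feats)), corr, size=n)
        for j, feat in enumerate(feats):
            m0, s0, m1, s1 = spec.params[feat]
            mean, sd = (m0, s0) if label == 0 else (m1, s1)
            z = None if zmat is None else zmat[:, j]
            block[feat] = _sample_feature(rng, feat, mean, sd, n, z)
        counts = BIRADS_CLASS_COUNTS[label]
        cats = list(counts.keys())
        probs = np.array([counts[c] for c in cats], dtype=float)
        probs /= probs.sum()
        draws = rng.choice(len(cats), size=n, p=probs)
        block["birads"] = np.array(
            [np.nan if cats[d] == "missing" else float(cats[d]) for d in draws])
        df = pd.DataFrame(block)
        df["label"] = label
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df["mass_id"] = [f"sim{idx:04d}" for idx in range(len(df))]
    if spec.n_missing_age > 0:
        miss = rng.choice(len(df), size=min(spec.n_missing_age, len(df)),
                          replace=False)
        df.loc[miss, "age"] = np.nan
    return cohort_from_frame(df)


def build_colorbar(vmax: float = 10.0,
                   bar_levels: np.ndarray | None = None) -> ColorBar:
    """ColorBar of the phantom palette without rendering a frame."""
    levels = default_bar_levels() if bar_levels is None else np.asarray(bar_levels)
    return ColorBar(levels, vmax=vmax)
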