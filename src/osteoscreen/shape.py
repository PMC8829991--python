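"""Shape analysis of the inter-trabecular (marrow) space.

The marrow space between bone struts enlarges as osteoporosis progresses, so
its outline geometry carries signal.  Within the cancellous mask (the
cortical shell is excluded — it is brighter than trabecular bone and would
skew the threshold), Otsu's maximum between-class-variance method binarises
the ROI; the *below*-threshold class is the inter-trabecular space.  Its
8-connected components, after dropping sub-``min_region_area`` specks, are
measured by 14 parameters each:

  perimeter, area, regional density (area / perimeter²),
  circularity (4π · area / perimeter²), solidity (area / convex-hull area),
  length–width ratio and rectangularity of the minimum-area *rotated*
  bounding rectangle, and the 7 Hu invariant moments.

Because a vertebra usually holds several such regions, the per-vertebra
descriptor is the mean and population SD of each parameter over regions —
28 values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from shapely.geometry import MultiPoint
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .imaging import as_gray_image

__all__ = [
    "SHAPE_PARAM_NAMES",
    "SHAPE_FEATURE_NAMES",
    "Region",
    "otsu_threshold",
    "intertrabecular_regions",
    "region_shape_parameters",
    "shape_vector",
]

SHAPE_PARAM_NAMES = (
    "perimeter",
    "area",
    "regional_density",
    "circularity",
    "solidity",
    "aspect_ratio",
    "rectangularity",
) + tuple(f"hu{k}" for k in range(1, 8))

#: Canonical ordering of the 28 per-vertebra shape feature names
#: (mean and population SD over regions of each parameter).
SHAPE_FEATURE_NAMES = tuple(
    f"shape_{p}_{agg}" for p in SHAPE_PARAM_NAMES for agg in ("rmean", "rsd")
)

#: Regions smaller than this (px²) have ill-defined perimeter and moments.
DEFAULT_MIN_REGION_AREA = 5


@dataclasses.dataclass
class Region:
    """One connected inter-trabecular region and its raw measurements."""

    coords: np.ndarray  # (n, 2) pixel coordinates (row, col)
    area: float
    perimeter: float
    convex_area: float
    moments_hu: np.ndarray
    rect_length: float
    rect_width: float


def otsu_threshold(img: np.ndarray, mask: np.ndarray | None = None) -> int:
    """Otsu's threshold over the masked pixels, by exhaustive sweep.

    Returns the integer t in [0, 254] maximising the between-class variance
    of the two classes {≤ t} and {> t}; ties break toward the smallest t.
    """
    a = as_gray_image(img)
    if mask is None:
        mask = np.ones_like(a, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape must match the image")
    vals = a[mask]
    if vals.size == 0 or np.unique(vals).size < 2:
        raise ValueError("Otsu threshold requires ≥2 distinct masked values")
    hist = np.bincount(vals, minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)[:-1]            # weight of class {<= t}, t = 0..254
    w1 = 1.0 - w0
    m0 = np.cumsum(p * levels)[:-1]   # unnormalised class means
    mu_t = (p * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_t - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))    # argmax returns the first (smallest) maximiser


def _min_area_rect(coords: np.ndarray) -> tuple[float, float]:
    """Side lengths (length ≥ width) of the minimum-area rotated rectangle.

    Built on the pixel *corners* so an axis-aligned n×n square measures
    exactly n×n.  Degenerate 1-pixel-wide regions get width floored at 1.
    """
    pts = np.repeat(coords.astype(float), 4, axis=0)
    offs = np.tile(np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]]),
                   (len(coords), 1))
    rect = MultiPoint(pts + offs).convex_hull.minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords) if rect.geom_type == "Polygon" else None
    if xy is None:
        # collinear fallback (LineString): length of the segment, width 1
        length = float(rect.length) if hasattr(rect, "length") else 1.0
        return max(length, 1.0), 1.0
    sides = np.hypot(*(np.diff(xy[:4 + 1], axis=0).T))
    length, width = float(np.max(sides)), float(np.min(sides))
    return max(length, 1.0), max(width, 1.0)


def intertrabecular_regions(
    img: np.ndarray,
    mask: np.ndarray,
    min_region_area: int = DEFAULT_MIN_REGION_AREA,
) -> list[Region]:
    """8-connected components of the below-threshold class inside the mask.

    Components smaller than ``min_region_area`` pixels are dropped.  An empty
    result is legal (the caller decides how to aggregate).
    """
    a = as_gray_image(img)
    mask = np.asarray(mask, dtype=bool)
    t = otsu_threshold(a, mask)
    binary = (a <= t) & mask
    labels = _cc_label(binary, connectivity=2)
    regions: list[Region] = []
    for prop in regionprops(labels):
        if prop.area < min_region_area:
            continue
        length, width = _min_area_rect(prop.coords)
        regions.append(
            Region(
                coords=prop.coords,
                area=float(prop.area),
                perimeter=float(prop.perimeter),
                convex_area=float(prop.area_convex),
                moments_hu=np.asarray(prop.moments_hu, dtype=float),
                rect_length=length,
                rect_width=width,
            )
        )
    return regions


def region_shape_parameters(region: Region) -> dict[str, float]:
    """The 14 shape parameters of one region."""
    A = region.area
    P = region.perimeter
    p_sq = P * P if P > 0 else 1.0  # 1-px-scale guard; min_region_area makes P>0 in practice
    out = {
        "perimeter": P,
        "area": A,
        "regional_density": A / p_sq,
        "circularity": 4.0 * np.pi * A / p_sq,
        "solidity": A / region.convex_area if region.convex_area > 0 else 1.0,
        "aspect_ratio": region.rect_length / region.rect_width,
        "rectangularity": A / (region.rect_length * region.rect_width),
    }
    for k in range(7):
        out[f"hu{k + 1}"] = float(region.moments_hu[k])
    return out


def shape_vector(
    img: np.ndarray,
    mask: np.ndarray,
    min_region_area: int = DEFAULT_MIN_REGION_AREA,
    vertebra: str | None = None,
) -> dict[str, float]:
    """The 28-value per-vertebra shape descriptor.

    Mean and population SD over regions of each of the 14 parameters (all
    SDs are 0 when a single region survives).  Raises if no region survives,
    naming the vertebra when given.
    """
    regions = intertrabecular_regions(img, mask, min_region_area=min_region_area)
    if not regions:
        where = f" on vertebra {vertebra}" if vertebra else ""
        raise ValueError(f"no inter-trabecular region survives{where}")
    table = {p: np.array([region_shape_parameters(r)[p] for r in regions])
             for p in SHAPE_PARAM_NAMES}
    out: dict[str, float] = {}
    for p in SHAPE_PARAM_NAMES:
        out[f"shape_{p}_rmean"] = float(table[p].mean())
        out[f"shape_{p}_rsd"] = float(table[p].std(ddof=0))
    return {name: out[name] for name in SHAPE_FEATURE_NAMES}
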