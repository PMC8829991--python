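"""Per-vertebra texture descriptors: GLCM, gradient and histogram statistics.

Three families, 20 values in all:

* **GLCM** — the gray-level co-occurrence matrix at unit distance, full 256
  gray levels, accumulated symmetrically in the four standard orientations
  (0°, 45°, 90°, 135°).  Five Haralick-style statistics (entropy, energy,
  contrast, correlation, homogeneity) are computed per orientation, then
  summarised as the mean and population SD over the four orientations
  (10 values).
* **Gradient** — mean, population variance, skewness and kurtosis of the
  Sobel gradient-magnitude image (4 values).  Trabecular thinning changes
  the edge-content of the ROI, which these moments summarise.
* **Histogram** — mean, variance, skewness, kurtosis, energy and entropy of
  the 256-bin gray-level distribution (6 values).  The histogram mean drops
  with bone mineral loss.

Entropies are in bits.  Skewness and kurtosis use population moments with
non-excess kurtosis (a normal distribution gives ≈ 3); degenerate
zero-variance cases return 0 so feature tables never contain NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .imaging import as_gray_image

__all__ = [
    "ORIENTATIONS",
    "GLCM_STATS",
    "TEXTURE_FEATURE_NAMES",
    "compute_glcm",
    "glcm_statistics",
    "texture_over_orientations",
    "gradient_statistics",
    "histogram_statistics",
    "texture_vector",
]

#: Orientation angles (degrees) of the four unit-distance GLCM offsets.
ORIENTATIONS = (0, 45, 90, 135)

GLCM_STATS = ("entropy", "energy", "contrast", "correlation", "homogeneity")

_GRADIENT_NAMES = tuple(f"gradient_{m}" for m in ("mean", "variance", "skewness", "kurtosis"))
_HIST_NAMES = tuple(
    f"hist_{m}" for m in ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
)

#: Canonical ordering of the 20 per-vertebra texture feature names.
TEXTURE_FEATURE_NAMES = tuple(
    f"glcm_{s}_{agg}" for s in GLCM_STATS for agg in ("omean", "osd")
) + _GRADIENT_NAMES + _HIST_NAMES


def compute_glcm(
    img: np.ndarray, orientation: int, distance: int = 1, levels: int = 256
) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts at one orientation.

    Returns a ``levels × levels`` integer count matrix; each pixel pair at
    the orientation's unit offset contributes to both (i, j) and (j, i), so
    the four orientations together cover all eight neighbours.
    """
    a = as_gray_image(img)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation}")
    if a.shape[0] * a.shape[1] < 2 or min(a.shape) < 2:
        raise ValueError("image admits no pixel pair at the offset")
    # orientations are counted with the 45° offset pointing up-right,
    # (-1, +1) in (row, col); skimage counts rows downward, so its diagonal
    # angles are mirrored — with symmetric accumulation 45° ↔ 135° maps
    # between the conventions exactly.
    angle = np.deg2rad({0: 0, 45: 135, 90: 90, 135: 45}[orientation])
    glcm = graycomatrix(
        a, distances=[distance], angles=[angle], levels=levels,
        symmetric=True, normed=False,
    )
    counts = glcm[:, :, 0, 0].astype(np.int64)
    if counts.sum() == 0:
        raise ValueError("image admits no pixel pair at the offset")
    return counts


def glcm_statistics(glcm: np.ndarray) -> dict[str, float]:
    """Entropy, energy, contrast, correlation and homogeneity of a GLCM.

    Computed on the normalised matrix p(i, j).  A constant image yields a
    single-cell matrix; its correlation is defined as 1 (degenerate limit).
    """
    counts = np.asarray(glcm, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("GLCM has no counts")
    p = counts / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    j = i
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    diff = i[:, None] - j[None, :]
    contrast = float((diff**2 * p).sum())
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    var_j = float(((j - mu_j) ** 2 * pj).sum())
    denom = np.sqrt(var_i * var_j)
    if denom <= 0:
        correlation = 1.0
    else:
        cov = float(((i[:, None] - mu_i) * (j[None, :] - mu_j) * p).sum())
        correlation = cov / denom
    homogeneity = float((p / (1.0 + np.abs(diff))).sum())
    return {
        "entropy": entropy,
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "homogeneity": homogeneity,
    }


def texture_over_orientations(img: np.ndarray) -> dict[str, float]:
    """Mean and population SD of each GLCM statistic over the 4 orientations."""
    per_stat: dict[str, list[float]] = {s: [] for s in GLCM_STATS}
    for orient in ORIENTATIONS:
        stats = glcm_statistics(compute_glcm(img, orient))
        for s in GLCM_STATS:
            per_stat[s].append(stats[s])
    out: dict[str, float] = {}
    for s in GLCM_STATS:
        vals = np.array(per_stat[s])
        out[f"glcm_{s}_omean"] = float(vals.mean())
        out[f"glcm_{s}_osd"] = float(vals.std(ddof=0))
    return out


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/variance/skewness/non-excess-kurtosis; degenerate → 0."""
    v = np.asarray(values, dtype=float).ravel()
    mean = float(v.mean())
    var = float(v.var(ddof=0))
    if var <= 0:
        return mean, 0.0, 0.0, 0.0
    centred = v - mean
    sd = np.sqrt(var)
    skew = float((centred**3).mean() / sd**3)
    kurt = float((centred**4).mean() / var**2)
    return mean, var, skew, kurt


def gradient_statistics(img: np.ndarray, operator: str = "sobel") -> dict[str, float]:
    """Moments of the gradient-magnitude image.

    ``operator`` is ``"sobel"`` (integer Sobel kernels, reflect boundary) or
    ``"central"`` (central differences).  A flat field has zero gradient
    everywhere, giving all four moments 0.
    """
    a = as_gray_image(img).astype(float)
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError(f"gradient statistics require at least a 3×3 image, got {a.shape}")
    if operator == "sobel":
        gx = ndimage.sobel(a, axis=1, mode="reflect")
        gy = ndimage.sobel(a, axis=0, mode="reflect")
    elif operator == "central":
        gy, gx = np.gradient(a)
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    mag = np.hypot(gx, gy)
    mean, var, skew, kurt = _moments(mag)
    return dict(zip(_GRADIENT_NAMES, (mean, var, skew, kurt)))


def histogram_statistics(img: np.ndarray) -> dict[str, float]:
    """First-order statistics of the 256-bin gray-level distribution."""
    a = as_gray_image(img)
    h = np.bincount(a.ravel(), minlength=256).astype(float)
    h /= h.sum()
    mean, var, skew, kurt = _moments(a)
    nz = h[h > 0]
    energy = float((h**2).sum())
    entropy = float(-(nz * np.log2(nz)).sum())
    return dict(
        zip(_HIST_NAMES, (mean, var, skew, kurt, energy, entropy))
    )


def texture_vector(img: np.ndarray, gradient_operator: str = "sobel") -> dict[str, float]:
    """The full 20-value per-vertebra texture descriptor, canonically ordered."""
    out: dict[str, float] = {}
    out.update(texture_over_orientations(img))
    out.update(gradient_statistics(img, operator=gradient_operator))
    out.update(histogram_statistics(img))
    return {name: out[name] for name in TEXTURE_FEATURE_NAMES}
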