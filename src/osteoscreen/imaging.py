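"""Reading, windowing and standardisation of vertebral ROI images.

The unit of all downstream computation is an 8-bit grayscale image
(``numpy.ndarray`` of ``uint8``), typically a 64×64 mid-sagittal crop of a
lumbar vertebral body (L1–L4).  CT data arrive either as already-windowed
8-bit BMP/PNG exports or as DICOM slices in Hounsfield units, which are
rescaled and windowed here with the standard bone window
(width 1500 HU, level 300 HU).

Manual vertebra segmentation is out of scope: ROI files are inputs, one file
per intact vertebra (fractured vertebrae are represented simply by omitting
the file).  Because the cortical shell must be excluded from shape analysis
but no segmentation of it is available, :func:`derive_cancellous_mask`
provides a deterministic proxy — a fixed-margin inward erosion of the ROI
extent.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "WindowSpec",
    "VertebraROI",
    "STANDARD_SIZE",
    "VERTEBRAE",
    "apply_window",
    "resize_to_standard",
    "load_roi_image",
    "derive_cancellous_mask",
]

#: Side length of the standardised ROI.
STANDARD_SIZE = 64

#: Lumbar vertebra labels measured by DXA and used as ROIs.
VERTEBRAE = ("L1", "L2", "L3", "L4")


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """A CT display window in Hounsfield units (default: bone window)."""

    width: float = 1500.0
    level: float = 300.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be positive, got {self.width}")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


@dataclasses.dataclass
class VertebraROI:
    """A standardised 64×64 vertebral ROI with its cancellous-bone mask."""

    image: np.ndarray
    vertebra: str
    cancellous_mask: np.ndarray

    def __post_init__(self) -> None:
        self.image = as_gray_image(self.image)
        if self.image.shape != (STANDARD_SIZE, STANDARD_SIZE):
            raise ValueError(
                f"VertebraROI image must be {STANDARD_SIZE}×{STANDARD_SIZE}, "
                f"got {self.image.shape}"
            )
        if self.vertebra not in VERTEBRAE:
            raise ValueError(f"vertebra must be one of {VERTEBRAE}, got {self.vertebra!r}")
        mask = np.asarray(self.cancellous_mask, dtype=bool)
        if mask.shape != self.image.shape:
            raise ValueError("cancellous_mask shape must match the image")
        if not mask.any():
            raise ValueError("cancellous_mask is empty")
        self.cancellous_mask = mask


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to an 8-bit grayscale image.

    Requires a 2-D array, at least 2×2, with all values in [0, 255].
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got ndim={a.ndim}")
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError(f"gray image must be at least 2×2, got {a.shape}")
    if a.size == 0:
        raise ValueError("gray image is empty")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("gray image values must lie in [0, 255]")
    return a.astype(np.uint8)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the contract here is round-half-up.
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def apply_window(hu_image: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Map Hounsfield units through a display window onto 8-bit gray levels.

    The interval ``[level - width/2, level + width/2]`` is mapped linearly
    onto [0, 255]; values outside are clipped.  Rounding is half-up so the
    mapping is bit-exactly reproducible.
    """
    hu = np.asarray(hu_image, dtype=float)
    if hu.size == 0:
        raise ValueError("cannot window an empty image")
    if hu.ndim != 2:
        raise ValueError(f"HU image must be 2-D, got ndim={hu.ndim}")
    scaled = (hu - window.lo) / window.width * 255.0
    out = np.clip(_round_half_up(scaled), 0, 255)
    return out.astype(np.uint8)


def resize_to_standard(img: np.ndarray, size: int = STANDARD_SIZE) -> np.ndarray:
    """Resize a gray image to the standard square size (bilinear, rounded).

    Eliminates the influence of vertebra size on texture and shape features;
    a constant image stays constant and an already-standard image passes
    through unchanged.
    """
    a = as_gray_image(img)
    if a.shape == (size, size):
        return a.copy()
    out = _sk_resize(
        a.astype(float), (size, size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


def load_roi_image(path: str | Path, window: WindowSpec | None = None) -> np.ndarray:
    """Load one ROI image file as an 8-bit gray image.

    BMP/PNG files must already be 8-bit grayscale.  DICOM files carry HU
    values: the rescale slope/intercept is applied, then the image is
    windowed with *window* (required for DICOM).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _load_dicom(path, window)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "P", "I;16", "1"):
                raise ValueError(
                    f"{path}: expected an 8-bit grayscale image, got mode {im.mode!r}"
                )
            if im.mode != "L":
                im = im.convert("L")
            arr = np.asarray(im)
    except ValueError:
        raise
    except Exception as exc:  # unreadable / not an image
        raise ValueError(f"{path}: unreadable image file ({exc})") from exc
    return as_gray_image(arr)


def _load_dicom(path: Path, window: WindowSpec | None) -> np.ndarray:
    import pydicom

    if window is None:
        raise ValueError(f"{path}: a WindowSpec is required to load DICOM HU data")
    try:
        ds = pydicom.dcmread(str(path))
        raw = ds.pixel_array.astype(float)
    except Exception as exc:
        raise ValueError(f"{path}: unreadable DICOM file ({exc})") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = raw * slope + intercept
    return apply_window(hu, window)


def derive_cancellous_mask(img: np.ndarray, margin_fraction: float = 0.1) -> np.ndarray:
    """Proxy cancellous-bone mask: erode the ROI extent inward by a margin.

    The cortical shell runs along the ROI boundary; removing a rim of
    ``round(margin_fraction * min(height, width))`` pixels keeps only the
    trabecular interior used for shape analysis.
    """
    a = as_gray_image(img)
    if not (0 <= margin_fraction < 0.5):
        raise ValueError(
            f"margin_fraction must lie in [0, 0.5), got {margin_fraction}"
        )
    h, w = a.shape
    m = int(_round_half_up(margin_fraction * min(h, w)))
    mask = np.zeros((h, w), dtype=bool)
    if h - 2 * m <= 0 or w - 2 * m <= 0:
        raise ValueError("margin erodes the mask to nothing")
    mask[m : h - m, m : w - m] = True
    return mask
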