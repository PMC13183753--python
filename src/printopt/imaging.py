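"""Surface-defect quantification from top-view printlet photographs.

Two-stage thresholding: (1) an automatic histogram (Otsu) threshold
separates the bright printlet from the dark background and the largest
connected bright component, with interior holes filled, becomes the
printlet mask; (2) a fixed gray-level void threshold classifies pixels
inside the mask as voids.  The defect fraction is

    defect = (# void pixels inside the printlet) / (# printlet pixels),

where the denominator counts voids and non-voids alike.  Default void
thresholds: 0.45 for the batch printer, 0.35 for the continuous printer
(the printlet textures reflect light differently between the two).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "SegmentationResult",
    "to_grayscale",
    "segment_printlet",
    "defect_fraction",
    "measure_image",
    "load_image",
]

#: luma weights used for RGB -> grayscale conversion
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class SegmentationResult:
    """Masks, thresholds and the resulting defect fraction for one image."""

    printlet_mask: np.ndarray
    void_mask: np.ndarray
    background_threshold: float | None
    void_threshold: float
    defect_fraction: float

    def __post_init__(self) -> None:
        if not self.printlet_mask.any():
            raise ValueError("printlet mask is empty")
        if np.any(self.void_mask & ~self.printlet_mask):
            raise ValueError("void mask must be a subset of the printlet mask")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF photograph into a float array scaled to [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    return _rescale(arr)


def _rescale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(float) / np.iinfo(image.dtype).max
    return np.clip(image.astype(float), 0.0, 1.0)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB or grayscale image to a single channel in [0, 1].

    RGB is collapsed with the 0.299/0.587/0.114 luma weights; grayscale
    input passes through after rescaling.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    image = _rescale(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[..., 0]
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ LUMA_WEIGHTS
    raise ValueError(
        f"unsupported channel count: expected 1 or 3, got shape {image.shape}"
    )


def segment_printlet(gray: np.ndarray) -> np.ndarray:
    """Boolean mask of the printlet: largest bright Otsu component, holes filled.

    Hole filling makes interior voids count as printlet pixels so the
    defect denominator includes voids and non-voids.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.max() == gray.min():
        raise ValueError("no foreground/background contrast in image")
    thresh = threshold_otsu(gray)
    bright = gray > thresh
    if not bright.any():
        raise ValueError("no foreground/background contrast in image")
    labels = label(bright)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    mask = labels == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def defect_fraction(
    gray: np.ndarray,
    printlet_mask: np.ndarray,
    void_threshold: float,
    background_threshold: float | None = None,
) -> SegmentationResult:
    """Fraction of printlet pixels strictly below the void threshold."""
    gray = np.asarray(gray, dtype=float)
    printlet_mask = np.asarray(printlet_mask, dtype=bool)
    if not printlet_mask.any():
        raise ValueError("printlet mask is empty")
    if not 0.0 < void_threshold < 1.0:
        raise ValueError("void threshold must lie in (0, 1)")
    void_mask = printlet_mask & (gray < void_threshold)
    fraction = float(void_mask.sum() / printlet_mask.sum())
    return SegmentationResult(
        printlet_mask=printlet_mask,
        void_mask=void_mask,
        background_threshold=background_threshold,
        void_threshold=void_threshold,
        defect_fraction=fraction,
    )


def measure_image(
    image: np.ndarray,
    void_threshold: float = 0.45,
    roi: tuple[int, int, int, int] | None = None,
) -> SegmentationResult:
    """Full pipeline on one photograph: grayscale, segment, threshold voids.

    ``roi`` is an optional (row0, col0, row1, col1) crop applied first,
    replacing the manual background cropping a human operator would do for
    images the automatic segmentation cannot handle.
    """
    gray = to_grayscale(image)
    if roi is not None:
        r0, c0, r1, c1 = roi
        gray = gray[r0:r1, c0:c1]
    mask = segment_printlet(gray)
    thresh = float(threshold_otsu(gray))
    return defect_fraction(gray, mask, void_threshold, background_threshold=thresh)


def save_grayscale_png(image: np.ndarray, path: str | Path, bits: int = 8) -> None:
    """Write a [0, 1] float image as an 8- or 16-bit grayscale PNG."""
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bits == 8:
        Image.fromarray((image * 255).round().astype(np.uint8)).save(path)
    elif bits == 16:
        arr = (image * 65535).round().astype(np.uint16)
        Image.fromarray(arr, mode="I;16").save(path)
    else:
        raise ValueError("bits must be 8 or 16")
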