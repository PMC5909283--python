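"""Image loading, polarity normalization and patch extraction.

The pipeline operates on a single-channel 2-D intensity field ``u`` defined on
a rectangular pixel domain.  All downstream stages assume *bright* objects on a
darker background, so brightfield slides (dark tissue on bright glass) are
inverted up front.  Coordinates follow one convention everywhere: 0-based
pixel indices, pixel centers at integer positions, points stored as
``(x=column, y=row)`` with the origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "IntensityImage",
    "Patch",
    "load_image",
    "invert_if_dark_objects",
    "extract_patch",
]

_MODALITIES = ("binary", "brightfield", "fluorescence", "unknown")


@dataclass
class IntensityImage:
    """A 2-D scalar intensity field with a known acquisition modality.

    Parameters
    ----------
    pixels : ndarray, shape (height, width)
        Real-valued intensities in arbitrary units.
    modality : {"binary", "brightfield", "fluorescence", "unknown"}
        Acquisition regime.  Brightfield (and dark-spot binary) images carry
        dark objects and must be inverted before detection.
    """

    pixels: np.ndarray
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite everywhere")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Patch:
    """A square window of a parent image, clipped at the image borders.

    ``xs`` / ``ys`` are the parent-image coordinates of the patch columns and
    rows, so energies evaluated on a patch see the same coordinate frame as
    the full image.  Patches are clipped, never padded: sums over a patch run
    over valid pixels only.
    """

    pixels: np.ndarray
    center: tuple[float, float]
    radius: float
    xs: np.ndarray = field(repr=False)
    ys: np.ndarray = field(repr=False)

    @property
    def clipped(self) -> bool:
        side = 2 * int(np.floor(self.radius)) + 1
        return self.pixels.shape != (side, side)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) meshgrids of parent-image coordinates."""
        return np.meshgrid(self.xs, self.ys)


def load_image(path: str | Path, modality: str = "unknown") -> IntensityImage:
    """Read a TIFF or PNG image and normalize it to a single channel.

    Multi-channel inputs are reduced by an unweighted average over channels.
    Values are converted to float without any rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {suffix!r}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] > 4:
            raise ValueError(f"expected 1-4 channels, got {arr.shape[-1]}")
        arr = arr.astype(float).mean(axis=-1)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return IntensityImage(arr.astype(float), modality=modality)


def invert_if_dark_objects(img: IntensityImage) -> IntensityImage:
    """Invert brightfield images so that objects of interest are bright.

    ``pixels <- max(pixels) - pixels`` for brightfield inputs; fluorescence
    (bright spots already) and bright-spot binary images pass through
    unchanged.  Applying the rule twice restores the original intensity
    ordering (involution up to an additive constant).
    """
    if img.modality == "brightfield":
        return IntensityImage(img.pixels.max() - img.pixels, modality=img.modality)
    return img


def extract_patch(img: IntensityImage, center: tuple[float, float], radius: float) -> Patch:
    """Extract the square patch of all pixels x with ||x - c||_inf <= radius.

    The patch is clipped to the image domain near borders; the returned
    coordinate vectors record the valid extent.
    """
    cx, cy = float(center[0]), float(center[1])
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0 <= cx <= img.width - 1 and 0 <= cy <= img.height - 1):
        raise ValueError(f"patch center {center} outside image domain")
    r = int(np.floor(radius))
    x0 = max(int(np.ceil(cx - radius)), 0)
    x1 = min(int(np.floor(cx + radius)), img.width - 1)
    y0 = max(int(np.ceil(cy - radius)), 0)
    y1 = min(int(np.floor(cy + radius)), img.height - 1)
    del r
    return Patch(
        pixels=img.pixels[y0 : y1 + 1, x0 : x1 + 1],
        center=(cx, cy),
        radius=radius,
        xs=np.arange(x0, x1 + 1, dtype=float),
        ys=np.arange(y0, y1 + 1, dtype=float),
    )
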