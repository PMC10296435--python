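"""Image I/O and min-max contrast normalization.

Grayscale 2-D slices are the working unit throughout the package: they are
read as-is (no rescaling on load), contrast-stretched with a linear min-max
map, and handed to segmentation and feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile


class FormatError(ValueError):
    """Input decodes, but not to a single 2-D grayscale plane."""


class DegenerateImageError(ValueError):
    """Image violates a precondition (e.g. constant intensity)."""


@dataclass(frozen=True)
class RawImage:
    """A 2-D grayscale intensity grid in its stored units."""

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise FormatError(f"expected a 2-D plane, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image too small: {px.shape} (need >= 8x8)")
        if not np.all(np.isfinite(px)):
            raise ValueError("non-finite intensities in image")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class NormalizedImage:
    """Intensity grid linearly rescaled to [new_min, new_max]."""

    pixels: np.ndarray
    new_min: float = 0.0
    new_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.new_min < self.new_max:
            raise ValueError("new_min must be < new_max")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))


def load_image(
    path: str | Path,
    format: str | None = None,
    *,
    slice_index: int | None = None,
    collapse_channels: bool = False,
) -> RawImage:
    """Read a single 2-D grayscale plane from PNG/TIFF or a NIfTI slice.

    Intensities are returned exactly as stored; no rescaling happens here.
    Multi-channel images raise :class:`FormatError` unless
    ``collapse_channels`` is set, in which case channels are averaged.
    NIfTI volumes require ``slice_index`` (axial slice along the last axis).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _guess_format(path)
    if fmt == "nifti-slice":
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 2:
            arr = vol
        else:
            if slice_index is None:
                raise FormatError("NIfTI volume requires a slice index")
            arr = vol[..., slice_index] if vol.ndim == 3 else vol[..., slice_index, 0]
    elif fmt in ("png", "tiff"):
        if fmt == "tiff":
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
        if arr.ndim == 3:
            if not collapse_channels:
                raise FormatError(
                    f"{path.name} has {arr.shape[-1]} channels; "
                    "pass collapse_channels=True to average them"
                )
            arr = arr.astype(float).mean(axis=-1)
    else:
        raise FormatError(f"unsupported format: {fmt}")
    return RawImage(pixels=np.asarray(arr, dtype=float), source_path=str(path))


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".nii", ".gz"):
        return "nifti-slice"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    return "png"


def save_image(img: NormalizedImage | RawImage, path: str | Path, *, quantize: bool = False) -> None:
    """Write an image as 32-bit float TIFF, or 8-bit PNG when ``quantize``."""
    path = Path(path)
    px = np.asarray(img.pixels, dtype=float)
    if quantize or path.suffix.lower() == ".png":
        lo, hi = px.min(), px.max()
        scale = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
        Image.fromarray((scale * 255).round().astype(np.uint8)).save(path)
    else:
        tifffile.imwrite(str(path), px.astype(np.float32))


def normalize(img: RawImage | np.ndarray, new_min: float = 0.0, new_max: float = 1.0) -> NormalizedImage:
    """Linear min-max rescale of an image onto [new_min, new_max].

    Each pixel maps by ``(I - Min) * (new_max - new_min) / (Max - Min) + new_min``
    with Min/Max taken from the image itself, so a non-constant image has its
    extrema mapped exactly onto the target endpoints. Constant images have no
    defined map (zero denominator) and are rejected.
    """
    px = img.pixels if isinstance(img, RawImage) else np.asarray(img, dtype=float)
    if not new_min < new_max:
        raise ValueError("new_min must be < new_max")
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise DegenerateImageError(
            "constant image: Max - Min = 0, the min-max rescale denominator vanishes"
        )
    out = (px - lo) * (new_max - new_min) / (hi - lo) + new_min
    return NormalizedImage(pixels=out, new_min=new_min, new_max=new_max)


def image_histogram(img: RawImage | NormalizedImage | np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Intensity histogram with equally spaced bin edges over [min, max].

    Returns ``(counts, edges)``; counts always sum to the pixel count.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        hi = lo + 1.0  # all pixels fall in the first bin
    counts, edges = np.histogram(px, bins=bins, range=(lo, hi))
    return counts, edges
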