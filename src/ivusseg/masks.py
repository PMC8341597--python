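"""Color-coded label-mask codec.

IVUS ground-truth masks are stored as RGB PNGs with one flat color per
vessel-component class: black background, green lumen, red media+plaque,
orange calcification, blue stent.  This module converts between that PNG
convention and the integer class grid used everywhere else in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND = 0
LUMEN = 1
MEDIA_PLAQUE = 2
CALCIFICATION = 3
STENT = 4

N_CLASSES = 5

CLASS_NAMES = ("background", "lumen", "media_plaque", "calcification", "stent")

#: class index -> RGB triple.  Pure primaries plus web-orange so that
#: nearest-color decoding is unambiguous even for antialiased inputs.
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    BACKGROUND: (0, 0, 0),
    LUMEN: (0, 255, 0),
    MEDIA_PLAQUE: (255, 0, 0),
    CALCIFICATION: (255, 165, 0),
    STENT: (0, 0, 255),
}


class MaskDecodeError(ValueError):
    """A mask image contains colors not attributable to any palette entry."""


@dataclass
class LabelMask:
    """Per-pixel class grid with physical pixel spacing.

    Parameters
    ----------
    labels : ndarray of int, shape (H, W)
        Class indices in ``{0..4}``: background, lumen, media+plaque,
        calcification, stent.
    pixel_spacing : float
        Physical size of one pixel in mm/px.  Converts pixel counts to
        areas (mm^2) in the clinical metrics.
    """

    labels: np.ndarray
    pixel_spacing: float = 0.02

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if self.labels.shape[0] != self.labels.shape[1]:
            raise ValueError(f"masks are square, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError("labels must lie in {0..4}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> np.ndarray:
        """Pixel count per class, length 5."""
        return np.bincount(self.labels.ravel(), minlength=N_CLASSES)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMask):
            return NotImplemented
        return (
            self.pixel_spacing == other.pixel_spacing
            and self.labels.shape == other.labels.shape
            and bool(np.array_equal(self.labels, other.labels))
        )


def palette_array(palette: dict[int, tuple[int, int, int]] | None = None) -> np.ndarray:
    """Palette as a (5, 3) uint8 array indexed by class."""
    palette = DEFAULT_PALETTE if palette is None else palette
    arr = np.zeros((N_CLASSES, 3), dtype=np.uint8)
    for cls, rgb in palette.items():
        arr[cls] = rgb
    return arr


def write_mask(
    mask: LabelMask,
    path: str | Path,
    palette: dict[int, tuple[int, int, int]] | None = None,
) -> None:
    """Write a label mask as an RGB PNG using the flat-color palette."""
    rgb = palette_array(palette)[mask.labels]
    Image.fromarray(rgb, mode="RGB").save(Path(path), format="PNG")


def read_mask(
    path: str | Path,
    palette: dict[int, tuple[int, int, int]] | None = None,
    tolerance: int = 10,
    pixel_spacing: float = 0.02,
) -> LabelMask:
    """Decode an RGB mask PNG back to a label grid.

    Each pixel is assigned the palette class with the smallest max-channel
    distance.  Pixels farther than ``tolerance`` from every palette color
    raise :class:`MaskDecodeError` listing the offending coordinates.
    """
    img = Image.open(Path(path)).convert("RGB")
    rgb = np.asarray(img, dtype=np.int16)  # (H, W, 3)
    pal = palette_array(palette).astype(np.int16)  # (5, 3)
    # max-channel (Chebyshev) distance to each palette entry
    dist = np.abs(rgb[:, :, None, :] - pal[None, None, :, :]).max(axis=-1)  # (H, W, 5)
    labels = dist.argmin(axis=-1)
    best = dist.min(axis=-1)
    bad = best > tolerance
    if bad.any():
        ys, xs = np.nonzero(bad)
        coords = list(zip(ys[:10].tolist(), xs[:10].tolist()))
        raise MaskDecodeError(
            f"{bad.sum()} pixel(s) farther than tolerance {tolerance} from every "
            f"palette color; first offenders (row, col): {coords}"
        )
    return LabelMask(labels.astype(np.uint8), pixel_spacing=pixel_spacing)


def collapse_to_binary(mask: LabelMask, target_class: int | str) -> np.ndarray:
    """One-vs-rest collapse: 1 where the pixel has ``target_class``, else 0.

    ``target_class`` may be a class index (0-4) or name (e.g. ``"lumen"``).
    """
    if isinstance(target_class, str):
        try:
            target_class = CLASS_NAMES.index(target_class)
        except ValueError:
            raise ValueError(f"unknown class name {target_class!r}") from None
    if not 0 <= int(target_class) < N_CLASSES:
        raise ValueError(f"target class must be in 0..4, got {target_class}")
    return (mask.labels == int(target_class)).astype(np.uint8)


def write_palette_json(path: str | Path, palette: dict[int, tuple[int, int, int]] | None = None) -> None:
    """Export the palette as a machine-readable JSON sidecar."""
    palette = DEFAULT_PALETTE if palette is None else palette
    doc = {CLASS_NAMES[cls]: list(rgb) for cls, rgb in sorted(palette.items())}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
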