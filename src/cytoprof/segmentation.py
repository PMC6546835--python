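"""Mean auto-thresholding, connected components and live/dead classification.

The binarization follows the classic "Mean" auto-threshold: the cutoff is
the arithmetic mean of all pixel intensities and foreground is everything
*strictly above* it (a constant image therefore yields an empty mask rather
than an all-foreground one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import EmptyInputError, GeometryError

__all__ = [
    "BinaryMask",
    "Component",
    "ClassifiedTargets",
    "mean_threshold",
    "to_mask",
    "segment_channel",
    "label_components",
    "components_to_mask",
    "classify_dead",
]


@dataclass
class BinaryMask:
    """A thresholded foreground mask with its pixel size."""

    pixels: np.ndarray  # 2D bool
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise GeometryError(f"mask must be 2D, got ndim={arr.ndim}")
        if self.pixel_size <= 0:
            raise GeometryError(f"pixel_size must be > 0, got {self.pixel_size}")
        self.pixels = arr.astype(bool)

    def area(self) -> float:
        """Total foreground area in μm²."""
        return float(self.pixels.sum()) * self.pixel_size**2


@dataclass
class Component:
    """One 8-connected foreground component.

    ``coords`` holds (row, col) pixel indices; ``centroid`` is the mean of
    pixel centers in μm as ``(x, y)``; ``bbox`` is ``(min_row, min_col,
    max_row, max_col)`` with exclusive maxima, in pixels.
    """

    label: int
    coords: np.ndarray
    area: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass
class ClassifiedTargets:
    """Live/dead partition of the target-cell foreground."""

    live_mask: BinaryMask
    dead_mask: BinaryMask
    live_components: list[Component]
    dead_components: list[Component]


def mean_threshold(image: np.ndarray) -> float:
    """Arithmetic mean of all pixel intensities (the "Mean" auto-threshold)."""
    image = np.asarray(image)
    if image.size == 0:
        raise EmptyInputError("cannot threshold an empty image")
    return float(image.mean())


def to_mask(image: np.ndarray, threshold: float, pixel_size: float = 1.0) -> BinaryMask:
    """Binarize: foreground is every pixel strictly greater than `threshold`."""
    if not np.isfinite(threshold):
        raise EmptyInputError(f"threshold must be finite, got {threshold}")
    return BinaryMask(np.asarray(image) > threshold, pixel_size)


def segment_channel(
    image: np.ndarray,
    pixel_size: float = 1.0,
    blank_guard: float = 0.45,
) -> BinaryMask:
    """Mean-threshold one fluorescence channel, guarding against blank fields.

    Mean thresholding a signal-free (noise-only) image marks ~50% of pixels
    as foreground, which is never a plausible cell mask in these sparse
    assays.  If the foreground fraction reaches `blank_guard` the channel is
    treated as blank and an empty mask is returned.  Set ``blank_guard=1``
    to disable the guard.
    """
    mask = to_mask(image, mean_threshold(image), pixel_size)
    if blank_guard < 1.0 and mask.pixels.mean() >= blank_guard:
        return BinaryMask(np.zeros_like(mask.pixels), pixel_size)
    return mask


def label_components(mask: BinaryMask, min_area: float = 0.0) -> list[Component]:
    """8-connected components of `mask`, dropping those below `min_area` μm².

    Labels are assigned in raster-scan order of each component's first
    pixel, so they are stable for a fixed input.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    px_area = mask.pixel_size**2
    out: list[Component] = []
    for region in measure.regionprops(labels):
        area = region.num_pixels * px_area
        if area < min_area:
            continue
        # regionprops centroid averages pixel *indices*; shift by half a
        # pixel so coordinates refer to pixel centers, then scale to μm.
        cy, cx = region.centroid
        out.append(
            Component(
                label=int(region.label),
                coords=region.coords,
                area=float(area),
                centroid=((cx + 0.5) * mask.pixel_size, (cy + 0.5) * mask.pixel_size),
                bbox=tuple(int(v) for v in region.bbox),
            )
        )
    return out


def components_to_mask(
    components: list[Component], shape: tuple[int, int], pixel_size: float
) -> BinaryMask:
    """Rasterize a list of components back into a boolean mask."""
    out = np.zeros(shape, dtype=bool)
    for comp in components:
        out[comp.coords[:, 0], comp.coords[:, 1]] = True
    return BinaryMask(out, pixel_size)


def classify_dead(
    target_components: list[Component],
    dead_mask: BinaryMask,
    shape: tuple[int, int],
    overlap_fraction: float = 0.5,
) -> ClassifiedTargets:
    """Split target components into live and dead by dead-stain overlap.

    A component is dead iff the fraction of its pixels covered by the
    dead-stain foreground is at least `overlap_fraction`.  The two output
    masks partition the input components' union exactly.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise GeometryError(
            f"overlap_fraction must be in [0, 1], got {overlap_fraction}"
        )
    if dead_mask.pixels.shape != tuple(shape):
        raise GeometryError(
            f"dead mask shape {dead_mask.pixels.shape} != target shape {tuple(shape)}"
        )
    live: list[Component] = []
    dead: list[Component] = []
    for comp in target_components:
        inside = dead_mask.pixels[comp.coords[:, 0], comp.coords[:, 1]]
        frac = float(inside.mean()) if inside.size else 0.0
        (dead if frac >= overlap_fraction else live).append(comp)
    ps = dead_mask.pixel_size
    return ClassifiedTargets(
        live_mask=components_to_mask(live, shape, ps),
        dead_mask=components_to_mask(dead, shape, ps),
        live_components=live,
        dead_components=dead,
    )
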