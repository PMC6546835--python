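"""Image stack I/O, z-projection and timestamp parsing.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; single-plane images are stacks with a
  z-extent of 1.
* Pixel indices are 0-based with the origin at the top-left corner; the
  x axis (columns) increases toward gel depth.
* All physical quantities are micrometres (μm) and minutes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, EmptyInputError, FormatError, GeometryError

__all__ = [
    "ImageStack",
    "TimeLapse",
    "read_stack",
    "write_stack",
    "z_project",
    "parse_timestamp",
]

CHANNELS = ("target", "effector", "dead_stain")


@dataclass
class ImageStack:
    """A single-channel intensity stack with physical metadata.

    Parameters
    ----------
    data
        Non-negative integer intensities shaped ``(z, y, x)``.  A 2D array
        is promoted to a single-plane stack.
    pixel_size
        Lateral pixel size in μm/pixel.
    z_interval
        Spacing between optical sections in μm (0 for single planes).
    channel
        One of ``target``, ``effector``, ``dead_stain`` (or free-form).
    bit_depth
        Bits per pixel; intensities must fit in ``[0, 2**bit_depth - 1]``.
    """

    data: np.ndarray
    pixel_size: float
    z_interval: float = 0.0
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[np.newaxis, :, :]
        if arr.ndim != 3:
            raise FormatError(f"expected 2D or 3D intensity array, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"intensities must be integer-typed, got {arr.dtype}")
        if self.pixel_size <= 0:
            raise ConfigError(f"pixel_size must be > 0, got {self.pixel_size}")
        top = 2**self.bit_depth - 1
        if arr.size and (int(arr.min()) < 0 or int(arr.max()) > top):
            raise FormatError(
                f"intensities outside [0, {top}] for bit_depth={self.bit_depth}"
            )
        self.data = arr

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class TimeLapse:
    """Time-ordered per-channel image stacks.

    ``frames[t]`` maps channel name to the :class:`ImageStack` of frame
    ``t``; ``timestamps[t]`` is the acquisition time in minutes from start.
    """

    frames: list[dict[str, ImageStack]]
    timestamps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps):
            raise ConfigError("frames and timestamps must have equal length")
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ConfigError("timestamps must be strictly increasing")
        shapes = {
            (s.shape_yx, round(s.pixel_size, 9))
            for frame in self.frames
            for s in frame.values()
        }
        if len(shapes) > 1:
            raise GeometryError(f"frames disagree in shape/pixel size: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def channel_series(self, channel: str) -> list[np.ndarray]:
        """2D image (single plane or max projection) of `channel` per frame."""
        return [z_project(frame[channel], "max") for frame in self.frames]


def read_stack(
    path: str | Path,
    pixel_size: float,
    z_interval: float = 0.0,
    channel: str = "",
    bit_depth: int | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF file into an :class:`ImageStack`.

    RGB-interleaved files are rejected: channels must be provided as
    separate grayscale files (or planes).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises a mix of ValueError/TiffFileError
        raise FormatError(f"could not read {path} as TIFF: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        raise FormatError(
            f"{path} looks RGB-interleaved; split fluorescence channels into "
            "separate grayscale files and load them individually"
        )
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: unsupported array layout with ndim={arr.ndim}")
    if bit_depth is None:
        bit_depth = 8 * arr.dtype.itemsize if np.issubdtype(arr.dtype, np.integer) else 16
    return ImageStack(arr, pixel_size=pixel_size, z_interval=z_interval,
                      channel=channel, bit_depth=bit_depth)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if stack.bit_depth <= 8 else np.uint16
    tifffile.imwrite(path, stack.data.astype(dtype), photometric="minisblack")
    return path


def z_project(stack: ImageStack, method: str = "max") -> np.ndarray:
    """Collapse a z-stack to a 2D image.

    ``max`` is the default (standard for sparse fluorescent cells); ``mean``
    is available by flag and returns a float image.
    """
    if stack.data.size == 0:
        raise EmptyInputError("cannot project an empty stack")
    if method == "max":
        return stack.data.max(axis=0)
    if method == "mean":
        return stack.data.mean(axis=0)
    raise ConfigError(f"unknown projection method {method!r}; use 'max' or 'mean'")


_TIMESTAMP_RE = re.compile(r"^(\d{1,3}):([0-5]\d)$")


def parse_timestamp(text: str) -> int:
    """Parse an ``HH:MM`` overlay timestamp into minutes from start."""
    m = _TIMESTAMP_RE.match(text.strip())
    if m is None:
        raise FormatError(f"timestamp {text!r} does not match HH:MM")
    hours, minutes = int(m.group(1)), int(m.group(2))
    return 60 * hours + minutes
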