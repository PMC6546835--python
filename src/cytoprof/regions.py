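"""Depth-binned infiltration and killing profiles over a square ROI.

The analysis window is a square of side 700 μm (one gel lane) divided into
seven 100-μm-wide depth bins labelled R0..R6, R0 adjacent to the gel-media
interface.  Bins are half-open in depth — R_i covers
``[i*bin_width, (i+1)*bin_width)`` — and a pixel belongs to the bin that
contains its center.  R0 and R6 sit at ambiguous gel boundaries and are
excluded from pooled statistics (but still reported per bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GeometryError, UndefinedStatisticError
from .quantify import CellCalibration, estimate_count, percent_killed
from .segmentation import BinaryMask

__all__ = [
    "ROISpec",
    "SubRegionProfile",
    "ConditionSummary",
    "make_roi",
    "bin_areas",
    "profile",
    "overall_percent_killed",
    "aggregate",
]


@dataclass(frozen=True)
class ROISpec:
    """Square ROI on the depth axis, split into equal-width bins."""

    interface_x: float
    side_length: float = 700.0
    bin_width: float = 100.0
    analysis_bins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.side_length <= 0 or self.bin_width <= 0:
            raise GeometryError("side_length and bin_width must be > 0")
        ratio = self.side_length / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9:
            raise GeometryError(
                f"side_length {self.side_length} is not an integral multiple "
                f"of bin_width {self.bin_width}"
            )
        if not self.analysis_bins:
            # default: drop the first and last bin (interface artifacts)
            n = round(ratio)
            bins = tuple(range(1, n - 1)) if n > 2 else tuple(range(n))
            object.__setattr__(self, "analysis_bins", bins)
        if any(b < 0 or b >= self.n_bins for b in self.analysis_bins):
            raise GeometryError(f"analysis_bins out of range: {self.analysis_bins}")

    @property
    def n_bins(self) -> int:
        return round(self.side_length / self.bin_width)

    @property
    def bin_labels(self) -> list[str]:
        return [f"R{i}" for i in range(self.n_bins)]

    def bin_edges(self) -> np.ndarray:
        """Depth-axis bin edges in μm, starting at 0 at the interface."""
        return np.arange(self.n_bins + 1) * self.bin_width

    def bin_of_depth(self, depth: float) -> int | None:
        """Bin index containing `depth` (μm from interface), or None."""
        if depth < 0 or depth >= self.side_length:
            return None
        return int(depth // self.bin_width)


def make_roi(
    interface_x: float, side_length: float = 700.0, bin_width: float = 100.0
) -> ROISpec:
    """Construct the ROI; bin edges sit at ``interface_x + i*bin_width``."""
    return ROISpec(interface_x=interface_x, side_length=side_length, bin_width=bin_width)


def bin_areas(mask: BinaryMask, roi: ROISpec) -> np.ndarray:
    """Foreground area (μm²) of `mask` in each ROI depth bin.

    Pixels are assigned to the bin containing their center's depth
    coordinate, so the per-bin areas sum exactly to the mask area inside
    the ROI.
    """
    ps = mask.pixel_size
    n_cols = mask.pixels.shape[1]
    x_centers = (np.arange(n_cols) + 0.5) * ps
    if roi.interface_x < -1e-9 or roi.interface_x + roi.side_length > n_cols * ps + 1e-9:
        raise GeometryError(
            f"ROI [{roi.interface_x}, {roi.interface_x + roi.side_length}) μm "
            f"exceeds image extent {n_cols * ps} μm"
        )
    depths = x_centers - roi.interface_x
    inside = (depths >= 0) & (depths < roi.side_length)
    bin_idx = np.floor_divide(depths[inside], roi.bin_width).astype(int)
    col_counts = mask.pixels.sum(axis=0)[inside]
    areas = np.bincount(bin_idx, weights=col_counts, minlength=roi.n_bins)
    return areas * ps**2


@dataclass
class SubRegionProfile:
    """Per-bin effector counts and percent killed for one replicate."""

    roi: ROISpec
    effector_count: list[float]
    percent_killed: list[float | None]
    condition: str = ""
    replicate: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "replicate": self.replicate,
                "bin": self.roi.bin_labels,
                "effector_count": self.effector_count,
                "percent_killed": [
                    v if v is not None else math.nan for v in self.percent_killed
                ],
            }
        )


def profile(
    effector_mask: BinaryMask,
    live_target_mask: BinaryMask,
    dead_target_mask: BinaryMask,
    roi: ROISpec,
    calibration: CellCalibration,
    condition: str = "",
    replicate: int = 0,
) -> SubRegionProfile:
    """Per-bin infiltration counts and percent killed from channel masks.

    Bins with no target area at all get ``None`` (undefined) rather than 0
    for percent_killed, so empty regions do not bias averages downward.
    """
    shapes = {m.pixels.shape for m in (effector_mask, live_target_mask, dead_target_mask)}
    if len(shapes) > 1:
        raise GeometryError(f"channel masks disagree in shape: {sorted(shapes)}")
    eff = bin_areas(effector_mask, roi)
    live = bin_areas(live_target_mask, roi)
    dead = bin_areas(dead_target_mask, roi)
    counts = [estimate_count(a, calibration.mean_effector_area) for a in eff]
    killed: list[float | None] = []
    for la, da in zip(live, dead):
        if la == 0 and da == 0:
            killed.append(None)
        else:
            killed.append(percent_killed(la, da, calibration))
    return SubRegionProfile(
        roi=roi,
        effector_count=counts,
        percent_killed=killed,
        condition=condition,
        replicate=replicate,
    )


def overall_percent_killed(
    live_target_mask: BinaryMask,
    dead_target_mask: BinaryMask,
    roi: ROISpec,
    calibration: CellCalibration,
) -> float:
    """Percent killed from areas pooled over the analysis bins only.

    The first and last bins (interface artifacts) contribute nothing.
    """
    live = bin_areas(live_target_mask, roi)
    dead = bin_areas(dead_target_mask, roi)
    idx = list(roi.analysis_bins)
    live_total = float(live[idx].sum())
    dead_total = float(dead[idx].sum())
    if live_total == 0 and dead_total == 0:
        raise UndefinedStatisticError(
            f"no target area in analysis bins {idx}; percent killed undefined"
        )
    return percent_killed(live_total, dead_total, calibration)


@dataclass
class ConditionSummary:
    """Per-bin mean ± SEM across replicates for one condition."""

    roi: ROISpec
    condition: str
    n_replicates: int
    count_mean: list[float]
    count_sem: list[float | None]
    killed_mean: list[float | None]
    killed_sem: list[float | None]
    killed_n: list[int]

    def to_frame(self) -> pd.DataFrame:
        nan = math.nan
        return pd.DataFrame(
            {
                "condition": self.condition,
                "bin": self.roi.bin_labels,
                "n": self.n_replicates,
                "effector_count_mean": self.count_mean,
                "effector_count_sem": [v if v is not None else nan for v in self.count_sem],
                "percent_killed_n": self.killed_n,
                "percent_killed_mean": [v if v is not None else nan for v in self.killed_mean],
                "percent_killed_sem": [v if v is not None else nan for v in self.killed_sem],
            }
        )


def _mean_sem(values: list[float]) -> tuple[float | None, float | None]:
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n == 1:
        return mean, None
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd / math.sqrt(n)


def aggregate(profiles: list[SubRegionProfile]) -> ConditionSummary:
    """Mean and SEM per bin across replicate profiles.

    Undefined percent-killed bins are excluded pairwise; the per-bin sample
    size actually used is reported alongside.  SEM is the sample standard
    deviation over √n and is undefined for n = 1.
    """
    if not profiles:
        raise EmptyInputError("aggregate requires at least one profile")
    roi = profiles[0].roi
    condition = profiles[0].condition
    for p in profiles[1:]:
        if p.roi != roi:
            raise GeometryError("profiles disagree in ROI geometry")
        if p.condition != condition:
            raise GeometryError("profiles mix conditions; aggregate one condition at a time")
    count_mean, count_sem = [], []
    killed_mean, killed_sem, killed_n = [], [], []
    for b in range(roi.n_bins):
        cm, cs = _mean_sem([p.effector_count[b] for p in profiles])
        count_mean.append(cm)
        count_sem.append(cs)
        defined = [p.percent_killed[b] for p in profiles if p.percent_killed[b] is not None]
        km, ks = _mean_sem(defined)
        killed_mean.append(km)
        killed_sem.append(ks)
        killed_n.append(len(defined))
    return ConditionSummary(
        roi=roi,
        condition=condition,
        n_replicates=len(profiles),
        count_mean=count_mean,
        count_sem=count_sem,
        killed_mean=killed_mean,
        killed_sem=killed_sem,
        killed_n=killed_n,
    )
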