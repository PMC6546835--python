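"""Area-to-count conversion and the percent-killed statistic.

Counting is area based: the number of cells in a mask is estimated by
dividing its total foreground area by a calibrated mean single-cell area.
Dead target cells are rounded and smaller than extended live ones, so dead
area is first converted to live-equivalent area via the calibrated ratio of
mean live to mean dead single-cell area.  Counts are kept fractional;
rounding happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import CalibrationError, UndefinedStatisticError

__all__ = [
    "CellCalibration",
    "calibrate",
    "estimate_count",
    "percent_killed",
    "save_calibration",
    "load_calibration",
]


def _pool(areas: Sequence) -> list[float]:
    """Flatten one level of nesting (per-rater lists) into a pooled list."""
    flat: list[float] = []
    for item in areas:
        if isinstance(item, Iterable) and not isinstance(item, (str, bytes)):
            flat.extend(float(v) for v in item)
        else:
            flat.append(float(item))
    return flat


@dataclass
class CellCalibration:
    """Mean single-cell areas (μm²) used to convert mask areas to counts."""

    mean_effector_area: float
    mean_live_target_area: float
    mean_dead_target_area: float
    n_cells_per_type: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mean_effector_area", "mean_live_target_area", "mean_dead_target_area"):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def conversion_ratio(self) -> float:
        """Mean live target area / mean dead target area."""
        return self.mean_live_target_area / self.mean_dead_target_area


def calibrate(
    effector_areas: Sequence,
    live_target_areas: Sequence,
    dead_target_areas: Sequence,
) -> CellCalibration:
    """Build a :class:`CellCalibration` from measured single-cell areas.

    Each argument is either a flat list of areas or a list of per-rater
    lists (e.g. five raters times twenty cells); rater lists are pooled and
    the arithmetic mean of the pooled sample is used.
    """
    pooled = {
        "effector": _pool(effector_areas),
        "live_target": _pool(live_target_areas),
        "dead_target": _pool(dead_target_areas),
    }
    for name, values in pooled.items():
        if not values:
            raise CalibrationError(f"no {name} areas supplied")
        if min(values) <= 0:
            raise CalibrationError(f"non-positive {name} area: {min(values)}")
    return CellCalibration(
        mean_effector_area=sum(pooled["effector"]) / len(pooled["effector"]),
        mean_live_target_area=sum(pooled["live_target"]) / len(pooled["live_target"]),
        mean_dead_target_area=sum(pooled["dead_target"]) / len(pooled["dead_target"]),
        n_cells_per_type={k: len(v) for k, v in pooled.items()},
    )


def estimate_count(total_area: float, mean_single_cell_area: float) -> float:
    """Fractional cell count: total foreground area / mean single-cell area."""
    if mean_single_cell_area <= 0:
        raise CalibrationError(
            f"mean single-cell area must be > 0, got {mean_single_cell_area}"
        )
    if total_area < 0:
        raise CalibrationError(f"total_area must be >= 0, got {total_area}")
    return total_area / mean_single_cell_area


def percent_killed(
    live_area: float, dead_area: float, calibration: CellCalibration
) -> float:
    """Percentage of killed target cells from live/dead mask areas.

    The dead area is converted to live-equivalent area by the calibrated
    live:dead single-cell area ratio; the result is
    ``100 * converted / (live_area + converted)``.
    """
    if live_area < 0 or dead_area < 0:
        raise UndefinedStatisticError("areas must be non-negative")
    if live_area == 0 and dead_area == 0:
        raise UndefinedStatisticError(
            "percent_killed undefined: no target-cell area in region"
        )
    converted = dead_area * calibration.conversion_ratio
    value = 100.0 * converted / (live_area + converted)
    return min(100.0, max(0.0, value))  # guard float round-off at the limits


def save_calibration(
    path: str | Path,
    effector_areas: Sequence,
    live_target_areas: Sequence,
    dead_target_areas: Sequence,
) -> Path:
    """Write raw calibration areas as CSV (cell_type, area_um2, rater)."""
    rows = []
    for cell_type, groups in (
        ("effector", effector_areas),
        ("live_target", live_target_areas),
        ("dead_target", dead_target_areas),
    ):
        nested = groups and isinstance(groups[0], Iterable) and not isinstance(groups[0], (str, bytes))
        for rater, group in enumerate(groups if nested else [groups]):
            for area in group:
                rows.append({"cell_type": cell_type, "area_um2": float(area), "rater": rater})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["cell_type", "area_um2", "rater"]).to_csv(path, index=False)
    return path


def load_calibration(path: str | Path) -> CellCalibration:
    """Load a calibration CSV written by :func:`save_calibration`."""
    df = pd.read_csv(path)
    required = {"cell_type", "area_um2"}
    if not required.issubset(df.columns):
        raise CalibrationError(f"calibration table must have columns {sorted(required)}")
    by_type = {t: g["area_um2"].tolist() for t, g in df.groupby("cell_type")}
    try:
        return calibrate(
            by_type.get("effector", []),
            by_type.get("live_target", []),
            by_type.get("dead_target", []),
        )
    except CalibrationError as exc:
        raise CalibrationError(f"{path}: {exc}") from exc
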