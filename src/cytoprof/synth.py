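"""Synthetic multi-channel fluorescence scenes with exported ground truth.

Generates the statistical structure the analysis assumes, so every
downstream stage can be tested without real microscopy data:

* extended (elliptical) live target cells vs. rounded (disc) dead ones;
* a depth-decaying effector distribution entering from one gel face
  (depths drawn with density ∝ exp(-depth / decay_length), truncated to
  the field);
* dead-stain signal confined to dead target cells;
* time-lapse kill events: contact → rounding → dead-stain onset after a
  truncated-normal delay.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical parameters and seed give bit-identical images and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, PlacementError
from .imaging import ImageStack, TimeLapse
from .regions import ROISpec, make_roi

__all__ = [
    "SceneParams",
    "TimeLapseParams",
    "CellTruth",
    "GroundTruth",
    "KillEventTruth",
    "generate_scene",
    "generate_timelapse",
    "render_cell_mask",
    "write_truth",
    "read_truth_cells",
    "read_events",
]

_PLACEMENT_ATTEMPTS = 1000
_Y_RETRIES = 50  # lateral retries per drawn effector depth


@dataclass
class SceneParams:
    """Parameters of one static synthetic scene (μm / μm² / a.u.)."""

    field_size: tuple[float, float] = (700.0, 700.0)  # (x extent, y extent)
    pixel_size: float = 2.0
    gel_interface_x: float = 0.0
    n_target_cells: int = 100
    dead_fraction: float = 0.2
    n_effector_cells: int = 200
    infiltration_decay_length: float = 200.0
    live_axis_ratio: float = 2.5
    live_area_mean: float = 400.0
    live_area_sd: float = 40.0
    dead_area_mean: float = 200.0
    dead_area_sd: float = 25.0
    effector_area_mean: float = 150.0
    effector_area_sd: float = 15.0
    background_level: float = 200.0
    foreground_level: float = 3000.0
    noise_sd: float = 50.0
    bit_depth: int = 16
    allow_overlap: bool = False
    roi_side_length: float | None = None  # default: largest multiple of bin width
    roi_bin_width: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ConfigError(f"dead_fraction must be in [0, 1], got {self.dead_fraction}")
        if self.live_axis_ratio < 1.0:
            raise ConfigError(f"live_axis_ratio must be >= 1, got {self.live_axis_ratio}")
        if self.pixel_size <= 0:
            raise ConfigError(f"pixel_size must be > 0, got {self.pixel_size}")
        for name in ("live_area_mean", "dead_area_mean", "effector_area_mean",
                     "infiltration_decay_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for extent in self.field_size:
            if extent <= 0 or abs(extent / self.pixel_size - round(extent / self.pixel_size)) > 1e-9:
                raise ConfigError(
                    f"field dimensions must be positive multiples of pixel_size, "
                    f"got {self.field_size} at {self.pixel_size} μm/px"
                )
        if not 0 <= self.gel_interface_x < self.field_size[0]:
            raise ConfigError("gel_interface_x must lie inside the field")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols)."""
        return (
            round(self.field_size[1] / self.pixel_size),
            round(self.field_size[0] / self.pixel_size),
        )

    def roi(self) -> ROISpec:
        """ROI spanning the gel depth, aligned to the interface."""
        depth = self.field_size[0] - self.gel_interface_x
        side = self.roi_side_length
        if side is None:
            side = math.floor(depth / self.roi_bin_width) * self.roi_bin_width
        return make_roi(self.gel_interface_x, side, self.roi_bin_width)


@dataclass
class TimeLapseParams(SceneParams):
    """Scene parameters plus kill-event kinetics for a time-lapse movie."""

    frame_interval: float = 5.0  # minutes
    n_frames: int = 40
    effector_step_sd: float = 4.0  # μm per frame, per axis
    contact_distance: float = 2.0  # μm surface-to-surface
    kill_probability_per_contact: float = 1.0
    rounding_delay: int = 1  # frames from contact to rounded morphology
    pi_delay_mean: float = 30.0  # minutes from contact to dead-stain onset
    pi_delay_sd: float = 6.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.frame_interval <= 0:
            raise ConfigError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.n_frames < 2:
            raise ConfigError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.pi_delay_mean <= 0:
            raise ConfigError(f"pi_delay_mean must be > 0, got {self.pi_delay_mean}")
        if self.contact_distance < self.pixel_size:
            raise ConfigError(
                f"contact_distance {self.contact_distance} μm is smaller than one "
                f"pixel ({self.pixel_size} μm)"
            )
        if not 0.0 <= self.kill_probability_per_contact <= 1.0:
            raise ConfigError("kill_probability_per_contact must be in [0, 1]")


@dataclass
class CellTruth:
    """Ground truth for one rendered cell.

    ``semi_major``/``semi_minor`` are the shape half-axes in μm (equal for
    discs); ``orientation`` is the major-axis angle in radians.  ``depth``
    is μm from the gel interface; ``rendered_area`` is the rasterized
    footprint area in μm².
    """

    cell_id: int
    cell_type: str  # {"effector", "target"}
    state: str  # {"live", "dead"}
    x: float
    y: float
    depth: float
    rendered_area: float
    semi_major: float
    semi_minor: float
    orientation: float


@dataclass
class GroundTruth:
    """All rendered cells plus the per-bin summaries the analysis targets."""

    cells: list[CellTruth]
    roi: ROISpec
    per_bin_effector_count: np.ndarray
    true_percent_killed: list[float | None]
    overall_percent_killed: float | None
    seed: int

    def targets(self) -> list[CellTruth]:
        return [c for c in self.cells if c.cell_type == "target"]

    def effectors(self) -> list[CellTruth]:
        return [c for c in self.cells if c.cell_type == "effector"]


@dataclass
class KillEventTruth:
    """One logged effector-target kill: contact → dead-stain onset."""

    effector_id: int
    target_id: int
    contact_time: float  # minutes
    pi_time: float

    @property
    def time_for_killing(self) -> float:
        return self.pi_time - self.contact_time


# ---------------------------------------------------------------------------
# geometry helpers

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw N(mean, sd) truncated to strictly positive values."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise ConfigError(f"truncated normal ({mean}, {sd}) never produced a positive draw")


def _ellipse_axes(area: float, axis_ratio: float) -> tuple[float, float]:
    """Semi-axes (a >= b) of an ellipse with the given area and a/b ratio."""
    b = math.sqrt(area / (math.pi * axis_ratio))
    return axis_ratio * b, b


def render_cell_mask(cell: CellTruth, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean footprint of one truth cell on the pixel grid.

    A pixel belongs to the footprint iff its center lies inside the
    (rotated) ellipse; discs are the circular special case.  This is the
    exact rasterization the generator uses, so tests can reconstruct every
    footprint from the truth table alone.
    """
    out = np.zeros(shape, dtype=bool)
    _paint_cell(out, cell, pixel_size, value=True)
    return out


def _paint_cell(canvas: np.ndarray, cell: CellTruth, ps: float, value) -> int:
    """Set `value` on the cell's footprint; returns the pixel count."""
    a, b, theta = cell.semi_major, cell.semi_minor, cell.orientation
    rows, cols = canvas.shape
    r0 = max(int((cell.y - a) / ps) - 1, 0)
    r1 = min(int((cell.y + a) / ps) + 2, rows)
    c0 = max(int((cell.x - a) / ps) - 1, 0)
    c1 = min(int((cell.x + a) / ps) + 2, cols)
    if r0 >= r1 or c0 >= c1:
        return 0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = (xx + 0.5) * ps - cell.x
    dy = (yy + 0.5) * ps - cell.y
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[r0:r1, c0:c1][inside] = value
    return int(inside.sum())


def _sample_depth(rng: np.random.Generator, decay: float, max_depth: float) -> float:
    """Exponential depth truncated to [0, max_depth) by inverse CDF."""
    u = rng.random()
    return -decay * math.log1p(-u * (1.0 - math.exp(-max_depth / decay)))


def _place_cells(params: SceneParams, rng: np.random.Generator) -> list[CellTruth]:
    """Draw shapes and non-overlapping positions for every cell.

    Targets are uniform over the gel; effector depths follow the truncated
    exponential infiltration law.  Overlap is checked conservatively on
    bounding circles; exhaustion of retries raises :class:`PlacementError`.
    """
    width, height = params.field_size
    placed: list[tuple[float, float, float]] = []  # (x, y, bounding radius)

    def admissible(x: float, y: float, rad: float) -> bool:
        if params.allow_overlap:
            return True
        gap = params.pixel_size
        return all(
            (x - px) ** 2 + (y - py) ** 2 >= (rad + pr + gap) ** 2
            for px, py, pr in placed
        )

    cells: list[CellTruth] = []
    cell_id = 0

    n_dead = round(params.n_target_cells * params.dead_fraction)
    states = ["dead"] * n_dead + ["live"] * (params.n_target_cells - n_dead)
    for state in states:
        if state == "live":
            area = _truncated_normal(rng, params.live_area_mean, params.live_area_sd)
            a, b = _ellipse_axes(area, params.live_axis_ratio)
            theta = rng.uniform(0.0, math.pi)
        else:
            area = _truncated_normal(rng, params.dead_area_mean, params.dead_area_sd)
            a = b = math.sqrt(area / math.pi)
            theta = 0.0
        for _ in range(_PLACEMENT_ATTEMPTS):
            x = rng.uniform(params.gel_interface_x + a, width - a)
            y = rng.uniform(a, height - a)
            if admissible(x, y, a):
                break
        else:
            raise PlacementError(
                f"could not place {params.n_target_cells} non-overlapping targets "
                f"in a {width}x{height} μm field; lower the cell density"
            )
        placed.append((x, y, a))
        cells.append(CellTruth(cell_id, "target", state, x, y,
                               x - params.gel_interface_x, 0.0, a, b, theta))
        cell_id += 1

    gel_depth = width - params.gel_interface_x
    for _ in range(params.n_effector_cells):
        area = _truncated_normal(rng, params.effector_area_mean, params.effector_area_sd)
        r = math.sqrt(area / math.pi)
        # Retry laterally (y) before redrawing the depth, so crowding does not
        # bias the realized depth distribution away from the infiltration law.
        for attempt in range(_PLACEMENT_ATTEMPTS):
            if attempt % _Y_RETRIES == 0:
                depth = _sample_depth(rng, params.infiltration_decay_length, gel_depth)
                depth = min(max(depth, r), gel_depth - r)
                x = params.gel_interface_x + depth
            y = rng.uniform(r, height - r)
            if admissible(x, y, r):
                break
        else:
            raise PlacementError(
                f"could not place {params.n_effector_cells} non-overlapping effectors "
                f"in a {width}x{height} μm field; lower the cell density"
            )
        placed.append((x, y, r))
        cells.append(CellTruth(cell_id, "effector", "live", x, y, depth, 0.0, r, r, 0.0))
        cell_id += 1
    return cells


def _render_channels(
    cells: Iterable[CellTruth],
    params: SceneParams,
    rng: np.random.Generator,
    dead_on: set[int] | None = None,
) -> dict[str, np.ndarray]:
    """Rasterize all channels and record rendered areas on the truth cells.

    `dead_on` overrides which target ids carry dead-stain signal (used by
    the time-lapse renderer); by default a cell's static ``state`` decides.
    """
    shape = params.shape
    ps = params.pixel_size
    planes = {name: np.full(shape, params.background_level, dtype=np.float64)
              for name in ("target", "effector", "dead_stain")}
    px_area = ps**2
    for cell in cells:
        if cell.cell_type == "effector":
            n = _paint_cell(planes["effector"], cell, ps, params.foreground_level)
        else:
            n = _paint_cell(planes["target"], cell, ps, params.foreground_level)
            is_dead = cell.state == "dead" if dead_on is None else cell.cell_id in dead_on
            if is_dead:
                _paint_cell(planes["dead_stain"], cell, ps, params.foreground_level)
        cell.rendered_area = n * px_area
    top = 2**params.bit_depth - 1
    out: dict[str, np.ndarray] = {}
    for name in ("target", "effector", "dead_stain"):
        img = planes[name]
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=shape)
        out[name] = np.clip(np.rint(img), 0, top).astype(
            np.uint8 if params.bit_depth <= 8 else np.uint16
        )
    return out


def _truth_from_cells(cells: list[CellTruth], params: SceneParams) -> GroundTruth:
    roi = params.roi()
    eff_counts = np.zeros(roi.n_bins, dtype=int)
    live = np.zeros(roi.n_bins, dtype=int)
    dead = np.zeros(roi.n_bins, dtype=int)
    for cell in cells:
        b = roi.bin_of_depth(cell.depth)
        if b is None:
            continue
        if cell.cell_type == "effector":
            eff_counts[b] += 1
        elif cell.state == "dead":
            dead[b] += 1
        else:
            live[b] += 1
    per_bin_pk: list[float | None] = [
        100.0 * d / (d + l) if (d + l) > 0 else None for d, l in zip(dead, live)
    ]
    idx = list(roi.analysis_bins)
    pooled_dead, pooled_all = int(dead[idx].sum()), int((dead[idx] + live[idx]).sum())
    overall = 100.0 * pooled_dead / pooled_all if pooled_all else None
    return GroundTruth(
        cells=cells,
        roi=roi,
        per_bin_effector_count=eff_counts,
        true_percent_killed=per_bin_pk,
        overall_percent_killed=overall,
        seed=params.seed,
    )


def generate_scene(params: SceneParams) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Render one static scene; returns per-channel stacks and ground truth."""
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    images = _render_channels(cells, params, rng)
    channels = {
        name: ImageStack(img, pixel_size=params.pixel_size, channel=name,
                         bit_depth=params.bit_depth)
        for name, img in images.items()
    }
    return channels, _truth_from_cells(cells, params)


# ---------------------------------------------------------------------------
# time lapse

def generate_timelapse(params: TimeLapseParams) -> tuple[TimeLapse, list[KillEventTruth]]:
    """Simulate and render a kill-event movie.

    Targets are stationary; effectors random-walk with reflecting
    boundaries.  At the *first* frame an effector's surface comes within
    ``contact_distance`` of a live target's, a kill occurs with
    ``kill_probability_per_contact``; on a kill the effector docks onto the
    target (forming a synapse, so the rendered masks touch at the contact
    frame), the target switches to rounded morphology ``rounding_delay``
    frames later, and its dead-stain signal turns on at
    ``contact_time + delay`` with delay drawn from the truncated-normal
    dead-stain onset distribution.
    """
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    targets = [c for c in cells if c.cell_type == "target"]
    effectors = [c for c in cells if c.cell_type == "effector"]

    width, height = params.field_size
    events: list[KillEventTruth] = []
    tried_pairs: set[tuple[int, int]] = set()
    dead_on_time: dict[int, float] = {}  # target id -> dead-stain onset minutes
    round_frame: dict[int, int] = {}  # target id -> frame index when rounded
    docked_until: dict[int, float] = {}  # effector id -> dead-stain onset time
    for t in targets:
        if t.state == "dead":
            dead_on_time[t.cell_id] = 0.0
            round_frame[t.cell_id] = 0

    frames: list[dict[str, ImageStack]] = []
    timestamps: list[float] = []

    for f in range(params.n_frames):
        now = f * params.frame_interval
        # move free effectors
        for eff in effectors:
            if eff.cell_id in docked_until:
                if now < docked_until[eff.cell_id]:
                    continue
                del docked_until[eff.cell_id]
            if f > 0:
                eff.x += rng.normal(0.0, params.effector_step_sd)
                eff.y += rng.normal(0.0, params.effector_step_sd)
                eff.x = _reflect(eff.x, params.gel_interface_x + eff.semi_major,
                                 width - eff.semi_major)
                eff.y = _reflect(eff.y, eff.semi_major, height - eff.semi_major)
                eff.depth = eff.x - params.gel_interface_x
        # contacts and kills (id order keeps this deterministic)
        for eff in effectors:
            for tgt in targets:
                if tgt.cell_id in dead_on_time:
                    continue
                pair = (eff.cell_id, tgt.cell_id)
                if pair in tried_pairs:
                    continue
                gap = math.hypot(eff.x - tgt.x, eff.y - tgt.y) - eff.semi_major - tgt.semi_major
                if gap > params.contact_distance:
                    continue
                tried_pairs.add(pair)
                if rng.random() >= params.kill_probability_per_contact:
                    continue
                delay = _truncated_normal(rng, params.pi_delay_mean, params.pi_delay_sd)
                pi_time = now + delay
                events.append(KillEventTruth(eff.cell_id, tgt.cell_id, now, pi_time))
                dead_on_time[tgt.cell_id] = pi_time
                round_frame[tgt.cell_id] = f + params.rounding_delay
                # dock the effector onto the target surface (slight overlap so
                # rasterized masks touch at the contact frame)
                d = math.hypot(eff.x - tgt.x, eff.y - tgt.y)
                ux, uy = ((eff.x - tgt.x) / d, (eff.y - tgt.y) / d) if d > 0 else (1.0, 0.0)
                reach = 0.9 * (eff.semi_major + tgt.semi_minor)
                eff.x, eff.y = tgt.x + ux * reach, tgt.y + uy * reach
                eff.depth = eff.x - params.gel_interface_x
                docked_until[eff.cell_id] = pi_time
                break  # one kill per effector per frame
        # rounding morphology switch
        for tgt in targets:
            if tgt.cell_id in round_frame and f >= round_frame[tgt.cell_id] \
                    and tgt.semi_major != tgt.semi_minor:
                area = _truncated_normal(rng, params.dead_area_mean, params.dead_area_sd)
                r = math.sqrt(area / math.pi)
                tgt.semi_major = tgt.semi_minor = r
                tgt.orientation = 0.0
        dead_now = {tid for tid, t0 in dead_on_time.items() if now >= t0}
        snapshot = [replace(c) for c in cells]
        images = _render_channels(snapshot, params, rng, dead_on=dead_now)
        frames.append({
            name: ImageStack(img, pixel_size=params.pixel_size, channel=name,
                             bit_depth=params.bit_depth)
            for name, img in images.items()
        })
        timestamps.append(now)

    return TimeLapse(frames=frames, timestamps=timestamps), events


def _reflect(v: float, lo: float, hi: float) -> float:
    if lo >= hi:  # cell larger than the field; just clamp
        return max(lo, min(v, hi)) if lo <= hi else v
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


# ---------------------------------------------------------------------------
# truth I/O

_CELL_COLUMNS = [
    "cell_id", "cell_type", "state", "x_um", "y_um", "depth_um",
    "rendered_area_um2", "semi_major_um", "semi_minor_um", "orientation_rad",
]
_EVENT_COLUMNS = [
    "effector_id", "target_id", "contact_time_min", "pi_time_min",
    "time_for_killing_min",
]


def write_truth(truth: GroundTruth | list[KillEventTruth], path: str | Path) -> Path:
    """Write ground truth (cells) or a kill-event log as CSV.

    One row per cell / event; an empty event list produces a header-only
    file that the matching reader accepts.
    """
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(truth, GroundTruth):
            rows = [
                [c.cell_id, c.cell_type, c.state, c.x, c.y, c.depth,
                 c.rendered_area, c.semi_major, c.semi_minor, c.orientation]
                for c in truth.cells
            ]
            pd.DataFrame(rows, columns=_CELL_COLUMNS).to_csv(
                path, index=False, float_format="%.17g"
            )
        else:
            rows = [
                [e.effector_id, e.target_id, e.contact_time, e.pi_time,
                 e.time_for_killing]
                for e in truth
            ]
            pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
                path, index=False, float_format="%.17g"
            )
    except OSError as exc:
        raise FormatError(f"cannot write truth table to {path}: {exc}") from exc
    return path


def read_truth_cells(path: str | Path) -> list[CellTruth]:
    """Read a cell-truth CSV back into :class:`CellTruth` records."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CELL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing truth columns {sorted(missing)}")
    return [
        CellTruth(int(r.cell_id), str(r.cell_type), str(r.state), float(r.x_um),
                  float(r.y_um), float(r.depth_um), float(r.rendered_area_um2),
                  float(r.semi_major_um), float(r.semi_minor_um),
                  float(r.orientation_rad))
        for r in df.itertuples()
    ]


def read_events(path: str | Path) -> list[KillEventTruth]:
    """Read a kill-event CSV back into :class:`KillEventTruth` records."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    return [
        KillEventTruth(int(r.effector_id), int(r.target_id),
                       float(r.contact_time_min), float(r.pi_time_min))
        for r in df.itertuples()
    ]
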