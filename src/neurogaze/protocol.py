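"""Calibration/test grids and the session protocol.

Calibration uses a uniformly spaced 5x4 grid of known screen points (it
samples the 4:3 screen uniformly); the user dwells on each point for
1200 ms, i.e. 30 frames at 25 fps, and every valid frame contributes a
(features, point) training pair.  The test grid consists of the 4x3
halfway points of the calibration cells — points the gaze never crossed
during calibration — each shown five times for 600 ms (15 frames) in a
seeded pseudo-random order.  Only extracted features are retained;
frames rejected by the detection chain are logged and skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union

import numpy as np

from .evaluation import SessionResult
from .features import DetectorConfig, EyeFeatures, Frame, FrameRejected, extract_features
from .geometry import ScreenGeometry
from .mapping import GazeModel, TrainingSet, predict_pog

__all__ = [
    "Grid",
    "ScheduleConfig",
    "make_calibration_grid",
    "make_test_grid",
    "test_sequence",
    "run_calibration",
    "run_test",
]

logger = logging.getLogger(__name__)


def _round_px(v) -> np.ndarray:
    # round-half-to-even keeps the grids mirror-symmetric within 1 px
    return np.rint(np.asarray(v, dtype=float)).astype(int)


@dataclass(frozen=True)
class Grid:
    """An ordered (row-major) set of screen points."""

    points: tuple[tuple[int, int], ...]
    cols: int
    rows: int
    kind: str  # "calibration" | "test"

    def __post_init__(self) -> None:
        if self.cols < 1 or self.rows < 1 or len(self.points) != self.cols * self.rows:
            raise ValueError("grid shape does not match its point count")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass
class ScheduleConfig:
    """Fixation schedule: dwell times and the frame rate that quantizes them."""

    fps: float = 25.0
    cal_dwell_ms: float = 1200.0
    test_dwell_ms: float = 600.0
    test_repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.cal_dwell_ms <= 0 or self.test_dwell_ms <= 0:
            raise ValueError("schedule times must be positive")
        if self.test_repetitions < 1:
            raise ValueError("test_repetitions must be >= 1")

    @property
    def frames_per_cal_point(self) -> int:
        return round(self.fps * self.cal_dwell_ms / 1000.0)

    @property
    def frames_per_test_show(self) -> int:
        return round(self.fps * self.test_dwell_ms / 1000.0)


def make_calibration_grid(
    screen: ScreenGeometry,
    cols: int = 5,
    rows: int = 4,
    margin_frac: float = 0.05,
) -> Grid:
    """Uniformly spaced cols x rows grid, inset by ``margin_frac`` per side.

    Continuous positions span [margin*W, (1-margin)*W] (endpoints
    included) and are rounded to integer pixels, then clamped
    onto the screen.
    """
    if cols < 2 or rows < 2:
        raise ValueError("grid needs at least 2 columns and 2 rows")
    if not (0 <= margin_frac < 0.25):
        raise ValueError("margin_frac must lie in [0, 0.25)")
    xs = np.linspace(margin_frac * screen.width_px,
                     (1 - margin_frac) * screen.width_px, cols)
    ys = np.linspace(margin_frac * screen.height_px,
                     (1 - margin_frac) * screen.height_px, rows)
    xs = np.clip(_round_px(xs), 0, screen.width_px - 1)
    ys = np.clip(_round_px(ys), 0, screen.height_px - 1)
    points = tuple((int(x), int(y)) for y in ys for x in xs)
    return Grid(points=points, cols=cols, rows=rows, kind="calibration")


def make_test_grid(cal: Grid) -> Grid:
    """Halfway points of every 2x2 calibration cell, (cols-1) x (rows-1)."""
    if cal.cols < 2 or cal.rows < 2:
        raise ValueError("calibration grid must have at least 2 columns and rows")
    pts = np.asarray(cal.points, dtype=float).reshape(cal.rows, cal.cols, 2)
    mids = (pts[:-1, :-1] + pts[1:, 1:]) / 2.0
    points = tuple(
        (int(x), int(y))
        for row in _round_px(mids)
        for x, y in row
    )
    if set(points) & set(cal.points):
        raise ValueError("test grid collides with calibration points")
    return Grid(points=points, cols=cal.cols - 1, rows=cal.rows - 1, kind="test")


def test_sequence(grid: Grid, sched: ScheduleConfig) -> list[int]:
    """Seeded pseudo-random order of the (point, repetition) shows.

    Each grid point appears exactly ``test_repetitions`` times; the
    permutation is re-drawn until no point is shown twice in a row.
    """
    shows = np.repeat(np.arange(grid.n_points), sched.test_repetitions)
    rng = np.random.default_rng(sched.seed)
    for _ in range(10_000):
        order = rng.permutation(shows)
        if grid.n_points == 1 or not np.any(order[1:] == order[:-1]):
            return order.tolist()
    raise RuntimeError("could not build a no-immediate-repeat sequence")


FeatureLike = Union[Frame, EyeFeatures, np.ndarray]


def _consume(
    stream: Iterator[FeatureLike],
    cfg: Optional[DetectorConfig],
    prev_state: dict,
) -> Optional[np.ndarray]:
    """Next item of the stream as an 8-vector, or None if the frame fails.

    Items may be raw frames (run through the detection chain, with
    region-of-interest tracking across frames), pre-extracted
    EyeFeatures, or bare 8-vectors from a feature-level simulation.
    """
    item = next(stream)
    if isinstance(item, Frame):
        if cfg is None:
            raise ValueError("a DetectorConfig is required for frame streams")
        try:
            feats = extract_features(item, cfg, prev_state.get("pupil"))
        except FrameRejected as rej:
            logger.info("frame %d rejected at stage %s", item.index, rej.stage)
            prev_state["pupil"] = None
            return None
        prev_state["pupil"] = feats.pupil
        return feats.vector
    if isinstance(item, EyeFeatures):
        return item.vector
    vec = np.asarray(item, dtype=float)
    if vec.shape != (8,):
        raise ValueError("feature items must be 8-vectors")
    return vec


def run_calibration(
    source: Iterable[FeatureLike],
    grid: Grid,
    sched: ScheduleConfig,
    cfg: Optional[DetectorConfig] = None,
) -> TrainingSet:
    """Collect the training set over the calibration schedule.

    The stream must supply ``frames_per_cal_point`` items per grid point
    in grid order.  Rejected frames are skipped; a grid point that
    yields no valid frame at all aborts the session.
    """
    if grid.n_points == 0:
        raise ValueError("empty calibration grid")
    stream = iter(source)
    state: dict = {}
    rows, targets, idx = [], [], []
    for p, point in enumerate(grid.points):
        n_valid = 0
        for _ in range(sched.frames_per_cal_point):
            vec = _consume(stream, cfg, state)
            if vec is None:
                continue
            rows.append(vec)
            targets.append(point)
            idx.append(p)
            n_valid += 1
        if n_valid == 0:
            raise ValueError(f"calibration point {p} at {point} has no valid frames")
    return TrainingSet(
        inputs=np.array(rows), targets=np.array(targets, dtype=float),
        point_index=np.array(idx),
    )


def run_test(
    model: GazeModel,
    source: Iterable[FeatureLike],
    grid: Grid,
    sched: ScheduleConfig,
    cfg: Optional[DetectorConfig] = None,
    metadata: Optional[dict] = None,
) -> SessionResult:
    """Predict the POG over the pseudo-random test schedule.

    The stream must follow the seeded schedule: ``frames_per_test_show``
    items for each show in ``test_sequence(grid, sched)`` order.
    """
    if grid.n_points == 0:
        raise ValueError("empty test grid")
    stream = iter(source)
    state: dict = {}
    records = []
    n = 0
    for show in test_sequence(grid, sched):
        true_pt = grid.points[show]
        for _ in range(sched.frames_per_test_show):
            vec = _consume(stream, cfg, state)
            if vec is not None:
                est = predict_pog(model, vec)
                records.append((n, true_pt, est))
            n += 1
    if not records:
        raise ValueError("no valid frames in the test session")
    return SessionResult.from_pairs(
        [r[1] for r in records],
        [r[2] for r in records],
        frame_index=[r[0] for r in records],
        phase="test",
        metadata=metadata or {},
    )
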