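"""Synthetic eye frames and feature-level gaze sessions with ground truth.

Two generators stand in for the camera and the human subject:

* :func:`render_eye_frame` draws a dark-pupil IR eye image — uniform
  background, a darker iris disk with a still darker anti-aliased pupil
  disk, and three Gaussian bright spots forming the triangular glint
  pattern — plus optional additive Gaussian noise.  It exercises the
  image-level feature extraction.

* :func:`simulate_gaze_features` maps a true point of gaze directly to
  an 8-coordinate feature vector through a smooth saturating forward
  model with additive feature noise.  It is a test oracle for the
  learned mapping only: the estimator never sees or inverts it.

The forward model moves the pupil from its rest position by a gain
times a tanh-type saturation of the gaze offset from the screen centre
(so the feature-to-gaze inverse is mildly nonlinear and a purely linear
regression leaves a few pixels of residual); the glint triangle drifts
weakly with the same saturated response, as corneal reflections share
the compressive geometry of the eye.  The noise-free mapping is
strictly monotone per axis and therefore injective over the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .features import Frame
from .geometry import ScreenGeometry
from .protocol import Grid, ScheduleConfig, test_sequence

__all__ = [
    "SceneParams",
    "SimParams",
    "SimulatedSample",
    "render_eye_frame",
    "simulate_gaze_features",
    "simulate_session",
    "scene_for_features",
    "noise_sigma_for_angle",
    "noise_floor_deg",
    "setting_preset",
]

# Canonical glint triangle (image px, y down): near-horizontal base below
# the pupil centre plus an apex above, sides ~= 25 px, matching the
# 0/60/120-degree validator.
_CANONICAL_TRIANGLE = (
    (307.5, 252.0),
    (332.5, 252.0),
    (320.0, 230.35),
)


@dataclass
class SceneParams:
    """Appearance of one rendered eye frame."""

    image_width_px: int = 640
    image_height_px: int = 480
    background_level: float = 110.0
    iris_level: float = 150.0
    pupil_level: float = 20.0
    glint_level: float = 255.0
    pupil_center: tuple[float, float] = (320.0, 240.0)
    pupil_radius_px: float = 40.0
    iris_radius_px: Optional[float] = None  # default 2.4 x pupil radius
    glint_centers: tuple = _CANONICAL_TRIANGLE
    glint_sigma_px: float = 2.5
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iris_radius_px is None:
            self.iris_radius_px = 2.4 * self.pupil_radius_px
        if not (self.pupil_level < self.iris_level < self.glint_level):
            raise ValueError("need pupil_level < iris_level < glint_level")
        for lvl in (self.background_level, self.iris_level, self.pupil_level,
                    self.glint_level):
            if not 0 <= lvl <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")
        if self.pupil_radius_px <= 0 or self.glint_sigma_px <= 0:
            raise ValueError("pupil radius and glint sigma must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        w, h = self.image_width_px, self.image_height_px
        centers = [self.pupil_center, *self.glint_centers]
        for (x, y) in centers:
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise ValueError(f"centre ({x}, {y}) lies outside the image")
        g = np.asarray(self.glint_centers, dtype=float)
        if g.shape != (3, 2):
            raise ValueError("exactly three glint centres are required")
        # non-collinearity: twice the triangle area
        d1, d2 = g[1] - g[0], g[2] - g[0]
        area2 = abs(d1[0] * d2[1] - d1[1] * d2[0])
        if area2 < 1e-9:
            raise ValueError("glint centres must not be collinear")


def _disk_coverage(
    shape: tuple[int, int], cx: float, cy: float, r: float, ss: int = 4
) -> np.ndarray:
    """Fractional pixel coverage of a disk, by ss x ss supersampling.

    Only the bounding box of the disk is evaluated; elsewhere the
    coverage is exactly 0.
    """
    h, w = shape
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, w)
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, h)
    cov = np.zeros(shape)
    if x1 <= x0 or y1 <= y0:
        return cov
    # subpixel sample offsets within each pixel (pixel centre at integer)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    ys = (np.arange(y0, y1)[:, None] + offs[None, :]).ravel()  # (ny*ss,)
    xs = (np.arange(x0, x1)[:, None] + offs[None, :]).ravel()
    inside = ((ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2) <= r * r
    block = inside.reshape(y1 - y0, ss, x1 - x0, ss).mean(axis=(1, 3))
    cov[y0:y1, x0:x1] = block
    return cov


def render_eye_frame(scene: SceneParams, index: int = 0) -> Frame:
    """Render one 8-bit eye frame; deterministic given (scene, seed)."""
    shape = (scene.image_height_px, scene.image_width_px)
    img = np.full(shape, float(scene.background_level))
    iris_cov = _disk_coverage(shape, *scene.pupil_center, scene.iris_radius_px)
    img = img * (1 - iris_cov) + scene.iris_level * iris_cov
    pupil_cov = _disk_coverage(shape, *scene.pupil_center, scene.pupil_radius_px)
    img = img * (1 - pupil_cov) + scene.pupil_level * pupil_cov
    # Gaussian spots evaluated on a +-6 sigma box (truncation error is
    # far below the 8-bit quantization step)
    half = int(np.ceil(6 * scene.glint_sigma_px)) + 1
    for (gx, gy) in scene.glint_centers:
        x0 = max(int(gx) - half, 0); x1 = min(int(gx) + half + 1, shape[1])
        y0 = max(int(gy) - half, 0); y1 = min(int(gy) + half + 1, shape[0])
        ys = np.arange(y0, y1)[:, None]
        xs = np.arange(x0, x1)[None, :]
        d2 = (xs - gx) ** 2 + (ys - gy) ** 2
        spot = np.exp(-d2 / (2.0 * scene.glint_sigma_px**2))
        img[y0:y1, x0:x1] += (scene.glint_level - img[y0:y1, x0:x1]) * spot
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sigma, size=shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return Frame(pixels=img, index=index)


@dataclass
class SimParams:
    """Forward model from true POG to eye features (test oracle only)."""

    pupil_gain: tuple[float, float] = (0.065, 0.065)  # image px per screen px
    nonlinearity_scale: float = 0.35  # 0 = affine mapping
    saturation_span_px: float = 350.0  # screen px scale of the tanh saturation
    glint_drift_gain: tuple[float, float] = (0.012, 0.012)
    feature_noise_sigma_px: float = 0.5
    rest_pupil_center: tuple[float, float] = (320.0, 240.0)
    glint_triangle: tuple = _CANONICAL_TRIANGLE
    screen_center: tuple[float, float] = (512.0, 384.0)

    def __post_init__(self) -> None:
        if self.feature_noise_sigma_px < 0:
            raise ValueError("feature_noise_sigma_px must be >= 0")
        if self.pupil_gain[0] == 0 or self.pupil_gain[1] == 0:
            raise ValueError("pupil_gain components must be nonzero")
        if not (0 <= self.nonlinearity_scale <= 1):
            raise ValueError("nonlinearity_scale must lie in [0, 1]")
        if self.saturation_span_px <= 0:
            raise ValueError("saturation_span_px must be positive")


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated fixation frame: ground-truth POG + feature vector."""

    true_pog: tuple[float, float]
    features: np.ndarray  # (8,)
    frame: Optional[Frame] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.shape != (8,) or not np.all(np.isfinite(f)):
            raise ValueError("features must be 8 finite coordinates")
        object.__setattr__(self, "features", f)


def _saturate(u: np.ndarray, sim: SimParams) -> np.ndarray:
    """Per-axis smooth saturation; affine when nonlinearity_scale is 0."""
    a = sim.nonlinearity_scale
    S = sim.saturation_span_px
    return (1.0 - a) * u + a * S * np.tanh(u / S)


def simulate_gaze_features(
    pog: tuple[float, float],
    sim: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSample:
    """Noise-free forward mapping plus optional Gaussian feature noise."""
    pog = np.asarray(pog, dtype=float)
    u = pog - np.asarray(sim.screen_center)
    s = _saturate(u, sim)
    pupil = np.asarray(sim.rest_pupil_center) + np.asarray(sim.pupil_gain) * s
    glints = np.asarray(sim.glint_triangle, dtype=float) + \
        np.asarray(sim.glint_drift_gain) * s
    feats = np.concatenate([pupil, glints.ravel()])
    if sim.feature_noise_sigma_px > 0:
        if rng is None:
            raise ValueError("an rng is required when feature noise is nonzero")
        feats = feats + rng.normal(0.0, sim.feature_noise_sigma_px, size=8)
    return SimulatedSample(true_pog=(float(pog[0]), float(pog[1])), features=feats)


def simulate_session(
    grid: Grid,
    sched: ScheduleConfig,
    sim: SimParams,
    seed: int,
    render: bool = False,
    scene: Optional[SceneParams] = None,
) -> list[SimulatedSample]:
    """Simulate a full calibration or test session.

    Calibration grids are visited sequentially with
    ``frames_per_cal_point`` samples each; test grids follow the seeded
    pseudo-random show order with ``frames_per_test_show`` samples per
    show.  With ``render=True`` each sample also carries a rendered
    frame whose planted pupil/glints equal the (noisy) features.
    """
    if grid.n_points == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    if grid.kind == "test":
        plan = [(grid.points[s], sched.frames_per_test_show)
                for s in test_sequence(grid, sched)]
    else:
        plan = [(p, sched.frames_per_cal_point) for p in grid.points]
    samples: list[SimulatedSample] = []
    idx = 0
    for point, n_frames in plan:
        for _ in range(n_frames):
            s = simulate_gaze_features(point, sim, rng)
            if render:
                sc = scene_for_features(s.features, scene)
                s = replace(s, frame=render_eye_frame(
                    replace(sc, seed=int(rng.integers(2**31))), index=idx))
            samples.append(s)
            idx += 1
    return samples


def scene_for_features(
    features: np.ndarray, base: Optional[SceneParams] = None
) -> SceneParams:
    """Scene whose planted pupil/glint centres equal a feature vector."""
    base = base or SceneParams()
    f = np.asarray(features, dtype=float)
    return replace(
        base,
        pupil_center=(f[0], f[1]),
        glint_centers=tuple((f[2 + 2 * k], f[3 + 2 * k]) for k in range(3)),
    )


def noise_sigma_for_angle(
    angle_deg: float, sim: SimParams, screen: ScreenGeometry
) -> float:
    """Feature-noise sigma whose pupil-channel POG floor is ~angle_deg radial.

    The radial angle is split evenly between the axes; the per-axis
    screen error sigma maps back to image pixels through the pupil
    gain.  Glint information can only shrink the real floor, so this is
    a conservative equivalence.
    """
    per_axis_px = screen.degrees_to_pixels(angle_deg) / np.sqrt(2.0)
    g = min(abs(sim.pupil_gain[0]), abs(sim.pupil_gain[1]))
    return float(per_axis_px * g)


def noise_floor_deg(sim: SimParams, screen: ScreenGeometry) -> float:
    """Radial POG noise floor (degrees) induced by the feature noise alone."""
    g = np.asarray(sim.pupil_gain)
    per_axis_px = sim.feature_noise_sigma_px / np.abs(g)
    radial_px = float(np.hypot(*per_axis_px))
    return screen.pixels_to_degrees(radial_px)


def setting_preset(setting: int) -> SimParams:
    """Simulator presets tagging the three camera/illuminator layouts.

    The three geometric settings (0, 30 and 60 degrees between the IR
    lights and the camera) differ only in where the eye appears and how
    strongly features respond; the estimator must never use this tag
    (free-geometry principle).
    """
    if setting == 1:
        return SimParams()
    if setting == 2:
        return SimParams(
            pupil_gain=(0.060, 0.068),
            rest_pupil_center=(280.0, 236.0),
            glint_triangle=tuple((x - 41.0, y - 3.0) for x, y in _CANONICAL_TRIANGLE),
            glint_drift_gain=(0.011, 0.013),
        )
    if setting == 3:
        return SimParams(
            pupil_gain=(0.055, 0.070),
            rest_pupil_center=(240.0, 230.0),
            glint_triangle=tuple((x - 82.0, y - 8.0) for x, y in _CANONICAL_TRIANGLE),
            glint_drift_gain=(0.010, 0.014),
            nonlinearity_scale=0.45,
        )
    raise ValueError("setting must be 1, 2 or 3")
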