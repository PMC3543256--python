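"""Eye-feature extraction: dark pupil centre and the three-glint triangle.

The detection chain mirrors a classic PCCR front end.  The pupil appears
as a dark disk under off-axis IR illumination and is located by a binary
threshold followed by a circle Hough transform on the mask boundary
(the target is the pupil *centre*, not its exact shape).  The three IR
sources project a triangular pattern of corneal reflections (glints);
these are segmented by a bright threshold, reduced to intensity-weighted
blob centroids with subpixel accuracy, and then validated geometrically:
the three lines joining the glint pairs must point at 0, 60 and 120
degrees (within a tolerance) and the triangle sides must fall inside a
configured length range, otherwise the frame is discarded as an
artifact.  The surviving pupil centre plus three glint centroids form
the 8-coordinate feature vector fed to the gaze mapping.

Image coordinate convention: origin at the top-left pixel centre, x
rightward, y downward; a point (x, y) addresses ``pixels[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle

__all__ = [
    "Frame",
    "DetectorConfig",
    "PupilDetection",
    "GlintCandidate",
    "GlintTriple",
    "EyeFeatures",
    "FrameRejected",
    "binarize",
    "detect_pupil",
    "detect_glint_candidates",
    "validate_triangle",
    "extract_features",
]

TRIANGLE_TARGET_DIRECTIONS = (0.0, 60.0, 120.0)


class FrameRejected(Exception):
    """A frame failed one stage of the detection chain.

    ``stage`` is one of ``"pupil"``, ``"glints"``, ``"triangle"`` so
    that session runners can log where each frame was lost.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class Frame:
    """One grayscale eye image (8-bit raster) with its frame index."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame must be a non-empty 2-D raster")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width_px - 1 and 0 <= y <= self.height_px - 1


@dataclass
class DetectorConfig:
    """Per-session detection constants.

    Thresholds are set once per (indoor) session.  ``side_range`` and
    ``angle_tol_deg`` bound the admissible glint triangle; both are
    deliberately loose by default and meant to be adapted to the
    expected glint pattern scale.
    """

    pupil_threshold: float = 60.0
    glint_threshold: float = 200.0
    r_min: float = 10.0
    r_max: float = 60.0
    hough_accumulator_step: float = 1.0
    roi_scale: float = 4.0
    angle_tol_deg: float = 10.0
    side_range: tuple[float, float] = (8.0, 60.0)
    min_blob_area: int = 3
    hough_min_score: float = 0.25  # minimal normalized accumulator support

    def __post_init__(self) -> None:
        if not (0 <= self.pupil_threshold <= 255 and 0 <= self.glint_threshold <= 255):
            raise ValueError("thresholds must lie in [0, 255]")
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if self.hough_accumulator_step <= 0:
            raise ValueError("hough_accumulator_step must be positive")
        if not (0.0 < self.angle_tol_deg < 30.0):
            raise ValueError("angle_tol_deg must lie in (0, 30) degrees")
        if not (self.side_range[0] < self.side_range[1]):
            raise ValueError("side_range must satisfy L_min < L_max")
        if self.min_blob_area < 1:
            raise ValueError("min_blob_area must be >= 1")
        if self.roi_scale <= 0:
            raise ValueError("roi_scale must be positive")


@dataclass(frozen=True)
class PupilDetection:
    center: tuple[float, float]
    radius_px: float
    score: float


@dataclass(frozen=True)
class GlintCandidate:
    centroid: tuple[float, float]
    area_px: int
    mass: float


@dataclass(frozen=True)
class GlintTriple:
    """Three validated glints in canonical order.

    Order: the two endpoints of the near-horizontal side left-to-right,
    then the apex.  ``side_directions``/``side_lengths`` are listed in
    the order matched to the 0/60/120-degree targets.
    """

    glints: tuple[GlintCandidate, GlintCandidate, GlintCandidate]
    side_directions: tuple[float, float, float]
    side_lengths: tuple[float, float, float]


@dataclass(frozen=True)
class EyeFeatures:
    pupil: PupilDetection
    triple: GlintTriple
    vector: np.ndarray  # (8,) pupil x,y then glints 1-3 x,y

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (8,) or not np.all(np.isfinite(v)):
            raise ValueError("feature vector must be 8 finite coordinates")
        object.__setattr__(self, "vector", v)


def binarize(
    frame: Frame, threshold: float, polarity: Literal["dark", "bright"]
) -> np.ndarray:
    """Binary mask of pixels strictly below (dark) or above (bright) threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if polarity == "dark":
        return frame.pixels < threshold
    if polarity == "bright":
        return frame.pixels > threshold
    raise ValueError(f"unknown polarity {polarity!r}")


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    # boundary = mask minus its 4-connected erosion
    if not mask.any():
        return mask
    eroded = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    return mask & ~eroded


def _hough_pupil(pixels: np.ndarray, cfg: DetectorConfig) -> Optional[PupilDetection]:
    mask = pixels < cfg.pupil_threshold
    edges = _mask_boundary(mask)
    if not edges.any():
        return None
    radii = np.arange(
        cfg.r_min, cfg.r_max + 0.5 * cfg.hough_accumulator_step,
        cfg.hough_accumulator_step,
    )
    acc = hough_circle(edges, radii, normalize=True)
    ir, iy, ix = np.unravel_index(np.argmax(acc), acc.shape)
    peak = float(acc[ir, iy, ix])
    if peak < cfg.hough_min_score:
        return None
    # refine the centre as the centroid of the supra-threshold accumulator
    # neighbourhood around the global maximum (half-peak support)
    sl = acc[ir]
    y0, y1 = max(iy - 2, 0), min(iy + 3, sl.shape[0])
    x0, x1 = max(ix - 2, 0), min(ix + 3, sl.shape[1])
    win = sl[y0:y1, x0:x1] - 0.5 * peak
    win = np.clip(win, 0.0, None)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    wsum = win.sum()
    cy = float((ys * win).sum() / wsum)
    cx = float((xs * win).sum() / wsum)
    return PupilDetection(center=(cx, cy), radius_px=float(radii[ir]), score=peak)


def detect_pupil(
    frame: Frame, cfg: DetectorConfig, prev: Optional[PupilDetection] = None
) -> Optional[PupilDetection]:
    """Locate the dark pupil by thresholding + circle Hough voting.

    When a previous detection is supplied, only a rectangular region of
    interest around it (half-width ``roi_scale * prev.radius_px``) is
    processed; if that fails, the full frame is retried.  Returns None
    when no circle gathers sufficient accumulator support.
    """
    if prev is not None:
        half = cfg.roi_scale * prev.radius_px
        x0 = max(int(np.floor(prev.center[0] - half)), 0)
        x1 = min(int(np.ceil(prev.center[0] + half)) + 1, frame.width_px)
        y0 = max(int(np.floor(prev.center[1] - half)), 0)
        y1 = min(int(np.ceil(prev.center[1] + half)) + 1, frame.height_px)
        if x1 > x0 and y1 > y0:
            det = _hough_pupil(frame.pixels[y0:y1, x0:x1], cfg)
            if det is not None:
                return PupilDetection(
                    center=(det.center[0] + x0, det.center[1] + y0),
                    radius_px=det.radius_px,
                    score=det.score,
                )
    return _hough_pupil(frame.pixels, cfg)


def detect_glint_candidates(
    frame: Frame, cfg: DetectorConfig
) -> list[GlintCandidate]:
    """Bright blobs above the glint threshold, as subpixel centres of mass.

    8-connected components with area >= ``min_blob_area`` are kept; each
    centroid is the intensity-weighted mean c = sum(p w(p)) / sum(w(p))
    over the component's pixels, with the detection threshold subtracted
    from the weights, w = I - threshold.  Background subtraction removes
    the pedestal bias of the quantized component support and is what
    makes the centroid genuinely subpixel (< 0.1 px for a planted
    Gaussian spot); with threshold 0 it reduces to plain intensity
    weighting.
    """
    mask = binarize(frame, cfg.glint_threshold, "bright")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask, labels, idx)
    pix = (frame.pixels.astype(float) - cfg.glint_threshold) * mask
    masses = ndimage.sum_labels(pix, labels, idx)
    coms = ndimage.center_of_mass(pix, labels, idx)  # (y, x), weighted
    out = []
    for a, m, (cy, cx) in zip(areas, masses, coms):
        if a >= cfg.min_blob_area:
            out.append(GlintCandidate(centroid=(float(cx), float(cy)),
                                      area_px=int(a), mass=float(m)))
    out.sort(key=lambda g: -g.mass)
    return out


def _fold_direction_deg(dx: float, dy: float) -> float:
    """Direction of an (unordered) line through two points, folded to [0, 180)."""
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    return float(ang % 180.0)


def _circ_dist_180(a: float, b: float) -> float:
    """Distance between two line directions on the 180-degree circle."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _triangle_geometry(points: np.ndarray):
    """Directions/lengths of the three sides of a candidate triple.

    Sides are indexed by the *opposite* vertex: side k joins the two
    vertices other than k.
    """
    dirs, lens = [], []
    for k in range(3):
        i, j = [m for m in range(3) if m != k]
        d = points[j] - points[i]
        dirs.append(_fold_direction_deg(d[0], d[1]))
        lens.append(float(np.hypot(d[0], d[1])))
    return dirs, lens


def _match_directions(dirs: Sequence[float], tol: float):
    """Best assignment of measured line directions to the 0/60/120 targets.

    Returns (total deviation, permutation) or None if no assignment puts
    every direction within ``tol`` of its target.
    """
    best = None
    for perm in permutations(range(3)):
        devs = [
            _circ_dist_180(dirs[perm[k]], TRIANGLE_TARGET_DIRECTIONS[k])
            for k in range(3)
        ]
        if max(devs) <= tol:
            tot = sum(devs)
            if best is None or tot < best[0]:
                best = (tot, perm)
    return best


def validate_triangle(
    candidates: Sequence[GlintCandidate], cfg: DetectorConfig
) -> GlintTriple:
    """Select the glint triple matching the 0/60/120-degree triangle.

    Every 3-subset of the candidates is tested: the directions of the
    three joining lines (folded to [0, 180) since glint pairs are
    unordered) must match {0, 60, 120} degrees within ``angle_tol_deg``
    and every side length must lie in ``side_range``.  Among passing
    subsets the one with minimal total angular deviation wins.  Raises
    :class:`FrameRejected` (stage "triangle") when no subset passes.
    """
    if len(candidates) < 3:
        raise FrameRejected("triangle", f"only {len(candidates)} glint candidates")
    lo, hi = cfg.side_range
    best = None
    for subset in combinations(candidates, 3):
        pts = np.array([g.centroid for g in subset], dtype=float)
        dirs, lens = _triangle_geometry(pts)
        if not all(lo <= L <= hi for L in lens):
            continue
        match = _match_directions(dirs, cfg.angle_tol_deg)
        if match is None:
            continue
        tot, perm = match
        if best is None or tot < best[0]:
            best = (tot, subset, dirs, lens, perm)
    if best is None:
        raise FrameRejected("triangle", "no candidate subset forms a valid triangle")
    _, subset, dirs, lens, perm = best
    # perm[k] is the side matched to target k; side perm[0] (the
    # near-horizontal one) is opposite the apex vertex perm[0].
    apex = perm[0]
    base = [m for m in range(3) if m != apex]
    base.sort(key=lambda m: subset[m].centroid[0])  # left to right
    ordered = (subset[base[0]], subset[base[1]], subset[apex])
    return GlintTriple(
        glints=ordered,
        side_directions=tuple(dirs[perm[k]] for k in range(3)),
        side_lengths=tuple(lens[perm[k]] for k in range(3)),
    )


def extract_features(
    frame: Frame, cfg: DetectorConfig, prev: Optional[PupilDetection] = None
) -> EyeFeatures:
    """Full per-frame chain: pupil -> glint blobs -> triangle validation.

    Raises :class:`FrameRejected` with the failing stage tag; a valid
    frame yields the ordered 8-coordinate feature vector.
    """
    pupil = detect_pupil(frame, cfg, prev)
    if pupil is None:
        raise FrameRejected("pupil", "no circle with sufficient support")
    if not frame.contains(*pupil.center):
        raise FrameRejected("pupil", "detected centre outside the frame")
    candidates = detect_glint_candidates(frame, cfg)
    if not candidates:
        raise FrameRejected("glints", "no bright blobs above threshold")
    triple = validate_triangle(candidates, cfg)
    vec = np.array(
        [*pupil.center,
         *triple.glints[0].centroid,
         *triple.glints[1].centroid,
         *triple.glints[2].centroid],
        dtype=float,
    )
    return EyeFeatures(pupil=pupil, triple=triple, vector=vec)
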