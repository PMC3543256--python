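"""Pupil detection, glint centroiding and the triangular-pattern validator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurogaze.features import (
    DetectorConfig,
    Frame,
    FrameRejected,
    GlintCandidate,
    binarize,
    detect_glint_candidates,
    detect_pupil,
    extract_features,
    validate_triangle,
)
from neurogaze.synth import SceneParams, render_eye_frame


def uniform_frame(level, w=64, h=48):
    return Frame(np.full((h, w), level, dtype=np.uint8))


class TestBinarize:
    def test_strict_inequality(self):
        frame = uniform_frame(100)
        assert not binarize(frame, 100, "dark").any()
        assert not binarize(frame, 100, "bright").any()

    def test_single_dark_pixel(self):
        px = np.full((48, 64), 200, dtype=np.uint8)
        px[10, 20] = 0
        mask = binarize(Frame(px), 50, "dark")
        assert mask.sum() == 1 and mask[10, 20]
        assert binarize(Frame(px), 150, "bright").sum() == 64 * 48 - 1

    def test_bad_polarity(self):
        with pytest.raises(ValueError):
            binarize(uniform_frame(10), 50, "sideways")


class TestDetectPupil:
    def test_planted_disk(self, detector_cfg):
        scene = SceneParams()
        det = detect_pupil(render_eye_frame(scene), detector_cfg)
        assert det is not None
        assert np.hypot(det.center[0] - 320, det.center[1] - 240) < 1.0
        assert abs(det.radius_px - 40) <= 2.0

    def test_subpixel_center_against_mask_centroid(self, detector_cfg):
        """Hough centre agrees with the brute-force dark-mask centroid,
        which is exact for a full disk."""
        scene = SceneParams(
            image_width_px=200, image_height_px=160,
            pupil_center=(100.5, 80.5), pupil_radius_px=20, iris_radius_px=45,
            glint_centers=((60.2, 40.4), (140.7, 40.2), (100.3, 120.6)),
        )
        frame = render_eye_frame(scene)
        det = detect_pupil(frame, detector_cfg)
        ys, xs = np.nonzero(frame.pixels < detector_cfg.pupil_threshold)
        oracle = (xs.mean(), ys.mean())
        assert np.hypot(det.center[0] - 100.5, det.center[1] - 80.5) < 1.0
        assert np.hypot(det.center[0] - oracle[0], det.center[1] - oracle[1]) < 1.0

    def test_uniform_bright_frame_not_found(self, detector_cfg):
        assert detect_pupil(uniform_frame(220), detector_cfg) is None

    def test_roi_agrees_with_full_frame(self, detector_cfg):
        frame = render_eye_frame(SceneParams())
        full = detect_pupil(frame, detector_cfg)
        via_roi = detect_pupil(frame, detector_cfg, prev=full)
        assert np.hypot(full.center[0] - via_roi.center[0],
                        full.center[1] - via_roi.center[1]) < 0.5

    def test_roi_miss_falls_back_to_full_frame(self, detector_cfg):
        from neurogaze.features import PupilDetection
        frame = render_eye_frame(SceneParams())
        stale = PupilDetection(center=(600.0, 50.0), radius_px=10.0, score=1.0)
        det = detect_pupil(frame, detector_cfg, prev=stale)
        assert det is not None
        assert np.hypot(det.center[0] - 320, det.center[1] - 240) < 1.0


class TestGlintCandidates:
    def test_symmetric_blob_integer_centroid(self):
        px = np.zeros((32, 32), dtype=np.uint8)
        px[9:12, 9:12] = 200
        cfg = DetectorConfig(glint_threshold=0, min_blob_area=1)
        (cand,) = detect_glint_candidates(Frame(px), cfg)
        assert cand.centroid == (10.0, 10.0)
        assert cand.area_px == 9

    def test_weighted_mean_arithmetic(self):
        """Two-pixel blob, intensities 100 and 200: the centroid is the
        intensity-weighted mean (threshold 0 keeps raw-intensity weights)."""
        px = np.zeros((8, 16), dtype=np.uint8)
        px[4, 10] = 100
        px[4, 11] = 200
        cfg = DetectorConfig(glint_threshold=0, min_blob_area=1)
        (cand,) = detect_glint_candidates(Frame(px), cfg)
        assert cand.centroid[0] == pytest.approx((10 * 100 + 11 * 200) / 300)
        assert cand.centroid[1] == pytest.approx(4.0)

    def test_min_area_filter(self):
        px = np.zeros((16, 16), dtype=np.uint8)
        px[3, 3] = 255  # area 1
        px[8:10, 8:10] = 255  # area 4
        cfg = DetectorConfig(glint_threshold=100, min_blob_area=2)
        cands = detect_glint_candidates(Frame(px), cfg)
        assert len(cands) == 1
        assert cands[0].area_px == 4

    def test_subpixel_accuracy_on_planted_spots(self, detector_cfg):
        """Centroid error < 0.1 px for Gaussian spots at random subpixel
        positions (noise-free)."""
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            gx, gy = 50 + rng.uniform(0, 1), 50 + rng.uniform(0, 1)
            scene = SceneParams(
                image_width_px=100, image_height_px=100,
                pupil_center=(20, 20), pupil_radius_px=8, iris_radius_px=12,
                glint_centers=((gx, gy), (80.3, 20.7), (20.6, 80.2)),
            )
            cands = detect_glint_candidates(render_eye_frame(scene), detector_cfg)
            c = min(cands, key=lambda g: (g.centroid[0] - gx) ** 2
                    + (g.centroid[1] - gy) ** 2)
            errs.append(np.hypot(c.centroid[0] - gx, c.centroid[1] - gy))
        assert max(errs) < 0.1


def cand(x, y):
    return GlintCandidate(centroid=(float(x), float(y)), area_px=5, mass=500.0)


EQUILATERAL = [cand(0, 0), cand(10, 0), cand(5, 8.660254)]


class TestValidateTriangle:
    def test_equilateral_accepted(self):
        cfg = DetectorConfig(side_range=(5, 20), angle_tol_deg=5)
        triple = validate_triangle(EQUILATERAL, cfg)
        assert sorted(round(d) % 180 for d in triple.side_directions) == [0, 60, 120]
        for L in triple.side_lengths:
            assert L == pytest.approx(10.0, abs=1e-6)

    def test_canonical_order(self):
        cfg = DetectorConfig(side_range=(5, 20), angle_tol_deg=5)
        triple = validate_triangle(EQUILATERAL, cfg)
        # near-horizontal side endpoints left-to-right, then the apex
        assert triple.glints[0].centroid[0] < triple.glints[1].centroid[0]
        assert triple.glints[2].centroid == (5.0, 8.660254)

    def test_collinear_rejected(self):
        cfg = DetectorConfig(side_range=(5, 40), angle_tol_deg=5)
        with pytest.raises(FrameRejected, match="triangle"):
            validate_triangle([cand(0, 0), cand(10, 0), cand(20, 0)], cfg)

    def test_side_length_rejection(self):
        cfg = DetectorConfig(side_range=(5, 20), angle_tol_deg=5)
        tiny = [cand(0, 0), cand(2, 0), cand(1, 1.732)]
        with pytest.raises(FrameRejected, match="triangle"):
            validate_triangle(tiny, cfg)

    def test_too_few_candidates(self):
        cfg = DetectorConfig()
        with pytest.raises(FrameRejected, match="triangle"):
            validate_triangle(EQUILATERAL[:2], cfg)

    def test_spurious_candidate_excluded(self):
        cfg = DetectorConfig(side_range=(5, 20), angle_tol_deg=5)
        triple = validate_triangle(EQUILATERAL + [cand(40, 40)], cfg)
        got = {g.centroid for g in triple.glints}
        assert (40.0, 40.0) not in got

    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        perm=st.permutations(range(3)),
    )
    @settings(max_examples=50, deadline=None)
    def test_acceptance_invariant_to_order_and_translation(self, dx, dy, perm):
        cfg = DetectorConfig(side_range=(5, 20), angle_tol_deg=5)
        moved = [cand(EQUILATERAL[i].centroid[0] + dx,
                      EQUILATERAL[i].centroid[1] + dy) for i in perm]
        triple = validate_triangle(moved, cfg)
        np.testing.assert_allclose(
            sorted(triple.side_lengths), [10.0] * 3, atol=1e-6)

    @given(
        tol=st.floats(1.0, 10.0), shrink=st.floats(0.1, 0.99),
        jitter=st.floats(0, 1.5), seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_rejection_monotone_in_tolerance(self, tol, shrink, jitter, seed):
        """Shrinking the angular tolerance never turns a rejection into
        an acceptance."""
        rng = np.random.default_rng(seed)
        pts = np.array([g.centroid for g in EQUILATERAL])
        pts = pts + rng.normal(0, jitter, size=pts.shape)
        cands = [cand(*p) for p in pts]
        def accepted(t):
            try:
                validate_triangle(cands, DetectorConfig(
                    side_range=(5, 20), angle_tol_deg=t))
                return True
            except FrameRejected:
                return False
        if accepted(tol * shrink):
            assert accepted(tol)


class TestExtractFeatures:
    def test_recovers_planted_scene(self, detector_cfg):
        scene = SceneParams()
        feats = extract_features(render_eye_frame(scene), detector_cfg)
        assert np.hypot(*(feats.vector[:2] - np.array(scene.pupil_center))) < 1.0
        planted = np.array(scene.glint_centers)
        detected = feats.vector[2:].reshape(3, 2)
        for p in planted:
            assert np.min(np.hypot(*(detected - p).T)) < 0.2

    def test_two_glints_rejected_with_stage_tag(self, detector_cfg):
        scene = SceneParams()
        frame = render_eye_frame(scene)
        # erase one glint region
        gx, gy = scene.glint_centers[2]
        px = frame.pixels.copy()
        px[int(gy) - 8:int(gy) + 8, int(gx) - 8:int(gx) + 8] = scene.iris_level
        with pytest.raises(FrameRejected) as exc:
            extract_features(Frame(px), detector_cfg)
        assert exc.value.stage == "triangle"

    def test_uniform_frame_rejected_at_pupil_stage(self, detector_cfg):
        with pytest.raises(FrameRejected) as exc:
            extract_features(uniform_frame(200), detector_cfg)
        assert exc.value.stage == "pupil"
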