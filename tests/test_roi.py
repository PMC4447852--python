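"""ROI battery: border tests, boundary curves, signature, landmarks."""

from __future__ import annotations

import numpy as np
import pytest

from cowtof.roi import (
    FailureStage,
    RoiResult,
    Signature,
    classify_and_detect_dishes,
    compute_boundary_curves,
    compute_signature,
    detect_tail,
    detect_tuberosities,
    fit_backbone,
    run_roi,
    validate_anatomy,
    _smooth,
)
# aliased so pytest does not collect the library's test_* operations
from cowtof.roi import test_hind_boundary as hind_boundary_test
from cowtof.roi import test_image_border as image_border_test
from cowtof.segment import SegmentedFrame, sort_frame
from cowtof.tofsim import fv_shape, hf_shape, render_cow_frame


def make_seg(mask: np.ndarray, depth: np.ndarray | None = None,
             camera_height: float = 2.55) -> SegmentedFrame:
    """A SegmentedFrame assembled directly from arrays (unit-test helper)."""
    if depth is None:
        depth = np.where(mask, 1.2, 0.0)
    else:
        depth = np.where(mask, depth, 0.0)
    from cowtof.segment import RejectionReason

    return SegmentedFrame(
        depth=depth.astype(float), mask=mask.astype(bool),
        keep_decision=True, rejection_reason=RejectionReason.NONE,
        camera_height=camera_height,
    )


def landmark_errors(result: RoiResult, gt) -> dict[str, float]:
    return {
        name: float(np.hypot(p[0] - g[0], p[1] - g[1]))
        for name, p in result.landmarks.items()
        for g in [gt.landmarks[name]]
    }


class TestImageBorder:
    def test_centred_cow_passes_both_sides(self, hf_seg, config):
        assert image_border_test(hf_seg, config.roi) == (1, 1)

    def test_cow_on_left_edge_fails_left_only(self, scene, scenery, config):
        frame, _ = render_cow_frame(scene, hf_shape(lateral_drift=-54.0))
        seg = sort_frame(frame, scenery, config.segment)
        assert image_border_test(seg, config.roi) == (0, 1)

    def test_mask_spanning_both_edges_fails_both(self, config):
        mask = np.zeros((20, 30), dtype=bool)
        mask[5:15, :] = True
        assert image_border_test(make_seg(mask), config.roi) == (0, 0)


class TestHindBoundary:
    def test_convex_cow_curves_identical(self, hf_seg):
        curves = compute_boundary_curves(hf_seg)
        assert np.array_equal(curves.outer, curves.inner)
        assert hind_boundary_test(curves) == 1

    def test_overhanging_tail_beyond_tolerance_fails(
        self, scene, scenery, config
    ):
        frame, _ = render_cow_frame(scene, hf_shape(tail_overhang=6))
        seg = sort_frame(frame, scenery, config.segment)
        curves = compute_boundary_curves(seg)
        assert (curves.inner - curves.outer).max() > config.roi.tol_rows
        assert hind_boundary_test(curves, config.roi.tol_rows) == 0

    def test_overhang_within_tolerance_passes(self, scene, scenery, config):
        frame, _ = render_cow_frame(scene, hf_shape(tail_overhang=2))
        seg = sort_frame(frame, scenery, config.segment)
        assert hind_boundary_test(compute_boundary_curves(seg), 3) == 1

    def test_stray_blob_above_cow_fails(self, hf_seg, config):
        mask = hf_seg.mask.copy()
        depth = hf_seg.depth.copy()
        cols = np.nonzero(mask.any(axis=0))[0]
        c = int(cols.mean()) + 10
        top = int(np.nonzero(mask[:, c])[0][0])
        mask[top - 8 : top - 5, c] = True  # leftover floor/wall fragment
        depth[top - 8 : top - 5, c] = 1.2
        seg = make_seg(mask, depth)
        assert hind_boundary_test(compute_boundary_curves(seg), config.roi.tol_rows) == 0


class TestSignature:
    def test_half_disc_signature_is_constant_radius(self, config):
        mask = np.zeros((80, 120), dtype=bool)
        rr, cc = np.mgrid[0:80, 0:120]
        # half-disc below the centre point (40, 60), radius 30
        mask[(np.hypot(rr - 40, cc - 60) <= 30) & (rr >= 40)] = True
        seg = make_seg(mask)
        sig = compute_signature(seg, config=config.roi)
        com = sig.com
        radii = np.hypot(sig.points[:, 0] - com[0], sig.points[:, 1] - com[1])
        # boundary points along the flat top edge vary little around the
        # distance from the centre of mass to that edge
        mid = radii[10:-10]
        assert mid.max() - mid.min() <= np.ptp(sig.points[10:-10, 1]) * 0.35

    def test_symmetric_cow_signature_is_palindromic(self, scene_sym, scenery_sym, config):
        frame, _ = render_cow_frame(scene_sym, hf_shape())
        seg = sort_frame(frame, scenery_sym, config.segment)
        sig = compute_signature(seg, config=config.roi)
        d = sig.distances
        assert np.abs(d - d[::-1]).max() <= 1.0

    def test_translation_invariance(self, hf_seg, config):
        sig = compute_signature(hf_seg, config=config.roi)
        shifted = make_seg(
            np.roll(hf_seg.mask, -3, axis=0), np.roll(hf_seg.depth, -3, axis=0)
        )
        sig2 = compute_signature(shifted, config=config.roi)
        assert np.allclose(sig.distances, sig2.distances)

    def test_breed_classes_have_distinct_signatures(
        self, hf_seg, fv_seg, config
    ):
        for seg, breed in ((hf_seg, "HF"), (fv_seg, "FV")):
            sig = compute_signature(seg, config=config.roi)
            tail_idx = detect_tail(sig, config.roi)
            res = run_roi(seg, breed, config.roi)
            tail_d = sig.smoothed[tail_idx]
            tub_cols = [res.tuberosity_left[1], res.tuberosity_right[1]]
            tub_d = [
                sig.smoothed[int(np.argmin(np.abs(sig.points[:, 1] - c)))]
                for c in tub_cols
            ]
            if breed == "FV":
                assert all(tail_d > 1.10 * t for t in tub_d)
            else:
                assert all(abs(tail_d - t) <= 0.10 * tail_d for t in tub_d)


class TestDetectTail:
    def test_tail_found_at_ground_truth(self, hf_seg, hf_render, config):
        _, gt = hf_render
        sig = compute_signature(hf_seg, config=config.roi)
        idx = detect_tail(sig, config.roi)
        assert idx is not None
        assert abs(sig.points[idx][1] - gt.tail[1]) <= 1

    def test_monotone_signature_has_no_tail(self, config):
        n = 40
        points = np.column_stack([np.arange(n), np.arange(n)])
        d = np.linspace(50, 20, n)
        sig = Signature(distances=d, points=points, com=(60.0, 20.0),
                        smoothed=_smooth(d, 5))
        assert detect_tail(sig, config.roi) is None

    def test_on_axis_maximum_wins_over_off_axis(self, config):
        # two local maxima: one straight above the COM, one ~40 deg off
        com = (50.0, 50.0)
        cols = np.arange(20, 81)
        rows = np.full_like(cols, 20)
        d = np.hypot(rows - com[0], cols - com[1]).astype(float)
        bump = 6.0 * np.exp(-0.5 * ((cols - 50) / 2.5) ** 2)  # on-axis
        bump += 8.0 * np.exp(-0.5 * ((cols - 75) / 2.5) ** 2)  # 40 deg off
        d = d + bump
        sig = Signature(
            distances=d, points=np.column_stack([rows, cols]), com=com,
            smoothed=_smooth(d, 5),
        )
        idx = detect_tail(sig, config.roi)
        assert abs(sig.points[idx][1] - 50) <= 1


class TestDishes:
    def test_hf_dishes_deep_at_ground_truth(self, hf_seg, hf_render, config):
        _, gt = hf_render
        sig = compute_signature(hf_seg, config=config.roi)
        tail = detect_tail(sig, config.roi)
        dishes = classify_and_detect_dishes(sig, tail, config.roi)
        for side, gt_pt in (("left", gt.dish_left), ("right", gt.dish_right)):
            idx, cls = dishes[side]
            assert cls == "deep"
            assert abs(sig.points[idx][1] - gt_pt[1]) <= 2

    def test_fv_dishes_flat(self, fv_seg, config):
        sig = compute_signature(fv_seg, config=config.roi)
        tail = detect_tail(sig, config.roi)
        dishes = classify_and_detect_dishes(sig, tail, config.roi)
        assert dishes["left"][1] == "flat"
        assert dishes["right"][1] == "flat"

    def test_mixed_dish_classes_detected_and_rejected(self, config):
        # constructed signature: explicit minimum left of the tail bump, a
        # flat course to its right — classes differ, so the frame is
        # discarded on the HF path
        cols = np.arange(10, 91)
        u = cols - 50.0
        d = 40.0 + 8.0 * np.exp(-0.5 * (u / 3.0) ** 2)
        d -= 2.0 * np.exp(-0.5 * ((u + 12) / 2.5) ** 2)  # left dish dip
        d += np.where(u > 0, -0.05 * u, 0.0)  # right side segues flat
        sig = Signature(
            distances=d, points=np.column_stack([60.0 - d, cols]),
            com=(60.0, 50.0), smoothed=_smooth(d, config.roi.smooth_window),
        )
        tail = detect_tail(sig, config.roi)
        dishes = classify_and_detect_dishes(sig, tail, config.roi)
        assert dishes["left"][1] == "deep"
        assert dishes["right"][1] == "flat"
        assert detect_tuberosities(sig, dishes, "HF", config.roi) is None

    def test_asymmetric_flat_rump_frame_discarded(self, scene, scenery, config):
        # one rump side with its features suppressed never survives the
        # cascade, whichever stage catches it first
        frame, _ = render_cow_frame(
            scene,
            hf_shape(dish_depth_right=1.0, dish_mode_right="flat", asymmetry=0.8),
        )
        seg = sort_frame(frame, scenery, config.segment)
        res = run_roi(seg, "HF", config.roi)
        assert not res.valid


class TestTuberosities:
    def test_hf_at_ground_truth(self, hf_seg, hf_render, config):
        _, gt = hf_render
        res = run_roi(hf_seg, "HF", config.roi)
        assert res.valid
        assert abs(res.tuberosity_left[1] - gt.tuberosity_left[1]) <= 2
        assert abs(res.tuberosity_right[1] - gt.tuberosity_right[1]) <= 2

    def test_fv_halfway_between_dish_and_drop(self, fv_seg, config):
        sig = compute_signature(fv_seg, config=config.roi)
        tail = detect_tail(sig, config.roi)
        dishes = classify_and_detect_dishes(sig, tail, config.roi)
        tubs = detect_tuberosities(sig, dishes, "FV", config.roi)
        s = sig.smoothed
        level = config.roi.drop_tol * s.max()
        for side, direction in (("left", -1), ("right", +1)):
            dish_idx = dishes[side][0]
            i = dish_idx
            while s[i] >= level:
                i += direction
            midway = dish_idx + direction * (abs(i - dish_idx) // 2)
            assert tubs[side] == midway

    def test_hf_rule_requires_both_dishes_deep(self, config):
        sig = None  # the rule rejects on classes before touching the signature
        dishes = {"left": (10, "deep"), "right": (30, "flat")}
        assert detect_tuberosities(sig, dishes, "HF", config.roi) is None
        dishes = {"left": (10, "flat"), "right": (30, "flat")}
        assert detect_tuberosities(sig, dishes, "HF", config.roi) is None


class TestBackbone:
    def test_fitted_line_tracks_ridge(self, hf_seg, config):
        slope, intercept = fit_backbone(hf_seg, config.roi)
        depth = np.where(hf_seg.mask, hf_seg.depth, np.inf)
        rows = np.nonzero(hf_seg.mask.any(axis=1))[0]
        span = rows[-1] - rows[0]
        for r in rows[rows >= rows[0] + 0.25 * span][::7]:
            crest = np.argmin(depth[r])
            assert abs((intercept + slope * r) - crest) <= 1

    def test_yawed_cow_slope_recovered_within_one_degree(
        self, scene, scenery, config
    ):
        frame, gt = render_cow_frame(scene, hf_shape(yaw_deg=5.0))
        seg = sort_frame(frame, scenery, config.segment)
        slope, _ = fit_backbone(seg, config.roi)
        assert abs(np.degrees(np.arctan(slope)) - 5.0) <= 1.0

    def test_single_row_mask_fails(self, config):
        mask = np.zeros((20, 30), dtype=bool)
        mask[10, 5:25] = True
        assert fit_backbone(make_seg(mask), config.roi) is None


class TestHips:
    def test_hips_at_ground_truth(self, hf_seg, hf_render, config):
        _, gt = hf_render
        res = run_roi(hf_seg, "HF", config.roi)
        assert res.valid
        for det, truth in ((res.hip_left, gt.hip_left), (res.hip_right, gt.hip_right)):
            assert np.hypot(det[0] - truth[0], det[1] - truth[1]) <= 2

    def test_suppressed_hip_rejects_frame(self, scene, scenery, config):
        frame, _ = render_cow_frame(scene, hf_shape(asymmetry=0.9))
        seg = sort_frame(frame, scenery, config.segment)
        res = run_roi(seg, "HF", config.roi)
        assert not res.valid

    def test_small_height_difference_accepted(self, scene, scenery, config):
        # ~5% feature asymmetry stays inside the 15% symmetry tolerance
        frame, _ = render_cow_frame(scene, hf_shape(asymmetry=0.05))
        seg = sort_frame(frame, scenery, config.segment)
        res = run_roi(seg, "HF", config.roi)
        assert res.valid


class TestValidateAnatomy:
    def _symmetric_result(self):
        return RoiResult(
            code_triple=(1, 1, 1),
            tail=(20, 50), backbone=(0.0, 50.0),
            tuberosity_left=(30, 30), tuberosity_right=(30, 70),
            dish_left=(26, 40), dish_right=(26, 60),
            hip_left=(80, 25), hip_right=(80, 75),
        )

    def _flat_seg(self, depth_left=1.2, depth_right=1.2):
        mask = np.ones((100, 101), dtype=bool)
        depth = np.full((100, 101), 1.2)
        depth[:, :50] = depth_left
        depth[:, 51:] = depth_right
        return make_seg(mask, depth)

    def test_symmetric_landmarks_valid(self, config):
        assert validate_anatomy(self._symmetric_result(), self._flat_seg(), config.roi)

    def test_depth_difference_beyond_tolerance_invalid(self, config):
        seg = self._flat_seg(depth_left=1.20, depth_right=1.25)
        assert not validate_anatomy(self._symmetric_result(), seg, config.roi)

    def test_distance_asymmetry_beyond_tolerance_invalid(self, config):
        res = self._symmetric_result()
        res.tuberosity_left = (30, 42)  # much closer to the tail
        assert not validate_anatomy(res, self._flat_seg(), config.roi)


class TestRunRoi:
    @pytest.mark.parametrize("breed,seg_fix,render_fix", [
        ("HF", "hf_seg", "hf_render"), ("FV", "fv_seg", "fv_render"),
    ])
    def test_valid_frame_yields_all_landmarks(
        self, breed, seg_fix, render_fix, request, config
    ):
        seg = request.getfixturevalue(seg_fix)
        _, gt = request.getfixturevalue(render_fix)
        res = run_roi(seg, breed, config.roi)
        assert res.valid
        assert res.code_triple == (1, 1, 1)
        assert len(res.landmarks) == 7
        assert res.backbone is not None
        errs = landmark_errors(res, gt)
        assert max(errs.values()) <= 2, errs

    def test_border_touch_yields_code_without_landmarks(
        self, scene, scenery, config
    ):
        frame, _ = render_cow_frame(scene, hf_shape(lateral_drift=-54.0))
        seg = sort_frame(frame, scenery, config.segment)
        res = run_roi(seg, "HF", config.roi)
        assert res.code_triple[1] == 0 and res.code_triple[2] == 1
        assert not res.valid
        assert res.landmarks == {}

    def test_landmark_ordering_invariants(self, hf_seg, fv_seg, config):
        for seg, breed in ((hf_seg, "HF"), (fv_seg, "FV")):
            res = run_roi(seg, breed, config.roi)
            # dishes strictly between tail and tuberosities in boundary order
            assert res.tuberosity_left[1] < res.dish_left[1] < res.tail[1]
            assert res.tail[1] < res.dish_right[1] < res.tuberosity_right[1]
            # hips forward (larger row) of the tuberosities
            assert res.hip_left[0] > res.tuberosity_left[0]
            assert res.hip_right[0] > res.tuberosity_right[0]

    def test_only_full_code_produces_landmarks(self, scene, scenery, config):
        frames = [
            render_cow_frame(scene, hf_shape(lateral_drift=-54.0))[0],
            render_cow_frame(scene, hf_shape(tail_overhang=6))[0],
            render_cow_frame(scene, hf_shape())[0],
        ]
        for frame in frames:
            seg = sort_frame(frame, scenery, config.segment)
            res = run_roi(seg, "HF", config.roi)
            if res.code_triple != (1, 1, 1):
                assert res.landmarks == {}
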