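"""Sheath, guide-wire, lumen, strut segmentation and malapposition scoring."""

import numpy as np
import pytest
from skimage import filters

from ivoct import (
    LumenContour,
    SegmentationParams,
    StrutDetection,
    classify_malapposition,
    cluster_struts,
    detect_guidewire_alines,
    detect_sheath,
    detect_struts,
    evaluate_detection,
    match_detections,
    refine_guidewire,
    score_phantom,
    segment_lumen,
)
from ivoct import stent_region as rg
from ivoct.segment import MALAPPOSITION_THRESHOLD_PX, mask_sheath


class TestSheath:
    def test_phantom_sheath_found(self, noisy_phantom):
        stack, truth = noisy_phantom
        for f in (0, 10, 19):
            found = detect_sheath(stack[f])
            assert abs(found - truth.sheath_depth_px[f]) <= 1

    def test_constant_image_tie_goes_to_smallest_row(self):
        assert detect_sheath(np.full((50, 8), 9.0)) == 0

    def test_matches_row_mean_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8))
        band = (0, 8)
        means = [img[r].mean() for r in range(8)]
        assert detect_sheath(img, band) == int(np.argmax(means))


class TestGuidewireAlines:
    def test_otsu_splits_two_level_image(self):
        img = np.array([[10.0] * 8, [200.0] * 8] * 4)
        thr = filters.threshold_otsu(img)
        assert 10 < thr < 200

    def test_phantom_candidates_cover_truth(self, noisy_phantom):
        stack, truth = noisy_phantom
        cands = detect_guidewire_alines(rg.build_enface(stack))
        for f in (0, 10, 19):
            t0, t1 = truth.guidewire_alines[f]
            assert cands[f] is not None
            c0, c1 = cands[f]
            # candidate interval covers most of the true shadow
            overlap = max(0, min(c1, t1) - max(c0, t0) + 1)
            assert overlap >= 0.8 * (t1 - t0 + 1)

    def test_uniform_enface_flags_absent(self):
        cands = detect_guidewire_alines(np.full((64, 5), 30.0))
        assert cands == [None] * 5


class TestRefineGuidewire:
    def test_phantom_centroid_close_to_truth(self, noisy_phantom):
        stack, truth = noisy_phantom
        f = 10
        sheath = detect_sheath(stack[f])
        cand = tuple(truth.guidewire_alines[f])
        seg = refine_guidewire(mask_sheath(stack[f], sheath), cand)
        assert seg.interval is not None
        cols = np.nonzero(seg.mask.any(axis=0))[0]
        centroid = cols.mean()
        truth_center = truth.guidewire_alines[f].mean()
        assert abs(centroid - truth_center) <= 3

    def test_narrow_bridge_to_noise_is_severed(self):
        """A wire blob connected to a noise blob through a 1-px bridge keeps
        only the wire component."""
        img = np.zeros((60, 120))
        img[30:40, 40:60] = 200.0  # guide-wire blob
        img[34, 60:80] = 200.0  # 1-px bridge
        img[28:44, 80:100] = 200.0  # noise blob, larger but outside candidate
        seg = refine_guidewire(img, candidate=(42, 58), pad_alines=10)
        assert seg.interval is not None
        cols = np.nonzero(seg.mask.any(axis=0))[0]
        assert cols.min() >= 40 and cols.max() < 62

    def test_all_zero_roi_flags_absent(self):
        seg = refine_guidewire(np.zeros((40, 80)), candidate=(30, 40))
        assert seg.interval is None and seg.mask is None


class TestLumen:
    def test_phantom_contour_error_le_2px_outside_shadows(self, clean_phantom):
        stack, truth = clean_phantom
        f = 10
        sheath = detect_sheath(stack[f])
        lum = segment_lumen(stack[f], sheath, tuple(truth.guidewire_alines[f]))
        valid = ~lum.interpolated
        err = np.abs(lum.surface_depth_px - truth.lumen_contour[f])
        assert err[valid].max() <= 2

    def test_centered_phantom_contour_constant(self, phantom_cfg):
        from ivoct import make_phantom_polar_pullback

        stack, truth = make_phantom_polar_pullback(
            phantom_cfg, catheter_offset_px=(0.0, 0.0), stent_frames=None, noise_sd=0.0, seed=0
        )
        lum = segment_lumen(stack[0], detect_sheath(stack[0]), tuple(truth.guidewire_alines[0]))
        valid = ~lum.interpolated
        assert np.ptp(lum.surface_depth_px[valid]) <= 1

    def test_all_dark_frame_unsegmentable(self):
        with pytest.raises(ValueError, match="unsegmentable"):
            segment_lumen(np.zeros((100, 64)), sheath_row=5, guidewire=None)


class TestDetectStruts:
    def test_phantom_struts_found_at_truth_depth(self, clean_phantom, clean_phantom_segmentation):
        stack, truth = clean_phantom
        by_frame = {s.frame: s for s in clean_phantom_segmentation}
        hits = total = 0
        for t in truth.struts:
            total += 1
            seg = by_frame[t.frame]
            for d in seg.struts:
                if abs(d.aline - t.aline) <= 2 and abs(d.depth_px - t.depth_px) <= 1.5:
                    hits += 1
                    break
        assert hits >= 0.95 * total

    def test_clean_wall_yields_no_candidates(self, phantom_cfg):
        from ivoct import make_phantom_polar_pullback

        stack, truth = make_phantom_polar_pullback(
            phantom_cfg, stent_frames=None, noise_sd=0.0, seed=1
        )
        f = 0
        lum = segment_lumen(stack[f], detect_sheath(stack[f]), tuple(truth.guidewire_alines[f]))
        cands = detect_struts(stack[f], lum, tuple(truth.guidewire_alines[f]))
        assert cands == []

    def test_bright_spot_without_shadow_rejected(self):
        img = np.zeros((200, 32))
        img[100:180, :] = 160.0  # wall
        img[95:99, 10:13] = 255.0  # bright spot sitting on a bright wall: no shadow
        lum = LumenContour(np.full(32, 100.0), np.zeros(32, bool))
        cands = detect_struts(img, lum, None)
        assert all(abs(a - 11) > 2 for a, _ in cands)


class TestClusterStruts:
    def test_contiguous_run_becomes_one_strut(self):
        cands = [(100, 50.0), (101, 51.0), (102, 50.0), (103, 52.0), (104, 51.0)]
        out = cluster_struts(cands)
        assert len(out) == 1
        assert out[0].aline == 102

    def test_separated_runs_become_two_struts(self):
        cands = [(10, 50.0), (11, 50.0), (21, 60.0), (22, 61.0)]
        out = cluster_struts(cands)
        assert len(out) == 2

    def test_singletons_discarded(self):
        assert cluster_struts([(5, 10.0)]) == []

    def test_matches_transitive_closure_oracle(self):
        def oracle(cands, gap=1, ddiff=5, min_size=2):
            groups = [{i} for i in range(len(cands))]
            merged = True
            while merged:
                merged = False
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        if any(
                            abs(cands[a][0] - cands[b][0]) - 1 <= gap
                            and abs(cands[a][1] - cands[b][1]) <= ddiff
                            for a in groups[i]
                            for b in groups[j]
                        ):
                            groups[i] |= groups[j]
                            del groups[j]
                            merged = True
                            break
                    if merged:
                        break
            result = set()
            for g in groups:
                if len(g) < min_size:
                    continue
                alines = sorted(cands[i][0] for i in g)
                depths = sorted(cands[i][1] for i in g)
                result.add((int(np.median(alines)), float(np.median(depths))))
            return result

        rng = np.random.default_rng(4)
        for _ in range(25):
            alines = sorted(rng.choice(40, size=rng.integers(2, 12), replace=False))
            cands = [(int(a), float(rng.integers(0, 30))) for a in alines]
            got = {(s.aline, s.depth_px) for s in cluster_struts(cands)}
            assert got == oracle(cands)


class TestMalapposition:
    def test_strict_threshold_boundary(self):
        lum = LumenContour(np.full(4, 100.0), np.zeros(4, bool))
        struts = [
            StrutDetection(frame=0, aline=0, depth_px=100.0 - 16),
            StrutDetection(frame=0, aline=1, depth_px=100.0 - 15),
            StrutDetection(frame=0, aline=2, depth_px=100.0),
        ]
        out = classify_malapposition(struts, lum, threshold_px=15)
        assert [s.malapposed for s in out] == [True, False, False]
        assert out[2].distance_px == 0.0

    def test_threshold_from_pixel_pitch(self):
        # 100 um strut-plus-polymer thickness at 6.5 um axial pitch
        assert int(100 // 6.5) == MALAPPOSITION_THRESHOLD_PX == 15

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        lum = LumenContour(np.full(50, 120.0), np.zeros(50, bool))
        struts = [
            StrutDetection(frame=0, aline=a, depth_px=120.0 - rng.integers(0, 40))
            for a in range(50)
        ]
        counts = []
        for thr in (5, 10, 15, 20, 30):
            out = classify_malapposition(struts, lum, threshold_px=thr)
            counts.append(sum(s.malapposed for s in out))
        assert counts == sorted(counts, reverse=True)


class TestEvaluateDetection:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,sens,spec",
        [
            (2473, 179, None, 329, 88.3, None),
            (142, 122, 2201, 8, 94.7, 94.7),
            (1, 0, 1, 0, 100.0, 100.0),
        ],
    )
    def test_reported_counts(self, tp, fp, tn, fn, sens, spec):
        assert evaluate_detection(tp, fp, tn, fn) == (sens, spec)

    def test_undefined_sensitivity(self):
        assert evaluate_detection(0, 3, 5, 0) == (None, 62.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detection(-1, 0, 0, 0)


class TestMatching:
    def test_identical_lists_match_perfectly(self):
        preds = [StrutDetection(frame=0, aline=a, depth_px=50.0) for a in (10, 30, 60)]
        tp, fp, fn, _ = match_detections(preds, preds)
        assert (tp, fp, fn) == (3, 0, 0)

    def test_extra_prediction_is_false_positive(self):
        truth = [StrutDetection(frame=0, aline=10, depth_px=50.0)]
        preds = truth + [StrutDetection(frame=0, aline=200, depth_px=50.0)]
        tp, fp, fn, _ = match_detections(preds, truth)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_perturbation_within_tolerance_all_matched(self):
        rng = np.random.default_rng(2)
        truth = [
            StrutDetection(frame=f, aline=20 + 30 * i, depth_px=100.0)
            for f in range(3)
            for i in range(4)
        ]
        preds = [
            StrutDetection(
                frame=t.frame,
                aline=t.aline + int(rng.integers(-3, 4)),
                depth_px=t.depth_px + float(rng.integers(-3, 4)),
            )
            for t in truth
        ]
        tp, fp, fn, _ = match_detections(preds, truth, tol_alines=5, tol_px=5)
        assert (tp, fp, fn) == (len(truth), 0, 0)


class TestPhantomRecovery:
    def test_zero_noise_apposition_labels_all_correct(
        self, clean_phantom, clean_phantom_segmentation
    ):
        stack, truth = clean_phantom
        preds = [s for seg in clean_phantom_segmentation for s in seg.struts]
        scores = score_phantom(preds, truth.struts)
        m = scores["malapposition"]
        assert m["fp"] == 0 and m["fn"] == 0
        assert m["tp"] + m["tn"] > 0

    def test_default_noise_sensitivity_thresholds(
        self, noisy_phantom, noisy_phantom_segmentation
    ):
        stack, truth = noisy_phantom
        preds = [s for seg in noisy_phantom_segmentation for s in seg.struts]
        scores = score_phantom(preds, truth.struts)
        assert scores["strut"]["sensitivity_pct"] >= 90.0
        assert scores["malapposition"]["sensitivity_pct"] >= 90.0
        assert scores["malapposition"]["specificity_pct"] >= 90.0
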