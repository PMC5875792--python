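"""ROI validation, segmentation, time-course extraction, cell matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from facile import (
    CellRecord,
    ImagingSession,
    RoiMask,
    auto_segment,
    extract_timecourses,
    f1_analysis,
    match_cells,
    pixelwise_maps,
    validate_mask,
)
from facile.fourier_maps import ActivityMaps

FR = 25.0


class TestValidateMask:
    def test_relabels_to_consecutive_ids(self):
        img = np.zeros((8, 8), dtype=int)
        img[0:3, 0:3] = 3
        img[5:8, 5:8] = 7
        out = validate_mask(RoiMask(img))
        assert list(out.roi_ids) == [1, 2]
        assert out.relabel_map == {3: 1, 7: 2}

    def test_drops_undersized_rois(self):
        img = np.zeros((8, 8), dtype=int)
        img[0, 0:2] = 1  # 2 px < min 4
        img[4:7, 4:7] = 2
        out = validate_mask(RoiMask(img), min_area=4)
        assert list(out.roi_ids) == [1]
        assert out.relabel_map == {2: 1}

    def test_empty_mask_ok(self):
        out = validate_mask(RoiMask(np.zeros((8, 8), dtype=int)))
        assert out.roi_ids.size == 0

    def test_shape_mismatch_rejected(self):
        sess = ImagingSession(np.zeros((2, 4, 4)), frame_rate=FR)
        with pytest.raises(ValueError, match="mask shape"):
            validate_mask(RoiMask(np.zeros((8, 8), dtype=int)), sess)


class TestExtractTimecourses:
    def test_single_pixel_roi_equals_pixel_trace(self):
        stack = np.random.default_rng(0).normal(size=(50, 6, 6))
        mask = np.zeros((6, 6), dtype=int)
        mask[2, 3] = 1
        recs = extract_timecourses(ImagingSession(stack, frame_rate=FR), RoiMask(mask))
        np.testing.assert_array_equal(recs[0].timecourse, stack[:, 2, 3])
        assert recs[0].centroid == (3.0, 2.0)
        assert recs[0].n_pixels == 1

    def test_opposite_traces_cancel(self):
        t = np.random.default_rng(1).normal(size=50)
        stack = np.zeros((50, 2, 2))
        stack[:, 0, 0] = t
        stack[:, 0, 1] = -t
        mask = np.zeros((2, 2), dtype=int)
        mask[0, :] = 1
        recs = extract_timecourses(ImagingSession(stack, frame_rate=FR), RoiMask(mask))
        np.testing.assert_allclose(recs[0].timecourse, 0.0, atol=1e-15)

    def test_matches_brute_force_loop(self):
        stack = np.random.default_rng(2).normal(100, 10, (40, 10, 10))
        mask = np.zeros((10, 10), dtype=int)
        mask[1:5, 2:6] = 1
        mask[6:9, 6:9] = 2
        recs = extract_timecourses(ImagingSession(stack, frame_rate=FR), RoiMask(mask))
        for rec in recs:
            expected = np.zeros(40)
            npx = 0
            for y in range(10):
                for x in range(10):
                    if mask[y, x] == rec.cell_id:
                        expected += stack[:, y, x]
                        npx += 1
            np.testing.assert_allclose(rec.timecourse, expected / npx, rtol=1e-12)

    def test_roi_mean_f1_equals_complex_averaged_pixel_f1(self, stim):
        # DFT linearity: F1 of the ROI-mean trace equals the complex mean of
        # per-pixel F1 vectors (noiseless input)
        t = np.arange(250) / FR
        stack = np.empty((250, 3, 3))
        rng = np.random.default_rng(3)
        for y in range(3):
            for x in range(3):
                a, ph = rng.uniform(0.1, 0.5), rng.uniform(-np.pi, np.pi)
                stack[:, y, x] = 1.0 + a * np.cos(2 * np.pi * stim.frequency * t + ph)
        mask = np.ones((3, 3), dtype=int)
        rec = extract_timecourses(ImagingSession(stack, frame_rate=FR), RoiMask(mask))[0]
        _, f1_roi, ph_roi = f1_analysis(rec.timecourse, FR, stim)
        zs = []
        for y in range(3):
            for x in range(3):
                _, f1, ph = f1_analysis(stack[:, y, x], FR, stim)
                zs.append(f1 * np.exp(1j * ph))
        z_mean = np.mean(zs)
        assert f1_roi == pytest.approx(abs(z_mean), rel=1e-9)
        assert ph_roi == pytest.approx(np.angle(z_mean), abs=1e-9)


class TestAutoSegment:
    def test_blank_maps_give_empty_mask(self):
        zero = np.zeros((32, 32))
        maps = ActivityMaps(
            sum_image=zero, f0_map=zero, f1_amp_map=zero,
            f1_phase_map=zero, norm_map=zero, valid_mask=zero > -1,
        )
        assert auto_segment(maps).roi_ids.size == 0

    def test_recovers_well_separated_cells(self, separated_field_video, stim):
        session, truth = separated_field_video
        mask = auto_segment(pixelwise_maps(session, stim))
        found = {
            k: (
                np.mean(np.nonzero(mask.label_image == k)[1]),
                np.mean(np.nonzero(mask.label_image == k)[0]),
            )
            for k in mask.roi_ids
        }
        claimed = set()
        matched = 0
        for c in truth.cells:
            best, bd = None, np.inf
            for k, (fx, fy) in found.items():
                if k in claimed:
                    continue
                d = np.hypot(fx - c.centroid[0], fy - c.centroid[1])
                if d < bd:
                    bd, best = d, k
            if best is not None and bd <= c.radius:
                claimed.add(best)
                matched += 1
        assert matched >= 18
        assert len(found) - len(claimed) <= 2

    def test_antiphase_pair_split_by_phase_rule(self, stim):
        from facile.synthetic_imaging import (
            CellTruth,
            FieldSpec,
            GroundTruth,
            _render_label_mask,
            render_video,
        )

        cells = [
            CellTruth(1, (30.0, 32.0), 7.0, "ON", 0.6, 100.0),
            CellTruth(2, (42.0, 32.0), 7.0, "OFF", 0.6, 100.0),
        ]
        gt = GroundTruth(
            cells=cells,
            label_mask=_render_label_mask(cells, 64, 80),
            seed=0,
            field_spec=FieldSpec(width_px=80, height_px=64, n_cells=2),
        )
        session, gt = render_video(gt, stim, n_frames=375, noise_sd=1.0, seed=5)
        # min_distance larger than the pair separation: the intensity cue
        # alone would fuse them into one candidate
        mask = auto_segment(pixelwise_maps(session, stim), min_distance=30)
        assert mask.roi_ids.size == 2
        xs = sorted(
            np.mean(np.nonzero(mask.label_image == k)[1]) for k in mask.roi_ids
        )
        assert xs[0] == pytest.approx(30.0, abs=3)
        assert xs[1] == pytest.approx(42.0, abs=3)


def _records_at(points):
    return [
        CellRecord(cell_id=i + 1, centroid=(float(x), float(y)), n_pixels=1,
                   timecourse=np.zeros(1))
        for i, (x, y) in enumerate(points)
    ]


class TestMatchCells:
    def test_identical_sets_match_perfectly(self):
        pts = [(5, 5), (20, 8), (11, 30)]
        tracks = match_cells(_records_at(pts), _records_at(pts))
        assert len(tracks) == 3
        assert all(t.match_distance == 0 for t in tracks)
        assert all(t.session_a_id == t.session_b_id for t in tracks)

    def test_uniform_transform_applied(self):
        pts = [(5, 5), (20, 8), (11, 30)]
        shifted = [(x - 3, y + 2) for x, y in pts]
        tracks = match_cells(
            _records_at(pts), _records_at(shifted), session_transform=(3, -2)
        )
        assert len(tracks) == 3
        assert all(t.match_distance < 1e-9 for t in tracks)

    def test_one_to_one_and_distance_bounded(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 100, (25, 2))
        b = rng.uniform(0, 100, (25, 2))
        tracks = match_cells(_records_at(a), _records_at(b), max_dist_um=5)
        ids_a = [t.session_a_id for t in tracks]
        ids_b = [t.session_b_id for t in tracks]
        assert len(set(ids_a)) == len(ids_a)
        assert len(set(ids_b)) == len(ids_b)
        assert all(t.match_distance <= 5 for t in tracks)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 60, (15, 2))
        b = a + rng.normal(0, 1, (15, 2))
        fwd = {(t.session_a_id, t.session_b_id) for t in match_cells(_records_at(a), _records_at(b))}
        rev = {(t.session_b_id, t.session_a_id) for t in match_cells(_records_at(b), _records_at(a))}
        assert fwd == rev

    def test_agrees_with_optimal_assignment(self):
        # known permutation + 1 px jitter on 30 cells; oracle: exhaustive
        # optimal assignment (Hungarian). Centroids carry soma-mosaic
        # spacing: two cells cannot sit closer than a soma diameter.
        rng = np.random.default_rng(6)
        pts = []
        while len(pts) < 30:
            p = rng.uniform(0, 150, 2)
            if all(np.hypot(*(p - q)) >= 10 for q in pts):
                pts.append(p)
        a = np.array(pts)
        perm = rng.permutation(30)
        b = a[perm] + rng.normal(0, 1.0, (30, 2))
        recs_a, recs_b = _records_at(a), _records_at(b)
        tracks = match_cells(recs_a, recs_b, max_dist_um=5)
        dist = np.hypot(
            a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1]
        )
        ri, ci = linear_sum_assignment(dist)
        optimal = {
            (int(r) + 1, int(c) + 1) for r, c in zip(ri, ci) if dist[r, c] <= 5
        }
        greedy = {(t.session_a_id, t.session_b_id) for t in tracks}
        agreement = len(greedy & optimal) / max(len(optimal), 1)
        assert agreement >= 0.95
        # and the greedy pairs must recover the generating permutation
        correct = sum((perm[t.session_b_id - 1] + 1) == t.session_a_id for t in tracks)
        assert correct / 30 >= 0.95
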