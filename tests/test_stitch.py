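import numpy as np
import pytest

from blurscan.errors import (InsufficientInputError, NoScanLinesError,
                             SizeError)
from blurscan.scansim import BlurKernel, motion_blur
from blurscan.stitch import (Mosaic, ScanLineSegment, SquareWaveModel,
                             assemble_mosaic, classify_motion,
                             detect_scan_lines, frame_correlations,
                             stitch_frames)


def square_series(high: float, low: float, n_high: int, n_low: int,
                  reps: int) -> np.ndarray:
    return np.tile(np.r_[np.full(n_high, high), np.full(n_low, low)], reps)


class TestFrameCorrelations:
    def test_identical_frames(self, rng):
        f = rng.random((64, 64, 3))
        series = frame_correlations([f, f.copy()])
        assert series[0] == pytest.approx(1.0)

    def test_independent_noise(self, rng):
        a, b = rng.random((128, 128)), rng.random((128, 128))
        series = frame_correlations([a, b])
        assert abs(series[0]) < 0.1

    def test_too_few_frames(self, rng):
        with pytest.raises(InsufficientInputError):
            frame_correlations([rng.random((8, 8))])

    def test_constant_pair_defined_high(self):
        f = np.full((32, 32), 0.7)
        assert frame_correlations([f, f + 0.0])[0] == 1.0

    def test_static_runs_correlate_higher(self, small_scan):
        series = frame_correlations(small_scan.frames)
        moving = small_scan.trace.moving
        static_pairs = ~moving[:-1] & ~moving[1:]
        moving_pairs = moving[:-1] & moving[1:]
        assert series[static_pairs].mean() > series[moving_pairs].mean()


class TestClassifyMotion:
    def test_clean_square_wave_recovered(self):
        series = square_series(0.99, 0.1, 20, 5, 4)
        model = classify_motion(series)
        assert model.line_period_frames == 25
        assert model.pause_frames == 20
        expected = square_series(1, 0, 20, 5, 4).astype(bool)
        assert np.array_equal(model.series_static, expected)

    def test_featureless_frames_repaired(self):
        series = square_series(0.99, 0.1, 20, 5, 4)
        # a featureless patch makes 3 moving frames look static
        low_idx = np.nonzero(series < 0.5)[0][:3]
        corrupted = series.copy()
        corrupted[low_idx] = 0.98
        raw = classify_motion(corrupted, fit=False)
        fitted = classify_motion(corrupted, fit=True)
        truth = square_series(1, 0, 20, 5, 4).astype(bool)
        assert not np.array_equal(raw.series_static, truth)
        assert np.array_equal(fitted.series_static, truth)

    def test_constant_series_error(self):
        with pytest.raises(NoScanLinesError):
            classify_motion(np.full(100, 0.9))

    def test_frame_labels_from_series(self):
        # frames: SSSMMSSS -> series high for pairs inside static runs
        series = np.array([0.99, 0.99, 0.2, 0.2, 0.2, 0.99, 0.99])
        model = classify_motion(series, fit=False)
        assert list(model.frame_moving) == [False, False, False, True,
                                            True, False, False, False]

    def test_recovers_true_labels_on_scan(self, small_scan):
        series = frame_correlations(small_scan.frames)
        model = classify_motion(series)
        assert np.array_equal(model.frame_moving, small_scan.trace.moving)


class TestDetectScanLines:
    def test_two_runs(self):
        model = SquareWaveModel.from_frame_labels(
            [True, True, False, False, True, True])
        segs = detect_scan_lines(model, "+x")
        assert len(segs) == 2
        assert [s.direction for s in segs] == ["+x", "-x"]
        assert (segs[0].start_frame, segs[0].end_frame) == (0, 2)

    def test_single_run(self):
        model = SquareWaveModel.from_frame_labels([False, True, True, False])
        segs = detect_scan_lines(model)
        assert len(segs) == 1

    def test_segments_match_trace_rows(self, small_scan):
        series = frame_correlations(small_scan.frames)
        model = classify_motion(series)
        segs = detect_scan_lines(model, "+x")
        assert len(segs) == small_scan.trace.n_rows

    def test_no_moving_run(self):
        model = SquareWaveModel.from_frame_labels([False, False, False])
        with pytest.raises(NoScanLinesError):
            detect_scan_lines(model)


class TestAssembleMosaic:
    def test_single_frame_identity(self, rng):
        frame = rng.random((16, 24, 3)).astype(np.float32)
        seg = [ScanLineSegment(0, 1, 0, "+x")]
        mosaic = assemble_mosaic([frame], seg, per_frame_advance_px=8,
                                 row_step_px=8)
        assert np.allclose(mosaic.raster, frame)

    def test_size_limit(self, rng):
        frame = rng.random((16, 24, 3)).astype(np.float32)
        seg = [ScanLineSegment(0, 1, 0, "+x")]
        with pytest.raises(SizeError):
            assemble_mosaic([frame], seg, per_frame_advance_px=8,
                            row_step_px=8, max_px=8)

    def test_round_trip_rmse(self, small_slide, scan_config, small_scan):
        slide, manifest = small_slide
        mosaic, segments, _ = stitch_frames(small_scan.frames, scan_config)
        h, w = slide.rgb.shape[:2]
        step = int(scan_config.effective_row_step_um)
        fh = scan_config.fov_px[1]
        gt = np.empty_like(slide.rgb, dtype=np.float64)
        blurred = {d: motion_blur(slide.rgb.astype(np.float64),
                                  BlurKernel.from_config(scan_config, d))
                   for d in ("+x", "-x")}
        for r, seg in enumerate(segments):
            y0 = r * step
            y1 = h if r == len(segments) - 1 else min(h, (r + 1) * step)
            gt[y0:y1] = blurred[seg.direction][y0:y1]
        rmse = np.sqrt(np.mean((mosaic.raster[:h, :w] - gt) ** 2))
        assert rmse < 0.02

    def test_components_preserved(self, small_slide, scan_config, small_scan):
        from blurscan.cores import count_tissue_components
        _, manifest = small_slide
        mosaic, _, _ = stitch_frames(small_scan.frames, scan_config)
        assert count_tissue_components(mosaic) == manifest.n_cores

    def test_centroid_round_trip(self, small_slide, scan_config, small_scan):
        from skimage.measure import label as cc_label, regionprops
        from blurscan.cores import tissue_mask
        slide, manifest = small_slide
        mosaic, _, _ = stitch_frames(small_scan.frames, scan_config)
        props = regionprops(cc_label(tissue_mask(mosaic.raster)))
        found = sorted((p.centroid[1], p.centroid[0]) for p in props)
        truth = sorted(zip(manifest.cores.center_x_um,
                           manifest.cores.center_y_um))
        blur_px = BlurKernel.from_config(scan_config).width_px
        for (fx, fy), (tx, ty) in zip(found, truth):
            assert np.hypot(fx - tx, fy - ty) < blur_px

    def test_blur_direction_alternates(self, scan_config):
        """Directional smear of a spot phantom alternates row to row.

        A blank slide defeats correlation-based motion classification by
        design, so the motion model here comes from the ground-truth trace
        and only the placement/blur-direction behaviour is under test.
        """
        from blurscan.scansim import plan_zigzag, simulate_scan
        from blurscan.synthslide import SlideImage
        # spots placed in row-exclusive bands (row r owns [r*96, (r+1)*96)
        # after last-wins overwriting, fov height 120, step 96)
        rgb = np.ones((340, 640, 3), dtype=np.float32)
        rgb[40:50, 315:325] = 0.0    # scan row 0 only
        rgb[150:160, 315:325] = 0.0  # scan row 1 only
        slide = SlideImage(rgb=rgb)
        trace = plan_zigzag((640.0, 340.0), scan_config)
        seq = simulate_scan(slide, trace, scan_config)
        model = SquareWaveModel.from_frame_labels(trace.moving)
        segments = detect_scan_lines(model, "+x")
        mosaic = assemble_mosaic(
            seq.frames, segments,
            per_frame_advance_px=scan_config.advance_px_per_frame,
            row_step_px=scan_config.effective_row_step_um)
        # a '+x' kernel spreads mass to x <= source; '-x' to x >= source
        dark0 = np.nonzero(mosaic.raster[40:50, :, 0].min(axis=0) < 0.9)[0]
        dark1 = np.nonzero(mosaic.raster[150:160, :, 0].min(axis=0) < 0.9)[0]
        assert segments[0].direction != segments[1].direction
        assert (dark0.mean() - 320) * (dark1.mean() - 320) < 0

    def test_average_blend_matches_last_within_rows(self, small_scan,
                                                    scan_config):
        last, segs, _ = stitch_frames(small_scan.frames, scan_config,
                                      blend="last")
        avg, _, _ = stitch_frames(small_scan.frames, scan_config,
                                  blend="average")
        assert last.raster.shape == avg.raster.shape
        # same-direction frames agree exactly where they overlap, so the two
        # blend rules can differ only in the cross-row overlap bands
        step = int(scan_config.effective_row_step_um)
        fh = scan_config.fov_px[1]
        for r in range(len(segs)):
            y0 = r * step + (fh - step) if r else 0
            y1 = (r + 1) * step
            band = slice(y0, y1)
            assert np.max(np.abs(last.raster[band] - avg.raster[band])) < 1e-5

    def test_mosaic_save_load(self, small_scan, scan_config, tmp_path):
        mosaic, _, _ = stitch_frames(small_scan.frames, scan_config)
        mosaic.save(tmp_path / "mosaic.tiff")
        back = Mosaic.load(tmp_path / "mosaic.tiff")
        assert np.max(np.abs(back.raster - mosaic.raster)) < 1 / 255 + 1e-6
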