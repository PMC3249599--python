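"""Fan geometry: polar coordinates, fan masks, ROI extraction, frame/table IO."""

import numpy as np
import pandas as pd
import pytest

from ustex import io as uio
from ustex.geometry import (
    DEFAULT_PIXEL_SPACING_CM,
    PolarCoord,
    RoiBoundsError,
    UltrasoundFrame,
    cartesian_to_polar,
    compute_fan_mask,
    extract_roi_patch,
    make_roi_record,
    polar_to_cartesian,
)


def wide_frame(pixels=None, aperture=80.0):
    """A frame whose fan covers most of the image, for window tests."""
    if pixels is None:
        pixels = np.full((200, 200), 120, dtype=np.uint8)
    return UltrasoundFrame(
        pixels=pixels,
        source_xy=(100.0, -5.0),
        aperture_deg=aperture,
        depth_cm=50.0,
        probe_radius_cm=0.0,
    )


class TestPolarConversion:
    def test_on_axis_point(self):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        sx, sy = frame.source_xy
        rho, theta, degenerate = cartesian_to_polar((sx, sy + 100), frame)
        assert rho == pytest.approx(100 * DEFAULT_PIXEL_SPACING_CM)
        assert rho == pytest.approx(4.09375)
        assert theta == pytest.approx(0.0)
        assert not degenerate

    def test_source_point_is_degenerate(self):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        assert cartesian_to_polar(frame.source_xy, frame) == PolarCoord(0.0, 0.0, True)

    def test_sign_convention(self):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        sx, sy = frame.source_xy
        _, theta_left, _ = cartesian_to_polar((sx - 50, sy + 100), frame)
        _, theta_right, _ = cartesian_to_polar((sx + 50, sy + 100), frame)
        assert theta_left < 0 < theta_right

    def test_matches_trigonometric_oracle(self, rng):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        sx, sy = frame.source_xy
        for _ in range(200):
            x = rng.uniform(0, 499)
            y = rng.uniform(0, 399)
            rho, theta, _ = cartesian_to_polar((x, y), frame)
            # independent recomputation: translate then rotate explicitly
            dx, dy = x - sx, y - sy
            assert rho == pytest.approx(
                np.sqrt(dx**2 + dy**2) * frame.pixel_spacing_cm, abs=1e-12
            )
            assert theta == pytest.approx(np.degrees(np.arctan2(dx, dy)), abs=1e-12)

    def test_round_trip_within_half_pixel(self, rng):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        mask = frame.fan_mask
        rows, cols = np.where(mask)
        idx = rng.choice(len(rows), size=1000)
        for r, c in zip(rows[idx], cols[idx]):
            rho, theta, _ = cartesian_to_polar((c, r), frame)
            x, y = polar_to_cartesian(rho, theta, frame)
            assert abs(x - c) < 0.5 and abs(y - r) < 0.5


class TestFanMask:
    def test_zero_aperture_is_single_ray(self):
        mask = compute_fan_mask((5.0, -2.0), 0.0, 100.0, (20, 11), 0.1)
        rows, cols = np.where(mask)
        assert set(cols) == {5}
        assert len(rows) == 20

    def test_aperture_bounds(self):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        sx, sy = frame.source_xy
        inside = polar_to_cartesian(8.0, 0.0, frame)
        outside = polar_to_cartesian(8.0, frame.aperture_deg + 1.0, frame)
        mask = frame.fan_mask
        assert mask[int(round(inside[1])), int(round(inside[0]))]
        assert not mask[int(round(outside[1])), int(round(outside[0]))]

    def test_monotone_in_aperture(self):
        shape = (400, 500)
        src = (249.5, -60.0)
        prev = compute_fan_mask(src, 5.0, 16.0, shape, DEFAULT_PIXEL_SPACING_CM, 2.46)
        for aperture in (10.0, 20.0, 30.0):
            cur = compute_fan_mask(
                src, aperture, 16.0, shape, DEFAULT_PIXEL_SPACING_CM, 2.46
            )
            assert (prev & ~cur).sum() == 0
            prev = cur

    def test_area_matches_annular_sector(self):
        # fully interior fan: no clipping by the image borders
        spacing = 0.05
        shape = (380, 500)
        src = (249.5, -20.0)
        aperture, depth, probe = 25.0, 15.0, 2.0
        mask = compute_fan_mask(src, aperture, depth, shape, spacing, probe)
        sector = (2 * aperture / 360.0) * np.pi * (depth**2 - probe**2)
        expected_px = sector / spacing**2
        assert mask.sum() == pytest.approx(expected_px, rel=0.02)


class TestExtractRoi:
    def test_identity_slice(self, rng):
        pixels = rng.integers(0, 256, (200, 200)).astype(np.uint8)
        frame = wide_frame(pixels)
        patch = extract_roi_patch(frame, (100, 100))
        assert patch.shape == (64, 64)
        np.testing.assert_array_equal(patch, pixels[68:132, 68:132])

    def test_boundary_rejection_names_bound(self):
        frame = wide_frame()
        with pytest.raises(RoiBoundsError, match="top"):
            extract_roi_patch(frame, (100, 10))
        with pytest.raises(RoiBoundsError, match="right"):
            extract_roi_patch(frame, (190, 100))

    def test_fan_rejection(self):
        frame = UltrasoundFrame(pixels=np.zeros((400, 500), dtype=np.uint8))
        with pytest.raises(RoiBoundsError, match="fan"):
            extract_roi_patch(frame, (40, 40))  # corner, outside the fan

    def test_patch_mean_matches_loop(self, rng):
        pixels = rng.integers(0, 256, (200, 200)).astype(np.uint8)
        frame = wide_frame(pixels)
        patch = extract_roi_patch(frame, (90, 110))
        total = 0.0
        for r in range(110 - 32, 110 + 32):
            for c in range(90 - 32, 90 + 32):
                total += pixels[r, c]
        assert patch.mean() == pytest.approx(total / 4096)

    def test_record_polar_consistency(self):
        frame = wide_frame()
        rec = make_roi_record(frame, "P1", 1, 1, (90, 110))
        rho, theta, _ = cartesian_to_polar((90, 110), frame)
        assert rec.center_polar == (rho, theta)
        assert rec.side_px == 64 and rec.patch.shape == (64, 64)


class TestIo:
    def test_roi_table_round_trip(self, tmp_path):
        frame = wide_frame()
        recs = [
            make_roi_record(frame, f"P{i}", 1, 2, (90 + i, 110 - i))
            for i in range(3)
        ]
        table = uio.roi_records_to_table(recs)
        path = tmp_path / "rois.csv"
        uio.write_roi_table(table, path)
        back = uio.read_roi_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_empty_table_round_trip(self, tmp_path):
        table = uio.roi_records_to_table([])
        path = tmp_path / "empty.csv"
        uio.write_roi_table(table, path)
        back = uio.read_roi_table(path)
        assert len(back) == 0
        assert list(back.columns) == list(table.columns)

    def test_malformed_rows_report_line_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,expert_id,iteration,x,y,rho,theta\n"
            "P1,1,1,10,20,1.0,0.5\n"
            "P2,not_an_int,1,10,20,1.0,0.5\n"
            "P3,1,1,10,20\n"
        )
        with pytest.raises(uio.RoiTableError) as err:
            uio.read_roi_table(path)
        assert "line 3" in str(err.value) and "line 4" in str(err.value)

    def test_png_round_trip(self, tmp_path, rng):
        pixels = rng.integers(0, 256, (50, 60)).astype(np.uint8)
        path = tmp_path / "frame.png"
        uio.write_frame_png(pixels, path)
        back = uio.read_frame_image(path)
        np.testing.assert_array_equal(back, pixels)

    def test_rejects_non_grayscale(self, tmp_path):
        from PIL import Image

        path = tmp_path / "rgb.png"
        Image.new("RGB", (10, 10), (255, 0, 0)).save(path)
        with pytest.raises(ValueError, match="grayscale"):
            uio.read_frame_image(path)
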