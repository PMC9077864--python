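"""TIFF round trips, channel selection, ROI geometry and statistics."""

import numpy as np
import pytest
import tifffile

from clodscan import (
    ROISpec,
    ScanConfig,
    ScanImage,
    default_material,
    extract_channel,
    read_scan,
    render_scan,
    roi_stats,
    roi_window,
    write_scan,
)
from clodscan.errors import BoundsError, ConfigurationError, DomainError, FormatError


@pytest.fixture
def rgb_image(rng):
    pixels = rng.integers(0, 2**16, size=(50, 60, 3), dtype=np.uint16)
    return ScanImage(pixels=pixels, dpi=300.0, bit_depth=16, channels=("red", "green", "blue"))


class TestReadWrite:
    def test_tiff_round_trip_preserves_pixels_and_dpi(self, tmp_path, rgb_image):
        path = write_scan(rgb_image, tmp_path / "scan.tiff", manifest={"k": 1})
        back = read_scan(path)
        assert np.array_equal(back.pixels, rgb_image.pixels)
        assert back.dpi == pytest.approx(300.0)
        assert back.bit_depth == 16
        assert (tmp_path / "scan.json").exists()

    def test_eight_bit_fixture(self, tmp_path, rng):
        pixels = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        img = ScanImage(pixels=pixels, dpi=150.0, bit_depth=8, channels=("gray",))
        back = read_scan(write_scan(img, tmp_path / "g.tiff"))
        assert back.bit_depth == 8
        assert back.pixels.max() <= 255
        assert back.channels == ("gray",)

    def test_generated_scan_keeps_dpi_tag(self, tmp_path, geometry, truth):
        img, man = render_scan(
            [0.25], geometry, default_material("OG"), ScanConfig(seed=1), truth
        )
        back = read_scan(write_scan(img, tmp_path / "s.tiff", man))
        assert back.dpi == pytest.approx(300.0)

    def test_missing_resolution_needs_override(self, tmp_path, rng):
        path = tmp_path / "notag.tiff"
        arr = rng.integers(0, 2**16, size=(10, 10), dtype=np.uint16)
        tifffile.imwrite(path, arr)  # no resolution tags
        with pytest.raises(ConfigurationError):
            read_scan(path)
        assert read_scan(path, dpi=300.0).dpi == 300.0

    def test_unsupported_sample_format_rejected(self, tmp_path):
        path = tmp_path / "f32.tiff"
        tifffile.imwrite(path, np.zeros((5, 5), dtype=np.float32))
        with pytest.raises(FormatError):
            read_scan(path, dpi=300.0)


class TestExtractChannel:
    def test_red_is_first_plane(self, rgb_image):
        red = extract_channel(rgb_image, "red")
        assert np.array_equal(red.pixels, rgb_image.pixels[:, :, 0])
        assert red.channels == ("red",)

    def test_grayscale_identity(self, rng):
        img = ScanImage(
            pixels=rng.integers(0, 255, (8, 8), dtype=np.uint8),
            dpi=300.0, bit_depth=8, channels=("gray",),
        )
        assert extract_channel(img, "red") is img

    def test_unknown_channel_rejected(self, rgb_image):
        with pytest.raises(DomainError):
            extract_channel(rgb_image, "alpha")

    def test_dose_signal_lives_in_red(self, geometry, truth, quiet_material):
        img, man = render_scan(
            [0.5], geometry, quiet_material, ScanConfig(seed=2), truth,
            disable_noise=True,
        )
        win = roi_window(
            ROISpec(tuple(man["footprints"][0]["center_mm"])),
            img.dpi, img.pixels.shape[:2],
        )
        red = roi_stats(extract_channel(img, "red"), win)
        green = roi_stats(extract_channel(img, "green"), win)
        assert red.mean < green.mean  # darkening only in the analysis channel


class TestROIWindow:
    @pytest.mark.parametrize(
        "side_mm,dpi,expected_px",
        [
            (3.5, 300.0, 41),        # 41.34 -> 41
            (25.4 / 300 * 40, 300.0, 40),  # exact 40-pixel side
            (3.5, 150.0, 21),        # 20.67 -> 21
        ],
    )
    def test_side_rounding(self, side_mm, dpi, expected_px):
        _, _, h, w = roi_window(ROISpec((20.0, 20.0), side_mm), dpi)
        assert h == w == expected_px

    def test_forced_even_side(self):
        _, _, h, w = roi_window(ROISpec((20.0, 20.0), 3.5), 300.0, force_side_px=40)
        assert h == w == 40

    def test_window_area_close_to_requested(self):
        spec = ROISpec((20.0, 20.0), 3.5)
        _, _, h, w = roi_window(spec, 300.0)
        pitch = 25.4 / 300.0
        assert abs(h * pitch - spec.side_mm) < pitch

    def test_window_clipped_by_edge_rejected(self):
        with pytest.raises(BoundsError):
            roi_window(ROISpec((1.0, 1.0), 3.5), 300.0, image_shape=(100, 100))


class TestROIStats:
    def test_constant_region(self):
        arr = np.full((10, 10), 40000, dtype=np.uint16)
        st = roi_stats(arr, (0, 0, 10, 10))
        assert (st.mean, st.sd, st.cv) == (40000.0, 0.0, 0.0)
        assert st.n_pixels == 100

    def test_hand_computed_sample_sd(self):
        arr = np.array([[1, 2], [3, 4]], dtype=np.uint16)
        st = roi_stats(arr, (0, 0, 2, 2))
        assert st.mean == pytest.approx(2.5)
        assert st.sd == pytest.approx(np.sqrt(5.0 / 3.0))  # N-1 denominator
        assert st.cv == pytest.approx(np.sqrt(5.0 / 3.0) / 2.5)

    def test_cv_is_sd_over_mean(self, rng):
        arr = rng.normal(40000, 400, (41, 41)).astype(np.uint16)
        st = roi_stats(arr, (0, 0, 41, 41))
        assert st.cv == pytest.approx(st.sd / st.mean, rel=1e-12)

    def test_zero_mean_flags_cv(self):
        st = roi_stats(np.zeros((4, 4), dtype=np.uint16), (0, 0, 4, 4))
        assert np.isnan(st.cv)

    def test_union_reproducible_from_pooled_sufficient_statistics(self, rng):
        """Stats of two disjoint halves pool exactly into the full-window stats."""
        arr = rng.integers(100, 50000, size=(20, 40), dtype=np.uint16)
        left = roi_stats(arr, (0, 0, 20, 20))
        right = roi_stats(arr, (0, 20, 20, 20))
        whole = roi_stats(arr, (0, 0, 20, 40))
        n1, n2 = left.n_pixels, right.n_pixels
        pooled_mean = (n1 * left.mean + n2 * right.mean) / (n1 + n2)
        ss1 = (n1 - 1) * left.sd**2 + n1 * left.mean**2
        ss2 = (n2 - 1) * right.sd**2 + n2 * right.mean**2
        pooled_sd = np.sqrt(
            (ss1 + ss2 - (n1 + n2) * pooled_mean**2) / (n1 + n2 - 1)
        )
        assert whole.mean == pytest.approx(pooled_mean, rel=1e-12)
        assert whole.sd == pytest.approx(pooled_sd, rel=1e-9)
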