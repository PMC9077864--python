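"""Generator physics: gap profile, fringe visibility, ring law, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clodscan import (
    GroundTruthResponse,
    LensGeometry,
    MaterialSpec,
    ScanConfig,
    air_gap_profile,
    compute_netod,
    dark_ring_radius,
    default_material,
    dose_to_clean_pixel,
    fringe_visibility,
    render_scan,
    ring_modulation,
)
from clodscan.errors import DomainError, LayoutError


class TestAirGapProfile:
    def test_contact_point_has_zero_gap(self, geometry):
        assert air_gap_profile(0.0, geometry) == 0.0

    def test_closed_form_sphere_on_flat(self):
        # t = r^2 / (2R): 1 mm^2 / 16 mm = 1/16 mm = 62.5 um
        g = LensGeometry(base_curve_radius_mm=8.0, contact_radius_mm=6.0)
        assert air_gap_profile(1.0, g) == pytest.approx(62.5, rel=1e-12)

    def test_monotone_nondecreasing(self, geometry):
        r = np.linspace(0, geometry.contact_radius_mm, 1000)
        t = air_gap_profile(r, geometry)
        assert np.all(np.diff(t) >= 0)

    @pytest.mark.parametrize("r", [-0.1, 6.1])
    def test_radius_outside_footprint_rejected(self, geometry, r):
        with pytest.raises(DomainError):
            air_gap_profile(r, geometry)


class TestFringeVisibility:
    def test_perfect_index_match_kills_fringes(self):
        matched = MaterialSpec("matched", 1.5, 0.0)
        assert fringe_visibility(matched, n_glass=1.5, n_lens=1.5) == 0.0

    def test_air_gap_more_visible_than_optical_grease(self):
        v_air = fringe_visibility(default_material("air"))
        v_og = fringe_visibility(default_material("OG"))
        assert v_air > v_og > 0.0

    def test_visibility_shrinks_as_gap_index_approaches_neighbors(self):
        vs = [
            fringe_visibility(MaterialSpec("m", n, 0.0), 1.52, 1.50)
            for n in (1.0, 1.1, 1.2, 1.3, 1.4, 1.46, 1.50)
        ]
        assert all(a > b for a, b in zip(vs, vs[1:]))

    def test_symmetric_in_glass_and_lens(self):
        m = MaterialSpec("m", 1.2, 0.0)
        assert fringe_visibility(m, 1.52, 1.45) == pytest.approx(
            fringe_visibility(m, 1.45, 1.52), abs=0
        )

    def test_bounded_in_unit_interval(self):
        for n in np.linspace(1.0, 2.5, 31):
            v = fringe_visibility(MaterialSpec("m", float(n), 0.0))
            assert 0.0 <= v <= 1.0

    def test_subunity_index_rejected(self):
        with pytest.raises(DomainError):
            fringe_visibility(MaterialSpec("m", 1.2, 0.0), n_glass=0.9)


class TestRingModulation:
    def test_dark_contact_spot(self):
        # reflected-light half-wave shift: factor 1 - V at zero gap
        assert ring_modulation(0.0, 1.0, 630.0, 0.3) == pytest.approx(0.7)

    def test_no_modulation_without_visibility(self):
        t = np.linspace(0, 50, 200)
        assert np.all(ring_modulation(t, 1.0, 630.0, 0.0) == 1.0)

    def test_dark_fringe_at_half_wavelength_gap(self):
        # t = lambda/(2 n): full 2*pi round-trip phase -> again a minimum
        lam, n = 632.8, 1.0
        t_um = lam / (2.0 * n) * 1e-3
        assert ring_modulation(t_um, n, lam, 0.4) == pytest.approx(0.6, rel=1e-9)

    def test_first_dark_ring_radius_closed_form(self):
        # sqrt(m lambda R): 632.8 nm, R = 8 mm -> 71.2 um
        g = LensGeometry(base_curve_radius_mm=8.0, contact_radius_mm=6.0)
        r1 = dark_ring_radius(1, 632.8, g, n_gap=1.0)
        assert r1 == pytest.approx(np.sqrt(632.8e-9 * 8e-3) * 1e3, rel=1e-12)
        # consistency with the gap profile: the gap there is lambda/2
        t = air_gap_profile(r1, g)
        assert t == pytest.approx(632.8e-3 / 2.0, rel=1e-9)

    def test_visibility_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            ring_modulation(1.0, 1.0, 630.0, 1.2)


class TestDoseToCleanPixel:
    def test_zero_dose_returns_unexposed_level(self, truth):
        assert dose_to_clean_pixel(0.0, truth) == pytest.approx(40000.0)

    def test_forward_model_closed_form(self, truth):
        # netOD* = 0.3 + 0.1 = 0.4 at 1 Gy -> 1000 + 39000 * 10^-0.4
        expected = 1000.0 + 39000.0 * 10.0 ** (-0.4)
        assert dose_to_clean_pixel(1.0, truth) == pytest.approx(expected, rel=1e-12)

    def test_reflective_mode_scales_netod_by_gain(self, truth):
        m_t = dose_to_clean_pixel(0.5, truth, mode="transmission")
        m_r = dose_to_clean_pixel(0.5, truth, mode="reflective")
        ratio = compute_netod(40000, m_r, 1000) / compute_netod(40000, m_t, 1000)
        assert ratio == pytest.approx(truth.mode_gain, rel=1e-9)

    def test_negative_dose_rejected(self, truth):
        with pytest.raises(DomainError):
            dose_to_clean_pixel(-0.1, truth)

    @settings(max_examples=50, deadline=None)
    @given(
        dose=st.floats(0.0, 2.0),
        a=st.floats(0.01, 1.0),
        b=st.floats(0.0, 0.5),
        n=st.floats(0.5, 3.0),
    )
    def test_netod_round_trip_is_exact(self, dose, a, b, n):
        """Generator and analyzer are exact inverses at the pixel level."""
        truth = GroundTruthResponse(lin_coeff=a, pow_coeff=b, exponent=n)
        m_exp = dose_to_clean_pixel(dose, truth)
        recovered = compute_netod(40000.0, m_exp, 1000.0)
        assert recovered == pytest.approx(truth.true_netod(dose), abs=1e-12)


class TestRenderScan:
    def test_same_seed_renders_identical_images(self, geometry, truth):
        mat = default_material("air")
        cfg = ScanConfig(seed=1)
        img1, _ = render_scan([0.25, 0.7], geometry, mat, cfg, truth)
        img2, _ = render_scan([0.25, 0.7], geometry, mat, cfg, truth)
        assert np.array_equal(img1.pixels, img2.pixels)
        img3, _ = render_scan(
            [0.25, 0.7], geometry, mat, ScanConfig(seed=2), truth
        )
        assert not np.array_equal(img1.pixels, img3.pixels)

    def test_degenerate_render_equals_clean_forward_model(
        self, geometry, truth, quiet_material, scan_config
    ):
        """Noise off, rings off: every footprint pixel is the clean value."""
        img, man = render_scan(
            [0.5],
            geometry,
            quiet_material,
            scan_config,
            truth,
            disable_rings=True,
            disable_noise=True,
            placement_jitter_mm=0.0,
            gap_offset_sd_um=0.0,
        )
        clean = dose_to_clean_pixel(0.5, truth)
        cx, cy = man["footprints"][0]["center_mm"]
        pitch = 25.4 / img.dpi
        red = img.pixels[:, :, 0]
        row = int(cy / pitch)
        cols = red[row, :].astype(float)
        inside = cols[np.abs((np.arange(cols.size) + 0.5) * pitch - cx) < 4.0]
        assert np.all(inside == np.rint(clean))

    def test_manifest_reports_true_netod(self, geometry, truth, quiet_material):
        _, man = render_scan(
            [0.0, 0.25], geometry, quiet_material, ScanConfig(seed=3), truth
        )
        assert [f["dose_gy"] for f in man["footprints"]] == [0.0, 0.25]
        assert man["footprints"][0]["true_netod"] == 0.0
        assert man["footprints"][1]["true_netod"] == pytest.approx(
            truth.true_netod(0.25)
        )
        assert man["background_center_mm"] is not None

    def test_overlapping_footprints_rejected(self, geometry, truth, quiet_material):
        with pytest.raises(LayoutError):
            render_scan(
                [0.1, 0.2],
                geometry,
                quiet_material,
                ScanConfig(seed=1),
                truth,
                centers_mm=[(8.0, 8.0), (9.0, 8.0)],
            )

    def test_empty_dose_list_rejected(self, geometry, truth, quiet_material):
        with pytest.raises(DomainError):
            render_scan([], geometry, quiet_material, ScanConfig(seed=1), truth)

    def test_roi_sd_increases_with_fringe_visibility(self, geometry, truth):
        """At fixed noise, stronger fringes widen the in-footprint spread."""
        from clodscan import ROISpec, extract_channel, roi_stats, roi_window

        sds = []
        for n_gap in (1.46, 1.2, 1.0):  # increasing mismatch -> increasing V
            mat = MaterialSpec("m", n_gap, pixel_noise_sd=100.0)
            img, man = render_scan(
                [0.25], geometry, mat, ScanConfig(seed=5), truth
            )
            red = extract_channel(img, "red")
            win = roi_window(
                ROISpec(tuple(man["footprints"][0]["center_mm"])),
                img.dpi,
                red.pixels.shape,
            )
            sds.append(roi_stats(red, win).sd)
        assert sds[0] < sds[1] < sds[2]
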